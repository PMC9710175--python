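import numpy as np
import pytest

from metapatch.geometry import build_geometry
from metapatch.lattice import ModelConfig
from metapatch.synthetic import SyntheticParams
from metapatch.tradeoff import TradeoffParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Small lattice for fast kernel-level checks."""
    return ModelConfig(width=20, height=20, burn_in=50, sample_steps=20,
                       rng_seed=7)


@pytest.fixture
def default_params():
    return TradeoffParams()


@pytest.fixture(scope="session")
def coarse_geometry():
    """85-motif patchy geometry at a coarse pixel pitch (fast to render)."""
    return build_geometry("patchy", pixel_pitch=7.168)


@pytest.fixture(scope="session")
def short_synth_params():
    """Short-horizon generator settings for render tests."""
    return SyntheticParams(horizon=6.0)
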