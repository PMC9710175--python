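"""Stochastic spatially explicit model of the competition-colonization trade-off.

Sites on a periodic 2D lattice are vacant, occupied by the superior
competitor, by the fast colonizer, or by both ("mixed": the two strategies
locked in an interference competition program).  Colonization of a site
depends on the state of its neighborhood; mixed sites neither die nor emit
colonizers and resolve by a competitive lottery with bias ``eta``.  The
asynchronous random-sequential scheme defines one time step as width*height
update attempts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from ._kernels import COLONIZER, COMPETITOR, MIXED, VACANT
from .tradeoff import TradeoffParams

__all__ = [
    "VACANT", "COMPETITOR", "COLONIZER", "MIXED",
    "ModelConfig", "LatticeState", "Trajectory",
    "seed_lattice", "neighborhood_density", "update_site", "step", "simulate",
]

_NEIGHBORHOODS = {"moore": K.MOORE, "von_neumann": K.VON_NEUMANN}


@dataclass(frozen=True)
class ModelConfig:
    """Lattice, scheduling and sampling configuration of a model run."""

    width: int = 100
    height: int = 100
    range_r: int = 1
    neighborhood: str = "moore"  # or "von_neumann"
    n_seed_each: int = 5
    burn_in: int = 100_000
    sample_steps: int = 1_000
    extinction_eps: float = 1e-3
    rng_seed: int = 0
    mixed_counts_both: bool = True  # mixed sites tallied into both densities
    # kernel-reconstruction knobs (defaults are the documented baseline):
    lock_resolution: float = 1.0    # lottery resolution prob per selection
    mixed_mortality: bool = False   # whether locked sites die like singles
    invasion_mode: str = "symmetric"  # or "shield_colonizer"

    def __post_init__(self) -> None:
        if not 0.0 < self.lock_resolution <= 1.0:
            raise ValueError("lock_resolution must lie in (0, 1]")
        if self.invasion_mode not in ("symmetric", "shield_colonizer"):
            raise ValueError(f"unknown invasion_mode {self.invasion_mode!r}")
        if self.width < 1 or self.height < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.neighborhood not in _NEIGHBORHOODS:
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.range_r < 1:
            raise ValueError("interaction range must be >= 1")
        if self.range_r >= min(self.width, self.height) / 2:
            raise ValueError("interaction range must be < half the lattice extent")
        if 2 * self.n_seed_each > self.width * self.height:
            raise ValueError("cannot seed more sites than the lattice holds")
        if not 0 <= self.extinction_eps < 1:
            raise ValueError("extinction_eps must lie in [0, 1)")

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    def replace(self, **kwargs) -> "ModelConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class LatticeState:
    """Grid of site states plus the number of completed time steps."""

    grid: np.ndarray
    step_count: int = 0

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy(), self.step_count)

    def densities(self, mixed_counts_both: bool = True) -> tuple[float, float]:
        """(rho_E, rho_P): colonizer and competitor densities."""
        counts = K.state_counts(self.grid)
        n = self.grid.size
        mix = counts[3] if mixed_counts_both else 0
        return (counts[2] + mix) / n, (counts[1] + mix) / n

    def state_fractions(self) -> np.ndarray:
        """Fractions (rho_0, rho_P, rho_E, rho_*) summing to one exactly."""
        return K.state_counts(self.grid) / self.grid.size


@dataclass
class Trajectory:
    """Sampled densities of a model run.

    ``rho_E`` / ``rho_P`` are colonizer / competitor densities per sampled
    step (mixed sites counted toward both by default); ``frac_col`` is the
    colonizer's fractional abundance rho_E / (rho_E + rho_P), NaN where both
    species are extinct.
    """

    times: np.ndarray
    rho_E: np.ndarray
    rho_P: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def frac_col(self) -> np.ndarray:
        tot = self.rho_E + self.rho_P
        out = np.full_like(tot, np.nan, dtype=float)
        np.divide(self.rho_E, tot, out=out, where=tot > 0)
        return out

    def mean_densities(self) -> tuple[float, float]:
        return float(self.rho_E.mean()), float(self.rho_P.mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"step": self.times, "rho_E": self.rho_E, "rho_P": self.rho_P,
             "frac_col": self.frac_col}
        )


def seed_lattice(config: ModelConfig,
                 rng: np.random.Generator | None = None) -> LatticeState:
    """Seed an empty lattice with ``n_seed_each`` sites per strategy.

    Sites are drawn uniformly without collision; reproducible from
    ``config.rng_seed`` when no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    grid = np.zeros((config.height, config.width), dtype=np.uint8)
    n = 2 * config.n_seed_each
    if n:
        flat = rng.choice(config.n_sites, size=n, replace=False)
        rows, cols = np.divmod(flat, config.width)
        grid[rows[: config.n_seed_each], cols[: config.n_seed_each]] = COMPETITOR
        grid[rows[config.n_seed_each:], cols[config.n_seed_each:]] = COLONIZER
    return LatticeState(grid)


def neighborhood_density(state: LatticeState, site: tuple[int, int],
                         species: int, r: int = 1,
                         neighborhood: str = "moore") -> float:
    """Fraction of the neighborhood of ``site`` singly occupied by ``species``.

    The neighborhood is the Chebyshev (Moore) or Manhattan (von Neumann)
    ball of radius ``r`` around the focal site, excluding it, with periodic
    wrap.  Mixed sites contribute zero: no dispersal takes place from sites
    locked in interference.
    """
    if species not in (COMPETITOR, COLONIZER):
        raise ValueError("species must be COMPETITOR or COLONIZER")
    h, w = state.grid.shape
    if r >= min(h, w) / 2:
        raise ValueError("interaction range must be < half the lattice extent")
    i, j = site
    if not (0 <= i < h and 0 <= j < w):
        raise ValueError(f"site {site} outside the lattice")
    n_comp, n_col, n_tot = K._neighbor_counts(
        state.grid, i, j, r, _NEIGHBORHOODS[neighborhood]
    )
    return (n_comp if species == COMPETITOR else n_col) / n_tot


def update_site(state: LatticeState, site: tuple[int, int],
                params: TradeoffParams, config: ModelConfig,
                rng: np.random.Generator) -> int:
    """One update attempt at ``site`` (in place); returns the new site state.

    Transition kernel: a vacant site is colonized by each species with
    probability beta * f (f the neighborhood density of that species), ties
    broken by a scramble lottery proportional to the firing weights; a singly
    occupied site dies with probability delta and is otherwise invaded to the
    mixed state with probability gamma * beta_other * f_other; a mixed site
    resolves to the competitor with probability eta, else to the colonizer.
    """
    i, j = site
    h, w = state.grid.shape
    if not (0 <= i < h and 0 <= j < w):
        raise ValueError(f"site {site} outside the lattice")
    K.attempt_update(
        state.grid, i, j, params.beta_comp, params.beta_col, params.gamma,
        params.delta, params.eta_effective, config.range_r,
        _NEIGHBORHOODS[config.neighborhood], config.lock_resolution,
        config.mixed_mortality, config.invasion_mode == "shield_colonizer",
        rng,
    )
    return int(state.grid[i, j])


def step(state: LatticeState, params: TradeoffParams, config: ModelConfig,
         rng: np.random.Generator, n_steps: int = 1) -> LatticeState:
    """Advance ``n_steps`` time steps (width*height attempts each), in place."""
    K.sweep(
        state.grid, n_steps, params.beta_comp, params.beta_col, params.gamma,
        params.delta, params.eta_effective, config.range_r,
        _NEIGHBORHOODS[config.neighborhood], config.lock_resolution,
        config.mixed_mortality, config.invasion_mode == "shield_colonizer",
        rng,
    )
    state.step_count += n_steps
    return state


def simulate(params: TradeoffParams, config: ModelConfig,
             rng: np.random.Generator | None = None) -> Trajectory:
    """Run burn-in then record densities over the sampling window.

    The model with delta > 0 on a finite lattice is eventually absorbed at
    the all-vacant state; the sampling window therefore measures the
    quasi-stationary regime reached after ``burn_in`` steps.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    state = seed_lattice(config, rng)
    n_comp, n_col, n_mix = K.run_trajectory(
        state.grid, config.burn_in, config.sample_steps, params.beta_comp,
        params.beta_col, params.gamma, params.delta, params.eta_effective,
        config.range_r, _NEIGHBORHOODS[config.neighborhood],
        config.lock_resolution, config.mixed_mortality,
        config.invasion_mode == "shield_colonizer", rng,
    )
    state.step_count = config.burn_in + config.sample_steps
    n = config.n_sites
    mix = n_mix if config.mixed_counts_both else np.zeros_like(n_mix)
    times = np.arange(config.burn_in + 1, config.burn_in + config.sample_steps + 1)
    return Trajectory(
        times=times,
        rho_E=(n_col + mix) / n,
        rho_P=(n_comp + mix) / n,
        meta={
            "params": params, "config": config,
            "final_state": state,
        },
    )
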