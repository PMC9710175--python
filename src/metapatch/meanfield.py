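"""Mean-field patch-occupancy analogue of the lattice model.

The classic hierarchical competition-colonization system for the fraction of
patches held by the superior competitor (p_K) and by the fast colonizer
(p_C):

    dp_K/dt = beta_comp * p_K * (1 - p_K) - delta * p_K
    dp_C/dt = beta_col * p_C * (1 - p_K - p_C) - delta * p_C
              - beta_comp * p_K * p_C

The competitor ignores the colonizer (strict hierarchy: it colonizes over
it), while the colonizer can only use patches empty of both and is displaced
wherever the competitor lands.  The resident competitor equilibrates at
p_K* = 1 - delta / beta_comp, and the colonizer invades that equilibrium iff
beta_col > beta_comp**2 / delta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .tradeoff import TradeoffParams

__all__ = ["patch_occupancy_ode", "resident_equilibrium", "can_invade",
           "MeanFieldResult"]


def resident_equilibrium(beta: float, delta: float) -> float:
    """Single-species equilibrium patch occupancy max(0, 1 - delta/beta)."""
    if beta <= 0:
        return 0.0
    return max(0.0, 1.0 - delta / beta)


def can_invade(beta_col: float, beta_comp: float, delta: float) -> bool:
    """Whether the colonizer grows when rare at the resident's equilibrium.

    Linearizing the colonizer equation at p_K = p_K* gives per-capita growth
    beta_col * delta / beta_comp - beta_comp, positive iff
    beta_col > beta_comp**2 / delta.
    """
    if resident_equilibrium(beta_comp, delta) == 0.0:
        # no resident to displace; invasion reduces to beta_col > delta
        return beta_col > delta
    if delta == 0.0:
        return False   # resident saturates every patch; no vacancies to take
    return beta_col > beta_comp**2 / delta


@dataclass
class MeanFieldResult:
    times: np.ndarray
    p_comp: np.ndarray
    p_col: np.ndarray
    resident_eq: float
    invasion_possible: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "p_comp": self.p_comp,
                             "p_col": self.p_col})


def patch_occupancy_ode(params: TradeoffParams,
                        p0: tuple[float, float] = (0.01, 0.01),
                        horizon: float = 500.0,
                        n_points: int = 501) -> MeanFieldResult:
    """Integrate the two-species patch-occupancy system.

    Parameters
    ----------
    params:
        Trade-off parameters; only beta_comp, beta_col and delta enter.
    p0:
        Initial fractions (p_comp, p_col); both >= 0 with sum <= 1.
    horizon, n_points:
        Integration horizon (model time) and number of reported points.
    """
    pK0, pC0 = p0
    if pK0 < 0 or pC0 < 0:
        raise ValueError("initial fractions must be >= 0")
    if pK0 + pC0 > 1 + 1e-12:
        raise ValueError("initial fractions must sum to <= 1")
    bK, bC, d = params.beta_comp, params.beta_col, params.delta
    if d == 0 and (bK > 0 or bC > 0):
        warnings.warn("delta = 0: occupancies fix at 1 with no turnover",
                      stacklevel=2)

    def rhs(_t, y):
        pK, pC = y
        return [bK * pK * (1 - pK) - d * pK,
                bC * pC * (1 - pK - pC) - d * pC - bK * pK * pC]

    times = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(rhs, (0.0, horizon), [pK0, pC0], t_eval=times,
                    method="LSODA", rtol=1e-8, atol=1e-10)
    return MeanFieldResult(
        times=sol.t, p_comp=sol.y[0], p_col=sol.y[1],
        resident_eq=resident_equilibrium(bK, d),
        invasion_possible=can_invade(bC, bK, d),
    )
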