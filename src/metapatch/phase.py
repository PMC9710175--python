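"""Phase structure of the lattice model over the (1 - delta_beta) x gamma plane.

Long-term behavior falls into three phases: *scramble* (only the colonizer
survives), *coexistence* (both persist) and *interference* (the competitor
wins); with both species below the extinction threshold the lattice is
*extinct*.  ``phase_scan`` sweeps the parameter plane, one quasi-stationary
simulation per grid cell, and estimates the critical boundaries
delta_beta* and delta_beta** (along the gamma = 1 row) and gamma_c (along
the smallest-delta_beta column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import ModelConfig, simulate
from .tradeoff import TradeoffParams

__all__ = ["classify_phase", "phase_scan", "PhaseMap",
           "SCRAMBLE", "COEXISTENCE", "INTERFERENCE", "EXTINCT"]

SCRAMBLE = "scramble"
COEXISTENCE = "coexistence"
INTERFERENCE = "interference"
EXTINCT = "extinct"


def classify_phase(mean_rho_E: float, mean_rho_P: float,
                   extinction_eps: float = 1e-3) -> str:
    """Label a run from its window-mean densities and extinction threshold."""
    if not (0 <= mean_rho_E <= 1 and 0 <= mean_rho_P <= 1):
        raise ValueError("densities must lie in [0, 1]")
    col_alive = mean_rho_E > extinction_eps
    comp_alive = mean_rho_P > extinction_eps
    if col_alive and comp_alive:
        return COEXISTENCE
    if col_alive:
        return SCRAMBLE
    if comp_alive:
        return INTERFERENCE
    return EXTINCT


@dataclass
class PhaseMap:
    """Result of a parameter-plane sweep.

    ``axis_comp_rate`` holds the (1 - delta_beta) grid values (the
    competitor's colonization rate), ``axis_gamma`` the priority-effect
    values.  ``mean_frac_col`` and ``phase_label`` are (n_gamma, n_rate)
    arrays indexed [gamma, rate].
    """

    axis_comp_rate: np.ndarray
    axis_gamma: np.ndarray
    mean_frac_col: np.ndarray
    mean_rho_E: np.ndarray
    mean_rho_P: np.ndarray
    phase_label: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        g, r = np.meshgrid(self.axis_gamma, self.axis_comp_rate, indexing="ij")
        return pd.DataFrame({
            "one_minus_delta_beta": r.ravel(),
            "gamma": g.ravel(),
            "mean_frac_col": self.mean_frac_col.ravel(),
            "mean_rho_E": self.mean_rho_E.ravel(),
            "mean_rho_P": self.mean_rho_P.ravel(),
            "phase": self.phase_label.ravel(),
        })

    def critical_delta_beta(self) -> dict:
        """delta_beta* / delta_beta** estimates along the gamma = 1 row.

        Boundaries are midpoints between adjacent cells whose labels differ;
        the half grid spacing is the quoted uncertainty.  Along increasing
        delta_beta the expected ordering is interference -> coexistence
        (delta_beta**) then coexistence -> scramble (delta_beta*).
        """
        row = int(np.argmax(self.axis_gamma))
        labels = self.phase_label[row]
        rates = self.axis_comp_rate
        d_beta = 1.0 - rates
        order = np.argsort(d_beta)
        d_beta, labels = d_beta[order], labels[order]
        out = {"delta_beta_star": np.nan, "delta_beta_star2": np.nan,
               "resolution": _resolution(d_beta)}
        for a, b in zip(range(len(d_beta) - 1), range(1, len(d_beta))):
            la, lb = labels[a], labels[b]
            mid = 0.5 * (d_beta[a] + d_beta[b])
            if la == INTERFERENCE and lb != INTERFERENCE and np.isnan(out["delta_beta_star2"]):
                out["delta_beta_star2"] = mid
            if la != SCRAMBLE and lb == SCRAMBLE and np.isnan(out["delta_beta_star"]):
                out["delta_beta_star"] = mid
        return out

    def critical_gamma(self) -> dict:
        """gamma_c estimate along the near-neutral (largest 1 - delta_beta) column."""
        col = int(np.argmax(self.axis_comp_rate))
        labels = self.phase_label[:, col]
        gam = self.axis_gamma
        order = np.argsort(gam)
        gam, labels = gam[order], labels[order]
        out = {"gamma_c": np.nan, "resolution": _resolution(gam)}
        for a in range(len(gam) - 1):
            if (labels[a] == EXTINCT) != (labels[a + 1] == EXTINCT):
                out["gamma_c"] = 0.5 * (gam[a] + gam[a + 1])
                break
        return out


def _resolution(axis: np.ndarray) -> float:
    return float(np.diff(np.sort(axis)).mean() / 2) if len(axis) > 1 else np.nan


def phase_scan(comp_rates: np.ndarray, gammas: np.ndarray,
               params: TradeoffParams, config: ModelConfig) -> PhaseMap:
    """One simulation + phase classification per (1 - delta_beta, gamma) cell.

    Each cell gets an independent child seed spawned from
    ``config.rng_seed`` so the map is reproducible bit for bit.
    """
    comp_rates = np.asarray(comp_rates, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    if comp_rates.min() < 0 or comp_rates.max() > 1 or \
            gammas.min() < 0 or gammas.max() > 1:
        raise ValueError("axis grids must lie within [0, 1]")
    shape = (len(gammas), len(comp_rates))
    frac = np.full(shape, np.nan)
    rho_E = np.zeros(shape)
    rho_P = np.zeros(shape)
    labels = np.empty(shape, dtype=object)
    seeds = np.random.SeedSequence(config.rng_seed).spawn(len(gammas) * len(comp_rates))
    for gi, gamma in enumerate(gammas):
        for ri, rate in enumerate(comp_rates):
            p = params.replace(delta_beta=1.0 - rate, gamma=gamma)
            rng = np.random.default_rng(seeds[gi * len(comp_rates) + ri])
            traj = simulate(p, config, rng=rng)
            mE, mP = traj.mean_densities()
            rho_E[gi, ri], rho_P[gi, ri] = mE, mP
            if mE + mP > 0:
                frac[gi, ri] = mE / (mE + mP)
            labels[gi, ri] = classify_phase(mE, mP, config.extinction_eps)
    return PhaseMap(
        axis_comp_rate=comp_rates, axis_gamma=gammas, mean_frac_col=frac,
        mean_rho_E=rho_E, mean_rho_P=rho_P, phase_label=labels,
        meta={"params": params, "config": config},
    )
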