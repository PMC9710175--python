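"""Landscape-scale statistics: ecotope partitions, correlations, state maps.

Occupancy tables from many landscapes are partitioned into *ecotopes*
(patches and corridors, real in patchy devices or virtual masks on flat
strips).  Per ecotope, the paired colonizer/competitor occupancy series
yield a Pearson coefficient; the population of coefficients is summarized
by variance, skewness and a bimodality verdict.  Long-term community states
are binned into a 2D density map over (1 - Theta, Z_half), and per-landscape
trajectories into an hourly ensemble histogram of the colonizer share.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .pipeline import OccupancyTable, spatial_average

__all__ = [
    "EcotopeSeries", "StateDensityMap", "TrajectoryEnsemble",
    "partition_ecotopes", "ecotope_pearson", "distribution_summary",
    "state_density_map", "trajectory_ensemble",
]


@dataclass
class EcotopeSeries:
    """Paired E/P occupancy time series within one ecotope mask."""

    landscape: int | str
    kind: str            # patch | corridor | virtual_patch | virtual_corridor
    index: int           # 1-based position along the chain
    E: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.E.shape != self.P.shape:
            raise ValueError("E and P series must have equal length")


def partition_ecotopes(tables: Sequence[OccupancyTable],
                       virtual: bool = False,
                       n_expected: int = 85) -> tuple[list[EcotopeSeries], dict]:
    """Split per-landscape occupancy tables into per-ecotope series.

    Every landscape must carry ``n_expected`` patch series and, if corridor
    occupancies are present, the same number of corridor series.  Returns
    the series list and a count per ecotope kind
    (= n_landscapes x n_expected).
    """
    series: list[EcotopeSeries] = []
    counts: dict[str, int] = {}
    p_kind = "virtual_patch" if virtual else "patch"
    c_kind = "virtual_corridor" if virtual else "corridor"
    for table in tables:
        if table.n_patches != n_expected:
            raise ValueError(
                f"landscape {table.landscape}: {table.n_patches} patch masks, "
                f"expected {n_expected}")
        for k in range(table.n_patches):
            series.append(EcotopeSeries(table.landscape, p_kind, k + 1,
                                        table.E[k], table.P[k]))
            counts[p_kind] = counts.get(p_kind, 0) + 1
        if table.corridor_E is not None:
            if table.corridor_E.shape[0] != n_expected:
                raise ValueError(
                    f"landscape {table.landscape}: corridor mask count "
                    f"{table.corridor_E.shape[0]} != {n_expected}")
            for k in range(n_expected):
                series.append(EcotopeSeries(table.landscape, c_kind, k + 1,
                                            table.corridor_E[k],
                                            table.corridor_P[k]))
                counts[c_kind] = counts.get(c_kind, 0) + 1
    return series, counts


def ecotope_pearson(series: EcotopeSeries,
                    window: tuple[float, float] | None = None,
                    times: np.ndarray | None = None) -> float:
    """Pearson r between the E and P series of one ecotope.

    ``window`` (same units as ``times``) restricts the comparison, e.g. to
    skip the empty pre-colonization period.  Zero-variance series give NaN
    (excluded from distributions downstream) rather than an error.
    """
    E, P = series.E, series.P
    if window is not None:
        if times is None:
            times = np.arange(len(E), dtype=float)
        keep = (times >= window[0]) & (times <= window[1])
        E, P = E[keep], P[keep]
    if len(E) < 3:
        raise ValueError("need at least 3 time points")
    if np.std(E) == 0 or np.std(P) == 0:
        return float("nan")
    return float(sps.pearsonr(E, P).statistic)


@dataclass
class DistributionSummary:
    n: int
    variance: float
    skewness: float          # adjusted Fisher-Pearson
    bimodal: bool
    bic_margin: float        # BIC(1 component) - BIC(2 components)

    def to_dict(self) -> dict:
        return {"n": self.n, "variance": self.variance,
                "skewness": self.skewness, "bimodal": self.bimodal,
                "bic_margin": self.bic_margin}


def distribution_summary(values: np.ndarray, bic_margin: float = 10.0,
                         min_weight: float = 0.01, ashman_d: float = 2.0,
                         random_state: int = 0) -> DistributionSummary:
    """Variance, adjusted skewness and a mixture-based bimodality verdict.

    Bimodality is decided on a 1- vs 2-component Gaussian mixture fit.  The
    sample is called bimodal when all three hold: the 2-component fit
    improves BIC by more than ``bic_margin``; the components are cleanly
    separated (Ashman's D = |mu1 - mu2| / sqrt((s1^2 + s2^2)/2) above
    ``ashman_d``, the classical threshold for a visible dip); and the minor
    component carries at least ``min_weight`` of the mass.  The separation
    and weight conditions keep a skewed or heavy-tailed unimodal sample from
    qualifying.
    """
    from sklearn.mixture import GaussianMixture

    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 30:
        raise ValueError(f"need >= 30 non-missing values, got {vals.size}")
    x = vals.reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=random_state).fit(x)
    g2 = GaussianMixture(2, random_state=random_state, n_init=3).fit(x)
    margin = g1.bic(x) - g2.bic(x)
    mu = g2.means_.ravel()
    var = g2.covariances_.ravel()
    d = abs(mu[0] - mu[1]) / np.sqrt((var[0] + var[1]) / 2.0)
    w_min = float(g2.weights_.min())
    return DistributionSummary(
        n=int(vals.size),
        variance=float(np.var(vals, ddof=1)),
        skewness=float(sps.skew(vals, bias=False)),
        bimodal=bool(margin > bic_margin and d > ashman_d
                     and w_min >= min_weight),
        bic_margin=float(margin),
    )


@dataclass
class StateDensityMap:
    """2D histogram of long-term local community states.

    x = colonizer share (1 - Theta) in [0, 1]; y = normalized total
    occupancy Z (half-sum dialect) in [0, 1].
    """

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    n_samples: int
    n_dropped: int

    def peak(self) -> tuple[float, float]:
        """(x, y) center of the most populated bin."""
        i, j = np.unravel_index(np.argmax(self.counts), self.counts.shape)
        return (float((self.x_edges[i] + self.x_edges[i + 1]) / 2),
                float((self.y_edges[j] + self.y_edges[j + 1]) / 2))

    def mass_near(self, x: float, y: float, radius: float = 0.1) -> float:
        """Fraction of samples within a square of half-side ``radius``."""
        xc = (self.x_edges[:-1] + self.x_edges[1:]) / 2
        yc = (self.y_edges[:-1] + self.y_edges[1:]) / 2
        keep = (np.abs(xc[:, None] - x) <= radius) & (np.abs(yc[None, :] - y) <= radius)
        return float(self.counts[keep].sum() / max(self.counts.sum(), 1))


def state_density_map(E, P, bins: int = 50) -> StateDensityMap:
    """Bin local community states {(1 - Theta), Z_half} over [0, 1]^2.

    Patches with E + P = 0 have no defined composition and are dropped;
    counts conserve the number of retained samples.
    """
    E = np.asarray(E, dtype=float).ravel()
    P = np.asarray(P, dtype=float).ravel()
    tot = E + P
    keep = tot > 0
    x = E[keep] / tot[keep]
    y = tot[keep] / 2.0
    counts, xe, ye = np.histogram2d(x, y, bins=bins, range=[[0, 1], [0, 1]])
    return StateDensityMap(counts=counts, x_edges=xe, y_edges=ye,
                           n_samples=int(keep.sum()),
                           n_dropped=int((~keep).sum()))


@dataclass
class TrajectoryEnsemble:
    """Hourly histogram ensemble of landscape-mean colonizer share."""

    hour_edges: np.ndarray          # (n_hours + 1,)
    frac_edges: np.ndarray          # (n_bins + 1,)
    counts: np.ndarray              # (n_hours, n_bins)
    configurations_per_hour: np.ndarray
    n_total: int


def trajectory_ensemble(tables: Sequence[OccupancyTable],
                        horizon_h: float = 48.0,
                        bins: int = 40,
                        n_expected: int = 85) -> TrajectoryEnsemble:
    """Hourly-binned ensemble of (1 - Theta_s) = Ebar_s / (Ebar_s + Pbar_s).

    Each (landscape, frame) pair contributes one configuration to the bin
    floor(t / 1 h); frames with Ebar + Pbar = 0 are excluded.  At a 10-min
    frame interval, each hour collects 6 frames per landscape.
    """
    n_hours = int(np.ceil(horizon_h))
    hour_edges = np.arange(n_hours + 1, dtype=float)
    frac_edges = np.linspace(0.0, 1.0, bins + 1)
    counts = np.zeros((n_hours, bins))
    per_hour = np.zeros(n_hours, dtype=int)
    n_total = 0
    for table in tables:
        Eb, Pb = spatial_average(table, n_expected=n_expected)
        t_h = np.asarray(table.times_min, dtype=float) / 60.0
        tot = Eb + Pb
        ok = (tot > 0) & (t_h < horizon_h)
        frac = Eb[ok] / tot[ok]
        hrs = np.floor(t_h[ok]).astype(int)
        for h, f in zip(hrs, frac):
            b = min(int(f * bins), bins - 1)
            counts[h, b] += 1
            per_hour[h] += 1
            n_total += 1
    return TrajectoryEnsemble(hour_edges=hour_edges, frac_edges=frac_edges,
                              counts=counts,
                              configurations_per_hour=per_hour,
                              n_total=n_total)
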