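"""Synthetic landscapes: succession dynamics with ground truth and rendered images.

A phenomenological generator (deliberately independent of the lattice
model) emulating the observed colonization narrative in the microfluidic
devices: a fast, low-density colonizer wave sweeps the patch chain first;
within-patch logistic growth follows; a dense competitor front enters after
a delay and advances patch by patch, halted at corridors blocked by
colonizer aggregates; wherever the front arrives, succession replaces the
colonizer.  The generator emits exact per-patch/per-corridor occupancy
tables (ground truth) and can render them into two-channel image stacks
with autofluorescence background, so the whole measurement pipeline can be
validated against known truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .geometry import LandscapeGeometry, build_geometry
from .pipeline import ImageStack, OccupancyTable

__all__ = ["SyntheticParams", "BlockageEvent", "GroundTruth",
           "simulate_succession", "render_images", "build_geometry"]


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic succession generator.

    Rates are per hour, occupancies in [0, 1]; defaults reproduce the
    experimental narrative: the colonizer wave traverses the 85 patches in
    ~7 h at low density and grows locally over tens of hours (~35% local
    occupancy some 15 h after inoculation); the competitor front enters
    after ~12 h, advances at ~8 patches/h and dominates the chain within a
    day unless corridor blockages fragment it, in which case the colonizer
    keeps maturing in the cut-off patches and the landscape-scale
    competitor share relaxes after its peak.
    """

    wave_speed: float = 12.0          # colonizer wave, patches/h
    wave_amplitude: float = 0.05      # occupancy left by the passing wave
    growth_rate: float = 0.15         # colonizer within-patch logistic rate, 1/h
    competitor_growth_rate: float = 0.8   # competitor local logistic rate, 1/h
    carrying_occupancy: float = 0.8   # colonizer local carrying occupancy
    entry_delay: float = 12.0         # competitor entry delay, h
    front_speed: float = 10.0         # competitor front, patches/h
    front_occupancy: float = 0.9      # competitor local carrying occupancy
    succession_rate: float = 1.0      # colonizer decay after invasion, 1/h
    succession_floor: float = 0.25    # residual colonizer fraction of carrying
    p_block: float = 0.03             # per-corridor blockage probability
    block_duration_mean: float = 2.0  # breakthrough delay once the front waits, h
    p_block_permanent: float = 0.2    # fraction of blockages never released
    corridor_passage: float = 0.5     # corridor occupancy / adjacent patch
    block_occupancy: float = 0.9      # colonizer occupancy of a blocked corridor
    block_fill_rate: float = 1.0      # aggregation rate in a blocked corridor, 1/h
    corridor_traffic_noise: float = 1.0   # relative SD of corridor wave traffic
    occupancy_jitter: float = 0.01    # SD of occupancy noise (zeros preserved)
    bg_mean: float = 100.0            # autofluorescence background, a.u.
    bg_sd: float = 5.0
    foreground_amplitude: float = 400.0   # added intensity of occupied pixels
    frame_interval: float = 10.0      # minutes
    horizon: float = 48.0             # hours
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("wave_speed", "growth_rate", "front_speed",
                     "succession_rate", "block_duration_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("wave_amplitude", "carrying_occupancy", "front_occupancy",
                     "p_block", "p_block_permanent", "corridor_passage",
                     "block_occupancy", "succession_floor"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def replace(self, **kwargs) -> "SyntheticParams":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class BlockageEvent:
    corridor: int        # 1-based corridor index
    start: float         # h; when the colonizer wave reaches the corridor
    duration: float      # h; inf = permanent


@dataclass
class GroundTruth:
    """Exact occupancy tables and event log behind a rendered landscape."""

    E: np.ndarray                     # (K, T) colonizer patch occupancy
    P: np.ndarray                     # (K, T) competitor patch occupancy
    corridor_E: np.ndarray            # (K, T)
    corridor_P: np.ndarray
    times_h: np.ndarray               # (T,)
    colonizer_arrival: np.ndarray     # (K,) h
    competitor_arrival: np.ndarray    # (K,) h; inf if never reached
    blockages: list[BlockageEvent]
    params: SyntheticParams
    landscape: int | str = 0

    def to_table(self) -> OccupancyTable:
        return OccupancyTable(
            E=self.E, P=self.P, times_min=self.times_h * 60.0,
            landscape=self.landscape,
            corridor_E=self.corridor_E, corridor_P=self.corridor_P,
            meta={"source": "synthetic ground truth"},
        )

    def event_log_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(b) for b in self.blockages], fh, indent=1)


def _logistic(t_since, start_level, carrying, rate):
    """Logistic rise from start_level toward carrying; 0 before arrival."""
    if carrying <= 0 or start_level <= 0:
        return np.zeros_like(t_since)
    ratio = carrying / start_level - 1.0
    with np.errstate(over="ignore"):
        val = carrying / (1.0 + ratio * np.exp(-rate * t_since))
    return np.where(t_since >= 0, val, 0.0)


def simulate_succession(params: SyntheticParams,
                        geometry: LandscapeGeometry,
                        rng: np.random.Generator | None = None,
                        landscape: int | str = 0) -> GroundTruth:
    """Generate per-patch / per-corridor occupancy dynamics for one landscape.

    Colonizer: patch k is reached at k / wave_speed at occupancy
    ``wave_amplitude``, grows logistically toward ``carrying_occupancy``,
    and decays at ``succession_rate`` once the competitor arrives.
    Competitor: the front enters after ``entry_delay`` and advances one
    patch per 1/front_speed hours, waiting out any blocked corridor;
    occupancy grows logistically toward ``front_occupancy``.  In flat
    (virtual-mask) geometries blockage is disabled: there are no physical
    corridors to jam.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    K = geometry.n_patches
    n_frames = int(round(params.horizon * 60.0 / params.frame_interval)) + 1
    t = np.arange(n_frames) * params.frame_interval / 60.0   # hours

    if params.wave_speed <= 0 or params.front_speed <= 0:
        import warnings

        warnings.warn("zero wave/front speed: species never arrive",
                      stacklevel=2)

    k_idx = np.arange(1, K + 1)
    t_col = (k_idx / params.wave_speed if params.wave_speed > 0
             else np.full(K, np.inf))

    # corridor blockages (physical corridors only): the colonizer aggregates
    # in a blocked corridor as its wave passes, and the jam holds until the
    # competitor front, once it reaches the corridor, breaks through after a
    # further Exp-distributed delay (or never, for permanent fragmentation)
    blocked = np.zeros(K, dtype=bool)
    hold = np.zeros(K)               # breakthrough delay once the front arrives
    if geometry.kind == "patchy" and params.p_block > 0:
        blocked = rng.random(K) < params.p_block
        permanent = rng.random(K) < params.p_block_permanent
        durations = rng.exponential(params.block_duration_mean, size=K)
        hold = np.where(permanent, math.inf, durations)

    # competitor front arrival per patch, gated by blocked corridors
    t_comp = np.full(K, np.inf)
    block_release = np.full(K, np.inf)   # when corridor k opens to the front
    blockages: list[BlockageEvent] = []
    if params.front_speed > 0:
        hop = 1.0 / params.front_speed
        arrival = params.entry_delay + hop
        for k in range(K):
            t_comp[k] = arrival
            # corridor k gates passage to patch k+1
            depart = arrival + (hold[k] if blocked[k] else 0.0)
            if not blocked[k]:
                block_release[k] = arrival      # front passes immediately
            elif math.isfinite(depart):
                block_release[k] = depart
            if not math.isfinite(depart):
                break
            arrival = depart + hop
    for j in np.nonzero(blocked)[0]:
        start = float(t_col[j])      # aggregation as the colonizer wave passes
        blockages.append(BlockageEvent(
            int(j + 1), start,
            float(block_release[j] - start) if math.isfinite(block_release[j])
            else math.inf))

    E = np.zeros((K, n_frames))
    P = np.zeros((K, n_frames))
    for k in range(K):
        dt_col = t - t_col[k]
        E[k] = _logistic(dt_col, params.wave_amplitude,
                         params.carrying_occupancy, params.growth_rate)
        if np.isfinite(t_comp[k]):
            dt_comp = t - t_comp[k]
            P[k] = _logistic(dt_comp, params.wave_amplitude,
                             params.front_occupancy,
                             params.competitor_growth_rate)
            # succession: colonizer decays toward a residual coexistence
            # floor once the competitor is present
            e_at = _logistic(np.array([t_comp[k] - t_col[k]]),
                             params.wave_amplitude,
                             params.carrying_occupancy,
                             params.growth_rate)[0]
            floor = params.succession_floor * params.carrying_occupancy
            floor = min(floor, e_at)
            decayed = floor + (e_at - floor) * np.exp(
                -params.succession_rate * np.maximum(dt_comp, 0.0))
            E[k] = np.where(dt_comp >= 0, decayed, E[k])

    # corridors: stochastic wave traffic scaled to the adjacent patches;
    # blocked corridors instead carry a deterministic colonizer jam that
    # excludes the competitor until release
    cE = np.zeros((K, n_frames))
    cP = np.zeros((K, n_frames))
    noise = params.corridor_traffic_noise
    for k in range(K):
        down = E[k + 1] if k + 1 < K else np.zeros(n_frames)
        base_E = params.corridor_passage * 0.5 * (E[k] + down)
        downP = P[k + 1] if k + 1 < K else np.zeros(n_frames)
        base_P = params.corridor_passage * 0.5 * (P[k] + downP)
        if noise > 0:
            cE[k] = base_E * (1.0 + rng.normal(0.0, noise, n_frames))
            cP[k] = base_P * (1.0 + rng.normal(0.0, noise, n_frames))
        else:
            cE[k], cP[k] = base_E, base_P
    for b in blockages:
        j = b.corridor - 1
        release = b.start + b.duration
        filling = _logistic(t - b.start, params.wave_amplitude,
                            params.block_occupancy, params.block_fill_rate)
        if math.isfinite(release):
            after = t >= release
            fill_at_release = _logistic(
                np.array([release - b.start]), params.wave_amplitude,
                params.block_occupancy, params.block_fill_rate)[0]
            decay = fill_at_release * np.exp(
                -params.succession_rate * np.maximum(t - release, 0.0))
            cE[j] = np.where(after, decay, filling)
            cP[j] = np.where(after, cP[j], 0.0)
        else:
            cE[j] = filling
            cP[j] = 0.0

    if params.occupancy_jitter > 0:
        # measurement-scale fluctuation on occupied ecotopes; true zeros
        # (species absent) stay exactly zero
        for arr in (E, P, cE, cP):
            jit = rng.normal(0.0, params.occupancy_jitter, size=arr.shape)
            arr += np.where(arr > 0, jit, 0.0)
    np.clip(E, 0.0, 1.0, out=E)
    np.clip(P, 0.0, 1.0, out=P)
    np.clip(cE, 0.0, 1.0, out=cE)
    np.clip(cP, 0.0, 1.0, out=cP)

    return GroundTruth(E=E, P=P, corridor_E=cE, corridor_P=cP, times_h=t,
                       colonizer_arrival=t_col, competitor_arrival=t_comp,
                       blockages=blockages, params=params,
                       landscape=landscape)


def render_images(truth: GroundTruth, geometry: LandscapeGeometry,
                  params: SyntheticParams | None = None,
                  rng: np.random.Generator | None = None,
                  dtype=np.float32) -> tuple[ImageStack, GroundTruth]:
    """Render ground truth into a two-channel stack; returns (stack, quantized).

    Per frame and channel, every pixel carries Gaussian autofluorescence
    background; within each patch/corridor ROI, round(occupancy * n_pixels)
    randomly placed pixels additionally carry the foreground amplitude.  The
    second return value is the ground truth with occupancies quantized to
    the rendered pixel counts (the best any pixel-level pipeline can
    recover).
    """
    params = params or truth.params
    if rng is None:
        rng = np.random.default_rng(params.rng_seed + 1)
    K, T = truth.E.shape
    if K != geometry.n_patches:
        raise ValueError("ground truth and geometry disagree on patch count")
    H, W = geometry.shape
    frames = np.empty((T, 2, H, W), dtype=dtype)
    rois = list(geometry.patch_rois) + list(geometry.corridor_rois)
    occ_by_channel = (np.vstack([truth.E, truth.corridor_E]),   # channel 0: E
                      np.vstack([truth.P, truth.corridor_P]))   # channel 1: P
    quantized = [np.zeros_like(o) for o in occ_by_channel]
    for tix in range(T):
        for ch in (0, 1):
            if params.bg_sd > 0:
                img = rng.normal(params.bg_mean, params.bg_sd,
                                 size=(H, W)).astype(dtype)
            else:
                img = np.full((H, W), params.bg_mean, dtype=dtype)
            occ = occ_by_channel[ch]
            for ridx, roi in enumerate(rois):
                n_occ = int(round(occ[ridx, tix] * roi.n_pixels))
                quantized[ch][ridx, tix] = n_occ / roi.n_pixels
                if n_occ == 0:
                    continue
                flat = rng.choice(roi.n_pixels, size=n_occ, replace=False)
                sub = img[roi.slices].reshape(-1)
                sub[flat] += params.foreground_amplitude
                img[roi.slices] = sub.reshape(roi.y1 - roi.y0, roi.x1 - roi.x0)
            frames[tix, ch] = img
    stack = ImageStack(
        frames=frames, channel_species=("colonizer", "competitor"),
        pixel_area=geometry.pixel_area,
        frame_interval=params.frame_interval,
        meta={"synthetic": True, "rng_seed": params.rng_seed},
    )
    qt = GroundTruth(
        E=quantized[0][:K], P=quantized[1][:K],
        corridor_E=quantized[0][K:], corridor_P=quantized[1][K:],
        times_h=truth.times_h, colonizer_arrival=truth.colonizer_arrival,
        competitor_arrival=truth.competitor_arrival,
        blockages=truth.blockages, params=params, landscape=truth.landscape,
    )
    return stack, qt
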