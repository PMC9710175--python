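"""Two-channel time-lapse images -> per-patch occupancy and derived statistics.

Fluorescence intensity is a poor biomass proxy, so every frame is reduced to
binary pixel occupancy: after background correction, a pixel counts as
occupied by a strain when its intensity exceeds that channel's
autofluorescence threshold (mean + k*SD of a cell-free control sample).
Per-patch occupancy is the occupied fraction of the patch mask, normalized
per channel to [0, 1]; from the competitor occupancy P_k and colonizer
occupancy E_k follow the fractional occupancy Theta_k = P_k / (E_k + P_k),
the total occupancy Z_k (sum and half-sum dialects) and the spatial and
ensemble averages used at the landscape scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .geometry import LandscapeGeometry

__all__ = [
    "ImageStack", "OccupancyTable", "FractionalOccupancy",
    "background_correct", "autofluorescence_threshold", "binarize",
    "patch_occupancy", "fractional_occupancy", "spatial_average",
    "ensemble_average", "kymograph", "process_stack",
]


@dataclass
class ImageStack:
    """Time-ordered two-channel frames with physical calibration.

    ``frames`` has shape (T, 2, H, W); ``channel_species`` declares which
    species each channel reports, supporting both the green-red and
    red-green strain pairings (e.g. ``("colonizer", "competitor")`` maps
    channel 0 to E and channel 1 to P).
    """

    frames: np.ndarray
    channel_species: tuple[str, str] = ("colonizer", "competitor")
    pixel_area: float = 0.803          # um^2 per pixel
    frame_interval: float = 10.0       # minutes
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[1] != 2:
            raise ValueError("frames must have shape (T, 2, H, W)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if sorted(self.channel_species) != ["colonizer", "competitor"]:
            raise ValueError(
                "channel_species must name 'colonizer' and 'competitor'")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def channel(self, species: str) -> int:
        return self.channel_species.index(species)

    def swapped_channels(self) -> "ImageStack":
        """Same pixels with the opposite channel -> species declaration."""
        return ImageStack(self.frames,
                          channel_species=self.channel_species[::-1],
                          pixel_area=self.pixel_area,
                          frame_interval=self.frame_interval,
                          meta=dict(self.meta))


def background_correct(frame: np.ndarray, radius: int = 25) -> np.ndarray:
    """Subtract a slowly varying background estimated by grayscale opening.

    A flat structuring element of side ``2*radius + 1`` (much larger than a
    cell footprint) erodes then dilates the frame, producing a background
    surface that follows illumination gradients but cannot climb onto
    cell-scale peaks; the corrected frame is clipped at zero.  Applying the
    correction twice is a near no-op since the background of a corrected
    frame is ~0.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2D array")
    size = 2 * int(radius) + 1
    if size > max(frame.shape):
        raise ValueError(
            f"filter size {size} exceeds frame extent {frame.shape}")
    background = ndimage.grey_opening(frame, size=(min(size, frame.shape[0]),
                                                   min(size, frame.shape[1])),
                                      mode="nearest")
    return np.clip(frame - background, 0.0, None)


def autofluorescence_threshold(control_pixels: np.ndarray,
                               k_sigma: float = 3.0) -> float:
    """Per-channel occupancy threshold: mean + k_sigma * SD of a control sample.

    The control sample comes from a cell-free region or a pre-inoculation
    frame of the same channel, after the same background correction.
    """
    control = np.asarray(control_pixels, dtype=np.float64).ravel()
    if control.size < 100:
        raise ValueError(
            f"need >= 100 control pixels, got {control.size}")
    if not np.all(np.isfinite(control)):
        raise ValueError("control sample contains non-finite values")
    return float(control.mean() + k_sigma * control.std())


def binarize(frame: np.ndarray, threshold: float) -> np.ndarray:
    """Pixel occupancy: 1 where intensity is strictly above the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (np.asarray(frame) > threshold).astype(np.uint8)


def patch_occupancy(binary: np.ndarray,
                    geometry: LandscapeGeometry,
                    which: str = "patch") -> np.ndarray:
    """Occupied-pixel fraction of every patch (or corridor) mask of one frame."""
    rois = geometry.patch_rois if which == "patch" else geometry.corridor_rois
    out = np.empty(len(rois))
    for idx, roi in enumerate(rois):
        sub = roi.crop(binary)
        out[idx] = np.count_nonzero(sub) / roi.n_pixels
    return out


class FractionalOccupancy(NamedTuple):
    theta: float          # competitor share P/(E+P); NaN when E+P = 0
    one_minus_theta: float
    z_sum: float          # total occupancy E+P, in [0, 2]
    z_half: float         # normalized total (E+P)/2, in [0, 1]


def fractional_occupancy(E, P) -> FractionalOccupancy:
    """Theta, 1-Theta and the two total-occupancy dialects, elementwise.

    Theta is undefined (NaN, never 0) at empty communities E + P = 0 and is
    excluded from averages downstream.
    """
    scalar = np.isscalar(E) and np.isscalar(P)
    E = np.asarray(E, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any((E < 0) | (E > 1)) or np.any((P < 0) | (P > 1)):
        raise ValueError("occupancies must lie in [0, 1]")
    tot = E + P
    theta = np.full(np.broadcast(E, P).shape, np.nan)
    np.divide(P, tot, out=theta, where=tot > 0)
    if scalar:
        return FractionalOccupancy(float(theta), float(1.0 - theta),
                                   float(tot), float(tot) / 2.0)
    return FractionalOccupancy(theta, 1.0 - theta, tot, tot / 2.0)


@dataclass
class OccupancyTable:
    """Per-patch, per-frame occupancies E[k, t], P[k, t] for one landscape."""

    E: np.ndarray                     # (K, T) colonizer occupancy
    P: np.ndarray                     # (K, T) competitor occupancy
    times_min: np.ndarray             # (T,)
    landscape: int | str = 0
    corridor_E: np.ndarray | None = None
    corridor_P: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.E.shape != self.P.shape or self.E.ndim != 2:
            raise ValueError("E and P must be equal-shape (K, T) arrays")
        if len(self.times_min) != self.E.shape[1]:
            raise ValueError("times length must match the frame axis")

    @property
    def n_patches(self) -> int:
        return self.E.shape[0]

    @property
    def n_frames(self) -> int:
        return self.E.shape[1]

    def theta(self) -> np.ndarray:
        """Competitor fractional occupancy Theta[k, t]; NaN where E+P = 0."""
        return fractional_occupancy(self.E, self.P).theta

    def z(self, dialect: str = "half") -> np.ndarray:
        fo = fractional_occupancy(self.E, self.P)
        if dialect == "half":
            return fo.z_half
        if dialect == "sum":
            return fo.z_sum
        raise ValueError("dialect must be 'half' or 'sum'")

    def to_frame(self):
        import pandas as pd

        K, T = self.E.shape
        fo = fractional_occupancy(self.E, self.P)
        return pd.DataFrame({
            "landscape": np.repeat(self.landscape, K * T),
            "patch": np.repeat(np.arange(1, K + 1), T),
            "time_min": np.tile(self.times_min, K),
            "E": self.E.ravel(), "P": self.P.ravel(),
            "theta": np.asarray(fo.theta).ravel(),
            "Z_sum": fo.z_sum.ravel(), "Z_half": fo.z_half.ravel(),
        })

    @classmethod
    def from_frame(cls, df) -> "OccupancyTable":
        df = df.sort_values(["patch", "time_min"])
        patches = df["patch"].unique()
        times = np.sort(df["time_min"].unique())
        K, T = len(patches), len(times)
        return cls(E=df["E"].to_numpy().reshape(K, T),
                   P=df["P"].to_numpy().reshape(K, T),
                   times_min=times.astype(float),
                   landscape=df["landscape"].iloc[0])


def spatial_average(table: OccupancyTable,
                    allow_partial: bool = False,
                    n_expected: int = 85) -> tuple[np.ndarray, np.ndarray]:
    """Landscape means Ebar(t), Pbar(t) = (1/K) sum_k over all patches."""
    if table.n_patches != n_expected and not allow_partial:
        raise ValueError(
            f"expected {n_expected} patches, got {table.n_patches}; "
            "pass allow_partial=True for partial landscapes")
    return table.E.mean(axis=0), table.P.mean(axis=0)


def ensemble_average(spatial_means: Sequence[tuple[np.ndarray, np.ndarray]]
                     ) -> np.ndarray:
    """Ensemble Theta(t): mean over landscapes of Pbar / (Ebar + Pbar).

    Landscapes with Ebar + Pbar = 0 at a time point are excluded from that
    point; the result is NaN where no landscape contributes.
    """
    if not spatial_means:
        raise ValueError("need at least one landscape")
    n_t = len(spatial_means[0][0])
    for Eb, Pb in spatial_means:
        if len(Eb) != n_t or len(Pb) != n_t:
            raise ValueError("landscapes must share a common time base")
    thetas = np.full((len(spatial_means), n_t), np.nan)
    for s, (Eb, Pb) in enumerate(spatial_means):
        tot = np.asarray(Eb) + np.asarray(Pb)
        np.divide(Pb, tot, out=thetas[s], where=tot > 0)
    out = np.full(n_t, np.nan)
    any_defined = ~np.all(np.isnan(thetas), axis=0)
    out[any_defined] = np.nanmean(thetas[:, any_defined], axis=0)
    return out


def kymograph(table: OccupancyTable, species: str = "colonizer") -> np.ndarray:
    """Patch x time occupancy matrix (row k = patch k, no smoothing)."""
    if species in ("colonizer", "E"):
        return table.E.copy()
    if species in ("competitor", "P"):
        return table.P.copy()
    raise ValueError("species must be 'colonizer' or 'competitor'")


def process_stack(stack: ImageStack, geometry: LandscapeGeometry,
                  k_sigma: float = 3.0, background_radius: int = 25,
                  control: str | np.ndarray = "first_frame",
                  landscape: int | str = 0,
                  correct_background: bool = True) -> OccupancyTable:
    """Full pipeline: stack -> background correction -> threshold -> occupancy.

    Parameters
    ----------
    control:
        ``"first_frame"`` uses the (pre-colonization) first frame of each
        channel as the autofluorescence control; alternatively pass an
        explicit (2, n) array of control pixel samples per channel.
    """
    use_virtual = geometry.kind == "flat"
    ch_E = stack.channel("colonizer")
    ch_P = stack.channel("competitor")
    thresholds = {}
    binaries = {}
    for ch in (ch_E, ch_P):
        corrected0 = (background_correct(stack.frames[0, ch], background_radius)
                      if correct_background else
                      np.asarray(stack.frames[0, ch], dtype=float))
        if isinstance(control, str):
            if control != "first_frame":
                raise ValueError(f"unknown control spec {control!r}")
            sample = corrected0[geometry.habitat_mask()]
        else:
            sample = np.asarray(control)[ch]
        thresholds[ch] = autofluorescence_threshold(sample, k_sigma)

    K = geometry.n_patches
    T = stack.n_frames
    E = np.empty((K, T))
    P = np.empty((K, T))
    cE = np.empty((len(geometry.corridor_rois), T))
    cP = np.empty((len(geometry.corridor_rois), T))
    for t in range(T):
        for ch, patch_out, corr_out in ((ch_E, E, cE), (ch_P, P, cP)):
            frame = (background_correct(stack.frames[t, ch], background_radius)
                     if correct_background else
                     np.asarray(stack.frames[t, ch], dtype=float))
            binary = binarize(frame, thresholds[ch])
            patch_out[:, t] = patch_occupancy(binary, geometry, "patch")
            corr_out[:, t] = patch_occupancy(binary, geometry, "corridor")
    return OccupancyTable(
        E=E, P=P, times_min=stack.times_min, landscape=landscape,
        corridor_E=cE, corridor_P=cP,
        meta={"thresholds": {"colonizer": thresholds[ch_E],
                             "competitor": thresholds[ch_P]},
              "k_sigma": k_sigma, "background_radius": background_radius,
              "virtual_masks": use_virtual},
    )
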