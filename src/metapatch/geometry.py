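"""Landscape geometries: patch/corridor pixel masks with physical calibration.

The patchy device is a linear chain of 85 patch-corridor motifs: habitat
patches of 100 x 100 um connected by 50 x 5 um corridors, imaged at a pixel
pitch of 0.896 um (pixel area 0.803 um^2).  The flat device is a single
12750 x 100 um strip of the same total length; *virtual* patch and corridor
masks tile the patchy motif footprint onto it so the same per-ecotope
statistics can be computed in both.

Patch index k = 1 sits at the competitor-inoculated (left) inlet; pixel
coordinates are 0-based, row-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ROI", "LandscapeGeometry", "build_geometry", "virtual_masks",
           "PATCH_UM", "CORRIDOR_UM", "MOTIF_UM", "STRIP_UM", "N_MOTIFS",
           "DEFAULT_PIXEL_PITCH"]

N_MOTIFS = 85
PATCH_UM = (100.0, 100.0)      # length x height of one patch
CORRIDOR_UM = (50.0, 5.0)      # length x height of one corridor
MOTIF_UM = PATCH_UM[0] + CORRIDOR_UM[0]          # 150 um
STRIP_UM = (N_MOTIFS * MOTIF_UM, 100.0)          # 12750 x 100 um
DEFAULT_PIXEL_PITCH = 0.896    # um per pixel side; pixel area ~0.803 um^2


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangular pixel region [y0, y1) x [x0, x1)."""

    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if self.y1 <= self.y0 or self.x1 <= self.x0:
            raise ValueError(f"empty ROI {self}")

    @property
    def n_pixels(self) -> int:
        return (self.y1 - self.y0) * (self.x1 - self.x0)

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def crop(self, frame: np.ndarray) -> np.ndarray:
        if self.y1 > frame.shape[-2] or self.x1 > frame.shape[-1]:
            raise ValueError(f"ROI {self} exceeds frame bounds {frame.shape}")
        return frame[..., self.y0:self.y1, self.x0:self.x1]

    def overlaps(self, other: "ROI") -> bool:
        return not (self.x1 <= other.x0 or other.x1 <= self.x0
                    or self.y1 <= other.y0 or other.y1 <= self.y0)

    def to_dict(self) -> dict:
        return {"y0": self.y0, "y1": self.y1, "x0": self.x0, "x1": self.x1}


@dataclass
class LandscapeGeometry:
    """Pixel masks for one landscape plus physical calibration.

    ``patch_rois`` / ``corridor_rois`` are ordered k = 1..85 from the
    competitor inlet; for ``kind='flat'`` they are virtual masks laid over
    the strip (``strip_roi``).
    """

    kind: str                      # "patchy" | "flat"
    shape: tuple[int, int]         # full frame (H, W)
    patch_rois: list[ROI]
    corridor_rois: list[ROI]
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    strip_roi: ROI | None = None
    virtual: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("patchy", "flat"):
            raise ValueError(f"unknown landscape kind {self.kind!r}")
        rois = self.patch_rois + self.corridor_rois
        for a in range(len(rois)):
            for b in range(a + 1, len(rois)):
                if rois[a].overlaps(rois[b]):
                    raise ValueError("patch/corridor masks must be pairwise disjoint")

    @property
    def n_patches(self) -> int:
        return len(self.patch_rois)

    @property
    def pixel_area(self) -> float:
        return self.pixel_pitch**2

    def habitat_mask(self) -> np.ndarray:
        """Boolean mask of all habitat pixels (strip, or patches + corridors)."""
        m = np.zeros(self.shape, dtype=bool)
        if self.kind == "flat" and self.strip_roi is not None:
            m[self.strip_roi.slices] = True
        else:
            for roi in self.patch_rois + self.corridor_rois:
                m[roi.slices] = True
        return m

    def to_label_image(self) -> np.ndarray:
        """Integer-coded mask: patch k -> k, corridor k -> 1000 + k, else 0."""
        lab = np.zeros(self.shape, dtype=np.int32)
        for k, roi in enumerate(self.patch_rois, start=1):
            lab[roi.slices] = k
        for k, roi in enumerate(self.corridor_rois, start=1):
            lab[roi.slices] = 1000 + k
        return lab

    def to_json(self, path) -> None:
        obj = {
            "kind": self.kind, "shape": list(self.shape),
            "pixel_pitch": self.pixel_pitch, "virtual": self.virtual,
            "patch_rois": [r.to_dict() for r in self.patch_rois],
            "corridor_rois": [r.to_dict() for r in self.corridor_rois],
            "strip_roi": self.strip_roi.to_dict() if self.strip_roi else None,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LandscapeGeometry":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            kind=obj["kind"], shape=tuple(obj["shape"]),
            patch_rois=[ROI(**r) for r in obj["patch_rois"]],
            corridor_rois=[ROI(**r) for r in obj["corridor_rois"]],
            pixel_pitch=obj["pixel_pitch"],
            strip_roi=ROI(**obj["strip_roi"]) if obj.get("strip_roi") else None,
            virtual=obj.get("virtual", False), meta=obj.get("meta", {}),
        )

    @classmethod
    def from_label_image(cls, label: np.ndarray, kind: str = "patchy",
                         pixel_pitch: float = DEFAULT_PIXEL_PITCH) -> "LandscapeGeometry":
        """Rebuild a geometry from an integer-coded mask (bounding boxes)."""
        def boxes(codes):
            out = []
            for c in codes:
                ys, xs = np.nonzero(label == c)
                out.append(ROI(int(ys.min()), int(ys.max()) + 1,
                               int(xs.min()), int(xs.max()) + 1))
            return out

        codes = np.unique(label)
        patch_codes = sorted(c for c in codes if 0 < c < 1000)
        corr_codes = sorted(c for c in codes if c >= 1000)
        return cls(kind=kind, shape=label.shape,
                   patch_rois=boxes(patch_codes),
                   corridor_rois=boxes(corr_codes), pixel_pitch=pixel_pitch)


def _px(um: float, pitch: float) -> int:
    return max(1, round(um / pitch))


def build_geometry(kind: str = "patchy",
                   pixel_pitch: float = DEFAULT_PIXEL_PITCH,
                   n_motifs: int = N_MOTIFS) -> LandscapeGeometry:
    """Pixel-resolved landscape geometry of the microfluidic devices.

    Parameters
    ----------
    kind:
        ``"patchy"`` (patch-corridor chain) or ``"flat"`` (single strip,
        with virtual masks attached via :func:`virtual_masks`).
    pixel_pitch:
        Micrometers per pixel side.  The default reproduces the microscope
        calibration (0.803 um^2 pixels); larger values give scaled-down
        geometries for fast tests.
    n_motifs:
        Number of patch-corridor repetitions (85 in the devices).
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be > 0")
    patch_w, patch_h = _px(PATCH_UM[0], pixel_pitch), _px(PATCH_UM[1], pixel_pitch)
    corr_w, corr_h = _px(CORRIDOR_UM[0], pixel_pitch), _px(CORRIDOR_UM[1], pixel_pitch)
    height = patch_h
    width = n_motifs * (patch_w + corr_w)
    y_corr0 = (height - corr_h) // 2   # corridor centered on the strip axis
    patch_rois, corridor_rois = [], []
    for k in range(n_motifs):
        x = k * (patch_w + corr_w)
        patch_rois.append(ROI(0, patch_h, x, x + patch_w))
        corridor_rois.append(
            ROI(y_corr0, y_corr0 + corr_h, x + patch_w, x + patch_w + corr_w))
    if kind == "patchy":
        return LandscapeGeometry(
            kind="patchy", shape=(height, width), patch_rois=patch_rois,
            corridor_rois=corridor_rois, pixel_pitch=pixel_pitch,
            meta={"n_motifs": n_motifs})
    if kind == "flat":
        return LandscapeGeometry(
            kind="flat", shape=(height, width), patch_rois=patch_rois,
            corridor_rois=corridor_rois, pixel_pitch=pixel_pitch,
            strip_roi=ROI(0, height, 0, width), virtual=True,
            meta={"n_motifs": n_motifs})
    raise ValueError(f"unknown landscape kind {kind!r}")


def virtual_masks(flat_geometry: LandscapeGeometry,
                  n_motifs: int = N_MOTIFS) -> LandscapeGeometry:
    """Tile virtual patch + corridor masks onto a flat strip.

    The patchy motif footprint (100 um patch followed by a 50 x 5 um
    corridor centered on the strip axis) is repeated along the strip; the
    strip must be long enough for ``n_motifs`` repetitions.
    """
    if flat_geometry.kind != "flat" or flat_geometry.strip_roi is None:
        raise ValueError("virtual masks require a flat-strip geometry")
    strip = flat_geometry.strip_roi
    pitch = flat_geometry.pixel_pitch
    motif_px = _px(PATCH_UM[0], pitch) + _px(CORRIDOR_UM[0], pitch)
    if strip.x1 - strip.x0 < n_motifs * motif_px:
        raise ValueError(
            f"strip of {strip.x1 - strip.x0} px cannot hold {n_motifs} motifs "
            f"of {motif_px} px")
    g = build_geometry("flat", pixel_pitch=pitch, n_motifs=n_motifs)
    g.shape = flat_geometry.shape
    g.strip_roi = strip
    return g
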