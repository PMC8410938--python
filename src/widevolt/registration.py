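"""Vessel masking, atlas registration, and region-averaged voltage traces.

Cortical regions (S1FL, S1HL, S1BF, M1, M2) are defined as millimetre
polygons relative to bregma, following the stereotaxic-atlas parcellation of
the dorsal cortex, and registered rigidly to each imaging window using the
annotated bregma pixel and the orientation of the interhemispheric fissure
(midline).  No inter-animal scaling is applied.

Coordinate convention (used everywhere in this package): image row 0 is at
the top; atlas x is lateral (positive towards the imaged right hemisphere,
i.e. increasing column) and atlas y is positive rostral (decreasing row) when
the midline angle is zero.  A positive ``midline_angle_deg`` rotates the
atlas counter-clockwise in the image about bregma.

The packaged default polygons approximate the atlas parcellation; exact
vertex coordinates are lab-specific, so the layout is a first-class,
user-replaceable YAML input and the provenance records which layout was used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
import yaml
from matplotlib.path import Path as MplPath
from skimage.filters import threshold_otsu

from .preprocessing import RatioSequence

__all__ = [
    "AtlasLayout",
    "RegionTrace",
    "default_layout",
    "make_vessel_mask",
    "rasterize_atlas",
    "region_trace",
    "DEFAULT_REGIONS_MM",
]

# Approximate dorsal-cortex parcellation, mm relative to bregma
# (x lateral, y rostral), right hemisphere.  Rectangles keep the regions
# disjoint; users replace them with their own traced polygons via YAML.
DEFAULT_REGIONS_MM: dict[str, list[list[float]]] = {
    "M2": [[0.1, 0.6], [0.9, 0.6], [0.9, 2.0], [0.1, 2.0]],
    "M1": [[0.9, 0.2], [1.9, 0.2], [1.9, 1.9], [0.9, 1.9]],
    "S1FL": [[1.9, -0.5], [3.1, -0.5], [3.1, 0.9], [1.9, 0.9]],
    "S1HL": [[1.0, -1.3], [1.9, -1.3], [1.9, 0.0], [1.0, 0.0]],
    "S1BF": [[2.4, -2.0], [3.9, -2.0], [3.9, -0.7], [2.4, -0.7]],
}


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _self_intersects(verts: np.ndarray) -> bool:
    """Check a closed polygon for edge self-intersection (O(n^2), small n)."""

    def seg_cross(p, q, r, s) -> bool:
        def orient(a, b, c):
            v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

        return (
            orient(p, q, r) != orient(p, q, s)
            and orient(r, s, p) != orient(r, s, q)
            and orient(p, q, r) != 0
            and orient(r, s, p) != 0
        )

    n = len(verts)
    edges = [(verts[i], verts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent via closure
            if seg_cross(*edges[i], *edges[j]):
                return True
    return False


@dataclass
class AtlasLayout:
    """Named cortical regions as mm polygons anchored to bregma.

    ``bregma_px`` is (row, col) at the resolution the layout will be
    rasterised at; ``pixel_size_um`` is the pixel pitch at that resolution.
    """

    regions: dict[str, np.ndarray]
    bregma_px: tuple[float, float]
    midline_angle_deg: float = 0.0
    pixel_size_um: float = 14.55

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        regs: dict[str, np.ndarray] = {}
        for name, verts in self.regions.items():
            v = np.asarray(verts, dtype=float)
            if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
                raise ValueError(f"region {name!r}: polygon must be Nx2 with N>=3")
            if _self_intersects(v):
                raise ValueError(f"region {name!r}: polygon self-intersects")
            regs[name] = v
        self.regions = regs
        self.bregma_px = (float(self.bregma_px[0]), float(self.bregma_px[1]))

    # -- geometry ---------------------------------------------------------
    def mm_to_px(self, verts_mm: np.ndarray) -> np.ndarray:
        """Map (x lateral, y rostral) mm vertices to (row, col) pixels."""
        v = np.asarray(verts_mm, dtype=float)
        a = np.deg2rad(self.midline_angle_deg)
        scale = 1000.0 / self.pixel_size_um  # px per mm
        x, y = v[:, 0] * scale, v[:, 1] * scale
        dcol = x * np.cos(a) + y * np.sin(a)
        drow = x * np.sin(a) - y * np.cos(a)
        return np.column_stack(
            [self.bregma_px[0] + drow, self.bregma_px[1] + dcol]
        )

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path: str | FsPath) -> None:
        doc = {
            "coordinate_convention": "x lateral (+col at angle 0), y rostral (-row); row 0 top",
            "regions": {k: v.tolist() for k, v in self.regions.items()},
            "bregma_px": list(self.bregma_px),
            "midline_angle_deg": float(self.midline_angle_deg),
            "pixel_size_um": float(self.pixel_size_um),
        }
        FsPath(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | FsPath) -> "AtlasLayout":
        doc = yaml.safe_load(FsPath(path).read_text())
        return cls(
            regions={k: np.asarray(v, dtype=float) for k, v in doc["regions"].items()},
            bregma_px=tuple(doc["bregma_px"]),
            midline_angle_deg=float(doc.get("midline_angle_deg", 0.0)),
            pixel_size_um=float(doc["pixel_size_um"]),
        )


def default_layout(
    bregma_px: tuple[float, float],
    pixel_size_um: float = 14.55,
    midline_angle_deg: float = 0.0,
) -> AtlasLayout:
    """Packaged approximate parcellation (S1FL, S1HL, S1BF, M1, M2)."""
    return AtlasLayout(
        regions={k: np.asarray(v) for k, v in DEFAULT_REGIONS_MM.items()},
        bregma_px=bregma_px,
        midline_angle_deg=midline_angle_deg,
        pixel_size_um=pixel_size_um,
    )


@dataclass
class RegionTrace:
    """Spatially averaged %dR/R time course of one registered region."""

    region: str
    drr: np.ndarray  # (n_frames,) %dR/R
    frame_rate: float
    stim_indices: tuple[int, ...]  # 0-based frame indices of stimuli
    n_pixels: int

    @property
    def time_ms(self) -> np.ndarray:
        """Time axis in ms relative to the first stimulus."""
        idx = np.arange(len(self.drr))
        return (idx - self.stim_indices[0]) * 1000.0 / self.frame_rate


def make_vessel_mask(
    raw_donor_frame: np.ndarray,
    method: str = "fixed",
    threshold: float | None = None,
) -> np.ndarray:
    """Binarise a raw (lit) donor frame; True marks excluded dark pixels.

    Blood vessels and window imperfections appear dark against the bright
    indicator fluorescence; pixels below the threshold are excluded from all
    further computation.  ``method='otsu'`` derives the threshold from the
    frame, but only applies it when the frame is genuinely bimodal (the dark
    class mean below half the bright class mean) — on a vessel-free frame
    Otsu would otherwise split the noise distribution and discard half the
    window.  ``'fixed'`` uses the supplied counts value (the lab's
    empirically fixed binarisation threshold).
    """
    frame = np.asarray(raw_donor_frame, dtype=float)
    if method == "otsu":
        thr = float(threshold_otsu(frame))
        dark = frame < thr
        if dark.any() and frame[dark].mean() >= 0.5 * frame[~dark].mean():
            warnings.warn(
                "no distinct dark (vessel) class in the frame; empty vessel mask",
                stacklevel=2,
            )
            return np.zeros(frame.shape, dtype=bool)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown vessel-mask method {method!r}")
    mask = frame < thr
    if thr <= frame.min():
        warnings.warn(f"vessel threshold {thr} at/below data minimum: empty mask", stacklevel=2)
    elif thr > frame.max():
        warnings.warn(f"vessel threshold {thr} above data maximum: full mask", stacklevel=2)
    return mask


def rasterize_atlas(
    layout: AtlasLayout, image_shape: tuple[int, int]
) -> tuple[np.ndarray, list[str]]:
    """Rasterise region polygons to a label image.

    Returns ``(labels, names)`` where ``labels`` is int (0 = background,
    ``i+1`` = ``names[i]``).  Pixel-centre containment decides membership;
    boundary pixels tie-break into the region (inclusive).  Where user-supplied
    polygons overlap, the first region in layout order wins.
    """
    h, w = image_shape
    br, bc = layout.bregma_px
    if not (0 <= br < h and 0 <= bc < w):
        raise ValueError(f"bregma {layout.bregma_px} outside image {image_shape}")
    rows, cols = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    labels = np.zeros((h, w), dtype=np.int32)
    names = list(layout.regions)
    for i, name in enumerate(names):
        verts_px = layout.mm_to_px(layout.regions[name])
        path = MplPath(verts_px)
        inside = path.contains_points(pts, radius=-1e-9)
        inside |= path.contains_points(pts, radius=1e-9)  # boundary inclusive
        m = inside.reshape(h, w) & (labels == 0)
        if not m.any():
            warnings.warn(f"region {name!r} projects outside the image", stacklevel=2)
        labels[m] = i + 1
    return labels, names


def region_trace(
    ratio: RatioSequence,
    labels: np.ndarray,
    names: list[str],
    region: str,
    extra_exclude: np.ndarray | None = None,
) -> RegionTrace:
    """Unweighted mean %dR/R over the valid pixels of one region, per frame.

    Excluded (vessel/invalid) pixels never contribute; an empty intersection
    raises rather than returning silent zeros.
    """
    if region not in names:
        raise KeyError(f"region {region!r} not in layout ({names})")
    sel = (labels == names.index(region) + 1) & ratio.valid_mask
    if extra_exclude is not None:
        sel &= ~np.asarray(extra_exclude, dtype=bool)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"region {region!r}: no valid pixels to average")
    trace = ratio.drr[:, sel].mean(axis=1)
    return RegionTrace(
        region=region,
        drr=trace,
        frame_rate=ratio.frame_rate,
        stim_indices=tuple(s - 1 for s in ratio.stim_frames),
        n_pixels=n,
    )
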