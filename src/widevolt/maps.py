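"""Trial-averaged, bregma-aligned per-pixel voltage maps.

A single-trial map is the %dR/R stack with the per-pixel pre-stimulus
baseline (mean of the 10 frames, 100 ms, before stimulation) subtracted.
Maps from different trials/animals are averaged per pixel after a rigid
alignment — translate each map's bregma to a common origin and rotate its
midline to vertical — with nearest-neighbour resampling and *no* additional
spatial or temporal filtering of any kind.  Rendering uses a symmetric
diverging colour scale clipped at +-0.5 % (depolarised red, hyperpolarised
blue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib import colors as mcolors

from .preprocessing import RatioSequence

__all__ = [
    "VoltageMap",
    "trial_map",
    "average_aligned_maps",
    "render_map_frames",
    "value_to_rgba",
    "DEFAULT_SCALE_PCT",
    "DEFAULT_RENDER_TIMES_MS",
]

DEFAULT_SCALE_PCT = 0.5
DEFAULT_RENDER_TIMES_MS = (-30.0, 0.0, 60.0, 120.0, 180.0)
BASELINE_FRAMES = 10


@dataclass
class VoltageMap:
    """Baseline-subtracted dR stack with alignment metadata.

    ``data`` is (T, H, W) in %, NaN at invalid pixels; ``n_trials`` counts
    contributing trials per pixel (0 = no data, rendered as missing, never 0 %).
    """

    data: np.ndarray
    bregma_px: tuple[float, float]
    midline_angle_deg: float
    pixel_size_um: float
    frame_rate: float
    stim_index: int
    n_trials: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale_pct: float = DEFAULT_SCALE_PCT

    def __post_init__(self) -> None:
        if self.n_trials is None:
            self.n_trials = (~np.isnan(self.data[0])).astype(np.int32)

    def time_ms(self) -> np.ndarray:
        return (np.arange(self.data.shape[0]) - self.stim_index) * 1000.0 / self.frame_rate


def trial_map(
    ratio: RatioSequence,
    stim_index: int | None = None,
    bregma_px: tuple[float, float] = (0.0, 0.0),
    midline_angle_deg: float = 0.0,
) -> VoltageMap:
    """Single-trial voltage map: dR = dR/R - pre-stimulus baseline, per pixel."""
    s = (ratio.stim_frames[0] - 1) if stim_index is None else stim_index
    if s - BASELINE_FRAMES < 0:
        raise ValueError("missing pre-stimulus baseline frames")
    baseline = ratio.drr[s - BASELINE_FRAMES : s].mean(axis=0)
    data = ratio.drr - baseline
    data[:, ~ratio.valid_mask] = np.nan
    return VoltageMap(
        data=data,
        bregma_px=bregma_px,
        midline_angle_deg=midline_angle_deg,
        pixel_size_um=ratio.pixel_size_um,
        frame_rate=ratio.frame_rate,
        stim_index=s,
    )


def average_aligned_maps(
    maps: list[VoltageMap],
    canvas_shape: tuple[int, int] | None = None,
) -> VoltageMap:
    """Rigidly align maps (bregma to canvas centre, midline vertical) and average.

    Nearest-neighbour resampling preserves the no-filtering guarantee: each
    output pixel is the plain mean, over contributing trials, of exactly one
    input pixel per trial.  Pixels with no contributing trial are NaN with
    ``n_trials`` 0.
    """
    if not maps:
        raise ValueError("need at least one map")
    t_len = maps[0].data.shape[0]
    if any(m.data.shape[0] != t_len for m in maps):
        raise ValueError("maps must have equal frame counts")
    if canvas_shape is None:
        canvas_shape = (
            max(m.data.shape[1] for m in maps),
            max(m.data.shape[2] for m in maps),
        )
    h, w = canvas_shape
    origin = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rows, cols = np.mgrid[0:h, 0:w]
    out_sum = np.zeros((t_len, h, w))
    out_n = np.zeros((t_len, h, w), dtype=np.int32)
    for m in maps:
        a = np.deg2rad(m.midline_angle_deg)
        # output offset (drow, dcol) -> input offset, rotating the midline back
        drow = rows - origin[0]
        dcol = cols - origin[1]
        in_r = m.bregma_px[0] + np.cos(a) * drow + np.sin(a) * dcol
        in_c = m.bregma_px[1] - np.sin(a) * drow + np.cos(a) * dcol
        ir = np.rint(in_r).astype(int)
        ic = np.rint(in_c).astype(int)
        inside = (ir >= 0) & (ir < m.data.shape[1]) & (ic >= 0) & (ic < m.data.shape[2])
        irc = np.clip(ir, 0, m.data.shape[1] - 1)
        icc = np.clip(ic, 0, m.data.shape[2] - 1)
        vals = m.data[:, irc, icc]  # (T, h, w)
        ok = inside[None] & ~np.isnan(vals)
        out_sum[ok] += vals[ok]
        out_n += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(out_n > 0, out_sum / np.maximum(out_n, 1), np.nan)
    return VoltageMap(
        data=mean,
        bregma_px=(origin[0], origin[1]),
        midline_angle_deg=0.0,
        pixel_size_um=maps[0].pixel_size_um,
        frame_rate=maps[0].frame_rate,
        stim_index=maps[0].stim_index,
        n_trials=out_n.max(axis=0),
        scale_pct=maps[0].scale_pct,
    )


def value_to_rgba(values: np.ndarray, scale_pct: float = DEFAULT_SCALE_PCT) -> np.ndarray:
    """Map dR values (%) to the diverging colour convention.

    Linear between -scale and +scale: hyperpolarised blue, 0 at the white
    midpoint, depolarised red; values beyond the limits saturate.  NaN
    (no-data) pixels map to transparent.
    """
    cmap = matplotlib.colormaps["bwr"].copy()
    cmap.set_bad(alpha=0.0)
    norm = mcolors.Normalize(vmin=-scale_pct, vmax=scale_pct, clip=True)
    return cmap(norm(np.ma.masked_invalid(values)))


def render_map_frames(
    vmap: VoltageMap,
    times_ms: tuple[float, ...] = DEFAULT_RENDER_TIMES_MS,
    out_dir: str | Path = ".",
    prefix: str = "map",
    dpi: int = 120,
) -> list[Path]:
    """Render selected frames as PNGs with bregma marker and mm scalebar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_axis = vmap.time_ms()
    paths = []
    for t in times_ms:
        k = int(np.argmin(np.abs(t_axis - t)))
        if abs(t_axis[k] - t) > 1000.0 / vmap.frame_rate:
            raise ValueError(f"requested time {t} ms outside the map extent")
        fig, ax = plt.subplots(figsize=(4, 3))
        rgba = value_to_rgba(vmap.data[k], vmap.scale_pct)
        ax.imshow(rgba, interpolation="nearest")
        ax.plot(vmap.bregma_px[1], vmap.bregma_px[0], "ks", markersize=4)
        bar_px = 1000.0 / vmap.pixel_size_um  # 1 mm
        h, w = vmap.data.shape[1:]
        ax.plot([w * 0.05, w * 0.05 + bar_px], [h * 0.95] * 2, "k-", lw=2)
        ax.text(w * 0.05, h * 0.92, "1 mm", fontsize=7)
        ax.set_title(f"{t_axis[k]:+.0f} ms (+-{vmap.scale_pct}% dR/R)", fontsize=8)
        ax.axis("off")
        p = out / f"{prefix}_{int(round(t_axis[k])):+04d}ms.png"
        fig.savefig(p, dpi=dpi, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
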