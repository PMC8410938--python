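"""Raw dual-channel stacks -> per-pixel %dR/R ratio sequences.

The FRET voltage indicator emits anticorrelated donor/acceptor fluorescence:
depolarisation decreases donor and increases acceptor emission, while
hemodynamic artifacts (dominated by the heartbeat) modulate both channels in
common mode.  The pipeline therefore

1. spatially bins the raw frames (default 4x4 averaging),
2. subtracts the per-pixel camera dark offset (mean over the dark frames),
3. normalises each pixel by its pre-stimulus mean (F/F0),
4. rescales the donor so both channels carry equal amplitude at the heartbeat
   frequency (found by FFT), and
5. forms the acceptor/donor ratio R and reports %dR/R = (R - R0)/R0 * 100.

Step 4 makes the residual common-mode artifact cancel in the ratio while the
anticorrelated voltage signal adds.  All frame ranges in configuration are
1-based inclusive (matching lab conventions such as "dark frames 1 to 25");
they are converted to 0-based indices in exactly one place (`frames_to_slice`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DualChannelSequence",
    "NormalizedSequence",
    "RatioSequence",
    "HeartbeatGain",
    "PreprocessConfig",
    "frames_to_slice",
    "bin_spatial",
    "subtract_dark_offset",
    "normalize_prestim",
    "estimate_heartbeat_gain",
    "apply_equalization",
    "compute_drr",
    "preprocess",
]


def frames_to_slice(frame_range: tuple[int, int]) -> slice:
    """Convert a 1-based inclusive frame range to a 0-based python slice."""
    lo, hi = int(frame_range[0]), int(frame_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid 1-based inclusive frame range {frame_range!r}")
    return slice(lo - 1, hi)


@dataclass
class DualChannelSequence:
    """Per-trial donor and acceptor frame stacks with timing metadata.

    Attributes
    ----------
    donor, acceptor : (T, H, W) arrays of camera counts (or floats after
        offset subtraction).
    frame_rate : acquisition rate in Hz.
    dark_frames : 1-based inclusive range of frames acquired before the
        excitation light was turned on (camera offset only).
    stim_frames : 1-based frame indices at which stimuli were delivered.
    hemisphere_mask : boolean (H, W) image, True inside the imaged hemisphere.
    pixel_size_um : pixel pitch in micrometres at the current resolution.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    frame_rate: float = 100.0
    dark_frames: tuple[int, int] = (1, 25)
    stim_frames: tuple[int, ...] = (125,)
    hemisphere_mask: np.ndarray | None = None
    pixel_size_um: float = 3.6375

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor)
        self.acceptor = np.asarray(self.acceptor)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError(
                f"donor shape {self.donor.shape} != acceptor shape {self.acceptor.shape}"
            )
        if self.donor.ndim != 3:
            raise ValueError("stacks must be (T, H, W)")
        lo, hi = self.dark_frames
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid dark frame range {self.dark_frames}")
        self.stim_frames = tuple(int(s) for s in self.stim_frames)
        if any(b <= a for a, b in zip(self.stim_frames, self.stim_frames[1:])):
            raise ValueError("stim_frames must be strictly increasing")
        if self.stim_frames and hi >= self.stim_frames[0]:
            raise ValueError("dark frames must precede the first stimulus frame")
        if self.hemisphere_mask is not None:
            self.hemisphere_mask = np.asarray(self.hemisphere_mask, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.donor.shape[1:]

    def lit_frames(self) -> tuple[int, int]:
        """1-based inclusive range of illuminated frames (after the dark block)."""
        return (self.dark_frames[1] + 1, self.n_frames)


@dataclass
class NormalizedSequence:
    """Dimensionless F/F0 stacks; baseline mean of every valid pixel is 1."""

    donor_norm: np.ndarray
    acceptor_norm: np.ndarray
    baseline_window: tuple[int, int]
    frame_rate: float
    stim_frames: tuple[int, ...]
    lit_start: int  # 1-based first illuminated frame
    valid_mask: np.ndarray
    pixel_size_um: float


@dataclass
class HeartbeatGain:
    """Per-pixel acceptor/donor amplitude ratio at the heartbeat frequency."""

    gain: np.ndarray
    f_hb: float
    fallback: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass
class RatioSequence:
    """%dR/R stack: the pipeline's voltage readout.

    ``drr`` is NaN outside ``valid_mask``; the mean over ``r0_window`` is zero
    at every valid pixel by construction of R0.
    """

    drr: np.ndarray
    r0_window: tuple[int, int]
    valid_mask: np.ndarray
    frame_rate: float
    stim_frames: tuple[int, ...]
    pixel_size_um: float

    @property
    def n_frames(self) -> int:
        return self.drr.shape[0]


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters (all frame ranges 1-based inclusive)."""

    bin_factor: int = 4
    baseline_window: tuple[int, int] = (31, 120)
    r0_window: tuple[int, int] = (31, 120)
    hb_band: tuple[float, float] = (5.0, 14.0)
    gain_clip: tuple[float, float] = (0.2, 5.0)
    gain_median_filter: bool = True
    gain_mode: str = "per_pixel"  # or "global"
    hann_window: bool = False
    peak_prominence: float = 2.0  # spectral peak vs in-band median amplitude


def bin_spatial(stack: np.ndarray, factor: int) -> np.ndarray:
    """Bin an image or stack spatially by block-averaging ``factor``x``factor``.

    Each output pixel is the arithmetic mean of its block, so the global mean
    is preserved exactly.  Shapes that are not divisible by ``factor`` raise,
    naming the crop that would make them divisible (no silent cropping).
    """
    a = np.asarray(stack)
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return a.astype(np.float64, copy=True) if a.ndim else a
    h, w = a.shape[-2], a.shape[-1]
    if h % factor or w % factor:
        raise ValueError(
            f"shape {h}x{w} not divisible by bin factor {factor}; "
            f"crop to {h - h % factor}x{w - w % factor} first"
        )
    lead = a.shape[:-2]
    out = a.reshape(*lead, h // factor, factor, w // factor, factor)
    return out.mean(axis=(-3, -1))


def subtract_dark_offset(seq: DualChannelSequence) -> DualChannelSequence:
    """Subtract the per-pixel camera offset, estimated from the dark frames."""
    sl = frames_to_slice(seq.dark_frames)
    if sl.stop > seq.n_frames:
        raise ValueError("dark frame range exceeds stack length")
    d_off = seq.donor[sl].mean(axis=0)
    a_off = seq.acceptor[sl].mean(axis=0)
    return replace(
        seq,
        donor=seq.donor.astype(np.float64) - d_off,
        acceptor=seq.acceptor.astype(np.float64) - a_off,
    )


def normalize_prestim(
    seq: DualChannelSequence, baseline_window: tuple[int, int] = (31, 120)
) -> NormalizedSequence:
    """Normalise each pixel by its mean over the pre-stimulus baseline window.

    Pixels whose baseline F0 is not strictly positive in either channel
    (vessels, window imperfections) are flagged invalid; a warning summarises
    their count.
    """
    sl = frames_to_slice(baseline_window)
    if sl.stop > seq.n_frames:
        raise ValueError("baseline window exceeds stack length")
    if seq.stim_frames and sl.stop > seq.stim_frames[0] - 1:
        raise ValueError("baseline window must end before the first stimulus frame")
    f0_d = seq.donor[sl].mean(axis=0)
    f0_a = seq.acceptor[sl].mean(axis=0)
    valid = (f0_d > 0) & (f0_a > 0)
    if seq.hemisphere_mask is not None:
        valid &= seq.hemisphere_mask
    n_bad = int(((f0_d <= 0) | (f0_a <= 0)).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} pixels with non-positive baseline flagged invalid (vessel-like)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        dn = seq.donor / f0_d
        an = seq.acceptor / f0_a
    dn[:, ~valid] = np.nan
    an[:, ~valid] = np.nan
    return NormalizedSequence(
        donor_norm=dn,
        acceptor_norm=an,
        baseline_window=baseline_window,
        frame_rate=seq.frame_rate,
        stim_frames=seq.stim_frames,
        lit_start=seq.dark_frames[1] + 1,
        valid_mask=valid,
        pixel_size_um=seq.pixel_size_um,
    )


def _spectral_segment(norm: NormalizedSequence) -> slice:
    """Lit, pre-stimulus frames used for heartbeat spectral estimation."""
    start = norm.lit_start - 1
    stop = (norm.stim_frames[0] - 1) if norm.stim_frames else norm.donor_norm.shape[0]
    if stop - start < 8:
        raise ValueError("pre-stimulus lit segment too short for spectral estimation")
    return slice(start, stop)


def estimate_heartbeat_gain(
    norm: NormalizedSequence,
    hb_band: tuple[float, float] = (5.0, 14.0),
    config: PreprocessConfig | None = None,
) -> HeartbeatGain:
    """Estimate the per-pixel donor->acceptor equalization gain by FFT.

    The heartbeat frequency f_hb is located as the peak of the valid-pixel-mean
    amplitude spectrum within ``hb_band`` on the lit pre-stimulus segment; the
    gain is the ratio of acceptor to donor spectral amplitude at that
    frequency.  If no peak stands above the configured prominence over the
    in-band median, the gain falls back to 1 everywhere (recorded in the
    result).  Per-pixel gains are clipped and median-filtered by default to
    suppress noise-dominated pixels.
    """
    cfg = config or PreprocessConfig(hb_band=hb_band)
    lo, hi = hb_band
    if not (0 < lo < hi < norm.frame_rate / 2):
        raise ValueError(f"heartbeat band {hb_band} outside (0, Nyquist)")
    seg = _spectral_segment(norm)
    n = seg.stop - seg.start
    freqs = np.fft.rfftfreq(n, d=1.0 / norm.frame_rate)
    valid = norm.valid_mask
    d = norm.donor_norm[seg][:, valid]
    a = norm.acceptor_norm[seg][:, valid]
    d = d - d.mean(axis=0)
    a = a - a.mean(axis=0)
    if cfg.hann_window:
        win = np.hanning(n)[:, None]
        d = d * win
        a = a * win
    fd = np.fft.rfft(d, axis=0)
    fa = np.fft.rfft(a, axis=0)
    band = (freqs >= lo) & (freqs <= hi)
    warns: list[str] = []
    if not band.any():
        warns.append(f"heartbeat band {hb_band} contains no FFT bin; gain set to 1")
        return HeartbeatGain(np.ones(norm.valid_mask.shape), float("nan"), True, warns)
    mean_amp = (np.abs(fd).mean(axis=1) + np.abs(fa).mean(axis=1)) / 2.0
    band_amp = mean_amp[band]
    k_band = int(np.argmax(band_amp))
    k = np.flatnonzero(band)[k_band]
    f_hb = float(freqs[k])
    med = float(np.median(band_amp))
    if med > 0 and band_amp[k_band] < cfg.peak_prominence * med:
        warns.append(
            f"no prominent heartbeat peak in {hb_band} Hz "
            f"(peak/median = {band_amp[k_band] / med:.2f}); gain set to 1"
        )
        return HeartbeatGain(np.ones(norm.valid_mask.shape), f_hb, True, warns)

    amp_d = np.abs(fd[k])
    amp_a = np.abs(fa[k])
    gain_v = np.ones_like(amp_d)
    ok = amp_d > 0
    gain_v[ok] = amp_a[ok] / amp_d[ok]
    if cfg.gain_mode == "global":
        g = float(np.median(gain_v))
        gain = np.full(norm.valid_mask.shape, g)
    else:
        gain = np.ones(norm.valid_mask.shape)
        gain[valid] = gain_v
        gain = np.clip(gain, *cfg.gain_clip)
        if cfg.gain_median_filter:
            gain = ndimage.median_filter(gain, size=3)
    gain = np.clip(gain, *cfg.gain_clip)
    return HeartbeatGain(gain=gain, f_hb=f_hb, fallback=False, warnings=warns)


def apply_equalization(norm: NormalizedSequence, gain: np.ndarray | HeartbeatGain) -> NormalizedSequence:
    """Rescale donor fluctuations about 1 so heartbeat amplitudes match.

    donor' = 1 + gain * (donor - 1); the acceptor is the reference channel and
    is left untouched.  dR/R is invariant to which channel carries the gain
    when the gain is exact.
    """
    g = gain.gain if isinstance(gain, HeartbeatGain) else np.asarray(gain)
    dn = 1.0 + g * (norm.donor_norm - 1.0)
    return replace(norm, donor_norm=dn)


def compute_drr(
    norm: NormalizedSequence, r0_window: tuple[int, int] = (31, 120)
) -> RatioSequence:
    """Form R = acceptor/donor and report %dR/R = (R - R0)/R0 * 100.

    R0 is the per-pixel mean of R over ``r0_window`` (default 90 frames,
    900 ms at 100 Hz, ending before the stimulus).  Pixels whose donor is not
    strictly positive in any illuminated frame are invalidated (the dark
    frames carry no fluorescence and are never analysed as ratios).
    """
    sl = frames_to_slice(r0_window)
    if sl.stop > norm.donor_norm.shape[0]:
        raise ValueError("r0 window exceeds stack length")
    valid = norm.valid_mask.copy()
    if valid.any():
        lit = norm.donor_norm[norm.lit_start - 1 :]
        nonpos = lit[:, valid].min(axis=0) <= 0
        v = valid[valid].copy()
        v[nonpos] = False
        valid[norm.valid_mask] = v
    with np.errstate(divide="ignore", invalid="ignore"):
        r = norm.acceptor_norm / norm.donor_norm
        r0 = r[sl].mean(axis=0)
        drr = (r - r0) / r0 * 100.0
    drr[:, ~valid] = np.nan
    return RatioSequence(
        drr=drr,
        r0_window=r0_window,
        valid_mask=valid,
        frame_rate=norm.frame_rate,
        stim_frames=norm.stim_frames,
        pixel_size_um=norm.pixel_size_um,
    )


def preprocess(
    seq: DualChannelSequence,
    config: PreprocessConfig | None = None,
    vessel_mask: np.ndarray | None = None,
) -> tuple[RatioSequence, dict]:
    """Full preprocessing chain on one trial; returns (ratio, provenance).

    ``vessel_mask`` (True = excluded) must be at the binned resolution; it is
    intersected into the validity mask before any spatial averaging downstream.
    """
    cfg = config or PreprocessConfig()
    f = cfg.bin_factor
    binned = replace(
        seq,
        donor=bin_spatial(seq.donor, f),
        acceptor=bin_spatial(seq.acceptor, f),
        hemisphere_mask=(
            None
            if seq.hemisphere_mask is None
            else bin_spatial(seq.hemisphere_mask.astype(float), f) > 0.5
        ),
        pixel_size_um=seq.pixel_size_um * f,
    )
    dark_sub = subtract_dark_offset(binned)
    norm = normalize_prestim(dark_sub, cfg.baseline_window)
    if vessel_mask is not None:
        norm.valid_mask &= ~np.asarray(vessel_mask, dtype=bool)
    hb = estimate_heartbeat_gain(norm, cfg.hb_band, cfg)
    eq = apply_equalization(norm, hb)
    ratio = compute_drr(eq, cfg.r0_window)
    prov = {
        "bin_factor": f,
        "baseline_window": list(cfg.baseline_window),
        "r0_window": list(cfg.r0_window),
        "hb_band": list(cfg.hb_band),
        "detected_f_hb": hb.f_hb,
        "gain_fallback": hb.fallback,
        "gain_median": float(np.median(hb.gain)),
        "gain_min": float(hb.gain.min()),
        "gain_max": float(hb.gain.max()),
        "n_valid_pixels": int(ratio.valid_mask.sum()),
        "warnings": list(hb.warnings),
    }
    return ratio, prov
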