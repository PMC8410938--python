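"""Forward model producing dual-channel stacks with known ground truth.

The generator emulates the statistical structure the analysis assumes for a
widefield FRET-GEVI recording of the dorsal cortex:

* per-region sub-threshold voltage transients (fast depolarisation followed
  by a slow hyperpolarisation), expressed in %dR/R-equivalent units;
* anticorrelated donor/acceptor fluorescence coupling (depolarisation
  decreases donor, increases acceptor emission);
* a common-mode heartbeat oscillation with channel-specific modulation depth
  (the artifact the equalization step is designed to cancel);
* camera dark offset and an initial block of dark frames, additive Gaussian
  read/shot noise, 12-bit clipping, and dark blood-vessel pixels;
* a behaviour-camera stack with optional movement epochs.

The depolarisation kernel is a normalized difference of exponentials (unit
peak by construction, so the configured amplitude IS the true peak);
the hyperpolarisation is a negative kernel of the same family peaking at a
configurable time.  Voltage is generated on the binned analysis grid and
upsampled to the raw sensor grid, so that analysis-side binning recovers
spatially homogeneous region blocks.

Action potentials, biophysical hemodynamics, breathing and photobleaching
are deliberately not modelled (the recordings this emulates reflect
sub-threshold activity, and the analysis applies no detrending); slow
multiplicative drift terms are available as stress-test options, default off.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml
from scipy.optimize import brentq

from .preprocessing import DualChannelSequence
from .registration import AtlasLayout, default_layout, rasterize_atlas

__all__ = [
    "RegionKernel",
    "Heartbeat",
    "Optics",
    "GainCoupling",
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "depol_kernel",
    "rise_tau_for_peak",
    "kernel_peak_time",
    "generate_voltage_truth",
    "render_trial",
    "generate_behavior_stack",
    "generate_session",
    "forepaw_config",
    "whisker_config",
]

MAX_COUNTS = 4095  # 12-bit sensor


# ---------------------------------------------------------------------------
# voltage kernels
# ---------------------------------------------------------------------------

def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Analytic peak time of exp(-t/decay) - exp(-t/rise) (rise < decay)."""
    if not 0 < rise_tau < decay_tau:
        raise ValueError("need 0 < rise_tau < decay_tau")
    return rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)


def rise_tau_for_peak(peak_time: float, decay_tau: float) -> float:
    """Solve for the rise time constant placing the kernel peak at ``peak_time``.

    The peak time of the difference of exponentials spans (0, decay_tau) as
    the rise constant spans (0, decay_tau), so ``peak_time`` must be strictly
    below ``decay_tau``.
    """
    if not 0 < peak_time < decay_tau:
        raise ValueError(
            f"peak time {peak_time} must lie in (0, decay_tau={decay_tau})"
        )
    f = lambda r: kernel_peak_time(r, decay_tau) - peak_time
    return brentq(f, 1e-9 * decay_tau, decay_tau * (1 - 1e-12), xtol=1e-12)


def depol_kernel(t_ms: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak; 0 for t<=0."""
    t = np.asarray(t_ms, dtype=float)
    if np.isclose(rise_tau, decay_tau):
        # degenerate limit: alpha function t/tau * e^(1 - t/tau)
        out = np.where(t > 0, t / rise_tau * np.exp(1 - t / rise_tau), 0.0)
        return out
    tp = kernel_peak_time(min(rise_tau, decay_tau), max(rise_tau, decay_tau))
    norm = np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)
    with np.errstate(over="ignore"):
        out = np.where(t > 0, (np.exp(-t / decay_tau) - np.exp(-t / rise_tau)) / norm, 0.0)
    return out


@dataclass
class RegionKernel:
    """Evoked-response parameters of one cortical region.

    Amplitudes are in % (dR/R-equivalent voltage units); times in ms after
    stimulus onset.  ``a_dep`` is the exact true peak of the depolarising
    component (the kernel is normalized to unit peak).
    """

    a_dep: float
    onset_delay_ms: float = 10.0
    rise_tau_ms: float = 14.0
    decay_tau_ms: float = 80.0
    a_hyp: float = 0.0
    hyp_onset_ms: float = 100.0  # the slow component begins ~100 ms post-stimulus
    hyp_peak_ms: float = 180.0
    hyp_tau_ms: float = 250.0

    @classmethod
    def from_peak(
        cls,
        a_dep: float,
        peak_ms: float,
        onset_delay_ms: float = 10.0,
        decay_tau_ms: float = 80.0,
        **kwargs,
    ) -> "RegionKernel":
        """Build a kernel whose depolarisation peaks at ``peak_ms`` post-stimulus."""
        rise = rise_tau_for_peak(peak_ms - onset_delay_ms, decay_tau_ms)
        return cls(
            a_dep=a_dep,
            onset_delay_ms=onset_delay_ms,
            rise_tau_ms=rise,
            decay_tau_ms=decay_tau_ms,
            **kwargs,
        )

    @property
    def peak_time_ms(self) -> float:
        """Analytic time of the depolarisation peak, ms after stimulus onset."""
        return self.onset_delay_ms + kernel_peak_time(
            min(self.rise_tau_ms, self.decay_tau_ms),
            max(self.rise_tau_ms, self.decay_tau_ms),
        )


@dataclass
class Heartbeat:
    """Single-sinusoid heartbeat artifact, multiplicative on both channels."""

    f_hb: float = 10.0  # Hz; mouse heart rate under head fixation
    donor_mod_depth: float = 0.02
    acceptor_mod_depth: float = 0.01
    phase: float = 0.3  # rad


@dataclass
class Optics:
    """Camera and illumination model (counts at the raw sensor resolution)."""

    donor_base_counts: float = 1600.0
    acceptor_base_counts: float = 1400.0
    camera_offset_counts: float = 100.0
    noise_sd_counts: float = 10.0


@dataclass
class GainCoupling:
    """Fractional dF/F per % voltage; donor gets -g_d, acceptor +g_a.

    After heartbeat equalization the donor's fluctuations (voltage deflection
    included) are rescaled by the channel amplitude ratio r = m_A/m_D, so the
    small-signal %dR/R read out by the pipeline is (g_a + r*g_d) * V.
    :meth:`balanced` picks g_d = g_a = 1/(1+r), making a unit ground-truth
    voltage read out as exactly 1 %dR/R in the noiseless limit — i.e. the
    configured region amplitudes are specified in pipeline %dR/R units.
    """

    g_d: float = 0.5
    g_a: float = 0.5

    @classmethod
    def balanced(cls, heartbeat: "Heartbeat") -> "GainCoupling":
        m_d, m_a = heartbeat.donor_mod_depth, heartbeat.acceptor_mod_depth
        if m_d <= 0 or m_a <= 0:
            return cls(0.5, 0.5)  # no equalization rescaling to compensate
        g = 1.0 / (1.0 + m_a / m_d)
        return cls(g, g)


@dataclass
class SyntheticConfig:
    """Full generator configuration; defaults mirror the acquisition protocol.

    200 frames at 100 Hz per trial; frames 1-25 dark; stimulation at frame
    125 (250 ms recording onset + 1000 ms of excitation light before the
    stimulus); 12-bit sensor.  ``pixel_size_um`` and ``bregma_px`` are at the
    binned analysis resolution (``raw_shape / bin_factor``).
    """

    frame_rate: float = 100.0
    n_frames: int = 200
    raw_shape: tuple[int, int] = (1200, 1920)
    bin_factor: int = 4
    pixel_size_um: float = 14.55  # binned resolution
    dark_frames: tuple[int, int] = (1, 25)
    stim_frames: tuple[int, ...] = (125,)
    stim_factors: tuple[float, ...] | None = None  # per-stimulus amplitude factors
    regions: dict[str, RegionKernel] = field(default_factory=dict)
    heartbeat: Heartbeat = field(default_factory=Heartbeat)
    optics: Optics = field(default_factory=Optics)
    gain: GainCoupling | None = None  # None -> GainCoupling.balanced(heartbeat)
    vessel_spec: list[tuple[float, float, float, float, float]] = field(
        default_factory=list
    )  # (r0, c0, r1, c1, width_px) at raw resolution
    bregma_px: tuple[float, float] | None = None  # binned (row, col)
    midline_angle_deg: float = 0.0
    # optional slow multiplicative stress terms (fraction per second), default off
    drift_per_s: float = 0.0
    bleach_tau_s: float | None = None
    # behaviour camera
    behavior_shape: tuple[int, int] = (120, 160)
    behavior_noise_sd: float = 1.0
    movement_area_frac: float = 0.05
    movement_shift_px: tuple[int, int] = (3, 3)
    calibration_n_frames: int = 600  # stationary-reference recording length
    seed: int = 0

    def __post_init__(self) -> None:
        self.stim_frames = tuple(int(s) for s in self.stim_frames)
        if self.gain is None:
            self.gain = GainCoupling.balanced(self.heartbeat)
        self.validate()

    def validate(self) -> None:
        h, w = self.raw_shape
        f = self.bin_factor
        if h % f or w % f:
            raise ValueError(f"raw_shape {self.raw_shape} not divisible by bin_factor {f}")
        if not 0 < self.heartbeat.f_hb < self.frame_rate / 2:
            raise ValueError("f_hb must lie strictly inside (0, frame_rate/2)")
        for depth in (self.heartbeat.donor_mod_depth, self.heartbeat.acceptor_mod_depth):
            if depth < 0:
                raise ValueError("modulation depths must be >= 0")
        o = self.optics
        if min(o.donor_base_counts, o.acceptor_base_counts, o.camera_offset_counts, o.noise_sd_counts) < 0:
            raise ValueError("optics counts must be >= 0")
        if any(b <= a for a, b in zip(self.stim_frames, self.stim_frames[1:])):
            raise ValueError("stim_frames must be strictly increasing")
        if self.stim_frames and self.dark_frames[1] >= self.stim_frames[0]:
            raise ValueError("dark frames must precede the first stimulus frame")
        if self.stim_factors is not None and len(self.stim_factors) != len(self.stim_frames):
            raise ValueError("stim_factors length must match stim_frames")
        for k in self.regions.values():
            if min(k.rise_tau_ms, k.decay_tau_ms, k.hyp_tau_ms) <= 0:
                raise ValueError("kernel time constants must be > 0")
        if not 0 <= self.movement_area_frac <= 1:
            raise ValueError("movement_area_frac must be within [0, 1]")

    @property
    def binned_shape(self) -> tuple[int, int]:
        return (self.raw_shape[0] // self.bin_factor, self.raw_shape[1] // self.bin_factor)

    def bregma_binned(self) -> tuple[float, float]:
        if self.bregma_px is not None:
            return self.bregma_px
        hb, wb = self.binned_shape
        return (hb / 2.0, wb / 12.0)

    def layout(self) -> AtlasLayout:
        return default_layout(
            bregma_px=self.bregma_binned(),
            pixel_size_um=self.pixel_size_um,
            midline_angle_deg=self.midline_angle_deg,
        )

    def frame_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * 1000.0 / self.frame_rate

    @classmethod
    def reduced(cls, scale: int = 5, **kwargs) -> "SyntheticConfig":
        """Down-scaled sensor (same field of view, coarser pixels) for speed."""
        if 1200 % scale or 1920 % scale:
            raise ValueError("scale must divide 1200 and 1920")
        kwargs.setdefault("raw_shape", (1200 // scale, 1920 // scale))
        kwargs.setdefault("pixel_size_um", 14.55 * scale)
        return cls(**kwargs)


def forepaw_config(scale: int = 5, **kwargs) -> SyntheticConfig:
    """Forepaw-stimulation condition: S1FL responds (0.195 % peaking 59.83 ms)."""
    kwargs.setdefault(
        "regions",
        {
            "S1FL": RegionKernel.from_peak(
                0.195, 59.83, a_hyp=0.05, hyp_peak_ms=180.0, hyp_tau_ms=250.0
            )
        },
    )
    kwargs.setdefault("vessel_spec", _default_vessels(scale))
    return SyntheticConfig.reduced(scale, **kwargs)


def whisker_config(scale: int = 5, **kwargs) -> SyntheticConfig:
    """Whisker-stimulation condition: S1BF responds (0.156 % peaking 50.58 ms)."""
    kwargs.setdefault(
        "regions",
        {
            "S1BF": RegionKernel.from_peak(
                0.156, 50.58, a_hyp=0.04, hyp_peak_ms=180.0, hyp_tau_ms=250.0
            )
        },
    )
    kwargs.setdefault("vessel_spec", _default_vessels(scale))
    return SyntheticConfig.reduced(scale, **kwargs)


def _default_vessels(scale: int) -> list[tuple[float, float, float, float, float]]:
    """A couple of dark surface vessels crossing the window (raw px coords)."""
    h, w = 1200 // scale, 1920 // scale
    return [
        (0.1 * h, 0.3 * w, 0.9 * h, 0.45 * w, max(2.0, 8.0 / scale * 4)),
        (0.5 * h, 0.1 * w, 0.6 * h, 0.95 * w, max(1.0, 5.0 / scale * 4)),
    ]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGroundTruth:
    """Hidden parameters against which pipeline recovery is scored."""

    voltage: dict[str, np.ndarray]  # region -> (n_frames,) % voltage
    peak_amp: dict[str, float]  # true depolarisation peak, %
    peak_time_ms: dict[str, float]  # analytic peak time after first stimulus
    labels: np.ndarray  # binned-grid region membership (0 background)
    label_names: list[str]
    vessel_mask_raw: np.ndarray
    movement_epochs: list[tuple[int, int]] = field(default_factory=list)


def _region_voltage(config: SyntheticConfig, kern: RegionKernel) -> np.ndarray:
    t = config.frame_times_ms()
    if kern.hyp_peak_ms <= kern.onset_delay_ms:
        raise ValueError("hyp_peak_ms must exceed onset_delay_ms")
    if kern.a_hyp != 0 and kern.hyp_peak_ms <= kern.hyp_onset_ms:
        raise ValueError("hyp_peak_ms must exceed hyp_onset_ms")
    factors = config.stim_factors or (1.0,) * len(config.stim_frames)
    v = np.zeros_like(t)
    for s_frame, fac in zip(config.stim_frames, factors):
        t_stim = (s_frame - 1) * 1000.0 / config.frame_rate
        tt = t - t_stim - kern.onset_delay_ms
        v += fac * kern.a_dep * depol_kernel(tt, kern.rise_tau_ms, kern.decay_tau_ms)
        if kern.a_hyp != 0:
            hyp_rise = rise_tau_for_peak(
                kern.hyp_peak_ms - kern.hyp_onset_ms, kern.hyp_tau_ms
            )
            tt_h = t - t_stim - kern.hyp_onset_ms
            v -= fac * kern.a_hyp * depol_kernel(tt_h, hyp_rise, kern.hyp_tau_ms)
    return v


def _vessel_mask_raw(config: SyntheticConfig) -> np.ndarray:
    h, w = config.raw_shape
    mask = np.zeros((h, w), dtype=bool)
    if not config.vessel_spec:
        return mask
    rows, cols = np.mgrid[0:h, 0:w]
    for r0, c0, r1, c1, width in config.vessel_spec:
        dr, dc = r1 - r0, c1 - c0
        L2 = dr * dr + dc * dc
        if L2 == 0:
            d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        else:
            u = np.clip(((rows - r0) * dr + (cols - c0) * dc) / L2, 0.0, 1.0)
            d2 = (rows - (r0 + u * dr)) ** 2 + (cols - (c0 + u * dc)) ** 2
        mask |= d2 <= (width / 2.0) ** 2
    return mask


def generate_voltage_truth(config: SyntheticConfig, seed: int | None = None) -> SyntheticGroundTruth:
    """Evaluate each region's voltage time course and record the exact truth.

    Deterministic; ``seed`` is accepted for interface symmetry but unused
    (truth has no random component — randomness enters at render time).
    """
    config.validate()
    labels, names = rasterize_atlas(config.layout(), config.binned_shape)
    voltage: dict[str, np.ndarray] = {}
    peak_amp: dict[str, float] = {}
    peak_time: dict[str, float] = {}
    for name in names:
        kern = config.regions.get(name)
        if kern is None:
            voltage[name] = np.zeros(config.n_frames)
            continue
        voltage[name] = _region_voltage(config, kern)
        peak_amp[name] = kern.a_dep * (config.stim_factors or (1.0,))[0]
        peak_time[name] = kern.peak_time_ms
    return SyntheticGroundTruth(
        voltage=voltage,
        peak_amp=peak_amp,
        peak_time_ms=peak_time,
        labels=labels,
        label_names=names,
        vessel_mask_raw=_vessel_mask_raw(config),
        movement_epochs=[],
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_trial(
    truth: SyntheticGroundTruth,
    config: SyntheticConfig,
    seed: int | np.random.Generator = 0,
) -> DualChannelSequence:
    """Render donor/acceptor 12-bit stacks from the ground truth.

    Signal model per channel (lit frames, non-vessel pixels)::

        D(x,t) = offset + F_D * (1 - g_d*V(x,t)/100) * (1 + m_D*sin(2*pi*f_hb*t + phi)) + noise
        A(x,t) = offset + F_A * (1 + g_a*V(x,t)/100) * (1 + m_A*sin(2*pi*f_hb*t + phi)) + noise

    Dark frames carry offset + noise only; vessel pixels sit at offset level
    in every frame.  Counts are rounded and clipped to [0, 4095].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = config.raw_shape
    f = config.bin_factor
    hb, wb = config.binned_shape
    t_s = np.arange(config.n_frames) / config.frame_rate

    # binned voltage field per frame from region membership
    v_binned = np.zeros((config.n_frames, hb, wb), dtype=np.float32)
    for i, name in enumerate(truth.label_names):
        v = truth.voltage.get(name)
        if v is None or not np.any(v):
            continue
        sel = truth.labels == i + 1
        v_binned[:, sel] = np.asarray(v, dtype=np.float32)[:, None]

    o = config.optics
    g = config.gain
    hbt = config.heartbeat
    vessel = truth.vessel_mask_raw
    lit_from = config.dark_frames[1]  # 0-based first lit frame index
    drift = config.drift_per_s
    bleach = config.bleach_tau_s

    donor = np.empty((config.n_frames, h, w), dtype=np.uint16)
    acceptor = np.empty_like(donor)
    for i in range(config.n_frames):
        if i < lit_from:
            d_sig = np.zeros((h, w), dtype=np.float32)
            a_sig = np.zeros((h, w), dtype=np.float32)
        else:
            v_up = np.repeat(np.repeat(v_binned[i], f, axis=0), f, axis=1)
            s = np.sin(2 * np.pi * hbt.f_hb * t_s[i] + hbt.phase)
            slow = 1.0
            if drift:
                slow *= 1.0 + drift * t_s[i]
            if bleach:
                slow *= np.exp(-t_s[i] / bleach)
            d_sig = (
                o.donor_base_counts
                * (1.0 - g.g_d * v_up / 100.0)
                * (1.0 + hbt.donor_mod_depth * s)
                * slow
            )
            a_sig = (
                o.acceptor_base_counts
                * (1.0 + g.g_a * v_up / 100.0)
                * (1.0 + hbt.acceptor_mod_depth * s)
                * slow
            )
            d_sig[vessel] = 0.0
            a_sig[vessel] = 0.0
        for sig, out in ((d_sig, donor), (a_sig, acceptor)):
            fr = sig + o.camera_offset_counts
            if o.noise_sd_counts > 0:
                fr = fr + o.noise_sd_counts * rng.standard_normal((h, w), dtype=np.float32)
            out[i] = np.clip(np.rint(fr), 0, MAX_COUNTS).astype(np.uint16)

    # hemisphere: lateral side of the midline through bregma
    br, bc = config.bregma_binned()
    br_raw = br * f + (f - 1) / 2.0
    bc_raw = bc * f + (f - 1) / 2.0
    a = np.deg2rad(config.midline_angle_deg)
    rows, cols = np.mgrid[0:h, 0:w]
    lateral = (cols - bc_raw) * np.cos(a) + (rows - br_raw) * np.sin(a)
    hemisphere = lateral >= 0

    return DualChannelSequence(
        donor=donor,
        acceptor=acceptor,
        frame_rate=config.frame_rate,
        dark_frames=config.dark_frames,
        stim_frames=config.stim_frames,
        hemisphere_mask=hemisphere,
        pixel_size_um=config.pixel_size_um / f,
    )


# ---------------------------------------------------------------------------
# behaviour camera
# ---------------------------------------------------------------------------

def _behavior_base(config: SyntheticConfig) -> np.ndarray:
    """Deterministic textured silhouette (elliptical body on a dim floor)."""
    h, w = config.behavior_shape
    rows, cols = np.mgrid[0:h, 0:w]
    ellipse = ((rows - h / 2) / (0.42 * h)) ** 2 + ((cols - w / 2) / (0.45 * w)) ** 2 <= 1
    texture = ((3 * rows + 7 * cols) % 211).astype(np.float32) + 30.0
    base = np.full((h, w), 20.0, dtype=np.float32)
    base[ellipse] = texture[ellipse]
    return base


def generate_behavior_stack(
    config: SyntheticConfig,
    movement_epochs: Sequence[tuple[int, int]] = (),
    seed: int | np.random.Generator = 0,
    n_frames: int | None = None,
) -> np.ndarray:
    """Behaviour-camera stack; a body patch translates during movement epochs.

    ``movement_epochs`` are 1-based inclusive frame ranges.  Outside them,
    frame-to-frame differences are pure sensor noise; inside, a patch of the
    silhouette covering ``movement_area_frac`` of the frame is displaced by
    ``movement_shift_px`` (>= 2 px), changing that fraction of pixels beyond
    noise.  Returns a (n_frames, H, W) uint8 stack.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config.movement_area_frac > 1:
        raise ValueError("movement area fraction > 1")
    total = config.n_frames if n_frames is None else int(n_frames)
    h, w = config.behavior_shape
    for lo, hi in movement_epochs:
        if not (1 <= lo <= hi <= total):
            raise ValueError(f"movement epoch {(lo, hi)} outside 1..{total}")
    base = _behavior_base(config)

    # centred patch of the requested area, aspect-matched to the frame
    area = config.movement_area_frac * h * w
    bh = max(1, int(round(np.sqrt(area * h / w))))
    bw = max(1, int(np.ceil(area / bh)))
    r0, c0 = (h - bh) // 2, (w - bw) // 2
    dy, dx = config.movement_shift_px
    if max(abs(dy), abs(dx)) < 2 and config.movement_area_frac > 0:
        raise ValueError("movement shift must be >= 2 px")

    moved = base.copy()
    src_r0, src_c0 = r0 - dy, c0 - dx
    if src_r0 < 0 or src_c0 < 0 or src_r0 + bh > h or src_c0 + bw > w:
        raise ValueError("displaced patch exceeds frame bounds")
    moved[r0 : r0 + bh, c0 : c0 + bw] = base[src_r0 : src_r0 + bh, src_c0 : src_c0 + bw]

    in_epoch = np.zeros(total, dtype=bool)
    for lo, hi in movement_epochs:
        in_epoch[lo - 1 : hi] = True

    stack = np.empty((total, h, w), dtype=np.uint8)
    for i in range(total):
        fr = moved if in_epoch[i] else base
        if config.behavior_noise_sd > 0:
            fr = fr + config.behavior_noise_sd * rng.standard_normal((h, w), dtype=np.float32)
        stack[i] = np.clip(np.rint(fr), 0, 255).astype(np.uint8)
    return stack


# ---------------------------------------------------------------------------
# sessions on disk
# ---------------------------------------------------------------------------

def generate_session(
    config: SyntheticConfig,
    n_trials: int,
    out_dir: str | Path,
    seed: int = 0,
    stimulus_type: str = "paw",
    movement_trial_epochs: dict[int, list[tuple[int, int]]] | None = None,
    session_id: str = "synthetic",
    mouse_id: str = "sim01",
    condition: str = "control",
) -> Path:
    """Write a complete synthetic session: TIFF stacks, manifest, truth sidecar.

    Per-trial seeds are derived from ``seed`` via ``numpy.random.SeedSequence``
    spawning, so the same seed reproduces the session byte-for-byte and any
    seed change alters every stack.  ``movement_trial_epochs`` maps 1-based
    trial numbers to behaviour-frame epochs; those trials should classify as
    movement downstream.  A stationary calibration stack (the "fabric mouse")
    is written alongside the trials.  Returns the manifest path.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    epochs_by_trial = movement_trial_epochs or {}
    interstim = None
    if len(config.stim_frames) == 2:
        interstim = (config.stim_frames[1] - config.stim_frames[0]) * 1000.0 / config.frame_rate

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_trials + 1)
    truth = generate_voltage_truth(config)

    calib_rng = np.random.default_rng(children[-1])
    calib = generate_behavior_stack(config, (), calib_rng, n_frames=config.calibration_n_frames)
    tifffile.imwrite(out / "calibration_behavior.tif", calib)

    trials = []
    truth_trials = {}
    for k in range(1, n_trials + 1):
        rng = np.random.default_rng(children[k - 1])
        seq = render_trial(truth, config, rng)
        epochs = epochs_by_trial.get(k, [])
        behavior = generate_behavior_stack(config, epochs, rng)
        d_path, a_path, b_path = (
            f"trial{k:03d}_donor.tif",
            f"trial{k:03d}_acceptor.tif",
            f"trial{k:03d}_behavior.tif",
        )
        tifffile.imwrite(out / d_path, seq.donor)
        tifffile.imwrite(out / a_path, seq.acceptor)
        tifffile.imwrite(out / b_path, behavior)
        trials.append(
            {
                "trial_id": f"t{k:03d}",
                "stimulus_type": stimulus_type,
                "interstim_ms": interstim,
                "stim_frames": list(config.stim_frames),
                "donor": d_path,
                "acceptor": a_path,
                "behavior": b_path,
                "bregma_px": [float(x) for x in config.bregma_binned()],
                "midline_angle_deg": float(config.midline_angle_deg),
            }
        )
        truth_trials[f"t{k:03d}"] = {
            "peak_amp_pct": {k2: float(v) for k2, v in truth.peak_amp.items()},
            "peak_time_ms": {k2: float(v) for k2, v in truth.peak_time_ms.items()},
            "movement_epochs": [list(e) for e in epochs],
        }

    manifest = {
        "session_id": session_id,
        "mouse_id": mouse_id,
        "condition": condition,
        "frame_rate": float(config.frame_rate),
        "n_frames": int(config.n_frames),
        "dark_frames": list(config.dark_frames),
        "pixel_size_um_binned": float(config.pixel_size_um),
        "bin_factor": int(config.bin_factor),
        "calibration_behavior": "calibration_behavior.tif",
        "trials": trials,
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))

    sidecar = {
        "seed": int(seed),
        "config": _config_to_jsonable(config),
        "voltage_truth": {k: np.asarray(v).tolist() for k, v in truth.voltage.items()},
        "trials": truth_trials,
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return manifest_path


def _config_to_jsonable(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["regions"] = {k: asdict(v) if not isinstance(v, dict) else v for k, v in config.regions.items()}
    return json.loads(json.dumps(d, default=lambda o: list(o) if hasattr(o, "__iter__") else float(o)))
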