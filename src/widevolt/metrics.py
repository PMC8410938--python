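"""Evoked-response quantification on region-averaged %dR/R traces.

Per trial and region: peak depolarisation amplitude (max over the 20-100 ms
post-stimulus window, relative to the mean of the 10 frames immediately
preceding the stimulus), the 2x-baseline-SD inclusion rule, hyperpolarisation
amplitude/time (minimum between the depolarisation peak and 300 ms), time to
50 % decay, the paired-pulse peak depolarisation ratio (second/first evoked
amplitude, each against its own immediately-preceding baseline), and the
cylinder-test asymmetry index.

Sign convention: depolarisation is positive %dR/R; ``hyp_amp`` is reported as
a positive magnitude of the below-baseline excursion (0 if the trace never
drops below baseline in the window), with ``hyp_time`` the time of the window
minimum either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .registration import RegionTrace

__all__ = [
    "ResponseMetrics",
    "AdaptationResult",
    "CylinderCounts",
    "detect_peak",
    "trial_inclusion",
    "measure_hyperpolarisation",
    "decay50",
    "paired_pulse",
    "asymmetry_index",
    "compute_metrics",
    "PEAK_WINDOW_MS",
    "BASELINE_FRAMES",
    "HYP_WINDOW_END_MS",
]

PEAK_WINDOW_MS = (20.0, 100.0)  # inclusive, post-stimulus
BASELINE_FRAMES = 10  # frames immediately preceding the stimulus (100 ms at 100 Hz)
HYP_WINDOW_END_MS = 300.0
INCLUSION_SD_FACTOR = 2.0


@dataclass
class ResponseMetrics:
    """Per-trial, per-region evoked-response measurements (% and ms units)."""

    trial_id: str
    region: str
    baseline_mean: float
    baseline_sd: float
    peak_amp: float
    peak_time_ms: float
    included: bool
    hyp_amp: float = math.nan
    hyp_time_ms: float = math.nan
    decay50_ms: float = math.nan  # NaN = never reached 50 % decay in the trace
    hyp_sign_convention: str = "magnitude_below_baseline"


@dataclass
class AdaptationResult:
    """Paired-pulse adaptation: ratio of second to first evoked amplitude."""

    trial_id: str
    region: str
    interstim_ms: float
    amp1: float
    amp2: float
    ratio: float  # NaN when amp1 <= 0 (undefined)


@dataclass
class CylinderCounts:
    """Cylinder-test wall-touch counts (left/right/both forelimbs)."""

    left: int
    right: int
    both: int
    n_rearings: int = 20

    def __post_init__(self) -> None:
        if min(self.left, self.right, self.both) < 0:
            raise ValueError("counts must be non-negative")


def _window_indices(
    trace: RegionTrace, stim_index: int, lo_ms: float, hi_ms: float
) -> np.ndarray:
    dt = 1000.0 / trace.frame_rate
    t = (np.arange(len(trace.drr)) - stim_index) * dt
    idx = np.flatnonzero((t >= lo_ms - 1e-9) & (t <= hi_ms + 1e-9))
    return idx


def detect_peak(
    trace: RegionTrace, stim_index: int | None = None
) -> tuple[float, float, float, float]:
    """Peak depolarisation relative to the immediate pre-stimulus baseline.

    Baseline: mean (and SD) of the 10 frames immediately preceding the
    stimulus frame.  Peak: maximum of (trace - baseline) over frames at
    20-100 ms inclusive post-stimulus; ties resolve to the earliest frame.

    Returns ``(peak_amp, peak_time_ms, baseline_mean, baseline_sd)``.
    """
    s = trace.stim_indices[0] if stim_index is None else stim_index
    if s - BASELINE_FRAMES < 0:
        raise ValueError("trace does not cover the 100 ms pre-stimulus baseline")
    base = trace.drr[s - BASELINE_FRAMES : s]
    b_mean = float(base.mean())
    b_sd = float(base.std(ddof=1))
    idx = _window_indices(trace, s, *PEAK_WINDOW_MS)
    if idx.size == 0 or idx[-1] >= len(trace.drr):
        raise ValueError("peak window exceeds trace extent")
    resp = trace.drr[idx] - b_mean
    k = int(np.argmax(resp))  # argmax returns the first (earliest) maximum
    peak_amp = float(resp[k])
    peak_time = (idx[k] - s) * 1000.0 / trace.frame_rate
    return peak_amp, peak_time, b_mean, b_sd


def trial_inclusion(peak_amp: float, baseline_sd: float) -> bool:
    """Inclusion rule: keep trials whose peak reaches 2x the baseline SD.

    The boundary is inclusive (responses *less than* 2 SD are excluded).
    A degenerate flat trace (sd == 0, peak == 0) is excluded.
    """
    if baseline_sd < 0:
        raise ValueError("baseline_sd must be >= 0")
    if baseline_sd == 0 and peak_amp == 0:
        return False
    return peak_amp >= INCLUSION_SD_FACTOR * baseline_sd


def measure_hyperpolarisation(
    trace: RegionTrace,
    peak_time_ms: float,
    baseline_mean: float,
    stim_index: int | None = None,
) -> tuple[float, float]:
    """Minimum of the trace from the depolarisation peak to 300 ms post-stimulus.

    Returns ``(hyp_amp, hyp_time_ms)`` with ``hyp_amp`` the positive magnitude
    of the below-baseline excursion (0 when the trace stays above baseline);
    ties resolve to the earliest frame.
    """
    s = trace.stim_indices[0] if stim_index is None else stim_index
    dt = 1000.0 / trace.frame_rate
    idx = _window_indices(trace, s, peak_time_ms + dt, HYP_WINDOW_END_MS)
    if idx.size == 0:
        raise ValueError("hyperpolarisation window empty or outside the trace")
    exc = trace.drr[idx] - baseline_mean
    k = int(np.argmin(exc))
    hyp_time = (idx[k] - s) * dt
    hyp_amp = float(max(0.0, -exc[k]))
    return hyp_amp, hyp_time


def decay50(
    trace: RegionTrace,
    peak_amp: float,
    peak_time_ms: float,
    baseline_mean: float,
    stim_index: int | None = None,
    interpolate: bool = True,
) -> float:
    """Time (ms post-stimulus) to decay to 50 % of the peak amplitude.

    First time after the peak at which (trace - baseline) <= 0.5 * peak_amp,
    with linear interpolation between the bracketing frames (set
    ``interpolate=False`` for strict frame resolution).  Returns NaN when the
    trace never reaches 50 % decay (flagged, not an error).
    """
    s = trace.stim_indices[0] if stim_index is None else stim_index
    dt = 1000.0 / trace.frame_rate
    target = 0.5 * peak_amp
    k_peak = s + int(round(peak_time_ms / dt))
    exc = trace.drr - baseline_mean
    for i in range(k_peak + 1, len(trace.drr)):
        if exc[i] <= target:
            if not interpolate or exc[i - 1] == exc[i]:
                return (i - s) * dt
            frac = (exc[i - 1] - target) / (exc[i - 1] - exc[i])
            return (i - 1 - s + frac) * dt
    return math.nan


def paired_pulse(
    trace: RegionTrace,
    stim_indices: tuple[int, int] | None = None,
    baseline_frames: int = 2,
    trial_id: str = "",
) -> AdaptationResult:
    """Peak depolarisation ratio for a double-stimulation trial.

    Each stimulus' amplitude is the 20-100 ms window maximum relative to the
    signal immediately preceding that stimulus (mean of ``baseline_frames``
    frames, default 2 = 20 ms).  The ratio amp2/amp1 measures adaptation
    (1 = none); it is NaN (undefined) when amp1 <= 0.
    """
    s1, s2 = stim_indices if stim_indices is not None else trace.stim_indices[:2]
    if s2 - s1 < 2:
        raise ValueError("stimuli must be at least 2 frames apart")
    dt = 1000.0 / trace.frame_rate
    amps = []
    for s in (s1, s2):
        if s - baseline_frames < 0:
            raise ValueError("trace does not cover the pre-stimulus baseline")
        base = float(trace.drr[s - baseline_frames : s].mean())
        idx = _window_indices(trace, s, *PEAK_WINDOW_MS)
        if idx.size == 0 or idx[-1] >= len(trace.drr):
            raise ValueError("peak window exceeds trace extent")
        amps.append(float(np.max(trace.drr[idx] - base)))
    amp1, amp2 = amps
    ratio = amp2 / amp1 if amp1 > 0 else math.nan
    return AdaptationResult(
        trial_id=trial_id,
        region=trace.region,
        interstim_ms=(s2 - s1) * dt,
        amp1=amp1,
        amp2=amp2,
        ratio=ratio,
    )


def asymmetry_index(counts: CylinderCounts, variant: str = "minus") -> float:
    """Cylinder-test forelimb asymmetry index.

    ``variant='minus'`` (default, the published formula):
        AI = (right - both/2) / (right + left + both)
    ``variant='plus'``:
        AI = (right + both/2) / (right + left + both)

    0.5 is the theoretical value for symmetric forelimb use (exact for any
    ``both`` count under the plus variant; for ``both == 0`` under the minus
    variant).
    """
    denom = counts.left + counts.right + counts.both
    if denom <= 0:
        raise ValueError("at least one wall contact is required")
    half = counts.both / 2.0
    if variant == "minus":
        num = counts.right - half
    elif variant == "plus":
        num = counts.right + half
    else:
        raise ValueError(f"unknown AI variant {variant!r}")
    return num / denom


def compute_metrics(
    trace: RegionTrace,
    trial_id: str = "",
    stim_index: int | None = None,
    decay_interpolate: bool = True,
) -> ResponseMetrics:
    """All single-stimulation metrics for one region trace."""
    peak_amp, peak_time, b_mean, b_sd = detect_peak(trace, stim_index)
    included = trial_inclusion(peak_amp, b_sd)
    hyp_amp, hyp_time = measure_hyperpolarisation(trace, peak_time, b_mean, stim_index)
    d50 = decay50(trace, peak_amp, peak_time, b_mean, stim_index, decay_interpolate)
    return ResponseMetrics(
        trial_id=trial_id,
        region=trace.region,
        baseline_mean=b_mean,
        baseline_sd=b_sd,
        peak_amp=peak_amp,
        peak_time_ms=peak_time,
        included=included,
        hyp_amp=hyp_amp,
        hyp_time_ms=hyp_time,
        decay50_ms=d50,
    )
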