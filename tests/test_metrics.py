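"""Peak detection, inclusion rule, hyperpolarisation, decay, adaptation, AI."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from widevolt.metrics import (
    CylinderCounts,
    asymmetry_index,
    compute_metrics,
    decay50,
    detect_peak,
    measure_hyperpolarisation,
    paired_pulse,
    trial_inclusion,
)
from widevolt.synthetic import depol_kernel, rise_tau_for_peak

from conftest import make_trace

STIM = 124  # 0-based index of the stimulus frame in a 200-frame trial


def kernel_trace(a_dep=0.156, peak_ms=60.0, onset_ms=10.0, decay_tau=80.0, n=200, stim=STIM):
    """Noiseless evoked trace built directly from the analytic kernel."""
    rise = rise_tau_for_peak(peak_ms - onset_ms, decay_tau)
    t = (np.arange(n) - stim) * 10.0
    v = a_dep * depol_kernel(t - onset_ms, rise, decay_tau)
    return make_trace(v, stim_indices=(stim,))


class TestDetectPeak:
    def test_flat_trace(self):
        tr = make_trace(np.full(200, 0.3))
        amp, t, b_mean, b_sd = detect_peak(tr)
        assert amp == pytest.approx(0.0, abs=1e-12)
        assert b_mean == pytest.approx(0.3)
        assert b_sd == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_kernel_recovers_amplitude(self):
        tr = kernel_trace(a_dep=0.156, peak_ms=60.0)
        amp, t, _, _ = detect_peak(tr)
        assert amp == pytest.approx(0.156, abs=2e-4)  # temporal quantization only
        assert t == 60.0

    def test_tie_breaks_to_earliest_frame(self):
        v = np.zeros(200)
        v[STIM + 4] = 0.5  # 40 ms
        v[STIM + 8] = 0.5  # 80 ms
        amp, t, _, _ = detect_peak(make_trace(v))
        assert t == 40.0

    def test_window_is_20_to_100_inclusive(self):
        v = np.zeros(200)
        v[STIM + 1] = 9.0  # 10 ms: outside the window
        v[STIM + 11] = 9.0  # 110 ms: outside
        v[STIM + 10] = 0.4  # 100 ms: inside (boundary)
        amp, t, _, _ = detect_peak(make_trace(v))
        assert (amp, t) == (0.4, 100.0)

    def test_baseline_is_ten_preceding_frames(self):
        v = np.zeros(200)
        v[STIM - 10 : STIM] = 1.0
        v[: STIM - 10] = 55.0  # earlier frames must not matter
        amp, t, b_mean, b_sd = detect_peak(make_trace(v))
        assert b_mean == 1.0
        assert amp == -1.0  # window max relative to baseline


class TestInclusion:
    @pytest.mark.parametrize(
        "peak, sd, expected",
        [
            (0.2, 0.05, True),  # 0.2 >= 0.1
            (0.09, 0.05, False),  # below 2x SD
            (0.10, 0.05, True),  # boundary inclusive
            (0.0, 0.0, False),  # degenerate flat trace
        ],
    )
    def test_rule(self, peak, sd, expected):
        assert trial_inclusion(peak, sd) is expected

    def test_false_positive_rate_matches_monte_carlo(self):
        """On pure-noise traces the implementation's inclusion rate equals a
        brute-force vectorized evaluation of max-of-9-frames >= 2*SD-hat."""
        rng = np.random.default_rng(42)
        n = 3000
        included = 0
        for _ in range(n):
            tr = make_trace(rng.standard_normal(200))
            amp, _, _, sd = detect_peak(tr)
            included += trial_inclusion(amp, sd)
        rate_impl = included / n

        # independent oracle: direct numpy evaluation of the rule
        rng2 = np.random.default_rng(43)
        traces = rng2.standard_normal((n, 200))
        base = traces[:, STIM - 10 : STIM]
        b_mean = base.mean(axis=1)
        b_sd = base.std(axis=1, ddof=1)
        window = traces[:, STIM + 2 : STIM + 11]
        peak = window.max(axis=1) - b_mean
        rate_oracle = np.mean(peak >= 2 * b_sd)

        se = math.sqrt(rate_oracle * (1 - rate_oracle) / n) * math.sqrt(2)
        assert abs(rate_impl - rate_oracle) <= 4 * se


class TestHyperpolarisation:
    def test_monotone_decay_never_below_baseline(self):
        tr = kernel_trace(a_dep=0.2, peak_ms=60.0)
        amp, t, b_mean, _ = detect_peak(tr)
        hyp_amp, hyp_time = measure_hyperpolarisation(tr, t, b_mean)
        assert hyp_amp == 0.0
        assert hyp_time == 300.0  # kernel decays monotonically: min at window end

    def test_known_negative_excursion(self):
        v = np.zeros(200)
        v[STIM + 6] = 0.3
        v[STIM + 18] = -0.1  # 180 ms
        hyp_amp, hyp_time = measure_hyperpolarisation(make_trace(v), 60.0, 0.0)
        assert hyp_amp == pytest.approx(0.1)
        assert hyp_time == 180.0

    def test_ties_resolve_to_earliest(self):
        v = np.zeros(200)
        v[STIM + 12] = -0.2
        v[STIM + 20] = -0.2
        _, hyp_time = measure_hyperpolarisation(make_trace(v), 60.0, 0.0)
        assert hyp_time == 120.0


class TestDecay50:
    def test_triangular_geometry(self):
        """Rise to A at 60 ms, linear to 0 at 160 ms: 50% crossing at 110 ms."""
        v = np.zeros(200)
        up = np.linspace(0, 1.0, 7)  # frames stim..stim+6
        down = np.linspace(1.0, 0.0, 11)  # frames stim+6..stim+16
        v[STIM : STIM + 7] = up
        v[STIM + 6 : STIM + 17] = down
        assert decay50(make_trace(v), 1.0, 60.0, 0.0) == pytest.approx(110.0)

    def test_exponential_half_life(self):
        tau = 70.0
        t = (np.arange(200) - STIM) * 10.0
        v = np.where(t >= 60.0, np.exp(-(t - 60.0) / tau), 0.0)
        v[(t > 0) & (t < 60)] = np.linspace(0.1, 0.9, ((t > 0) & (t < 60)).sum())
        d = decay50(make_trace(v), 1.0, 60.0, 0.0)
        assert d == pytest.approx(60.0 + tau * math.log(2), abs=10.0)

    def test_plateau_flagged_undefined(self):
        v = np.zeros(200)
        v[STIM + 6 :] = 1.0
        assert math.isnan(decay50(make_trace(v), 1.0, 60.0, 0.0))

    def test_frame_resolution_mode(self):
        v = np.zeros(200)
        v[STIM + 6] = 1.0
        v[STIM + 7 :] = 0.2
        d = decay50(make_trace(v), 1.0, 60.0, 0.0, interpolate=False)
        assert d == 70.0


class TestPairedPulse:
    def test_identical_nonoverlapping_responses_ratio_one(self):
        """Two verbatim copies of a compact response 400 ms apart: ratio 1."""
        v = np.zeros(200)
        pulse = np.sin(np.linspace(0, np.pi, 9)) * 0.2  # 90 ms half-sine
        v[STIM + 2 : STIM + 11] = pulse
        v[STIM + 42 : STIM + 51] = pulse
        res = paired_pulse(make_trace(v, stim_indices=(STIM, STIM + 40)))
        assert res.ratio == pytest.approx(1.0, abs=1e-12)
        assert res.interstim_ms == 400.0

    def test_absent_second_response_ratio_zero(self):
        v = np.zeros(200)
        v[STIM + 6] = 0.2
        res = paired_pulse(make_trace(v, stim_indices=(STIM, STIM + 40)))
        assert res.ratio == 0.0
        assert res.ratio < 1.0  # adaptation signature

    def test_overlapping_kernels_match_analytic_oracle(self):
        """At a 100 ms gap the first kernel's tail rides under the second
        response; the implementation must match a direct evaluation of the
        summed analytic kernels under the same baseline rule."""
        rise = rise_tau_for_peak(50.0, 80.0)
        t = (np.arange(200) - STIM) * 10.0
        k1 = 0.2 * depol_kernel(t - 10.0, rise, 80.0)
        k2 = 0.2 * depol_kernel(t - 100.0 - 10.0, rise, 80.0)
        v = k1 + k2
        res = paired_pulse(make_trace(v, stim_indices=(STIM, STIM + 10)))

        def oracle_amp(sig, s):
            base = sig[s - 2 : s].mean()
            return (sig[s + 2 : s + 11] - base).max()

        a1 = oracle_amp(v, STIM)
        a2 = oracle_amp(v, STIM + 10)
        assert res.amp1 == pytest.approx(a1, abs=1e-12)
        assert res.amp2 == pytest.approx(a2, abs=1e-12)
        assert res.ratio == pytest.approx(a2 / a1, abs=1e-12)

    def test_nonpositive_first_amplitude_flagged(self):
        v = np.zeros(200)
        v[STIM + 2 : STIM + 11] = -0.5
        res = paired_pulse(make_trace(v, stim_indices=(STIM, STIM + 40)))
        assert math.isnan(res.ratio)


class TestAsymmetryIndex:
    def test_symmetric_use_is_half(self):
        c = CylinderCounts(left=10, right=10, both=0)
        assert asymmetry_index(c, "minus") == 0.5
        assert asymmetry_index(c, "plus") == 0.5

    def test_pure_right_is_one(self):
        assert asymmetry_index(CylinderCounts(left=0, right=10, both=0)) == 1.0

    def test_both_counts_split_variants(self):
        c = CylinderCounts(left=10, right=10, both=10)
        assert asymmetry_index(c, "minus") == pytest.approx((10 - 5) / 30)
        assert asymmetry_index(c, "plus") == pytest.approx(0.5)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_index(CylinderCounts(left=0, right=0, both=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CylinderCounts(left=-1, right=0, both=0)


class TestMetricInvariances:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(k=st.floats(0.1, 10.0), c=st.floats(-5.0, 5.0), seed=st.integers(0, 1000))
    def test_scale_equivariance_and_shift_invariance(self, k, c, seed):
        """Scaling a trace by k scales amplitudes by k and leaves all times
        and the adaptation ratio unchanged; adding a constant changes nothing."""
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 0.05, 200)
        v[STIM + 4 : STIM + 9] += np.array([0.2, 0.5, 0.6, 0.4, 0.2])
        base = compute_metrics(make_trace(v))
        scaled = compute_metrics(make_trace(k * v))
        shifted = compute_metrics(make_trace(v + c))
        assert scaled.peak_amp == pytest.approx(k * base.peak_amp, rel=1e-9)
        assert scaled.hyp_amp == pytest.approx(k * base.hyp_amp, rel=1e-9, abs=1e-12)
        assert scaled.peak_time_ms == base.peak_time_ms
        assert scaled.hyp_time_ms == base.hyp_time_ms
        assert scaled.included == base.included
        assert shifted.peak_amp == pytest.approx(base.peak_amp, abs=1e-9)
        assert shifted.peak_time_ms == base.peak_time_ms
        if not math.isnan(base.decay50_ms):
            assert scaled.decay50_ms == pytest.approx(base.decay50_ms, rel=1e-9)
            assert shifted.decay50_ms == pytest.approx(base.decay50_ms, abs=1e-6)
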