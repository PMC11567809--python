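"""Baseline estimation, transient detection, and activity metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catrace import (
    AcquisitionParams,
    CohortSpec,
    NeuronSpec,
    compute_metrics,
    detect_transients,
    estimate_baseline,
    session_metrics,
    simulate_session,
)
from catrace.transients import BaselineEstimate, TransientSet


def brute_force_baseline(x, window_fraction=0.15, k=5.0):
    """Independent exhaustive scan over every window (ties -> earliest)."""
    n = len(x)
    w = max(2, int(round(window_fraction * n)))
    best_start, best_sd = 0, np.inf
    for start in range(n - w + 1):
        sd = np.std(x[start : start + w], ddof=1)
        if sd < best_sd:
            best_start, best_sd = start, sd
    mean = float(np.mean(x[best_start : best_start + w]))
    return best_start, mean, float(best_sd), mean + k * float(best_sd)


class TestEstimateBaseline:
    def test_constant_trace(self):
        b = estimate_baseline(np.full(100, 3.7))
        assert b.baseline_mean == pytest.approx(3.7)
        assert b.baseline_sd == pytest.approx(0.0, abs=1e-12)
        assert b.threshold == pytest.approx(3.7)

    def test_zero_sd_window_wins(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.zeros(15), rng.normal(1.0, 0.5, 85)])
        b = estimate_baseline(x)
        assert (b.window_start_frame, b.window_end_frame) == (0, 15)
        assert b.threshold == 0.0

    @pytest.mark.parametrize("n", [20, 73, 200, 517])
    def test_matches_brute_force_scan(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(0, 1, n) + np.sin(np.arange(n) / 17)
        b = estimate_baseline(x)
        start, mean, sd, thr = brute_force_baseline(x)
        assert b.window_start_frame == start
        assert b.baseline_mean == pytest.approx(mean)
        assert b.baseline_sd == pytest.approx(sd)
        assert b.threshold == pytest.approx(thr)

    @given(st.integers(0, 10_000), st.integers(20, 300))
    @settings(max_examples=60, deadline=None)
    def test_brute_force_property(self, seed, n):
        x = np.random.default_rng(seed).normal(0, 1, n)
        b = estimate_baseline(x)
        start, _, sd, _ = brute_force_baseline(x)
        assert b.window_start_frame == start
        assert b.baseline_sd == pytest.approx(sd)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            estimate_baseline(np.zeros(5), window_fraction=0.15)

    def test_non_finite_rejected(self):
        x = np.zeros(50)
        x[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            estimate_baseline(x)


def zero_baseline():
    return BaselineEstimate(0, 2, baseline_mean=0.0, baseline_sd=0.0, threshold=0.0)


class TestDetectTransients:
    def test_flat_trace_no_events(self):
        ts = detect_transients(np.zeros(100), zero_baseline(), 2.0)
        assert len(ts) == 0

    def test_single_rectangular_pulse(self):
        x = np.zeros(100)
        x[50:55] = 1.0
        ts = detect_transients(x, zero_baseline(), 2.0)
        assert len(ts) == 1
        t = ts.transients[0]
        assert (t.onset_frame, t.offset_frame) == (50, 55)
        assert t.peak_value == 1.0
        assert t.area == pytest.approx(5 * 0.5 * 1.0)

    def test_three_pulses_match_crossing_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.01, 300)
        for start in (50, 120, 200):
            x[start : start + 4] += 1.0
        b = estimate_baseline(x)
        ts = detect_transients(x, b, 2.0)
        # oracle: count upward threshold crossings frame by frame
        above = x > b.threshold
        crossings = int(above[0]) + int(np.sum(~above[:-1] & above[1:]))
        assert len(ts) == crossings == 3

    def test_shift_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 0.05, 200)
        x[40:44] += 1.0
        x[150:154] += 0.8
        for shift in (0.0, -3.0, 42.0):
            y = x + shift
            b = estimate_baseline(y)
            ts = detect_transients(y, b, 2.0)
            assert [(t.onset_frame, t.offset_frame) for t in ts.transients] == [
                (40, 44),
                (150, 154),
            ]

    def test_extra_pulse_adds_exactly_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.01, 400)
        for start in (60, 160):
            x[start : start + 3] += 1.0
        b = estimate_baseline(x)
        n_before = len(detect_transients(x, b, 2.0))
        x2 = x.copy()
        x2[300:303] += 1.0
        n_after = len(detect_transients(x2, b, 2.0))
        assert n_after == n_before + 1

    def test_min_frames_filter(self):
        x = np.zeros(50)
        x[10] = 1.0
        x[30:33] = 1.0
        assert len(detect_transients(x, zero_baseline(), 2.0, min_frames=1)) == 2
        assert len(detect_transients(x, zero_baseline(), 2.0, min_frames=2)) == 1


class TestComputeMetrics:
    def _ts(self, peaks, areas=None):
        from catrace.transients import Transient

        areas = areas or [0.0] * len(peaks)
        events = [
            Transient(onset_frame=i * 10, offset_frame=i * 10 + 2, peak_value=p, area=a)
            for i, (p, a) in enumerate(zip(peaks, areas))
        ]
        return TransientSet(transients=events, baseline=zero_baseline())

    def test_frequency_three_per_100s(self):
        m = compute_metrics(self._ts([1, 1, 1]), duration_s=100.0, frame_rate_hz=2.0)
        assert m.frequency_per_min == pytest.approx(1.8)

    def test_auc_per_min_single_pulse(self):
        x = np.zeros(120)  # 60 s at 2 Hz
        x[40:45] = 1.0
        ts = detect_transients(x, zero_baseline(), 2.0)
        m = compute_metrics(ts, duration_s=60.0, frame_rate_hz=2.0)
        assert m.total_activity_per_min == pytest.approx(2.5)

    def test_peak_and_mean_amplitude(self):
        m = compute_metrics(self._ts([0.5, 1.5]), duration_s=60.0, frame_rate_hz=2.0)
        assert m.peak_amplitude == pytest.approx(1.5)
        assert m.mean_amplitude == pytest.approx(1.0)

    def test_zero_transients_nan_amplitudes(self):
        m = compute_metrics(self._ts([]), duration_s=60.0, frame_rate_hz=2.0)
        assert m.frequency_per_min == 0.0
        assert np.isnan(m.peak_amplitude) and np.isnan(m.mean_amplitude)


def resolvable_cohort(rates_hz, seed, amplitude=0.8):
    specs = [
        NeuronSpec(rest_rate_hz=r, amplitude_mean=amplitude, amplitude_sd=0.0)
        for r in rates_hz
    ]
    return CohortSpec(
        n_neurons=len(specs),
        neuron_specs=specs,
        kernel_rise_s=0.05,
        kernel_decay_s=0.3,
        noise_sd=0.02,
        drift_amplitude=0.0,
        modulation_depth=0.0,
        seed=seed,
    )


class TestParameterRecovery:
    ACQ = AcquisitionParams(frame_rate_hz=10.0, rest_block_s=100.0, n_running_trials=1)

    def test_all_zero_cohort_all_zero_frequency(self):
        spec = resolvable_cohort([0.0] * 3, seed=0)
        trace, _, _ = simulate_session(spec)
        m = session_metrics(trace, "rest")
        assert (m["frequency_per_min"] == 0).all()

    def test_detected_frequency_tracks_true_rate(self):
        """Mean detected resting frequency at 4/min stays inside the
        Poisson 95% band for a 100 s observation, across many seeds."""
        lo, hi = (np.array([2, 12]) / (100 / 60))  # central 95% of Poisson(6.67)
        means = []
        for seed in range(50):
            spec = resolvable_cohort([4.0 / 60.0] * 10, seed=seed)
            trace, _, _ = simulate_session(spec, self.ACQ)
            means.append(session_metrics(trace, "rest")["frequency_per_min"].mean())
        assert lo <= np.mean(means) <= hi
        assert np.mean(means) == pytest.approx(4.0, rel=0.15)

    def test_doubling_rate_doubles_detected_frequency(self):
        freqs = {}
        for rate in (2.0, 4.0):
            vals = []
            for seed in range(30):
                spec = resolvable_cohort([rate / 60.0] * 10, seed=seed)
                trace, _, _ = simulate_session(spec, self.ACQ)
                vals.append(session_metrics(trace, "rest")["frequency_per_min"].mean())
            freqs[rate] = np.mean(vals)
        assert freqs[4.0] / freqs[2.0] == pytest.approx(2.0, rel=0.25)

    def test_detected_amplitude_correlates_with_truth(self):
        true_amps = np.linspace(0.3, 1.5, 12)
        spec = CohortSpec(
            n_neurons=12,
            neuron_specs=[
                NeuronSpec(rest_rate_hz=2.0 / 60.0, amplitude_mean=a, amplitude_sd=0.0)
                for a in true_amps
            ],
            kernel_rise_s=0.05,
            kernel_decay_s=0.3,
            noise_sd=0.02,
            drift_amplitude=0.0,
            modulation_depth=0.0,
            seed=17,
        )
        trace, _, _ = simulate_session(spec, self.ACQ)
        m = session_metrics(trace, "rest")
        keep = m["n_transients"] > 0
        r = np.corrcoef(true_amps[keep], m.loc[keep, "mean_amplitude"])[0, 1]
        assert r > 0.95
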