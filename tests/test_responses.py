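"""Onset alignment, trial averaging, and response categorization."""

import numpy as np
import pytest

from catrace import (
    align_and_average,
    categorize_response,
    categorize_session,
    persistence_frames,
    response_fractions,
    response_table,
    sort_by_peak_time,
)
from catrace.responses import AlignedTraces
from catrace.session import SessionError
from conftest import make_session


def five_trial_windows(pre=50, run=200, iti=50, n_trials=5):
    """Schedule like the treadmill protocol: rest block then run/ITI."""
    windows, cursor = [(0, pre, "rest")], pre
    for k in range(n_trials):
        windows.append((cursor, cursor + run, "run"))
        cursor += run
        if k < n_trials - 1:
            windows.append((cursor, cursor + iti, "inter_trial"))
            cursor += iti
    return windows, cursor


class TestAlignAndAverage:
    def test_constant_trials_average_to_constant(self):
        windows, n = five_trial_windows()
        trace, _ = make_session(np.full((n, 2), 3.3), windows)
        aligned = align_and_average(trace)
        assert np.allclose(aligned.values, 3.3)
        assert aligned.onset_index == 50
        assert aligned.n_trials == 5

    def test_per_trial_constants_average_to_mean(self):
        windows, n = five_trial_windows()
        values = np.zeros((n, 1))
        v_t = [1.0, 2.0, 3.0, 4.0, 5.0]
        for k, (start, end, state) in enumerate(w for w in windows if w[2] == "run"):
            pass
        run_windows = [w for w in windows if w[2] == "run"]
        for v, (start, end, _) in zip(v_t, run_windows):
            values[start:end] = v
        trace, _ = make_session(values, windows)
        aligned = align_and_average(trace)
        post = aligned.values[0, aligned.onset_index :]
        assert np.allclose(post, np.mean(v_t))

    def test_matches_independent_reimplementation(self):
        windows, n = five_trial_windows(pre=40, run=100, iti=30, n_trials=4)
        rng = np.random.default_rng(8)
        values = rng.normal(size=(n, 3))
        trace, _ = make_session(values, windows)
        aligned = align_and_average(trace)

        # oracle: segment, stack, mean, written from the schedule directly
        run_windows = [w for w in windows if w[2] == "run"]
        pre_lens, segs = [], []
        for start, end, _ in run_windows:
            prev = [w for w in windows if w[1] == start][0]
            pre_lens.append(prev[1] - prev[0])
        pre = min(pre_lens)
        run = min(e - s for s, e, _ in run_windows)
        for start, _, _ in run_windows:
            segs.append(values[start - pre : start + run])
        oracle = np.mean(segs, axis=0).T
        np.testing.assert_allclose(aligned.values, oracle)
        assert aligned.onset_index == pre

    def test_no_running_trials_is_error(self):
        trace, _ = make_session(np.zeros((100, 1)), [(0, 100, "rest")])
        with pytest.raises(SessionError, match="no running trials"):
            align_and_average(trace)


def profile(post, pre_sd=1.0, pre_len=50, rng=None):
    """Aligned trace with N(0, pre_sd) pre-onset segment and given post."""
    rng = rng or np.random.default_rng(0)
    pre = rng.normal(0, pre_sd, pre_len)
    pre = (pre - pre.mean()) / pre.std(ddof=1) * pre_sd  # exact mean 0, sd pre_sd
    return np.concatenate([pre, np.asarray(post, dtype=float)]), pre_len


class TestCategorizeResponse:
    def test_sustained_positive_deviation_is_activated(self):
        post = np.zeros(100)
        post[10:13] = 5.0  # 3 frames at +5 SD
        x, onset = profile(post)
        cat, _, _, _ = categorize_response(x, onset, 2.0)
        assert cat == "activated"

    def test_two_frame_deviation_is_rejected(self):
        post = np.zeros(100)
        post[10:12] = 5.0  # only 2 frames: below the 1.5 s persistence
        x, onset = profile(post)
        cat, _, _, _ = categorize_response(x, onset, 2.0)
        assert cat == "no_change"

    def test_both_directions_is_mixed(self):
        post = np.zeros(100)
        post[10:13] = 4.0
        post[60:63] = -4.0
        x, onset = profile(post)
        cat, _, _, _ = categorize_response(x, onset, 2.0)
        assert cat == "mixed"

    def test_sustained_negative_is_suppressed(self):
        post = np.zeros(100)
        post[20:25] = -4.0
        x, onset = profile(post)
        cat, _, _, _ = categorize_response(x, onset, 2.0)
        assert cat == "suppressed"

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        post = rng.normal(0, 1, 100)
        post[30:35] += 8.0
        x, onset = profile(post, rng=rng)
        for gain in (1.0, 0.01, 250.0):
            cat, _, _, _ = categorize_response(x * gain, onset, 2.0)
            assert cat == categorize_response(x, onset, 2.0)[0]

    def test_zero_baseline_sd_floored_and_flagged(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        cat, _, sd, floored = categorize_response(x, 50, 2.0)
        assert floored and sd > 0
        assert cat == "activated"

    def test_persistence_frames_scale_with_rate(self):
        assert persistence_frames(2.0) == 3
        assert persistence_frames(10.0) == 15
        assert persistence_frames(1.0) == 2


class TestResponseFractions:
    def _table(self, cats, animals=None):
        import pandas as pd

        animals = animals or ["a"] * len(cats)
        return pd.DataFrame(
            {"animal_id": animals, "neuron_id": [f"n{i}" for i in range(len(cats))], "category": cats}
        )

    def test_fraction_arithmetic(self):
        out = response_fractions(
            self._table(["activated", "activated", "suppressed", "no_change"]), "pooled"
        ).iloc[0]
        assert out["activated"] == pytest.approx(0.5)
        assert out["suppressed"] == pytest.approx(0.25)
        assert out["mixed"] == 0.0
        assert out["no_change"] == pytest.approx(0.25)

    def test_invariant_to_neuron_order(self):
        cats = ["activated", "mixed", "no_change", "suppressed", "activated"]
        a = response_fractions(self._table(cats), "pooled")
        b = response_fractions(self._table(cats[::-1]), "pooled")
        for c in ("activated", "suppressed", "mixed", "no_change"):
            assert a[c].iloc[0] == b[c].iloc[0]

    def test_each_neuron_gets_exactly_one_category(self):
        windows, n = five_trial_windows()
        rng = np.random.default_rng(5)
        trace, _ = make_session(rng.normal(0, 0.1, (n, 4)), windows)
        profiles, _ = categorize_session(trace)
        table = response_table(profiles)
        assert len(table) == 4
        assert table["category"].isin(["activated", "suppressed", "mixed", "no_change"]).all()


class TestSortByPeakTime:
    def _aligned(self, rows, ids=None):
        rows = np.asarray(rows, dtype=float)
        return AlignedTraces(
            values=rows,
            neuron_ids=ids or [f"n{i}" for i in range(rows.shape[0])],
            onset_index=2,
            frame_rate_hz=2.0,
            n_trials=5,
        )

    def test_orders_by_peak_time(self):
        rows = np.zeros((3, 50))
        rows[0, 20] = 1.0  # peak at index 20
        rows[1, 10] = 1.0
        rows[2, 40] = 1.0
        order, _ = sort_by_peak_time(self._aligned(rows))
        assert list(order) == [1, 0, 2]

    def test_identical_traces_fall_back_to_id_order(self):
        rows = np.tile(np.sin(np.linspace(0, 3, 50)), (3, 1))
        order, _ = sort_by_peak_time(self._aligned(rows, ids=["c", "a", "b"]))
        assert list(order) == [1, 2, 0]

    def test_normalization_preserves_order_for_unique_maxima(self):
        rng = np.random.default_rng(6)
        rows = rng.normal(size=(8, 60))
        aligned = self._aligned(rows)
        o1, _ = sort_by_peak_time(aligned, normalize=False)
        o2, raster = sort_by_peak_time(aligned, normalize=True)
        assert list(o1) == list(o2)
        assert raster.min() >= 0.0 and raster.max() <= 1.0
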