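"""Baseline estimation, Ca²⁺ transient detection, and activity metrics.

The baseline of a ΔF/F trace is the sliding window (15% of the trace
length by default, stepped one frame at a time) with minimal standard
deviation; the detection threshold is that window's mean plus five times
its SD. A transient is a maximal run of consecutive frames strictly above
threshold. Four per-neuron statistics summarize activity: transient
frequency (events/min), peak amplitude (maximum transient value in the
trace), mean amplitude (average of transient peaks), and total activity
(area under the baseline-subtracted curve over transient frames, per
minute).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import REST, TraceMatrix, slice_state


@dataclass(frozen=True)
class BaselineEstimate:
    """Minimum-SD window statistics and the derived detection threshold."""

    window_start_frame: int
    window_end_frame: int
    baseline_mean: float
    baseline_sd: float
    threshold: float


@dataclass(frozen=True)
class Transient:
    """One supra-threshold event: half-open frame run, peak, and area.

    ``area`` is the left-Riemann sum of (value - baseline_mean) over the
    run, in (ΔF/F)·s.
    """

    onset_frame: int
    offset_frame: int
    peak_value: float
    area: float


@dataclass
class TransientSet:
    """Detected transients of one trace plus the baseline that produced them."""

    transients: list[Transient]
    baseline: BaselineEstimate

    def __len__(self) -> int:
        return len(self.transients)

    @property
    def peaks(self) -> np.ndarray:
        return np.array([t.peak_value for t in self.transients])

    @property
    def total_area(self) -> float:
        return float(sum(t.area for t in self.transients))


@dataclass(frozen=True)
class NeuronMetrics:
    """The four activity statistics of one neuron (one state-slice).

    Amplitudes are NaN when the trace has no detected transients; such
    neurons still contribute frequency = 0.
    """

    n_transients: int
    frequency_per_min: float
    peak_amplitude: float
    mean_amplitude: float
    total_activity_per_min: float


def estimate_baseline(
    trace_1d: np.ndarray, window_fraction: float = 0.15, k: float = 5.0
) -> BaselineEstimate:
    """Select the minimum-SD sliding window as baseline.

    Window length is round(window_fraction * n), at least 2 frames; the
    window slides one frame at a time and ties go to the earliest window.
    Threshold = window mean + k * window SD (sample SD, ddof=1). A zero-SD
    window yields threshold = mean, so any positive excursion is detected.
    """
    x = np.asarray(trace_1d, dtype=float)
    if x.ndim != 1:
        raise ValueError("trace must be 1-D")
    if not np.isfinite(x).all():
        raise ValueError("trace contains non-finite values")
    n = x.size
    if n < math.ceil(1.0 / window_fraction):
        raise ValueError(
            f"trace too short ({n} frames) for window_fraction={window_fraction}"
        )
    w = max(2, int(round(window_fraction * n)))
    windows = np.lib.stride_tricks.sliding_window_view(x, w)
    sds = windows.std(axis=1, ddof=1)
    start = int(np.argmin(sds))  # argmin returns the first minimum
    mean = float(windows[start].mean())
    sd = float(sds[start])
    return BaselineEstimate(
        window_start_frame=start,
        window_end_frame=start + w,
        baseline_mean=mean,
        baseline_sd=sd,
        threshold=mean + k * sd,
    )


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean vector."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_transients(
    trace_1d: np.ndarray,
    baseline: BaselineEstimate,
    frame_rate_hz: float,
    min_frames: int = 1,
) -> TransientSet:
    """Find maximal runs of frames strictly above the detection threshold.

    Runs shorter than ``min_frames`` are discarded (default keeps all).
    Peak is the maximum value in the run; area is the baseline-subtracted
    left-Riemann sum over the run at 1/frame_rate per frame.
    """
    x = np.asarray(trace_1d, dtype=float)
    dt = 1.0 / frame_rate_hz
    events = []
    for start, end in _runs_above(x > baseline.threshold):
        if end - start < min_frames:
            continue
        seg = x[start:end]
        events.append(
            Transient(
                onset_frame=start,
                offset_frame=end,
                peak_value=float(seg.max()),
                area=float((seg - baseline.baseline_mean).sum() * dt),
            )
        )
    return TransientSet(transients=events, baseline=baseline)


def compute_metrics(
    transients: TransientSet, duration_s: float, frame_rate_hz: float
) -> NeuronMetrics:
    """Summarize a TransientSet into the four activity statistics."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = len(transients)
    minutes = duration_s / 60.0
    peaks = transients.peaks
    return NeuronMetrics(
        n_transients=n,
        frequency_per_min=n / minutes,
        peak_amplitude=float(peaks.max()) if n else float("nan"),
        mean_amplitude=float(peaks.mean()) if n else float("nan"),
        total_activity_per_min=transients.total_area / minutes,
    )


def session_metrics(
    trace: TraceMatrix,
    state: str,
    window_fraction: float = 0.15,
    k: float = 5.0,
    min_frames: int = 1,
    include_inter_trial: bool = False,
    baseline_scope: str = "state",
    animal_id: str | None = None,
) -> pd.DataFrame:
    """Per-neuron activity metrics for one behavioral state of a session.

    Each neuron's trace is restricted to the requested state (short
    inter-trial rests excluded by default), a baseline is estimated on
    that slice (``baseline_scope="state"``, the default) or on the whole
    session (``"session"``), transients are detected, and the four
    statistics are computed. Returns a tidy table with one row per neuron.
    """
    if baseline_scope not in ("state", "session"):
        raise ValueError("baseline_scope must be 'state' or 'session'")
    sliced = slice_state(trace, state, include_inter_trial=include_inter_trial)
    duration_s = sliced.n_frames / trace.frame_rate_hz
    rows = []
    for i, nid in enumerate(trace.neuron_ids):
        x = sliced.values[:, i]
        if baseline_scope == "session":
            baseline = estimate_baseline(trace.values[:, i], window_fraction, k)
        else:
            baseline = estimate_baseline(x, window_fraction, k)
        ts = detect_transients(x, baseline, trace.frame_rate_hz, min_frames)
        m = compute_metrics(ts, duration_s, trace.frame_rate_hz)
        rows.append(
            {
                "animal_id": animal_id or "",
                "neuron_id": nid,
                "state": state,
                "n_transients": m.n_transients,
                "frequency_per_min": m.frequency_per_min,
                "peak_amplitude": m.peak_amplitude,
                "mean_amplitude": m.mean_amplitude,
                "total_activity_per_min": m.total_activity_per_min,
            }
        )
    return pd.DataFrame(rows)


def animal_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean of each metric over neurons, one row per animal.

    Amplitude columns average only neurons with at least one transient
    (NaN amplitudes are skipped); frequency and total activity average all
    neurons.
    """
    cols = [
        "frequency_per_min",
        "peak_amplitude",
        "mean_amplitude",
        "total_activity_per_min",
    ]
    return metrics.groupby("animal_id", sort=True)[cols].mean().reset_index()
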