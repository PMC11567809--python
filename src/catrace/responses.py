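"""Running-response categorization from onset-aligned, trial-averaged traces.

Each neuron's ΔF/F is segmented around every treadmill onset (a pre-onset
stationary stretch plus the running trial), trials are truncated to the
shortest common lengths and averaged. The pre-onset segment of the
averaged trace provides a baseline mean and SD; the post-onset trace,
baseline-subtracted, is scanned for qualifying deviations: at least ``m``
consecutive frames beyond ``c`` baseline SDs (defaults 3 frames and 3 SD;
at 2 Hz, 3 frames span the 1.5 s persistence requirement). Positive-only
deviations mark a neuron activated, negative-only suppressed, both mixed,
neither no-change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import RUN, SessionError, TraceMatrix
from .synth import ACTIVATED, MIXED, NO_CHANGE, SUPPRESSED
from .transients import _runs_above


@dataclass
class AlignedTraces:
    """Trial-averaged onset-aligned traces for all neurons of a session.

    ``values`` is neurons x time; column ``onset_index`` is the first
    running frame, preceding columns are the stationary baseline segment.
    """

    values: np.ndarray
    neuron_ids: list[str]
    onset_index: int
    frame_rate_hz: float
    n_trials: int

    @property
    def time_s(self) -> np.ndarray:
        """Time axis relative to treadmill onset (s)."""
        return (np.arange(self.values.shape[1]) - self.onset_index) / self.frame_rate_hz


@dataclass
class ResponseProfile:
    """One neuron's aligned trace, baseline statistics, and category."""

    neuron_id: str
    aligned_trace: np.ndarray
    baseline_mean: float
    baseline_sd: float
    category: str
    peak_time_s: float
    sd_floored: bool = False


def persistence_frames(frame_rate_hz: float, persistence_s: float = 1.5) -> int:
    """Frames spanning the persistence requirement at a given frame rate.

    At the native 2 Hz acquisition this is 3 frames = 1.5 s; at other
    rates the duration criterion is preserved (ceil of rate x 1.5 s).
    """
    return max(1, math.ceil(persistence_s * frame_rate_hz))


def align_and_average(trace: TraceMatrix) -> AlignedTraces:
    """Average onset-aligned segments across running trials.

    Each running trial contributes its run frames plus the contiguous
    stationary (rest or inter-trial rest) frames immediately preceding the
    onset. Pre- and post-onset segments are truncated to the shortest
    lengths common to all trials.
    """
    trial_ids = np.unique(trace.trial_id[trace.trial_id >= 0])
    if trial_ids.size == 0:
        raise SessionError("session has no running trials")
    pre_spans: list[tuple[int, int]] = []  # [pre_start, onset)
    run_spans: list[tuple[int, int]] = []
    state = trace.state_per_frame
    for k in trial_ids:
        idx = np.flatnonzero(trace.trial_id == k)
        onset, end = int(idx[0]), int(idx[-1]) + 1
        pre_start = onset
        while pre_start > 0 and state[pre_start - 1] != RUN:
            pre_start -= 1
        if pre_start == onset:
            raise SessionError(
                f"running trial {int(k)} has no preceding stationary segment"
            )
        pre_spans.append((pre_start, onset))
        run_spans.append((onset, end))
    pre_len = min(onset - start for start, onset in pre_spans)
    run_len = min(end - onset for onset, end in run_spans)
    stacks = []
    for (pre_start, onset), (_, _end) in zip(pre_spans, run_spans):
        seg = trace.values[onset - pre_len : onset + run_len]
        stacks.append(seg)
    mean = np.mean(stacks, axis=0).T  # neurons x time
    return AlignedTraces(
        values=mean,
        neuron_ids=list(trace.neuron_ids),
        onset_index=pre_len,
        frame_rate_hz=trace.frame_rate_hz,
        n_trials=int(trial_ids.size),
    )


def categorize_response(
    aligned_1d: np.ndarray,
    onset_index: int,
    frame_rate_hz: float,
    m: int | None = None,
    c: float = 3.0,
    sd_floor: float = 1e-12,
) -> tuple[str, float, float, bool]:
    """Categorize one aligned trace; returns (category, mean, sd, floored).

    The baseline mean and SD come from the pre-onset segment of the
    trial-averaged trace. Only post-onset frames are scanned for
    qualifying runs. A zero baseline SD is replaced by ``sd_floor`` and
    flagged.
    """
    x = np.asarray(aligned_1d, dtype=float)
    if not (0 < onset_index < x.size):
        raise ValueError("onset_index must fall inside the trace")
    if m is None:
        m = persistence_frames(frame_rate_hz)
    base = x[:onset_index]
    mu = float(base.mean())
    sd = float(base.std(ddof=1)) if base.size > 1 else 0.0
    floored = False
    if not np.isfinite(sd) or sd < sd_floor:
        sd = sd_floor
        floored = True
    post = x[onset_index:] - mu
    pos = any(end - start >= m for start, end in _runs_above(post > c * sd))
    neg = any(end - start >= m for start, end in _runs_above(post < -c * sd))
    if pos and neg:
        cat = MIXED
    elif pos:
        cat = ACTIVATED
    elif neg:
        cat = SUPPRESSED
    else:
        cat = NO_CHANGE
    return cat, mu, sd, floored


def categorize_session(
    trace: TraceMatrix,
    m: int | None = None,
    c: float = 3.0,
    sd_floor: float = 1e-12,
) -> tuple[list[ResponseProfile], AlignedTraces]:
    """Align, average, and categorize every neuron of a session."""
    aligned = align_and_average(trace)
    profiles = []
    for i, nid in enumerate(aligned.neuron_ids):
        row = aligned.values[i]
        cat, mu, sd, floored = categorize_response(
            row, aligned.onset_index, aligned.frame_rate_hz, m=m, c=c, sd_floor=sd_floor
        )
        profiles.append(
            ResponseProfile(
                neuron_id=nid,
                aligned_trace=row,
                baseline_mean=mu,
                baseline_sd=sd,
                category=cat,
                peak_time_s=float(aligned.time_s[int(np.argmax(row))]),
                sd_floored=floored,
            )
        )
    return profiles, aligned


def response_table(
    profiles: list[ResponseProfile], animal_id: str = ""
) -> pd.DataFrame:
    """Tidy per-neuron table of categories and aligned-trace summaries."""
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "neuron_id": [p.neuron_id for p in profiles],
            "category": [p.category for p in profiles],
            "baseline_mean": [p.baseline_mean for p in profiles],
            "baseline_sd": [p.baseline_sd for p in profiles],
            "peak_time_s": [p.peak_time_s for p in profiles],
        }
    )


RESPONSE_CATEGORIES = (ACTIVATED, SUPPRESSED, MIXED, NO_CHANGE)


def response_fractions(table: pd.DataFrame, group_by: str = "pooled") -> pd.DataFrame:
    """Fractions of the four response categories, pooled or per animal."""
    if table.empty:
        raise ValueError("response table is empty")
    if group_by not in ("pooled", "animal"):
        raise ValueError("group_by must be 'pooled' or 'animal'")

    def fracs(sub: pd.DataFrame) -> dict[str, float]:
        counts = sub["category"].value_counts()
        total = len(sub)
        return {c: counts.get(c, 0) / total for c in RESPONSE_CATEGORIES}

    if group_by == "pooled":
        return pd.DataFrame(
            [{"animal_id": "pooled", "n_neurons": len(table), **fracs(table)}]
        )
    rows = [
        {"animal_id": animal, "n_neurons": len(sub), **fracs(sub)}
        for animal, sub in table.groupby("animal_id", sort=True)
    ]
    return pd.DataFrame(rows)


def sort_by_peak_time(
    aligned: AlignedTraces, normalize: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Order neurons by time-to-peak of the aligned trace.

    Returns (row order into ``aligned.values``, reordered raster). With
    ``normalize`` each row is min-max scaled before the raster is built
    (scaling never moves a unique argmax). Ties fall back to neuron-id
    order.
    """
    values = aligned.values
    peak_idx = values.argmax(axis=1)
    order = sorted(
        range(values.shape[0]), key=lambda i: (peak_idx[i], aligned.neuron_ids[i])
    )
    order = np.asarray(order)
    raster = values[order].astype(float).copy()
    if normalize:
        lo = raster.min(axis=1, keepdims=True)
        span = raster.max(axis=1, keepdims=True) - lo
        span[span == 0] = 1.0
        raster = (raster - lo) / span
    return order, raster
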