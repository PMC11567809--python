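"""Activity classes: hypoactive / normal / hyperactive binning.

Neurons firing fewer than 2 transients/min are hypoactive, more than 6
are hyperactive, and 2-6 inclusive are normal. The module also builds the
cohort bookkeeping around that rule: class fractions pooled over neurons
or per animal, and the active-neuron subset (frequency > 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HYPOACTIVE = "hypoactive"
NORMAL = "normal"
HYPERACTIVE = "hyperactive"

ACTIVITY_CLASSES = (HYPOACTIVE, NORMAL, HYPERACTIVE)


def classify_activity(
    frequency_per_min: float, hypo_bound: float = 2.0, hyper_bound: float = 6.0
) -> str:
    """Bin one frequency; the boundaries themselves count as normal."""
    if frequency_per_min < 0:
        raise ValueError("frequency must be >= 0")
    if not hypo_bound < hyper_bound:
        raise ValueError("hypo_bound must be below hyper_bound")
    if frequency_per_min < hypo_bound:
        return HYPOACTIVE
    if frequency_per_min > hyper_bound:
        return HYPERACTIVE
    return NORMAL


def classify_table(
    metrics: pd.DataFrame, hypo_bound: float = 2.0, hyper_bound: float = 6.0
) -> pd.DataFrame:
    """Append an ``activity_class`` column to a metrics table."""
    freq = metrics["frequency_per_min"].to_numpy()
    if (freq < 0).any():
        raise ValueError("frequency must be >= 0")
    if not hypo_bound < hyper_bound:
        raise ValueError("hypo_bound must be below hyper_bound")
    labels = np.where(
        freq < hypo_bound, HYPOACTIVE, np.where(freq > hyper_bound, HYPERACTIVE, NORMAL)
    )
    out = metrics.copy()
    out["activity_class"] = labels
    return out


def cohort_fractions(
    metrics: pd.DataFrame,
    group_by: str = "pooled",
    hypo_bound: float = 2.0,
    hyper_bound: float = 6.0,
) -> pd.DataFrame:
    """Class fractions, pooled over all neurons or per animal.

    Returns one row per group (a single ``pooled`` row, or one per
    ``animal_id``) with columns hypoactive/normal/hyperactive summing to 1.
    """
    if metrics.empty:
        raise ValueError("metrics table is empty")
    if group_by not in ("pooled", "animal"):
        raise ValueError("group_by must be 'pooled' or 'animal'")
    classed = classify_table(metrics, hypo_bound, hyper_bound)
    if group_by == "pooled":
        counts = classed["activity_class"].value_counts()
        total = len(classed)
        row = {c: counts.get(c, 0) / total for c in ACTIVITY_CLASSES}
        return pd.DataFrame([{"animal_id": "pooled", "n_neurons": total, **row}])
    rows = []
    for animal, sub in classed.groupby("animal_id", sort=True):
        counts = sub["activity_class"].value_counts()
        total = len(sub)
        rows.append(
            {
                "animal_id": animal,
                "n_neurons": total,
                **{c: counts.get(c, 0) / total for c in ACTIVITY_CLASSES},
            }
        )
    return pd.DataFrame(rows)


def active_subset(metrics: pd.DataFrame) -> pd.DataFrame:
    """Rows with frequency > 0 (the "active neurons" analysis subset).

    An empty result is legitimate (an entirely silent cohort), not an
    error; the filter is idempotent.
    """
    return metrics[metrics["frequency_per_min"] > 0].copy()
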