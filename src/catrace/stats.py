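"""Normality-gated group comparisons.

Each sample is first assessed with the Shapiro-Wilk test; when both
groups look normal (p > alpha in each), a paired or unpaired t-test is
used, otherwise the comparison routes to a nonparametric test: Wilcoxon
signed-rank for paired designs, Mann-Whitney U for unpaired location
comparisons, or two-sample Kolmogorov-Smirnov when the question is about
distribution shape. All tests are two-tailed; group summaries are
mean ± SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ComparisonResult:
    """Outcome of one routed two-sample comparison."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    normality_p: tuple[float, float]
    alpha: float = 0.05
    paired: bool = False
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def route_and_compare(
    x,
    y,
    paired: bool = False,
    family: str = "location",
    alpha: float = 0.05,
    force: str | None = None,
) -> ComparisonResult:
    """Pick and run the appropriate two-sample test.

    ``family`` selects the unpaired nonparametric branch: ``location``
    (Mann-Whitney U) or ``distribution`` (Kolmogorov-Smirnov). ``force``
    overrides the Shapiro-Wilk gate with ``"parametric"`` or
    ``"nonparametric"`` (the latter also allows n = 2, below the
    Shapiro-Wilk minimum).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if family not in ("location", "distribution"):
        raise ValueError("family must be 'location' or 'distribution'")
    if force not in (None, "parametric", "nonparametric"):
        raise ValueError("force must be None, 'parametric', or 'nonparametric'")
    min_n = 2 if force == "nonparametric" else 3
    if len(x) < min_n or len(y) < min_n:
        raise ValueError(f"each sample needs n >= {min_n}")
    if paired and len(x) != len(y):
        raise ValueError("paired samples must have equal length")

    if force is None:
        px = float(sps.shapiro(x).pvalue)
        py = float(sps.shapiro(y).pvalue)
        parametric = px > alpha and py > alpha
    else:
        px = py = float("nan")
        parametric = force == "parametric"

    degenerate = False
    if parametric:
        if paired:
            res = sps.ttest_rel(x, y)
            name = "paired t-test"
        else:
            res = sps.ttest_ind(x, y)
            name = "unpaired t-test"
        stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(p):  # zero-variance degenerate inputs
            stat, p, degenerate = 0.0, 1.0, True
    elif paired:
        diff = x - y
        if np.all(diff == 0):
            # all-tied differences: signed-rank is undefined; report null
            stat, p, degenerate = 0.0, 1.0, True
        else:
            res = sps.wilcoxon(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        name = "Wilcoxon signed-rank"
    elif family == "location":
        method = "exact" if (len(x) <= 8 and len(y) <= 8) else "auto"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "Mann-Whitney U"
    else:
        res = sps.ks_2samp(x, y, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        name = "Kolmogorov-Smirnov"

    return ComparisonResult(
        test_name=name,
        statistic=stat,
        p_value=p,
        n_per_group=(len(x), len(y)),
        normality_p=(px, py),
        alpha=alpha,
        paired=paired,
        degenerate=degenerate,
    )


def _aggregate(table: pd.DataFrame, metric: str, level: str) -> np.ndarray:
    if metric not in table.columns:
        raise KeyError(f"unknown metric {metric!r}; columns: {list(table.columns)}")
    if level == "neuron":
        vals = table[metric].to_numpy(dtype=float)
    elif level == "animal":
        vals = table.groupby("animal_id")[metric].mean().to_numpy(dtype=float)
    else:
        raise ValueError("level must be 'neuron' or 'animal'")
    return vals[np.isfinite(vals)]


def compare_cohorts(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric: str,
    level: str = "animal",
    paired: bool = False,
    family: str = "location",
    alpha: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[ComparisonResult, pd.DataFrame]:
    """Compare one metric between two cohorts at neuron or animal level.

    At the animal level each animal contributes its neuron-mean (one data
    point per animal). Returns the routed test result plus a summary
    table with mean, SEM, and n per group; the sign of (mean_A - mean_B)
    gives the direction of the difference.
    """
    a = _aggregate(table_a, metric, level)
    b = _aggregate(table_b, metric, level)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    result = route_and_compare(a, b, paired=paired, family=family, alpha=alpha)
    summary = pd.DataFrame(
        {
            "group": labels,
            "metric": metric,
            "level": level,
            "n": [a.size, b.size],
            "mean": [a.mean(), b.mean()],
            "sem": [sps.sem(a), sps.sem(b)],
        }
    )
    return result, summary
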