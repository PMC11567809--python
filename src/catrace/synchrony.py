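"""Population synchrony: pairwise Pearson matrices and correlation indices.

Within one field of view, Pearson's r of raw ΔF/F is computed between
every pair of neurons. Running-state matrices are computed per trial and
averaged arithmetically across trials; the resting matrix uses the
dedicated rest block. A neuron's correlation index is the mean of its
off-diagonal row, and the animal mean is the mean of the indices.

Zero-variance (constant) traces produce undefined pairs; these are stored
as NaN, counted, and excluded from index averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import REST, RUN, SessionError, TraceMatrix, slice_state


class SubgroupTooSmall(SessionError):
    """Fewer than two neurons in the requested response subgroup."""


@dataclass
class SynchronyResult:
    """Pairwise Pearson matrix plus bookkeeping for one FOV and state."""

    matrix: np.ndarray
    neuron_ids: list[str]
    state: str
    n_undefined_pairs: int = 0
    subgroup: str | None = None
    n_trials_averaged: int = 1

    def correlation_index(self) -> pd.Series:
        """Per-neuron mean off-diagonal correlation (NaN pairs skipped)."""
        m = self.matrix.copy()
        np.fill_diagonal(m, np.nan)
        defined = np.isfinite(m)
        idx = np.full(m.shape[0], np.nan)
        rows = defined.any(axis=1)
        idx[rows] = np.nanmean(np.where(defined, m, np.nan)[rows], axis=1)
        return pd.Series(idx, index=self.neuron_ids, name="correlation_index")

    @property
    def animal_mean(self) -> float:
        idx = self.correlation_index().to_numpy()
        return float(np.nanmean(idx)) if np.isfinite(idx).any() else float("nan")


def _pearson_matrix(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Pearson matrix of columns; constant columns give NaN rows/cols."""
    n = values.shape[1]
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    r = np.atleast_2d(r)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    off = ~np.eye(n, dtype=bool)
    n_undef = int(np.isnan(r[off]).sum() // 2)
    return r, n_undef


def correlation_matrix(
    trace: TraceMatrix,
    state: str,
    include_inter_trial: bool = False,
    fisher_z: bool = False,
) -> SynchronyResult:
    """Pairwise Pearson matrix for one behavioral state.

    Running: one matrix per running trial, averaged across trials —
    arithmetically by default, or as the inverse-transformed mean of
    Fisher z values with ``fisher_z=True``. Resting: a single matrix over
    the rest block (inter-trial rests excluded by default).
    """
    if trace.n_neurons < 2:
        raise SessionError("correlation requires at least 2 neurons")
    if state == RUN:
        trial_ids = np.unique(trace.trial_id[trace.trial_id >= 0])
        if trial_ids.size == 0:
            raise SessionError("session has no running trials")
        mats = []
        n_undef = 0
        for k in trial_ids:
            seg = trace.values[trace.trial_id == k]
            if seg.shape[0] < 3:
                raise SessionError(f"running trial {int(k)} shorter than 3 frames")
            r, u = _pearson_matrix(seg)
            mats.append(r)
            n_undef = max(n_undef, u)
        stack = np.stack(mats)
        with np.errstate(invalid="ignore"):
            if fisher_z:
                z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
                mean = np.tanh(np.nanmean(z, axis=0))
            else:
                mean = np.nanmean(stack, axis=0)
        np.fill_diagonal(mean, 1.0)
        off = ~np.eye(mean.shape[0], dtype=bool)
        return SynchronyResult(
            matrix=mean,
            neuron_ids=list(trace.neuron_ids),
            state=state,
            n_undefined_pairs=int(np.isnan(mean[off]).sum() // 2),
            n_trials_averaged=int(trial_ids.size),
        )
    sliced = slice_state(trace, REST, include_inter_trial=include_inter_trial)
    if sliced.n_frames < 3:
        raise SessionError("resting segment shorter than 3 frames")
    r, n_undef = _pearson_matrix(sliced.values)
    return SynchronyResult(
        matrix=r,
        neuron_ids=list(trace.neuron_ids),
        state=REST,
        n_undefined_pairs=n_undef,
    )


def correlation_index(result: SynchronyResult) -> tuple[pd.Series, float]:
    """Per-neuron correlation indices and their animal-level mean."""
    idx = result.correlation_index()
    return idx, result.animal_mean


def subgroup_synchrony(
    trace: TraceMatrix,
    categories: pd.Series | dict,
    subgroup: str,
    state: str = RUN,
    fisher_z: bool = False,
) -> SynchronyResult:
    """Correlation matrix restricted to neurons of one response category.

    Raises :class:`SubgroupTooSmall` when fewer than two neurons carry the
    requested category; callers typically skip that animal and log it.
    """
    cats = dict(categories)
    members = [i for i, nid in enumerate(trace.neuron_ids) if cats.get(nid) == subgroup]
    if len(members) < 2:
        raise SubgroupTooSmall(
            f"subgroup {subgroup!r} has {len(members)} neuron(s); need >= 2"
        )
    sub = TraceMatrix(
        values=trace.values[:, members],
        neuron_ids=[trace.neuron_ids[i] for i in members],
        state_per_frame=trace.state_per_frame,
        acquisition=trace.acquisition,
        inter_trial=trace.inter_trial,
        trial_id=trace.trial_id,
    )
    result = correlation_matrix(sub, state, fisher_z=fisher_z)
    result.subgroup = subgroup
    return result
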