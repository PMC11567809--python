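"""Session data model and on-disk formats.

A recording session is a frames x neurons matrix of ΔF/F values (the
denoised output of an upstream source-extraction step such as CNMF),
together with a behavioral schedule: an initial quiet-rest block, a series
of forced-running treadmill trials, and short inter-trial rests. The trace
matrix is stored as a plain CSV table (one row per frame, one column per
neuron, header = neuron ids); the schedule and animal metadata live in a
JSON manifest next to it.

Frames are 0-based and trial windows are half-open ``[start, end)``
intervals. Frames inside the short inter-trial rests are labeled ``rest``
but carry an ``inter_trial`` flag; by default downstream resting-state
analyses use only the dedicated initial rest block.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

REST = "rest"
RUN = "run"
INTER_TRIAL = "inter_trial"

_WINDOW_STATES = {REST, RUN, INTER_TRIAL}


class SessionError(ValueError):
    """Raised for malformed manifests, trace tables, or inconsistent schedules."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition protocol: frame rate and treadmill trial schedule.

    Defaults reproduce the head-fixed treadmill protocol the pipeline was
    designed around: 2 Hz imaging, an initial 100 s quiet-rest block, then
    five 100 s forced-running trials separated by 25 s rests.
    """

    frame_rate_hz: float = 2.0
    trial_duration_s: float = 100.0
    n_running_trials: int = 5
    inter_trial_rest_s: float = 25.0
    rest_block_s: float = 100.0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise SessionError("frame_rate_hz must be > 0")
        for name in ("trial_duration_s", "inter_trial_rest_s", "rest_block_s"):
            if getattr(self, name) <= 0:
                raise SessionError(f"{name} must be > 0")
        if self.n_running_trials < 1:
            raise SessionError("n_running_trials must be >= 1")

    def frames(self, seconds: float) -> int:
        """Number of frames spanning ``seconds`` at this frame rate."""
        return int(round(seconds * self.frame_rate_hz))

    def schedule(self) -> list[tuple[int, int, str]]:
        """Trial windows ``(start, end, state)`` for the full protocol.

        Rest block, then running trials with inter-trial rests between
        consecutive trials (none after the last).
        """
        windows: list[tuple[int, int, str]] = []
        cursor = 0
        n_rest = self.frames(self.rest_block_s)
        windows.append((cursor, cursor + n_rest, REST))
        cursor += n_rest
        n_run = self.frames(self.trial_duration_s)
        n_iti = self.frames(self.inter_trial_rest_s)
        for i in range(self.n_running_trials):
            windows.append((cursor, cursor + n_run, RUN))
            cursor += n_run
            if i < self.n_running_trials - 1:
                windows.append((cursor, cursor + n_iti, INTER_TRIAL))
                cursor += n_iti
        return windows

    @property
    def n_frames(self) -> int:
        return self.schedule()[-1][1]


@dataclass
class SessionManifest:
    """Animal/session metadata plus the trial-window schedule."""

    animal_id: str
    group: str = ""
    timepoint: str = ""
    frame_rate_hz: float = 2.0
    trial_windows: list[tuple[int, int, str]] = field(default_factory=list)
    source_path: str = ""

    def validate(self, n_frames: int | None = None) -> None:
        prev_end = 0
        for i, (start, end, state) in enumerate(self.trial_windows):
            if state not in _WINDOW_STATES:
                raise SessionError(
                    f"window {i}: unknown state {state!r} (expected one of {sorted(_WINDOW_STATES)})"
                )
            if not (0 <= start < end):
                raise SessionError(f"window {i}: invalid range [{start}, {end})")
            if start < prev_end:
                raise SessionError(
                    f"window {i}: [{start}, {end}) overlaps or precedes previous window ending at {prev_end}"
                )
            prev_end = end
        if n_frames is not None and self.trial_windows:
            last_end = self.trial_windows[-1][1]
            if last_end > n_frames:
                raise SessionError(
                    f"window end {last_end} exceeds trace length {n_frames}"
                )

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "group": self.group,
            "timepoint": self.timepoint,
            "frame_rate_hz": self.frame_rate_hz,
            "trial_windows": [list(w) for w in self.trial_windows],
            "source_path": self.source_path,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionManifest":
        required = {"animal_id", "frame_rate_hz", "trial_windows"}
        missing = required - d.keys()
        if missing:
            raise SessionError(f"manifest missing keys: {sorted(missing)}")
        return cls(
            animal_id=str(d["animal_id"]),
            group=str(d.get("group", "")),
            timepoint=str(d.get("timepoint", "")),
            frame_rate_hz=float(d["frame_rate_hz"]),
            trial_windows=[(int(s), int(e), str(st)) for s, e, st in d["trial_windows"]],
            source_path=str(d.get("source_path", "")),
        )


def _labels_from_windows(
    trial_windows: Sequence[tuple[int, int, str]], n_frames: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (state, inter_trial flag, running-trial id) from windows.

    Frames not covered by any window are treated as unanalyzed rest
    (labeled ``rest`` with the inter-trial flag set), so they are excluded
    from resting-state statistics by default.
    """
    state = np.full(n_frames, REST, dtype="<U4")
    inter = np.ones(n_frames, dtype=bool)
    trial = np.full(n_frames, -1, dtype=np.int64)
    run_idx = 0
    for start, end, st in trial_windows:
        if st == RUN:
            state[start:end] = RUN
            inter[start:end] = False
            trial[start:end] = run_idx
            run_idx += 1
        elif st == REST:
            inter[start:end] = False
        # INTER_TRIAL: stays rest-labeled with the flag set
    return state, inter, trial


@dataclass
class TraceMatrix:
    """Frames x neurons ΔF/F with per-frame behavioral labels.

    ``values[t, i]`` is the ΔF/F of neuron ``neuron_ids[i]`` at frame ``t``.
    ``state_per_frame`` holds ``rest``/``run``; ``inter_trial`` flags rest
    frames that belong to short between-trial pauses; ``trial_id`` numbers
    running trials 0..k (-1 outside running windows).
    """

    values: np.ndarray
    neuron_ids: list[str]
    state_per_frame: np.ndarray
    acquisition: AcquisitionParams
    inter_trial: np.ndarray | None = None
    trial_id: np.ndarray | None = None
    source_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SessionError("values must be 2-D (frames x neurons)")
        n_frames, n_neurons = self.values.shape
        if n_neurons < 1:
            raise SessionError("session must contain at least one neuron")
        if n_frames < 2:
            raise SessionError("session must contain at least two frames")
        if len(self.neuron_ids) != n_neurons:
            raise SessionError("neuron_ids length does not match value columns")
        if len(set(self.neuron_ids)) != n_neurons:
            raise SessionError("neuron_ids must be unique")
        self.state_per_frame = np.asarray(self.state_per_frame)
        if self.state_per_frame.shape != (n_frames,):
            raise SessionError("state_per_frame length does not match frame count")
        if not np.isfinite(self.values).all():
            t, i = np.argwhere(~np.isfinite(self.values))[0]
            raise SessionError(
                f"non-finite ΔF/F at frame {t}, neuron {self.neuron_ids[i]!r}"
            )
        if self.inter_trial is None:
            self.inter_trial = np.zeros(n_frames, dtype=bool)
        if self.trial_id is None:
            self.trial_id = np.where(self.state_per_frame == RUN, 0, -1).astype(np.int64)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    @property
    def frame_rate_hz(self) -> float:
        return self.acquisition.frame_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @classmethod
    def from_manifest(
        cls,
        values: np.ndarray,
        neuron_ids: Sequence[str],
        manifest: SessionManifest,
        acquisition: AcquisitionParams | None = None,
    ) -> "TraceMatrix":
        values = np.asarray(values, dtype=float)
        manifest.validate(n_frames=values.shape[0])
        state, inter, trial = _labels_from_windows(
            manifest.trial_windows, values.shape[0]
        )
        if acquisition is None:
            acquisition = AcquisitionParams(frame_rate_hz=manifest.frame_rate_hz)
        return cls(
            values=values,
            neuron_ids=list(map(str, neuron_ids)),
            state_per_frame=state,
            acquisition=acquisition,
            inter_trial=inter,
            trial_id=trial,
        )


def read_session(manifest_path: str | Path) -> tuple[TraceMatrix, SessionManifest]:
    """Load a session from its JSON manifest and the CSV table it references.

    Raises :class:`SessionError` naming the offending location for ragged
    rows, non-numeric or missing cells, and out-of-range trial windows.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise SessionError(f"manifest not found: {manifest_path}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = SessionManifest.from_dict(json.load(fh))
    trace_path = Path(manifest.source_path)
    if not trace_path.is_absolute():
        trace_path = manifest_path.parent / trace_path
    if not trace_path.exists():
        raise SessionError(f"trace table not found: {trace_path}")

    with open(trace_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        neuron_ids = [c.strip() for c in header.split(",")]
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(",")
            if len(cells) != len(neuron_ids):
                raise SessionError(
                    f"{trace_path.name}:{lineno}: expected {len(neuron_ids)} "
                    f"columns, found {len(cells)}"
                )
            row = []
            for col, cell in zip(neuron_ids, cells):
                try:
                    v = float(cell)
                except ValueError:
                    raise SessionError(
                        f"{trace_path.name}:{lineno}: non-numeric value "
                        f"{cell!r} in column {col!r}"
                    ) from None
                if not np.isfinite(v):
                    raise SessionError(
                        f"{trace_path.name}:{lineno}: missing/non-finite value "
                        f"in column {col!r}"
                    )
                row.append(v)
            rows.append(row)
    if not rows:
        raise SessionError(f"{trace_path.name}: no data rows")
    values = np.array(rows, dtype=float)
    trace = TraceMatrix.from_manifest(values, neuron_ids, manifest)
    return trace, manifest


def write_session(
    trace: TraceMatrix, manifest: SessionManifest, out_dir: str | Path
) -> Path:
    """Write a session to ``out_dir``; returns the manifest path.

    Floats are written with 17 significant digits so that
    ``read_session(write_session(...))`` reproduces values bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = manifest.animal_id or "session"
    trace_path = out_dir / f"{stem}_traces.csv"
    with open(trace_path, "w", encoding="utf-8") as fh:
        fh.write(",".join(trace.neuron_ids) + "\n")
        for row in trace.values:
            fh.write(",".join(format(v, ".17g") for v in row) + "\n")
    manifest = dataclasses.replace(manifest, source_path=trace_path.name)
    manifest.validate(n_frames=trace.n_frames)
    manifest_path = out_dir / f"{stem}_manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
        fh.write("\n")
    return manifest_path


def slice_state(
    trace: TraceMatrix, state: str, include_inter_trial: bool = True
) -> TraceMatrix:
    """Concatenate all frames with the requested behavioral state.

    Frame order and running-trial ids are preserved; original frame indices
    are kept in ``source_frames``. With ``include_inter_trial=False`` the
    short between-trial rest frames are dropped from a ``rest`` slice,
    restricting it to the dedicated initial rest block.
    """
    if state not in (REST, RUN):
        raise SessionError(f"state must be {REST!r} or {RUN!r}, got {state!r}")
    mask = trace.state_per_frame == state
    if not include_inter_trial:
        mask &= ~trace.inter_trial
    if not mask.any():
        raise SessionError(f"session contains no {state!r} frames")
    idx = np.flatnonzero(mask)
    return TraceMatrix(
        values=trace.values[idx],
        neuron_ids=list(trace.neuron_ids),
        state_per_frame=trace.state_per_frame[idx],
        acquisition=trace.acquisition,
        inter_trial=trace.inter_trial[idx],
        trial_id=trace.trial_id[idx],
        source_frames=idx,
    )
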