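"""Synthetic GCaMP-like session generator with known ground truth.

Generates ΔF/F matrices that emulate denoised CNMF output under the
head-fixed treadmill protocol: sparse calcium transients (difference-of-
exponentials kernel, unit peak) riding on a slowly drifting baseline with
additive Gaussian noise. Event times come from an inhomogeneous Poisson
process whose intensity is the product of a state-dependent rate (rest vs
running, per-neuron gain) and a positive unit-mean modulator that mixes a
private per-neuron process with a shared common drive; the mixing weight
controls population synchrony.

Ground truth (event times and amplitudes, per-state realized rates,
response-class labels, the common-drive trace) is returned alongside the
session so every downstream stage can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .session import (
    REST,
    RUN,
    AcquisitionParams,
    SessionManifest,
    TraceMatrix,
    _labels_from_windows,
)

ACTIVATED = "activated"
SUPPRESSED = "suppressed"
MIXED = "mixed"
NO_CHANGE = "no_change"

RESPONSE_CLASSES = (ACTIVATED, SUPPRESSED, MIXED, NO_CHANGE)


class SpecError(ValueError):
    """Raised for invalid simulator specifications."""


def calcium_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials calcium impulse response, unit peak.

    K(t) = (exp(-t/decay) - exp(-t/rise)) / K_max for t >= 0, else 0.
    """
    if not (decay_s > rise_s > 0):
        raise SpecError("kernel requires decay_s > rise_s > 0")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    raw = np.exp(-t[pos] / decay_s) - np.exp(-t[pos] / rise_s)
    peak_t = kernel_peak_time(rise_s, decay_s)
    peak = math.exp(-peak_t / decay_s) - math.exp(-peak_t / rise_s)
    out[pos] = raw / peak
    return out


def kernel_peak_time(rise_s: float, decay_s: float) -> float:
    """Time of the kernel maximum (closed form for two exponentials)."""
    return (rise_s * decay_s) / (decay_s - rise_s) * math.log(decay_s / rise_s)


@dataclass
class NeuronSpec:
    """Per-neuron generative parameters.

    ``run_gain`` multiplies the rest-state event rate during running
    trials: > 1 activated-like, < 1 suppressed-like, 1 non-responsive. It
    may be a per-trial sequence. ``within_trial_profile`` overrides it with
    a biphasic (or arbitrary piecewise) gain schedule inside each running
    trial, given as ``(t_start_s, t_end_s, gain)`` segments relative to
    trial onset — the way a mixed-response neuron (activation followed by
    suppression, or vice versa) is realized.
    """

    rest_rate_hz: float
    run_gain: float | Sequence[float] = 1.0
    amplitude_mean: float = 0.8
    amplitude_sd: float = 0.1
    response_class_truth: str | None = None
    within_trial_profile: Sequence[tuple[float, float, float]] | None = None
    forced_event_times: Sequence[float] | None = None
    forced_event_amplitudes: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.rest_rate_hz < 0:
            raise SpecError("rest_rate_hz must be >= 0")
        if self.amplitude_mean <= 0:
            raise SpecError("amplitude_mean must be > 0")
        gains = self.run_gain if np.iterable(self.run_gain) else [self.run_gain]
        if any(g < 0 for g in gains):
            raise SpecError("run_gain must be >= 0")
        if (
            self.response_class_truth is not None
            and self.response_class_truth not in RESPONSE_CLASSES
        ):
            raise SpecError(
                f"response_class_truth must be one of {RESPONSE_CLASSES}"
            )

    def derived_response_class(self) -> str:
        """Response-class label implied by the gain schedule."""
        if self.response_class_truth is not None:
            return self.response_class_truth
        if self.within_trial_profile is not None:
            gains = [g for _, _, g in self.within_trial_profile]
        elif np.iterable(self.run_gain):
            gains = list(self.run_gain)
        else:
            gains = [self.run_gain]
        up = any(g > 1 for g in gains)
        down = any(g < 1 for g in gains)
        if up and down:
            return MIXED
        if up:
            return ACTIVATED
        if down:
            return SUPPRESSED
        return NO_CHANGE


@dataclass
class CohortSpec:
    """Parameters of one simulated field of view (one animal/session).

    ``common_drive_weight`` (w in [0, 1]) is the fraction of each neuron's
    event intensity driven by the shared latent modulator; higher w means
    more synchronous populations. ``modulation_depth`` sets the log-scale
    amplitude of the (unit-mean, log-AR(1)) modulators.
    """

    n_neurons: int
    neuron_specs: list[NeuronSpec]
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.5
    noise_sd: float = 0.05
    drift_amplitude: float = 0.05
    drift_period_s: float = 60.0
    common_drive_weight: float = 0.1
    modulation_depth: float = 1.5
    modulation_tau_s: float = 5.0
    run_onset_ramp_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise SpecError("n_neurons must be >= 1")
        if len(self.neuron_specs) != self.n_neurons:
            raise SpecError("neuron_specs length must equal n_neurons")
        if not (0.0 <= self.common_drive_weight <= 1.0):
            raise SpecError("common_drive_weight must be in [0, 1]")
        if not (self.kernel_decay_s > self.kernel_rise_s > 0):
            raise SpecError("kernel requires decay_s > rise_s > 0")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise SpecError("noise_sd and drift_amplitude must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    event_times: list[np.ndarray]
    event_amplitudes: list[np.ndarray]
    true_rates_per_min: list[dict[str, float]]  # realized events/min per state
    expected_rates_per_min: list[dict[str, float]]
    response_class_truth: list[str]
    common_drive: np.ndarray
    neuron_ids: list[str] = field(default_factory=list)


def _unit_mean_log_ar1(
    rng: np.random.Generator, n: int, rho: float, depth: float
) -> np.ndarray:
    """Positive unit-mean modulator: exponentiated stationary AR(1)."""
    if depth == 0:
        return np.ones(n)
    g = np.empty(n)
    g[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * math.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        g[t] = rho * g[t - 1] + innov[t - 1]
    return np.exp(depth * g - 0.5 * depth * depth)


def _gain_per_frame(
    spec: NeuronSpec,
    state: np.ndarray,
    trial_id: np.ndarray,
    frame_rate_hz: float,
    ramp_s: float,
) -> np.ndarray:
    """State/trial gain schedule sampled on the frame grid."""
    n = state.size
    gain = np.ones(n)
    n_trials = int(trial_id.max()) + 1 if (trial_id >= 0).any() else 0
    for k in range(n_trials):
        idx = np.flatnonzero(trial_id == k)
        t_rel = (idx - idx[0]) / frame_rate_hz
        if spec.within_trial_profile is not None:
            g = np.ones(idx.size)
            for t0, t1, gv in spec.within_trial_profile:
                g[(t_rel >= t0) & (t_rel < t1)] = gv
        elif np.iterable(spec.run_gain):
            gains = list(spec.run_gain)
            g = np.full(idx.size, float(gains[k % len(gains)]))
        else:
            g = np.full(idx.size, float(spec.run_gain))
        if ramp_s > 0:
            # belt speed ramps up over the first seconds of each trial
            frac = np.clip(t_rel / ramp_s, 0.0, 1.0)
            g = 1.0 + frac * (g - 1.0)
        gain[idx] = g
    return gain


def simulate_session(
    spec: CohortSpec,
    acquisition: AcquisitionParams | None = None,
    animal_id: str = "sim",
    group: str = "",
    timepoint: str = "",
) -> tuple[TraceMatrix, SessionManifest, GroundTruth]:
    """Simulate one session; identical spec + seed gives bit-identical output."""
    if acquisition is None:
        acquisition = AcquisitionParams()
    windows = acquisition.schedule()
    n_frames = windows[-1][1]
    rate = acquisition.frame_rate_hz
    dt = 1.0 / rate
    frame_t = np.arange(n_frames) * dt
    state, inter, trial = _labels_from_windows(windows, n_frames)
    rest_mask = (state == REST) & ~inter
    run_mask = state == RUN
    rho = math.exp(-dt / spec.modulation_tau_s)

    ss = np.random.SeedSequence(spec.seed)
    common_ss, *neuron_ss = ss.spawn(1 + spec.n_neurons)
    common_rng = np.random.default_rng(common_ss)
    xi_common = _unit_mean_log_ar1(common_rng, n_frames, rho, spec.modulation_depth)

    neuron_ids = [f"n{i:03d}" for i in range(spec.n_neurons)]
    values = np.zeros((n_frames, spec.n_neurons))
    event_times: list[np.ndarray] = []
    event_amps: list[np.ndarray] = []
    true_rates: list[dict[str, float]] = []
    expected_rates: list[dict[str, float]] = []
    classes: list[str] = []
    w = spec.common_drive_weight

    for i, (nspec, nss) in enumerate(zip(spec.neuron_specs, neuron_ss)):
        rng = np.random.default_rng(nss)
        xi_own = _unit_mean_log_ar1(rng, n_frames, rho, spec.modulation_depth)
        gain = _gain_per_frame(nspec, state, trial, rate, spec.run_onset_ramp_s)
        lam = nspec.rest_rate_hz * gain * ((1.0 - w) * xi_own + w * xi_common)

        if nspec.forced_event_times is not None:
            times = np.asarray(nspec.forced_event_times, dtype=float)
            if nspec.forced_event_amplitudes is not None:
                amps = np.asarray(nspec.forced_event_amplitudes, dtype=float)
            else:
                amps = np.full(times.size, nspec.amplitude_mean)
            if times.size and (times.min() < 0 or times.max() >= n_frames * dt):
                raise SpecError("forced event times outside session duration")
        else:
            counts = rng.poisson(lam * dt)
            reps = np.repeat(np.arange(n_frames), counts)
            times = frame_t[reps] + rng.uniform(0.0, dt, size=reps.size)
            amps = np.maximum(
                rng.normal(nspec.amplitude_mean, nspec.amplitude_sd, size=times.size),
                0.0,
            )
        order = np.argsort(times, kind="stable")
        times, amps = times[order], amps[order]

        col = np.zeros(n_frames)
        for t_e, a in zip(times, amps):
            k0 = int(math.ceil(t_e * rate))
            if k0 >= n_frames:
                continue
            col[k0:] += a * calcium_kernel(
                frame_t[k0:] - t_e, spec.kernel_rise_s, spec.kernel_decay_s
            )
        if spec.drift_amplitude > 0:
            phase = rng.uniform(0.0, 2.0 * math.pi)
            col += spec.drift_amplitude * np.sin(
                2.0 * math.pi * frame_t / spec.drift_period_s + phase
            )
        if spec.noise_sd > 0:
            col += rng.normal(0.0, spec.noise_sd, size=n_frames)
        values[:, i] = col

        ev_frame = np.clip((times * rate).astype(int), 0, n_frames - 1)
        n_rest = int(rest_mask[ev_frame].sum()) if times.size else 0
        n_run = int(run_mask[ev_frame].sum()) if times.size else 0
        rest_min = rest_mask.sum() * dt / 60.0
        run_min = run_mask.sum() * dt / 60.0
        true_rates.append(
            {
                REST: n_rest / rest_min if rest_min else 0.0,
                RUN: n_run / run_min if run_min else 0.0,
            }
        )
        mean_run_gain = float(gain[run_mask].mean()) if run_mask.any() else 1.0
        expected_rates.append(
            {
                REST: nspec.rest_rate_hz * 60.0,
                RUN: nspec.rest_rate_hz * mean_run_gain * 60.0,
            }
        )
        event_times.append(times)
        event_amps.append(amps)
        classes.append(nspec.derived_response_class())

    trace = TraceMatrix(
        values=values,
        neuron_ids=neuron_ids,
        state_per_frame=state,
        acquisition=acquisition,
        inter_trial=inter,
        trial_id=trial,
    )
    manifest = SessionManifest(
        animal_id=animal_id,
        group=group,
        timepoint=timepoint,
        frame_rate_hz=rate,
        trial_windows=windows,
    )
    truth = GroundTruth(
        event_times=event_times,
        event_amplitudes=event_amps,
        true_rates_per_min=true_rates,
        expected_rates_per_min=expected_rates,
        response_class_truth=classes,
        common_drive=xi_common,
        neuron_ids=neuron_ids,
    )
    return trace, manifest, truth


# ---------------------------------------------------------------------------
# YAML (de)serialization of cohort specs


def spec_to_yaml(spec: CohortSpec, path) -> None:
    """Write a cohort spec (including all neuron specs) to YAML."""
    import dataclasses

    import yaml

    d = dataclasses.asdict(spec)
    for ns in d["neuron_specs"]:
        for key in ("within_trial_profile", "forced_event_times", "forced_event_amplitudes"):
            if ns[key] is not None:
                ns[key] = [list(v) if np.iterable(v) else v for v in ns[key]]
        if np.iterable(ns["run_gain"]):
            ns["run_gain"] = list(ns["run_gain"])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def spec_from_yaml(path) -> CohortSpec:
    """Load a cohort spec written by :func:`spec_to_yaml`."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    d["neuron_specs"] = [NeuronSpec(**ns) for ns in d["neuron_specs"]]
    return CohortSpec(**d)


# ---------------------------------------------------------------------------
# Preset cohorts


def _mixed_profile(trial_duration_s: float) -> list[tuple[float, float, float]]:
    half = trial_duration_s / 2.0
    return [(0.0, half, 3.0), (half, trial_duration_s, 1.0 / 3.0)]


_PRESET_DOC: dict[str, dict] = {
    "wt_like": {
        "activity_mix": {"hypoactive": 0.15, "normal": 0.70, "hyperactive": 0.15},
        "rate_ranges_per_min": {
            "hypoactive": (0.3, 1.5),
            "normal": (2.5, 5.5),
            "hyperactive": (6.5, 9.0),
        },
        "response_mix": {
            ACTIVATED: 0.40,
            SUPPRESSED: 0.15,
            MIXED: 0.30,
            NO_CHANGE: 0.15,
        },
        "amplitude_range": (0.6, 1.0),
        "common_drive_weight": 0.10,
    },
    "tg_like": {
        "activity_mix": {"hypoactive": 0.60, "normal": 0.32, "hyperactive": 0.08},
        "rate_ranges_per_min": {
            "hypoactive": (0.2, 1.2),
            "normal": (2.2, 4.5),
            "hyperactive": (6.5, 8.0),
        },
        "response_mix": {
            ACTIVATED: 0.20,
            SUPPRESSED: 0.45,
            MIXED: 0.20,
            NO_CHANGE: 0.15,
        },
        "amplitude_range": (0.35, 0.65),
        "common_drive_weight": 0.60,
    },
}


def preset_parameter_table() -> dict[str, dict]:
    """Documented parameter tables behind the shipped presets."""
    return {k: dict(v) for k, v in _PRESET_DOC.items()}


def preset_cohorts(
    name: str,
    n_neurons: int = 50,
    seed: int = 0,
    trial_duration_s: float = 100.0,
) -> CohortSpec:
    """Build a preset cohort spec.

    ``wt_like`` emulates a healthy cortical population: mostly 2-6
    transients/min at rest, more running-activated than suppressed
    responders, weak common drive. ``tg_like`` emulates a hypofunctional
    tauopathy-like population: a hypoactive majority, smaller event
    amplitudes, suppressed responders dominant, and a stronger common
    drive (more synchronous residual activity).

    Response-class truth is assigned independently of the activity class;
    note that suppression of ΔF/F is only *observable* against an elevated
    baseline, so suppressed-truth neurons with sparse resting activity may
    be undetectable by the deviation rule — as in real recordings.
    """
    if name not in _PRESET_DOC:
        raise SpecError(f"unknown preset {name!r}; choose from {sorted(_PRESET_DOC)}")
    doc = _PRESET_DOC[name]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0F0)))

    def n_of(fracs: dict[str, float]) -> dict[str, int]:
        keys = list(fracs)
        counts = {k: int(round(fracs[k] * n_neurons)) for k in keys}
        while sum(counts.values()) > n_neurons:
            counts[max(keys, key=lambda k: counts[k])] -= 1
        while sum(counts.values()) < n_neurons:
            counts[max(keys, key=lambda k: fracs[k])] += 1
        return counts

    act_counts = n_of(doc["activity_mix"])
    resp_counts = n_of(doc["response_mix"])

    rates = []
    for cls, cnt in act_counts.items():
        lo, hi = doc["rate_ranges_per_min"][cls]
        rates.extend(rng.uniform(lo, hi, size=cnt) / 60.0)
    rng.shuffle(rates)

    resp_labels: list[str] = []
    for cls, cnt in resp_counts.items():
        resp_labels.extend([cls] * cnt)
    rng.shuffle(resp_labels)

    a_lo, a_hi = doc["amplitude_range"]
    specs: list[NeuronSpec] = []
    for r, cls in zip(rates, resp_labels):
        amp = float(rng.uniform(a_lo, a_hi))
        kwargs: dict = {
            "rest_rate_hz": float(r),
            "amplitude_mean": amp,
            "amplitude_sd": 0.15 * amp,
            "response_class_truth": cls,
        }
        if cls == ACTIVATED:
            kwargs["run_gain"] = 3.0
        elif cls == SUPPRESSED:
            kwargs["run_gain"] = 1.0 / 3.0
        elif cls == MIXED:
            kwargs["within_trial_profile"] = _mixed_profile(trial_duration_s)
        else:
            kwargs["run_gain"] = 1.0
        specs.append(NeuronSpec(**kwargs))

    return CohortSpec(
        n_neurons=n_neurons,
        neuron_specs=specs,
        common_drive_weight=doc["common_drive_weight"],
        seed=seed,
    )
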