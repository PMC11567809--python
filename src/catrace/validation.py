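"""Canonical recovery experiments that benchmark the pipeline end to end.

Each experiment simulates sessions with known ground truth, runs the
corresponding analysis stage, and reports a recovery statistic. The
cohort designs place each stage in the regime where its assumptions hold
and its output is identifiable, so the experiments measure the analysis
logic rather than the physics of indicator kernels:

* classification recovery uses fast-kernel, finely sampled sessions so
  individual transients stay resolvable across the whole 0-10/min rate
  range (with a slow indicator at 2 Hz, events above ~6/min merge and
  exact counting is impossible — see the methods note);
* response recovery uses tonically active neurons, because a running-
  induced *decrease* of ΔF/F is only observable against a sustained
  elevated baseline, and high-rate/low-amplitude activity keeps the
  pre-onset SD representative of the post-onset fluctuations;
* the synchrony sweep uses the running state, whose five trials give the
  longest correlation estimation window.

All experiments are deterministic given ``seed``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import classify_activity
from .responses import categorize_session
from .session import REST, RUN, AcquisitionParams
from .stats import route_and_compare
from .synchrony import correlation_matrix
from .synth import MIXED, CohortSpec, NeuronSpec, preset_cohorts, simulate_session
from .transients import session_metrics


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# Classification recovery


def classification_cohort(seed: int) -> tuple[CohortSpec, AcquisitionParams, np.ndarray]:
    """High-SNR cohort with rates drawn per activity class.

    Sampled at 10 Hz with a fast (0.05 s rise / 0.3 s decay) kernel so
    that transient counts are exact up to sub-0.3 s coincidences; noise
    SD is amplitude/16, no drift, no rate modulation. Returns the spec,
    the acquisition, and the drawn rates (events/min).
    """
    rng = np.random.default_rng(seed)
    rates = np.concatenate(
        [
            rng.uniform(0.2, 1.5, 7),  # hypoactive
            rng.uniform(2.5, 5.5, 8),  # normal
            rng.uniform(6.5, 9.0, 5),  # hyperactive
        ]
    )
    specs = [
        NeuronSpec(rest_rate_hz=r / 60.0, amplitude_mean=0.8, amplitude_sd=0.08)
        for r in rates
    ]
    spec = CohortSpec(
        n_neurons=len(specs),
        neuron_specs=specs,
        kernel_rise_s=0.05,
        kernel_decay_s=0.3,
        noise_sd=0.05,
        drift_amplitude=0.0,
        modulation_depth=0.0,
        seed=seed,
    )
    acq = AcquisitionParams(frame_rate_hz=10.0, rest_block_s=100.0, n_running_trials=1)
    return spec, acq, rates


def classification_recovery(
    n_seeds: int = 50, seed: int = 0, boundary_margin_per_min: float = 0.5
) -> dict:
    """Fraction of eligible neurons whose detected-frequency class matches
    the class of their realized resting rate.

    Eligible neurons have a realized rate at least ``boundary_margin_per_min``
    away from both class boundaries; at desk-scale durations the drawn
    rate and its Poisson realization decouple, so recovery is judged
    against the realization.
    """
    ok = n = 0
    for s in _child_seeds(seed, n_seeds):
        spec, acq, _rates = classification_cohort(s)
        trace, _, truth = simulate_session(spec, acq)
        detected = session_metrics(trace, REST)["frequency_per_min"].to_numpy()
        for i in range(spec.n_neurons):
            realized = truth.true_rates_per_min[i][REST]
            if (
                abs(realized - 2.0) < boundary_margin_per_min
                or abs(realized - 6.0) < boundary_margin_per_min
            ):
                continue
            n += 1
            ok += classify_activity(realized) == classify_activity(detected[i])
    return {"recovery_rate": ok / n if n else float("nan"), "n_eligible": n}


# ---------------------------------------------------------------------------
# Response recovery


def response_cohort(seed: int, n_per_class: int = 10) -> CohortSpec:
    """Tonic cohort probing the running-response rule at gains 3, 1/3, 1.

    All neurons fire at 6 events/s with small (0.06 ΔF/F) unitary events,
    producing a sustained elevated baseline whose fluctuations are noise-
    dominated; the run gain is the only difference between classes. Mixed
    neurons get a biphasic within-trial schedule (gain 3 then 1/3).
    """
    tonic = dict(rest_rate_hz=6.0, amplitude_mean=0.06, amplitude_sd=0.008)
    specs = [NeuronSpec(run_gain=g, **tonic) for g in (3.0, 1.0 / 3.0, 1.0) for _ in range(n_per_class)]
    specs += [
        NeuronSpec(within_trial_profile=[(0.0, 50.0, 3.0), (50.0, 100.0, 1.0 / 3.0)], **tonic)
        for _ in range(n_per_class)
    ]
    return CohortSpec(
        n_neurons=len(specs),
        neuron_specs=specs,
        noise_sd=0.08,
        drift_amplitude=0.0,
        modulation_depth=0.0,
        seed=seed,
    )


def response_recovery(n_seeds: int = 10, seed: int = 0) -> dict:
    """Agreement between assigned response categories and simulator truth."""
    ok_all = n_all = ok_core = n_core = 0
    confusion: dict[tuple[str, str], int] = {}
    for s in _child_seeds(seed, n_seeds):
        spec = response_cohort(s)
        trace, _, truth = simulate_session(spec)
        profiles, _ = categorize_session(trace)
        for p, t in zip(profiles, truth.response_class_truth):
            n_all += 1
            ok_all += p.category == t
            if t != MIXED:
                n_core += 1
                ok_core += p.category == t
            confusion[(t, p.category)] = confusion.get((t, p.category), 0) + 1
    return {
        "agreement_all": ok_all / n_all,
        "agreement_core": ok_core / n_core,  # gains {3, 1/3, 1}
        "confusion": confusion,
    }


# ---------------------------------------------------------------------------
# Synchrony sweep


def synchrony_sweep(
    weights: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 20,
    seed: int = 0,
    n_neurons: int = 20,
) -> dict:
    """Animal-mean correlation index versus common-drive weight.

    Neutral cohort (8 events/min, no state response), running-state
    correlations (five trials averaged). Returns the sweep points and
    their Spearman rank correlation.
    """
    seeds = _child_seeds(seed, n_seeds)
    points: list[tuple[float, float]] = []
    for w in weights:
        for s in seeds:
            specs = [
                NeuronSpec(rest_rate_hz=8.0 / 60.0, run_gain=1.0, amplitude_mean=0.8, amplitude_sd=0.1)
                for _ in range(n_neurons)
            ]
            spec = CohortSpec(
                n_neurons=n_neurons, neuron_specs=specs, common_drive_weight=w, seed=s
            )
            trace, _, _ = simulate_session(spec)
            points.append((w, correlation_matrix(trace, RUN).animal_mean))
    ws, vals = zip(*points)
    rho = float(sps.spearmanr(ws, vals).statistic)
    return {"spearman": rho, "points": points}


# ---------------------------------------------------------------------------
# Group direction experiment (wt-like vs tg-like presets)


def group_direction_experiment(
    seed: int = 0, n_animals: int = 7, n_neurons: int = 50
) -> dict:
    """One replicate of the two-cohort comparison at the animal level.

    Simulates matched wt-like and tg-like cohorts (common random numbers:
    animal k of both groups shares a seed) and summarizes resting-state
    frequency, amplitudes, total activity, hypoactive fraction, and
    correlation index per group. Returns per-group animal-level tables
    and the sign checks of interest.
    """
    animal_seeds = _child_seeds(seed, n_animals)
    out: dict[str, pd.DataFrame] = {}
    for preset, group in (("wt_like", "WT"), ("tg_like", "TG")):
        rows = []
        for a, s in enumerate(animal_seeds):
            spec = preset_cohorts(preset, n_neurons=n_neurons, seed=s)
            trace, _, _ = simulate_session(spec, animal_id=f"{group}{a:02d}", group=group)
            m = session_metrics(trace, REST, animal_id=f"{group}{a:02d}")
            freq = m["frequency_per_min"].to_numpy()
            rows.append(
                {
                    "animal_id": f"{group}{a:02d}",
                    "frequency_per_min": float(freq.mean()),
                    "peak_amplitude": float(np.nanmean(m["peak_amplitude"])),
                    "mean_amplitude": float(np.nanmean(m["mean_amplitude"])),
                    "total_activity_per_min": float(m["total_activity_per_min"].mean()),
                    "hypoactive_fraction": float((freq < 2.0).mean()),
                    "rest_correlation_index": correlation_matrix(trace, REST).animal_mean,
                }
            )
        out[group] = pd.DataFrame(rows)
    wt, tg = out["WT"], out["TG"]
    directions = {
        "tg_lower_frequency": tg["frequency_per_min"].mean() < wt["frequency_per_min"].mean(),
        "tg_lower_peak_amplitude": tg["peak_amplitude"].mean() < wt["peak_amplitude"].mean(),
        "tg_lower_mean_amplitude": tg["mean_amplitude"].mean() < wt["mean_amplitude"].mean(),
        "tg_lower_total_activity": tg["total_activity_per_min"].mean() < wt["total_activity_per_min"].mean(),
        "tg_higher_hypoactive_fraction": tg["hypoactive_fraction"].mean() > wt["hypoactive_fraction"].mean(),
        "tg_higher_rest_correlation": tg["rest_correlation_index"].mean() > wt["rest_correlation_index"].mean(),
    }
    return {"tables": out, "directions": directions}


# ---------------------------------------------------------------------------
# Type-I error of the routed comparison


def type_i_error(
    n_sims: int = 2000, n_per_group: int = 20, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Empirical false-positive rate of route_and_compare on null normals."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        x = rng.standard_normal(n_per_group)
        y = rng.standard_normal(n_per_group)
        res = route_and_compare(x, y, alpha=alpha)
        rejections += res.p_value <= alpha
    return {"type_i_error": rejections / n_sims, "n_sims": n_sims}
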