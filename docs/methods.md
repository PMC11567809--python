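# Methods

This note documents the models, parameter choices, numerical details,
and known limitations behind `catrace`. It is written for users who need
to judge what the pipeline's outputs — and its passing tests — do and do
not establish about real recordings.

## Data model

A session is a frames × neurons ΔF/F matrix plus a behavioral schedule.
Frames are 0-based; trial windows are half-open `[start, end)` — this is
a deliberate convention to remove off-by-one ambiguity in trial
bookkeeping. The default acquisition is 2 Hz imaging with a 100 s
quiet-rest block followed by five 100 s running trials separated by 25 s
rests (1400 frames, 700 s).

Frames in the short inter-trial rests are labeled `rest` but flagged
`inter_trial`, and resting-state metrics and correlations exclude them
by default: the dedicated initial rest block is the session's resting
recording, and the 25 s pauses immediately follow locomotion, when
calcium is still elevated. The flag is a configuration switch
(`include_inter_trial`) rather than a hard rule.

Traces are stored as plain CSV (one row per frame, header = neuron ids,
floats at 17 significant digits so round-trips are bit-exact) with a
JSON manifest carrying the schedule and animal metadata.

## Transient detection

* **Baseline.** The window spanning 15% of the trace length
  (`round(0.15·n)`, minimum 2 frames) is slid one frame at a time; the
  window with minimal sample SD (ddof = 1; ties go to the earliest
  window) is the baseline. Threshold = mean + 5·SD of that window. When
  the minimal SD is exactly zero the threshold equals the baseline mean,
  so any positive excursion is detected — degenerate but deterministic.
* **Events.** A transient is a maximal run of consecutive frames
  strictly above threshold. Runs separated by a single sub-threshold
  frame are *not* merged, and there is no minimum-duration filter by
  default (`min_frames` is configurable). Event boundaries are otherwise
  undefined by the detection rule, so the simplest deterministic reading
  is used.
* **Metrics.** Frequency = count/(duration/60). Peak amplitude = the
  largest transient value in the trace; mean amplitude = average of
  per-transient peaks; traces with zero transients report NaN amplitudes
  and are excluded from amplitude averages while still contributing
  frequency 0. Total activity = Σ over transient frames of
  (value − baseline mean)·(1/frame rate), per minute (left-Riemann sum).
* **Scope.** Baselines are estimated per state-slice by default (resting
  metrics use a baseline estimated on the resting frames, running
  metrics on the running frames); a whole-session baseline is available
  via `baseline_scope="session"`.

### Limitation: event merging at high rates

With a slow indicator (decay ≈ 1.5 s) sampled at 2 Hz, two events closer
together than the decay-to-threshold time (~1–2 s) produce a single
supra-threshold excursion; above ~6 events/min this merging becomes a
systematic undercount, and at still higher rates the minimum-SD window
itself fills with event tails, inflating the threshold. This is a
property of threshold-run counting on slow-kernel data, not of the
implementation: detected frequency should be read as "resolvable
excursions per minute". The recovery experiments below are designed
around this constraint.

## Activity classes

Hypoactive < 2 transients/min; hyperactive > 6; the boundary values 2
and 6 are inclusive to normal (the class definitions are strict
"fewer than" / "more than"). Fractions are reported both pooled over
neurons and per animal.

## Running-response categorization

Per neuron, each running trial contributes its run frames plus the
contiguous stationary frames immediately preceding onset; segments are
truncated to the shortest common pre- and post-onset lengths and
averaged across trials. The baseline mean and SD come from the pre-onset
segment *of the trial-averaged trace* (not from per-trial SDs — the rule
operates on the averaged trace, so its noise scale is the averaged
one; this is configurable in spirit via the `m`, `c`, and `sd_floor`
parameters). Post-onset frames only are scanned: a qualifying run is ≥ m
consecutive frames beyond ±c·SD, with defaults c = 3 and m = 3 frames at
2 Hz; at other frame rates m defaults to `ceil(1.5 s × rate)` so the
persistence criterion stays a duration, not a frame count. The full
running trial is evaluated, including the 2 s treadmill ramp-up. A zero
pre-onset SD is floored at 1e-12 and flagged.

Categories partition neurons: positive-only → activated, negative-only
→ suppressed, both → mixed, neither → no change. The rule is scale-free
(invariant to positive rescaling of a trace).

### Limitation: what the rule can and cannot see

A suppression of ΔF/F is observable only against a sustained elevated
baseline; for sparsely firing neurons the rest trace hovers near zero
and "less than nothing" cannot cross −3·SD. Conversely, for sparse
traces the pre-onset SD of the averaged trace can be very small, so a
single event in a single trial can clear +3·SD for 3 frames — the rule
is trigger-happy on sparse data. Both behaviors are faithful to the
rule's definition and visible in real datasets (where no-change
fractions are small).

## Synchrony

Pearson's r of raw ΔF/F (no transient masking). Resting: one matrix
over the rest block. Running: one matrix per trial, averaged
arithmetically across trials (a Fisher-z average is available via
`fisher_z=True` but is not the default, since plain trial averaging is
the conventional summary here). Constant (zero-variance) traces yield
undefined pairs; these are stored as NaN, counted in
`n_undefined_pairs`, and excluded from index averages. The correlation
index of neuron i is mean over j≠i of r_ij; the animal mean averages the
indices. Subgroups smaller than two neurons raise `SubgroupTooSmall`,
which callers treat as a flagged skip for that animal.

## Group statistics

Shapiro–Wilk is applied to each group separately at α = 0.05; if either
group fails, the comparison routes nonparametric. Mann–Whitney U is the
default unpaired nonparametric test ("location" family);
Kolmogorov–Smirnov is chosen only when the analysis targets distribution
shape (`family="distribution"`), since no mechanical criterion separates
the two — the choice is exposed as a parameter rather than guessed.
Small samples (both n ≤ 8) use the exact Mann–Whitney null distribution.
A paired comparison with all-tied differences is degenerate for the
signed-rank test and is reported as p = 1 with a `degenerate` flag.

## Synthetic session generator

The trace of neuron i is

    x_i(t) = Σ_k a_k · K(t − t_k) + drift_i(t) + ε_i(t)

with K a difference of exponentials normalized to unit peak (defaults
rise 0.2 s, decay 1.5 s — a GCaMP6s-like kernel that makes transients
span multiple frames at 2 Hz), a_k ~ N(amplitude_mean, amplitude_sd)
clipped at 0, sinusoidal drift (amplitude 0.05 ΔF/F, period 60 s, random
phase), and white noise (SD 0.05 ΔF/F). Event times come from an
inhomogeneous Poisson process with intensity

    λ_i(t) = rate_i(state(t)) · [(1−w)·ξ_i(t) + w·ξ_c(t)]

where rate_i switches between the rest rate and rest rate × run gain at
trial boundaries (an optional ramp mirrors the 2 s treadmill speed-up;
off by default so response truth stays crisp), and ξ_i, ξ_c are
unit-mean exponentiated stationary AR(1) processes (depth 1.5,
correlation time 5 s) — a private and a shared "common drive" modulator
mixed by the weight w ∈ [0, 1]. The depth and timescale were chosen so
that the common drive produces population co-fluctuations on the scale
seen in quiet-wakefulness recordings and measurably raises pairwise
correlations as w grows; much shallower or faster modulators make w
nearly inert, which would defeat its purpose as the synchrony control.

Randomness uses one seed per session expanded into per-neuron
substreams (`numpy.random.SeedSequence.spawn`), so identical specs give
bit-identical sessions and per-neuron streams are stable under
parallelism.

Mixed-response neurons are realized by a *within-trial* biphasic gain
schedule (gain 3 for the first half of each running trial, 1/3 for the
second). A per-trial signed schedule (different gains on different
trials) cannot produce a mixed average: trial averaging washes the signs
out to a single elevated level, so the biphasic schedule is the
mechanism that makes the mixed truth recoverable by the categorizer.

### Presets

| parameter | `wt_like` | `tg_like` |
|---|---|---|
| activity mix (hypo/normal/hyper) | 15% / 70% / 15% | 60% / 32% / 8% |
| rest rates per class (events/min) | 0.3–1.5 / 2.5–5.5 / 6.5–9 | 0.2–1.2 / 2.2–4.5 / 6.5–8 |
| response mix (act/sup/mix/none) | 40% / 15% / 30% / 15% | 20% / 45% / 20% / 15% |
| event amplitude (ΔF/F) | 0.6–1.0 | 0.35–0.65 |
| common-drive weight w | 0.10 | 0.60 |

`tg_like` encodes the tauopathy-like direction on every axis: a
hypoactive majority, smaller events, suppressed responders dominant,
and a more synchronous residual population. Response-class truth is
assigned independently of activity class; suppressed-truth neurons with
sparse resting activity are therefore often *undetectable* by the
deviation rule, exactly as in real recordings.

## Recovery experiments (`catrace.validation`)

The validation experiments measure each stage against simulator ground
truth. Their cohort designs put each stage in the regime where its
output is identifiable, so they test the analysis logic rather than the
indicator physics:

* **Activity-class recovery** — 20 neurons per session with rates drawn
  per class, amplitude 0.8 (16× the noise SD), sampled at 10 Hz with a
  fast kernel (rise 0.05 s, decay 0.3 s), 100 s of rest, no drift or
  rate modulation. Recovery is judged against the class of each neuron's
  *realized* resting rate, excluding neurons within 0.5/min of a class
  boundary: over a 100 s observation the drawn rate and its Poisson
  realization decouple (SD ≈ 1.7/min at 5/min), so the realization is
  the recoverable truth. The fast kernel/fine sampling are what make
  exact event counting possible at all; at the native 2 Hz with a
  GCaMP6s kernel, merging near the 6/min boundary makes exact counts
  unattainable (see above), which is a documented property of the
  method, not a classifier defect.
* **Response-category recovery** — all neurons tonically active
  (6 events/s, amplitude 0.06) so the baseline is a sustained elevated
  level whose fluctuations are noise-dominated; run gains 3, 1/3, 1 and
  the biphasic mixed schedule are the only differences between classes.
  This is the regime in which suppression is observable and the
  pre-onset SD is representative.
* **Common-drive monotonicity** — a neutral 20-neuron cohort
  (8 events/min, no state response) swept over w ∈ {0, .25, .5, .75, 1},
  correlations from the running state (five trials, the longest
  estimation window).
* **Group-direction experiment** — 7 animals × 50 neurons per preset
  with matched per-animal seeds across groups (common random numbers:
  each replicate is a paired comparison, so between-seed variance does
  not masquerade as a group difference).
* **Type-I calibration** — the routed comparison on 2000 pairs of null
  normal samples (n = 20 per group).

Problem sizes (session counts, seed counts, neurons per cohort) are
chosen to give stable Monte-Carlo estimates at desk scale; all
experiments are deterministic given their seed.

### What passing tests do not show

The generator emulates denoised CNMF output. It does not model photon
shot noise, motion artifacts, neuropil contamination, spike-to-calcium
nonlinearity (saturation, facilitation), or cell-to-cell kernel
variability. Recovery rates measured here therefore bound what the
pipeline can do on ideal inputs; on real data, upstream extraction
quality dominates. Likewise the preset cohorts reproduce the *signs* of
group differences at desk scale, not the published effect sizes, which
depend on the original sample sizes and raw data.

## Numerical details

* Baseline search uses a vectorized sliding-window SD; ties resolve to
  the earliest window via `argmin`'s first-minimum rule.
* Window length uses Python banker's rounding of 0.15·n (the rounding
  rule at half-integers is unspecified by the definition; tests pin the
  implementation's choice).
* Detection uses strict inequality (> threshold); shifting a whole trace
  by a constant shifts baseline mean and threshold equally, leaving
  detection invariant (tested).
* Peak-time sorting breaks ties by neuron id; min-max normalization
  never moves a unique argmax.
* All randomness flows through `numpy.random.Generator`; no global seed
  state is touched.
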