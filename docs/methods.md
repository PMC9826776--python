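# Methods

This note documents the statistical model behind `mammogist`, the
conventions adopted where the analysis admits more than one reasonable
reading, the generative model of the synthetic experiment, and what the
package's tests do and do not establish about real data.

## Signal-detection model

Ratings r ∈ {0, …, 100} are binarised at a threshold t (default 50) with
the strict rule *abnormal ⇔ r > t*, so a rating of exactly 50 is a
"normal" decision — the same convention the training feedback uses.  With
hit rate H and false-alarm rate F,

    d′ = z(H) − z(F),        c = −(z(H) + z(F)) / 2,

under the equal-variance Gaussian model (z = standard-normal quantile).

**Extreme proportions.**  z is undefined at 0 and 1.  The log-linear
correction Ĥ = (k + ½)/(n + 1) is applied to *every* cell, not only the
extreme ones, so corrected and uncorrected cells remain on one scale and
small-n estimates are mildly shrunk toward ½ uniformly.  A clamping
alternative (0 → 1/2n, 1 → 1 − 1/2n) is available via
`correction="clamp"`; it leaves interior cells untouched.

**Category groups.**  Contralateral and prior stimuli are pooled as
*global*, since both carry only global abnormality signals and no
localisable lesion.  Each phase has a single pool of normal trials, so the
false-alarm rate is computed once per phase and shared across the
obvious / subtle / global / all-abnormal groups; per-group d′ differences
therefore reflect hit-rate differences only, which is the quantity of
interest.

## ROC variants

**Empirical.**  Decision thresholds sweep 1–99 with the rule r ≥ t
(so the fixed-threshold metric at 50, r > 50 ⇔ r ≥ 51, coincides with
sweep point t = 51).  Endpoints (0,0) and (1,1) are appended, duplicates
collapsed, and the AUC taken by the trapezoid rule.  For integer ratings
this equals the Mann-Whitney statistic P(A > N) + ½P(A = N), which the
test suite verifies exhaustively.

**Likelihood-ratio.**  Each class's rating histogram on the 0–100 lattice
is convolved with a Gaussian kernel of standard deviation 10 rating units
(the conventional meaning of a kernel "width"; an FWHM reading is
available via `width_is_fwhm`).  The kernel is truncated at the scale
boundaries and each source value's kernel mass renormalised to 1 on the
lattice, so no probability leaks off the scale.  A floor of ε = 10⁻⁶ keeps
densities positive before the log-likelihood ratio is taken.  Lattice
values are then admitted in order of decreasing likelihood ratio, exact
ties merged, and the cumulative class masses traced; each segment's slope
equals its likelihood ratio, so the curve is concave (proper) by
construction.  On well-separated unimodal data this agrees with the
empirical AUC to within the smoothing blur; on bimodal rating
distributions — where the threshold sweep folds back — it dominates it,
which is the method's purpose.

**Above-chance test.**  The null resamples *both* classes, with
replacement and at the original class sizes, from the pooled ratings:
labels carry no information under this scheme, making it a genuine chance
model.  (Resampling within class, the variability bootstrap, is available
via `scheme="within_class"` but recentres on the observed AUC rather than
0.5, so it cannot serve as a chance null.)  The cutoff is the nearest-rank
95th percentile of the 100 null AUCs and the observation must strictly
exceed it.  With 100 replicates this construction has an exact exceedance
probability of 6/101 ≈ 5.9% under the null (the observation is
exchangeable with the replicates), which the calibration test brackets
with [2%, 12%] at 500 simulated null datasets.

## Learner classification and its null

The trajectory is the nine training-phase d′ values with all abnormal
categories pooled against each phase's normal trials.  A participant is a
*learner* iff the Pearson correlation between trajectory and phase index
1–9 is strictly positive; a zero-variance trajectory has an undefined
coefficient and is classified non-learner with r recorded as 0.

The null simulation rates every trial uniformly at random (integers 0–100;
a continuous option exists).  Because per-phase d′ depends on the data only
through the counts of ratings above threshold, the simulation draws those
counts directly as binomials with p = 50/101 — an exact, not approximate,
vectorisation of trial-level uniform rating.  Each cohort (15 raters by
default) completes a 200-trial pre-test (80 normal / 120 abnormal), nine
training phases of 720 scored trials (288 / 432) and a 200-trial
post-test; raters are split by the trajectory correlation and the subgroup
means of (post − pre) d′ recorded per run.  Attention trials and the
staircase are omitted here — neither influences a uniform rater's scored
ratings — while the full-schedule generator remains available for
cross-checks.  Confidence intervals over runs are mean ± 1.96·SD/√runs;
runs with an empty subgroup contribute nothing to that subgroup.  At 1000
runs both subgroup means land within ±0.01 of zero with CI half-widths
near 0.006.

## Exclusion and timing rules

A participant is excluded for (1) more than 30 of the 144 training
attention checks missed in total, (2) more than 6 of 16 missed in a single
training session, or (3) rating ≥ 85% of trials as exactly 50 in any test
session or in more than one training session.  A missed attention check is
a decision on the wrong side of 50 given the scene instruction (beach low,
forest high), mirroring the mammogram feedback rule; the ≥ 85% rule is
evaluated over mammogram trials only (attention and practice trials are
neither rated stimuli nor part of the denominator) and the boundary is
inclusive.  Repeat presentations of failed attention checks are not
modelled; each scheduled check counts once.

Timing summaries are per participant × session × screen.  The outlier pass
is single-pass: mean and SD over all values in the session, one sweep
removing values outside mean ± 3 SD, statistics over the remainder.  The
trial schema records viewing and rating durations; feedback-screen
durations are accepted through an optional `feedback_time_ms` column and
the summary is emitted empty-flagged when the screen produced no data
(test phases, or the column absent).

## Generative observer model

An SDT observer draws latent evidence x ~ N(0, 1) on normal trials and
x ~ N(d_cat, 1) on abnormal ones, where d_cat = max(0, d₀(cat) + n·Δd(cat))
after n completed training phases, and rates

    r = round(100 · Φ((x − c) / spread)),   c = c₀ + n·Δc.

c is an *absolute* cutoff on the evidence axis; the measured
signal-detection criterion of such an observer sits at c − d/2 (plus a
+0.0125·spread discretisation offset from rounding the 0–100 scale), which
the parameter-recovery tests account for.  Thresholding r at 50 reproduces
the generative hit/false-alarm structure, so estimated d′ recovers d_cat
unbiasedly.  At the retention test a fraction `retention_decay` of the
accumulated training change (in both sensitivity and bias) is removed.

Cohort presets: baseline sensitivities d₀ = 0.6 / 0.35 / 0.2 / 0.2
(obvious / subtle / contralateral / prior) — obvious easiest, global
weakest, the ordering the task is built around and comparable to the weak
pre-training sensitivity naive observers show; the learner preset gains
Δd = 0.022 per phase per category (≈ 0.2 d′ over nine phases), drifts
liberal at Δc = −0.035 per phase (≈ −0.32 over training) and retains a
third of the gain at retention; the static preset has the same baseline
and no change.  Actual viewing times are drawn uniformly between the
500 ms minimum and the current staircase maximum (observers release the
stimulus at an arbitrary point of the window); rating times are lognormal
around 1.5 s.  Attention checks are answered on the correct side of 50,
with a configurable miss rate for exercising the exclusion rules.

**Staircase.**  The maximum viewing time starts at 2500 ms at the first
block of the experiment and the state carries across blocks *and* phases:
a per-phase reset would contradict the observation that maximum viewing
times keep declining across phases.  After each block, block d′ > 0.2
sets the maximum to 0.9 × the block's mean actual viewing time; d′ < 0.05
multiplies the current maximum by 1.05; in the dead zone [0.05, 0.2] the
maximum is unchanged.  Results are clamped to [500, 2500] ms — the lower
clamp keeps the window at or above the minimum exposure, so for a
competent observer the staircase converges onto the 500 ms floor.

**Block composition.**  The 54 global slots per block split between
contralateral and prior stimuli binomially in proportion to the pool
sizes (1868 : 324).  Stimuli never repeat within a block; repeats across
blocks arise naturally from independent sampling.  The generator makes no
attempt to reproduce any particular across-block repetition profile — that
depends on unstated details of the original scheduling — and its own
repetition statistics follow from independent per-block draws.

**End-to-end recovery cohort.**  The integration test classifies a cohort
of 9 improving observers (Δd = +0.04/phase) against 6 mildly declining
ones (Δd = −0.03/phase).  Declining rather than flat non-learners is a
deliberate design choice: a perfectly flat observer's trajectory is
exchangeable noise, its correlation sign a fair coin, so *no* classifier
can beat 50% on that subgroup and "recovery" would be undefined for it.
The split criterion itself defines non-learners by negative correlation,
which a negative generative trend realises.

## Numerical and interface choices

- Per-phase trial-count bookkeeping: test phases have 203 rows (3 practice
  trials with feedback + 200 test trials), training phases 736 (4 × 184);
  a full participant is 7233 rows.
- Sessions map to phases as in the original schedule: session 1 = pre-test
  + training 1, sessions 2–8 = training 2–8, session 9 = training 9 +
  post-test, session 10 = retention.
- Trial tables are comma-separated UTF-8 with a required header; a
  tab-separated dialect is accepted.  All readers validate row-level
  invariants and report the first offending row.
- Every stochastic entry point takes a seed; the CLI expands one top-level
  seed into per-stage seeds through SHA-256-keyed `SeedSequence` children
  and records them in the run manifest, making whole runs byte-identical
  under a fixed seed.
- Simulation sizes in the test suite (3-observer cohorts, 500-seed
  calibration, 2-seed end-to-end recovery, 1000-run null) were chosen so
  the statistical assertions have comfortable margins at the package's
  own tolerances.

## Limitations

The generator emulates the *structure* of the experiment, not mammographic
perception: evidence is unidimensional Gaussian with equal variances,
learning is linear in phase count, viewing time does not modulate
sensitivity (so the staircase shapes exposure bookkeeping, not
performance), and rating-time distributions are schematic.  Passing tests
therefore establish that the analysis chain is correct and calibrated
under its stated model — recovery of known parameters, exact structural
counts, null calibration — not that any empirical claim about human
observers holds; analysing real rating data requires only the trial-table
CSV contract.
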