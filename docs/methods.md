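# Methods

This note documents the models, conventions and design choices behind
`ppgr`: what each stage computes, what the synthetic-cohort generator
does and does not emulate, and the numerical decisions that matter for
reproducing its behaviour.

## Outcome: 2-h incremental area under the glucose curve

The postprandial response to a meal at time *t* is the incremental area
under the interstitial glucose curve over (*t*, *t* + 120 min], in
mmol/l·min.  The curve is piecewise linear through the CGM readings
(trapezoidal rule).  Conventions:

- **Baseline** — glucose at the meal time itself, linearly interpolated
  between the bracketing readings (self-reported meal times rarely fall
  on the 15-min grid).  A last-reading-carried-forward (`locf`)
  alternative is available.
- **Sign convention** — the default `positive_only` mode integrates
  only the area above baseline, splitting any trapezoid exactly at a
  baseline crossing; the field's sources differ on whether
  below-baseline area is subtracted, so a signed `net` mode is kept as
  an option.  `positive_only ≥ net` always, with equality iff the curve
  never dips below baseline.
- **Window end** — if no reading falls exactly at +120 min, the
  endpoint is interpolated when a bracketing reading exists beyond the
  window; otherwise the curve is truncated at the last in-window
  reading.
- **Gaps** — interpolation across more than 45 min (three missed
  readings) is refused and surfaces as a coverage error.

The pre-prandial covariate is the arithmetic mean of the readings in
the closed 2-h window before the meal.

## Meal records and inclusion rules

Meal timestamps combine the reported "HH:MM" with the survey response
date.  For intakes reported the next morning on the "after the last
survey, before sleep yesterday" occasion, a clock time ≥ 12:00 places
the meal on the previous calendar day; an after-midnight clock time
keeps the response date.  (The source protocol states the rule only for
before-midnight meals; the 12:00 cut operationalises "before
midnight".)

A meal qualifies when all three rules pass, evaluated independently so
the audit table can report every failure:

1. **CGM coverage** — "time-matched CGM measures" is not formally
   defined anywhere, so the package requires: ≥ 1 reading in the closed
   2-h pre-window *and* within 45 min before the meal (so baseline and
   pre-prandial mean are computable), ≥ 80% of expected readings
   (≥ 7 of 8 at 15-min spacing) in the half-open 2-h post-window, and
   the ±2-h window inside the trace span.  The fraction is
   configurable.
2. **Prior intake** — any *reported* meal (qualified or not) in
   [t − 2.5 h, t) disqualifies the meal; beverage-only reports count as
   intake (configurable reading of an unstated detail).
3. **Clock time** — meal time in [06:00, 24:00), half-open at both
   category and day boundaries.

Participants with fewer than three qualifying meals are excluded.
Duplicate reports of the same meal (identical participant and
timestamp) keep the first record with a logged warning.

## Activity and sleep exposures

ENMO cut-points classify 5-s epochs with the lower edge of each band
inclusive: < 40 mg inactive, [40, 100) mg LPA, ≥ 100 mg MVPA, ≥ 400 mg
additionally flagged vigorous.  Durations are epoch counts × 5 s with
no bout-length requirement.  Windows are half-open and consistent —
postprandial (t, t+2h], daily [t−24h, t) — so no epoch is double
counted across the meal boundary.  "Sleep the night before" is the
most recent sleep window whose wake precedes the meal within 24 h;
among several candidates the later wake wins, and naps are not merged
into main sleep.  Features are marked missing (not imputed) when a
window leaves the series span.

## Decomposition and ICC

Person-mean centering: between_i = x̄_i (grand-mean centered by
default, which changes only the intercept's interpretation), within_ij
= x_ij − x̄_i.  Person means are taken over the analysis meal set.
ICCs come from intercept-only random-intercept models: REML for
continuous measures; for binary food flags a logistic random-intercept
model fitted by maximum likelihood with 41-node Gauss–Hermite
quadrature, reporting the latent-threshold-scale ICC
σ²_b / (σ²_b + π²/3).  An observed-scale binary ICC is deliberately not
implemented.  The outcome's ICC is reported unadjusted.

## Association models

Random-intercept linear mixed models, REML.  The basic model carries
one exposure's within/between pair plus the covariates (age, sex,
ethnicity, education, smoking, heavy alcohol, BMI, pre-prandial mean)
and the meal-time category; the full model carries all 21 exposures
jointly.  Meal-time category appears in both modes (reference:
morning); reference levels are female, Chinese, secondary-or-below.
Missing terms are handled complete-case with counts logged.  Fixed-
effect p-values are two-sided Wald tests on the normal scale.

The solver profiles β and σ²_e out of the restricted likelihood and
optimises the single variance ratio ψ = σ²_b/σ²_e with per-cluster
Woodbury algebra, making one fit cost O(G·p²) per objective evaluation
(~milliseconds).  This is what makes a 200-replicate cluster bootstrap
and the simulation studies affordable; the test suite verifies
agreement with statsmodels MixedLM and lme4 to optimiser precision.
Degenerate design columns (a covariate constant within a stratum, or a
categorical level empty there) are dropped and recorded; collinearity
involving an exposure term raises an error naming the terms.

**Bootstrap** — participants are resampled with replacement (cluster
bootstrap; each draw gets a fresh cluster label), the model refit, and
percentile 2.5/97.5 bounds taken; B = 1000 by default, seeded, with
non-converging replicates dropped and counted (flagged above 10%).
Percentile cluster bootstrap is the simplest scheme that respects the
random-intercept dependence; the source analyses name only
"bootstrapping".

**Sensitivity analyses** — interaction models add within-exposure ×
modifier and meal-time × modifier products (modifier: sex or
prediabetes, the latter defined as fasting glucose ≥ 5.6 mmol/l or
HbA1c ≥ 5.7%); stratified fits repeat the full model inside each
stratum.  In both, between-person exposures are excluded and the
stratifying variable leaves the covariate list, limiting the parameter
count in the smaller samples.  Interaction p < 0.05 is flagged
significant, [0.05, 0.10) marginal.

## The synthetic cohort

The generator emulates the study design the pipeline targets: nine
free-living days, six EMA windows per day (8:00–9:30, 10:30–12:00,
13:00–14:30, 15:30–17:00, 18:00–19:30, 20:30–21:30), 15-min CGM, 5-s
ENMO epochs, nightly sleep windows.  Wearables start one day before
the first survey day — device fitting at the baseline visit — so every
meal has a 24-h activity history and a prior night of sleep.

**Truth model.**  Each meal's intended iAUC is
max(0, α + Σ β_w x + Σ (β_b − β_w) x̄_i + meal-time effect + b_i + ε),
with b_i ~ N(0, 32²) and ε ~ N(0, 50²) mmol/l·min.  Default β are the
full-model estimates of the published cohort this design mirrors
(refined grains +46.2, postprandial MVPA −58.0/h, sleep −2.7/h,
afternoon +54.4, evening +42.9, …; between-person refined grains
51.7, other between effects set equal to the within effects in the
absence of published values).  The intercept α is calibrated so the
mean iAUC is 137.4 mmol/l·min at the nominal exposure means; the
variance components split the published total SD of 71 into ≈ 77%
within / 23% between, matching the reported variance decomposition.

**Delivery.**  The intended value is injected into the glucose trace
as a smooth non-negative bump: a Beta(5, 8) density over a 120-min
support (peak ≈ 44 min), normalised to unit area and scaled.  The
density and its derivative vanish at both ends of the support, so the
15-min trapezoid recovers the scaled area with no truncation-edge
artefact — a truncated-gamma bump was rejected for exactly that
reason.  The baseline trace is a person level ~ N(5.4, 0.4) mmol/l
plus a small circadian sinusoid (amplitude 0.05 mmol/l, acrophase
16:00) and N(0, 0.1) measurement noise.  Because a drifting baseline
contributes deterministic area of its own, the bump is scaled by the
intended value *minus* the window's net circadian area: the intended
iAUC is defined as the total incremental area, and the closed loop
(recompute the trapezoid iAUC from the trace, get the intended value
back up to discretisation error) holds by construction.  The test
suite verifies recovery within 5% on noise-free configurations.

**Behaviour.**  Meals follow a morning/lunch/dinner schedule
(probabilities 0.75/0.95/0.90, ≥ 2.6 h spacing), reproducing the
29/36/35% meal-time shares; a configurable 6% of days add a
closely-spaced extra meal (exercising the 2.5-h filter) and 1.5% a
night meal (exercising the clock filter).  Food flags are thresholded
Gaussian latents with a person component (latent ICC 0.2) and an
optional cross-food correlation matrix (used to reproduce the
refined/whole-grain confounding sign flip); printed per-meal
frequencies calibrate the 13 published food groups, with the two
beverage groups (not printed) set to 0.15/0.35.  Activity is built
from Dirichlet-placed LPA/MVPA bouts (8/6 min mean) inside each waking
period, with day-level totals around person-level means (daily LPA
2.8 h, daily MVPA 1.6 h; 3% of MVPA epochs vigorous), so postprandial
activity inherits both within- and between-person variance from bout
placement; sleep and daily-activity variance components are split so
that, as reported, every measure varies more within than between
persons except daily MVPA.  EMA behaviour: meals are reported at the
next answered survey (8% non-response), late dinners roll into the
next morning's first survey, and unreported meals still leave their
glucose bump in the trace — the analysis never sees them, exactly as
in real data.

Randomness: one seed, fanned out per participant via
`SeedSequence.spawn`, so enlarging a cohort never changes existing
participants.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: glucose physiology (no insulin
compartment; the bump shape is a convenience, not a model of
absorption), EMA response psychology, raw 100-Hz accelerometry and
device error, food-group portion sizes, and any correlation between
diet composition and activity beyond what the linear truth induces.

## Numerical choices and degenerate inputs

- iAUC trapezoids split exactly at baseline crossings; fine-grid
  agreement is tested to 10⁻⁶ relative error.
- The LMM profile is optimised over log ψ ∈ [−14, 10] with a bounded
  scalar minimiser (xatol 10⁻⁹) and an explicit boundary check at
  ψ → 0; ψ below 2×10⁻⁶ is reported as zero between-cluster variance.
- Gauss–Hermite: 41 nodes, Nelder–Mead on (μ, log σ); stable
  log-sigmoid throughout.
- Ties and boundaries: all window conventions half-open as stated
  above; ENMO band edges inclusive at the lower edge; the ≥ 3-meal
  rule inclusive.
- Degenerate inputs: empty windows are errors (glucose) or zeros
  (activity); single-meal participants centre to within = 0; constant
  binary measures make the ICC undefined and raise.

## Problem sizes in validation

The recovery studies use 200 participants × 9 days (≈ 4,600 analysed
meals) across 10 fixed seeds with B = 200 bootstrap replicates, the
null-calibration study 200 cohorts of 25 participants, and the ICC
grid 300 × 10 with five replicates per cell — sizes chosen so the
whole suite completes on a single CPU while keeping Monte-Carlo error
well inside the asserted tolerances.  Relative-bias assertions (≤ 10%
of the true effect) are made for effects large enough that the
Monte-Carlo standard error of a 10-seed mean is small against the
bound; near-null effects (|β| < 20 mmol/l·min) carry an absolute bound
of 6 mmol/l·min (~3 Monte-Carlo SEs) instead, since a 10% relative
band around, say, β = 0.8 cannot be resolved at any reasonable
simulation size.

## Known limitations

- The zero-truncation of the intended iAUC mildly attenuates all
  recovered effects (≈ 2–4% under default conditions); it is part of
  the truth model, not an estimator defect.
- The full model needs more participants than person-level columns
  (21 between-person exposures + 9 baseline covariates + intercept ⇒
  cohorts of ≳ 35); smaller cohorts are rank-deficient by construction.
- Wald p-values use the normal reference; with hundreds of clusters
  this is inconsequential, but small-stratum p-values are approximate.
- The bootstrap treats the person-mean centering as fixed; person
  means are not recomputed inside replicates (each resampled cluster
  keeps its own means, so the within columns are unchanged).
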