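# ppgr — free-living postprandial glucose response analysis

`ppgr` is a Python library for analysing how everyday diet, physical
activity and sleep relate to post-meal glucose under free-living
conditions, when meals are self-logged on a smartphone (ecological
momentary assessment, EMA), glucose comes from a continuous glucose
monitor (CGM) sampling every 15 min, and movement comes from a wrist
accelerometer summarised as 5-s ENMO epochs.  It is written for
researchers running (or planning) such multi-sensor observational
studies.

The pipeline:

1. **Meal events** — combine each EMA response's reported clock time
   ("HH:MM") with the response date into a meal timestamp, then keep the
   meals with (i) time-matched CGM coverage, (ii) no other reported
   intake in the prior 2.5 h, and (iii) a clock time in 06:00–24:00;
   participants need ≥ 3 qualifying meals.
2. **Glucose features** — the outcome is the 2-h incremental area under
   the curve, iAUC = ∫₀¹²⁰ max(G(t) − G₀, 0) dt (trapezoidal rule,
   baseline G₀ interpolated at the meal time; a signed "net" mode is
   available), plus the mean glucose of the 2-h pre-prandial window.
3. **Activity and sleep exposures** — ENMO cut-points 40 mg (light,
   LPA) and 100 mg (moderate-to-vigorous, MVPA) classify each 5-s
   epoch; durations are epoch counts × 5 s in the (t, t+2h] postprandial
   and [t−24h, t) daily windows, plus sleep duration the night before.
4. **Decomposition** — person-mean centering splits every exposure
   x_ij into a between-person part x̄_i and a within-person part
   x_ij − x̄_i; intraclass correlations (ICC) from random-intercept
   models quantify each measure's between-person variance share
   (latent-scale ICC with residual π²/3 for binary food flags).
5. **Association models** — linear mixed models with person-specific
   random intercepts, y_ij = β_w(x_ij − x̄_i) + β_b x̄_i + meal-time +
   covariates + b_i + ε_ij, fitted by REML; a *basic* model per
   exposure and a *full* mutually adjusted model; 95% CIs by cluster
   (participant-level) bootstrap; sex/prediabetes interaction tests and
   stratified fits.

A **synthetic-cohort generator** produces complete, seeded datasets —
EMA logs, CGM traces, epoch series, sleep windows, participant table —
in which every meal's true iAUC follows a known linear model, so the
whole pipeline is testable by parameter recovery without access to any
real cohort.

## A worked example

```bash
python examples/05_association_models.py
```

simulates 80 participants × 9 days, runs qualification and feature
extraction, and fits the full model.  Output from that run:

```
1796 meals, 80 participants
                        beta    se  p_value
term
refined_grains_within  46.58  2.79     0.00
whole_grains_within    20.00  3.19     0.00
pp_mvpa_h_within      -62.26  9.21     0.00
sleep_h_within         -2.10  1.14     0.07
afternoon_1200_1800    59.01  3.04     0.00
evening_1800_2400      46.10  3.09     0.00

refined grains (within): bootstrap 95% CI [41.3, 51.4]
```

Units are mmol/l·min of 2-h iAUC per unit exposure: at meals where this
cohort's members added refined grains to their usual diet the glucose
response ran ≈ 47 mmol/l·min higher, an hour of postprandial MVPA
lowered it ≈ 62, and afternoon meals ran ≈ 59 above morning meals —
all within sampling error of the generating effects (46.2, −58.0,
54.4), which is the point: the estimates are recovered from raw
simulated sensor streams, not read back from the truth table.

Other examples: `01_simulate_cohort.py` (the generator and its hidden
truth), `02_meal_qualification.py` (the filter ledger),
`03_glucose_features.py` (iAUC on a hand-built trace),
`04_variance_decomposition.py` (within/between shares and ICC).

## Command line

A thin CLI wraps the pipeline for end-to-end runs from a YAML config:

```bash
ppgr all --seed 7 --out myrun          # simulate → qualify → features → fit
ppgr qualify --seed 7 --out myrun      # stop after the filter ledger
ppgr report myrun                      # print the run manifest
```

Every run writes its tables (meal records, qualification audit, meal
events, variance contributions, association table) plus a JSON manifest
with per-stage row counts; identical config + seed gives byte-identical
artefacts.

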