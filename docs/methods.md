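# Methods

## Estimand

Disease-free years (DFY) between ages 40 and 75: the expected years lived
without a first diagnosis of any of six chronic diseases, conditional on
being disease-free at 40,

    DFY = ∫₄₀⁷⁵ S(t | disease-free at 40) dt,   0 ≤ DFY ≤ 35.

Differences are reported against a reference exposure category (moderate
consumption without binge drinking in the 6-level grouping; moderate
consumption in the 3-level one). Age 40 is the conditioning age because that
is where routine health surveillance typically begins.

## Exposure coding

One unit of alcohol is 10 g ethanol (8 g in a sensitivity recoding, applied
as `units × 10 / unit_grams`). The groupings:

* 3-level: non-drinker / moderate (0 < units ≤ threshold) / heavy
  (> threshold). The threshold is 14 units/week, 21 in a sensitivity. Any
  reported positive consumption counts as drinking, however small.
* 6-level: non-drinkers split into never/former by the ever-drinking item;
  drinkers cross moderate/heavy with binge drinking (self-reported
  alcohol-induced loss of consciousness in the past year). Non-drinkers
  without the ever-drinking item are coded `missing` and dropped from the
  6-level analysis only — a real feature of consortium data, where only some
  cohorts field that item.
* 5-level (biobank-style): an explicit occasional-drinking flag that
  overrides the unit-based coding (conflicts logged, occasional wins).
* 8-level daily doses: 0 reserved for exact zero; positive consumption maps
  to `max(1, round_half_up(weekly/7))` capped at 7. The rounding rule and the
  floor-to-1 are package choices: treating a light drinker as dose-0 would
  conflate them with abstainers, and no convention is standard here.

ICD-10 code sets (hospitalisation for alcohol abuse/poisoning, alcohol-related
death, wholly alcohol-attributable conditions) ship as editable JSON. A listed
3-character category (`F10`) matches all subcodes; a listed 4-character code
(`F10.0`) matches only itself and extensions; ranges (`C01–C06`, `S00–Y91`)
expand over the letter-number grid with letter carry-over. The
alcohol-related-death range S00–Y91 is implemented verbatim although it spans
all external causes; users substituting their own registry definitions should
edit the JSON resource.

## Survival model

Flexible parametric model on the log cumulative-hazard scale with age as the
timescale: `ln H(t; c, z) = s_c(ln t; γ_c) + βᵀz`, with `s_c` a restricted
cubic spline (linear beyond its boundary knots), a separate baseline per
exposure category, and optional proportional covariates. The log likelihood
with delayed entry is `Σ d_i ln h(t_i) − [H(t_i) − H(t0_i)]` with
`h = H·s′/t`. Modelling `ln H` guarantees a positive cumulative hazard and
makes the conditional survival `exp(−[H(t) − H(40)])` a one-liner.

Knots: boundary at the min/max uncensored log event age; internal knots at
equally spaced centiles of log event ages (median for 1; 33/67 for 2; 25/50/75
for 3; 20/40/60/80 for 4), de-duplicated with a warning when centiles
coincide. The internal-knot count (0–4) is selected by AIC by default.

Two parameterisations: per-category baselines (used for DFY) and a
proportional variant with a single baseline and category dummies (used for
hazard ratios with Wald CIs from the observed information). They answer
different questions and the API refuses to mix them.

### Numerical strategy

The raw cubic basis on a narrow log-age span is nearly collinear, and under
left truncation the level of `ln H` is only weakly identified (a likelihood
ridge trades level against log-log slope). The fitter therefore:

* orthonormalises the design per fit (QR), storing the transform for
  prediction;
* starts from a regression of the log Nelson–Aalen estimate (risk sets with
  delayed entry, plus a constant-rate level correction for hazard before the
  earliest entry) on the basis, and from a projection of the previous
  (fewer-knot) fit — which also keeps log likelihoods nested across knot
  counts up to optimiser tolerance;
* maximises by BFGS with an analytic gradient; hazard positivity enters as a
  smooth softplus barrier on the spline slope at event times (exact to ~1e-7
  wherever the slope exceeds 0.1), with an absurdity guard against the
  pathological region where a decreasing `H` over censored follow-up
  masquerades as likelihood; stalled line searches are finished by a
  Levenberg-damped Newton polish;
* rejects any candidate whose fitted log-log slope drops below 0.1 or whose
  `H` exceeds ~100 anywhere on the observed age grid — an identifiability
  guard that removes ridge solutions with absurd out-of-range behaviour while
  admitting any hazard growing at least like `t^0.1`;
* reports standard errors from the inverse observed information (finite
  differences of the analytic gradient).

Bootstrap refits reuse the point fit's knots and basis transform, warm-start
from its coefficients, and use a block-separable damped Newton (analytic
Hessian) when there are no shared covariates — that is what makes
1000-replicate bootstraps affordable.

## DFY estimation and uncertainty

The conditional survival curve is integrated by cubic-spline quadrature on a
0.05-year grid (documented tolerance 1e-3 years against a halved step; the
observed error is far smaller). Percentile bootstrap CIs: subjects are
resampled with replacement within cohort × category strata, preserving the
design margins; the two-sided p-value for a difference is
`2·min(P(diff* ≤ 0), P(diff* ≥ 0))`. Replicates that fail to converge are
dropped and counted; more than 5% failures aborts with an error, and in the
two-stage first stage such a cohort is excluded with a warning. The default
is 1000 replicates; per-cohort first-stage standard errors use a reduced
count (50) since only an SE is needed.

Death is treated as censoring in the main analysis, with the
disease-or-death composite endpoint as the sensitivity switch
(`death_handling="composite"`); the competing-risk analysis below quantifies
the difference. Exclusions run missing-data first, then prevalent disease,
with a count-reconciled report.

## Pooling

Two-stage: per-cohort DFY differences (bootstrap SEs) pooled by the classical
DerSimonian–Laird moment estimator — fixed-effect weights `1/se²`, Cochran's
Q, `τ² = max(0, (Q − df)/(Σw − Σw²/Σw))`, random-effects weights
`1/(se² + τ²)`, normal CIs, `I² = max(0, (Q − df)/Q)·100`. One-stage: a
single fit on the pooled data with proportional study effects; DFY is
reported at the reference study level and as a study-frequency-weighted
average, since "adjusted for study" leaves the prediction level open.
`compare_stages` puts the two side by side with CI-overlap flags.

Per-cohort first-stage fits cap the spline at one internal knot: cohort-level
curves only feed pooled differences, and richer per-cohort splines make the
bootstrap SEs fragile on cohorts with narrow age support.

## Competing risks

The Aalen–Johansen estimator with delayed entry:
`CIF_dis(t) = Σ_{t_j ≤ t} S_all(t_j−)·d_dis,j/n_j`, computed so that
`1 − CIF_dis − CIF_death` equals the all-cause product-limit survival by
construction. The regression counterpart (subdistribution hazards) is out of
scope: the survival-bias question is answerable by the nonparametric CIF
comparison plus the composite-endpoint DFY, without an extra estimation
machinery orthogonal to the estimand.

## Synthetic consortium

The default generator emulates a 12-cohort working-age consortium: cohort
sizes 1,915–44,527 (total 129,942), sex splits 16–84% male, entry ages
40.8–50.3 (SD 2.8–13.6), administrative censoring after 5.0–24.7 years —
and six alcohol-use categories with prevalences (never 6%, former 6%,
moderate non-binge 55%, moderate binge 8%, heavy non-binge 19%, heavy binge
6%). Disease hazards are Gompertz with slope 0.045/year and age-40 rates
0.0095–0.0145 by category, calibrated so first-event incidence lands near
15.7/1000 person-years in men; women's rates are scaled by 0.707, targeting
11.1/1000. Death is an independent Gompertz (0.0015 at 40, slope 0.08).
Missing-data and prevalent-disease flags (5.6% and 7.2%) are drawn
independently of outcomes — the exclusion cascade is exercised as plumbing,
not as a bias study. Event ages are drawn by inverse transform conditional on
being event-free at entry, with one RNG stream per cohort keyed by name so
results do not depend on cohort order.

Hazards extend below age 40 by analytic continuation (`a·e^{b·u}` for u < 0)
rather than a flat extrapolation: a kink at 40 is not representable by a
smooth log-age spline, and with mixed entry-age distributions it induced a
systematic −0.1 year bias in recovered DFY that had nothing to do with the
estimators under test. The estimand is unaffected (only the hazard above 40
enters it).

What the generator does **not** emulate: informative censoring,
cohort-varying hazards (heterogeneity in the pooling tests comes from design
differences only), non-proportional sex effects, measurement error in
self-reported consumption, and registry-linkage artefacts. Passing tests
therefore demonstrate estimator correctness under a clean data-generating
process, not robustness to those real-data features.

## Validation design

Every estimator has an independent check: closed forms (exponential and
competing-exponential integrals), dual quadratures (adaptive vs Simpson),
lifelines' left-truncated Weibull MLE for the 0-knot model, a Kaplan–Meier
trapezoid AUC for model-based DFY, statsmodels' `combine_effects` for
DerSimonian–Laird, a frozen hand-computed 3-study pooling oracle, and the
product-limit identity for Aalen–Johansen. Estimand recovery on the default
consortium holds every (sex, category) cell with ≥ 5,000 subjects to within
0.2 years of the analytic truth, using the sex-combined fit with a
proportional sex effect (correctly specified under the generator and ~30%
more efficient than sex-stratified fits; the pipeline's reporting default
remains sex-stratified). Bootstrap calibration uses 100 outer replications
of a 20,000-subject two-category design with 200 replicates each — scaled
down from the production 1000 — and checks 95% interval coverage against the
binomial band 89–99%. Monte-Carlo sampling SDs of the recovery error are
0.05–0.15 years per cell, so the 0.2-year bound is a ~1.3–4 SD event per
cell; the suite fixes its seeds.

## Known limitations

* The level of `ln H` is weakly identified under left truncation with narrow
  entry windows; the identifiability guards keep predictions sane, but
  per-cohort fits at a few thousand subjects can still land on small-slope
  solutions whose bootstrap occasionally presses the positivity boundary —
  such cohorts are excluded from pooling by the failure contract rather than
  silently smoothed over.
* AIC knot selection is shared across categories within a fit, not per
  category.
* Percentile CIs, not BCa; delta-method CIs for DFY are deliberately absent.
* The 8-level daily-dose rounding convention is a package choice (see
  Exposure coding).
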