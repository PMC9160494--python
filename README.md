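# dfyears

Disease-free life-years from multi-cohort survival data.

`dfyears` estimates the expected number of years lived **between ages 40 and
75 without a first major chronic disease** (type-2 diabetes, coronary heart
disease, stroke, cancer, asthma, COPD), by category of alcohol use, from
left-truncated cohort data of the kind held by multi-study consortia and
biobanks. It is written for epidemiologists and biostatisticians who want the
full estimation chain — exposure coding, flexible parametric survival
modelling, area-under-curve life-years, bootstrap uncertainty, random-effects
pooling and a competing-risk sensitivity — as an importable, tested Python
library with a small CLI on top.

## The model

With age `t` as the timescale and `x = ln t`, each exposure category `c` gets
its own baseline on the log cumulative-hazard scale,

```
ln H(t; c, z) = s_c(x; γ_c) + βᵀz,
```

where `s_c` is a restricted cubic spline with 0–4 internal knots (selected by
AIC) and `z` holds optional proportional covariates (study, sex). Subjects
enter the risk set at their baseline age (left truncation / delayed entry).
Disease-free years are the area under the conditional disease-free survival
curve,

```
DFY(c) = ∫₄₀⁷⁵ exp(−[H(t; c) − H(40; c)]) dt   (at most 35 years),
```

evaluated by cubic-spline quadrature; differences are taken against moderate
non-binge drinkers (6-level grouping) or moderate drinkers (3-level).
Confidence intervals and p-values come from a bootstrap stratified by cohort
× category (1000 replicates by default). Across cohorts, differences are
pooled by two-stage DerSimonian–Laird random-effects meta-analysis with
I² heterogeneity, with a one-stage pooled fit (study-adjusted) as the
cross-check. Survival bias is probed by the left-truncation-aware
Aalen–Johansen cumulative incidence (death competing) and by re-running the
pipeline on the disease-or-death composite endpoint.

A synthetic-data module generates a 12-cohort consortium (n = 129,942, entry
ages ≈ 43 ± 10, follow-up 5–25 years, category-specific Gompertz hazards,
independent death hazard) whose true disease-free years are known in closed
form, so every estimator in the package is tested against a recoverable
truth.

## Worked example

```python
from dfyears import (CohortSpec, DFYConfig, HazardSpec, ModelConfig,
                     estimate_dfy, generate_cohort)

hz = {"exposed": HazardSpec("exponential", 0.02),
      "reference": HazardSpec("exponential", 0.01)}
spec = CohortSpec(name="demo", n=20000, sex_split=1.0, entry_age_mean=45,
                  entry_age_sd=3, admin_followup=35,
                  category_prevalence={"exposed": 0.5, "reference": 0.5},
                  disease_hazard=hz, death_hazard=HazardSpec("exponential", 1e-12),
                  female_hazard_ratio=1.0)
data = generate_cohort(spec, seed=11)

fit, estimates = estimate_dfy(
    data,
    ModelConfig(category_column="category", knot_candidates=(0,), selection="fixed"),
    DFYConfig(n_boot=200, seed=1),
    reference="reference",
)
for e in estimates:
    print(f"{e.category:<10} DFY {e.years:6.2f}  diff {e.diff_vs_reference:+.2f} "
          f"[{e.diff_ci_low:+.2f}, {e.diff_ci_high:+.2f}]")
```

prints

```
exposed    DFY  25.10  diff -4.43 [-4.82, -3.99]
reference  DFY  29.53  diff +0.00 [+0.00, +0.00]
```

The closed-form truths are 25.17 and 29.53 years (difference −4.36): the
exposed category loses about 4.4 disease-free years, and the 95% percentile
interval excludes zero. More narrative scripts live in `examples/` — one per
capability (simulation, exposure/ICD coding, estimation, pooling,
competing-risk sensitivity).

The same pipeline is available from a shell:

```bash
dfyears simulate --seed 1 --out runs/sim
dfyears code-exposure --in runs/sim/cohort.csv --out runs/sim/coded.csv
dfyears dfy --in runs/sim/coded.csv --grouping 6 --boot 1000 --seed 1
dfyears all --config config.yaml        # simulate → code → exclude → fit →
                                        # DFY → pool → sensitivity → report
```

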