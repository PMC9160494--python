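"""Fit the flexible parametric model and estimate disease-free years with CIs.

A single synthetic cohort with two exposure categories (disease rates 0.02 vs
0.01 per person-year) has closed-form true values: 25.17 and 29.53 years, a
difference of -4.36. The model is fit on the log cumulative-hazard scale with
age as the timescale; the bootstrap resamples subjects within category strata.
"""

from dfyears import (CohortSpec, DFYConfig, HazardSpec, ModelConfig,
                     analytic_dfy, estimate_dfy, generate_cohort)

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
    truth = analytic_dfy(hz[e.category])
    print(f"{e.category:<10} DFY {e.years:6.2f} y (true {truth:5.2f})  "
          f"diff {e.diff_vs_reference:+.2f} "
          f"[{e.diff_ci_low:+.2f}, {e.diff_ci_high:+.2f}]  p={e.p_value:.3g}")
# The exposed category loses ~4.4 disease-free years relative to the
# reference; the 95% percentile interval excludes zero.
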