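"""Competing-risk sensitivity: cumulative incidence and composite endpoint.

With disease rate a = 0.02 and death rate m = 0.01 (competing exponentials),
the cumulative incidence of disease tends to a/(a+m) = 2/3, and years lived
free of disease AND death over [40, 75] are (1 - e^(-35*0.03))/0.03 = 21.67.
"""

import numpy as np

from dfyears import (CohortSpec, DFYConfig, HazardSpec, ModelConfig,
                     aalen_johansen, composite_dfy, estimate_dfy,
                     generate_cohort)

spec = CohortSpec(name="cr", n=30000, sex_split=1.0, entry_age_mean=45,
                  entry_age_sd=3, admin_followup=35,
                  category_prevalence={"only": 1.0},
                  disease_hazard={"only": HazardSpec("exponential", 0.02)},
                  death_hazard=HazardSpec("exponential", 0.01),
                  female_hazard_ratio=1.0)
data = generate_cohort(spec, seed=21)

cif = aalen_johansen(data, "only", "category")
print(f"CIF of disease at age 75: {cif.cif_at(75.0):.3f} "
      f"(death competing; would keep rising toward 2/3)")
resid = np.max(np.abs(1 - cif.cif_disease - cif.cif_death - cif.survival_allcause))
print(f"Aalen-Johansen identity residual: {resid:.2e}")

mc = ModelConfig(category_column="category", knot_candidates=(0,), selection="fixed")
_, main = estimate_dfy(data, mc, DFYConfig(n_boot=0), reference="only")
_, comp = composite_dfy(data, mc, DFYConfig(n_boot=0), reference="only")
print(f"\nDFY, death treated as censoring : {main[0].years:.2f} y")
print(f"DFY, disease-or-death composite : {comp[0].years:.2f} y (closed form 21.67)")
# The composite endpoint is necessarily shorter: adding death as an event
# can only reduce event-free time. The gap quantifies the survival-bias
# exposure of the censoring convention.
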