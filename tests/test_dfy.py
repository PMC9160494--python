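"""Disease-free years: quadrature, differences, exclusions and the bootstrap."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from dfyears import (CohortSpec, DFYConfig, HazardSpec, ModelConfig,
                     conditional_survival, dfy_difference, disease_free_years,
                     estimate_dfy, generate_cohort, run_exclusions)
from tests.test_model import manual_fit
from tests.conftest import two_rate_cohort


class TestConditionalSurvival:
    def test_identity_at_base_age(self):
        f = manual_fit([np.log(0.02), 1.0])
        assert conditional_survival(f, "c", [40.0])[0] == pytest.approx(1.0)

    def test_exponential_closed_form_at_75(self):
        # H = 0.02 t so H(75) - H(40) = 0.7
        f = manual_fit([np.log(0.02), 1.0])
        S = conditional_survival(f, "c", [75.0])
        assert S[0] == pytest.approx(np.exp(-0.7), abs=1e-12)

    def test_curve_non_increasing(self):
        f = manual_fit([np.log(0.02), 1.0])
        S = conditional_survival(f, "c", np.linspace(40, 75, 300))
        assert np.all(np.diff(S) <= 0)

    def test_ages_before_base_rejected(self):
        f = manual_fit([np.log(0.02), 1.0])
        with pytest.raises(ValueError):
            conditional_survival(f, "c", [39.0])


class TestDiseaseFreeYears:
    def test_zero_hazard_curve_reaches_maximum(self):
        f = manual_fit([-30.0, 1.0])
        assert disease_free_years(f, "c") == pytest.approx(35.0, abs=1e-3)

    def test_exponential_quadrature_matches_closed_form(self):
        f = manual_fit([np.log(0.02), 1.0])
        closed = (1 - np.exp(-0.7)) / 0.02
        assert disease_free_years(f, "c") == pytest.approx(closed, abs=1e-3)

    def test_quadrature_converged_at_default_step(self):
        # halving the grid step moves a curved (2-knot) integrand < 1e-3 y
        ks_gamma = [np.log(0.015), 1.0, 0.4]
        from dfyears import KnotSet
        from dfyears.model import CHModelFit
        f = CHModelFit(categories=("c",), knots={"c": KnotSet((np.log(35), np.log(78)), (np.log(55),))},
                       gamma={"c": np.array(ks_gamma)}, beta=np.array([]), covariate_names=(),
                       loglik=0.0, n_params=3, n_subjects=0, converged=True)
        coarse = disease_free_years(f, "c", DFYConfig(grid_step=0.05))
        fine = disease_free_years(f, "c", DFYConfig(grid_step=0.025))
        assert abs(coarse - fine) < 1e-3


class TestDifference:
    def test_same_category_is_zero(self):
        f = manual_fit([np.log(0.02), 1.0])
        assert dfy_difference(f, "c", "c") == 0.0

    def test_exponential_pair_closed_form(self):
        from dfyears import KnotSet
        from dfyears.model import CHModelFit
        ks = KnotSet((np.log(30), np.log(80)))
        f = CHModelFit(
            categories=("A", "B"), knots={"A": ks, "B": ks},
            gamma={"A": np.array([np.log(0.02), 1.0]), "B": np.array([np.log(0.01), 1.0])},
            beta=np.array([]), covariate_names=(), loglik=0.0, n_params=4,
            n_subjects=0, converged=True)
        expected = (1 - np.exp(-0.7)) / 0.02 - (1 - np.exp(-0.35)) / 0.01
        assert dfy_difference(f, "A", "B") == pytest.approx(expected, abs=2e-3)
        assert dfy_difference(f, "B", "A") == pytest.approx(-expected, abs=2e-3)
        with pytest.raises(ValueError):
            dfy_difference(f, "A", "zzz")


class TestExclusions:
    @staticmethod
    def _frame(n, n_missing, n_prevalent_among_rest):
        missing = np.zeros(n, dtype=int)
        missing[:n_missing] = 1
        prevalent = np.zeros(n, dtype=int)
        prevalent[n_missing:n_missing + n_prevalent_among_rest] = 1
        return pd.DataFrame({"missing_flag": missing, "prevalent_flag": prevalent})

    def test_consortium_cascade_arithmetic(self):
        out, rep = run_exclusions(self._frame(148_299, 8_323, 10_034))
        assert rep["n_analytic"] == len(out) == 129_942

    def test_replication_cohort_cascade_arithmetic(self):
        out, rep = run_exclusions(self._frame(502_462, 3_549, 71_292))
        assert rep["n_analytic"] == len(out) == 427_621

    def test_no_flags_is_identity(self):
        df = pd.DataFrame({"missing_flag": [0, 0], "prevalent_flag": [0, 0]})
        out, rep = run_exclusions(df)
        assert len(out) == 2 and rep["n_missing"] == rep["n_prevalent"] == 0

    def test_missing_dropped_before_prevalent(self):
        # a subject flagged both ways counts as a missing-data exclusion
        df = pd.DataFrame({"missing_flag": [1], "prevalent_flag": [1]})
        _, rep = run_exclusions(df)
        assert rep["n_missing"] == 1 and rep["n_prevalent"] == 0


class TestBootstrap:
    MC = ModelConfig(category_column="category", knot_candidates=(0,), selection="fixed")

    def test_no_bootstrap_means_no_intervals(self):
        d = two_rate_cohort(4000, seed=21)
        _, ests = estimate_dfy(d, self.MC, DFYConfig(n_boot=0), reference="B")
        assert all(e.n_boot == 0 and np.isnan(e.ci_low) for e in ests)
        assert all(0 <= e.years <= 35 for e in ests)

    def test_identical_seeds_reproduce_intervals(self):
        d = two_rate_cohort(4000, seed=22)
        _, a = estimate_dfy(d, self.MC, DFYConfig(n_boot=40, seed=5), reference="B")
        _, b = estimate_dfy(d, self.MC, DFYConfig(n_boot=40, seed=5), reference="B")
        for x, y in zip(a, b):
            assert (x.ci_low, x.ci_high, x.p_value) == (y.ci_low, y.ci_high, y.p_value)

    def test_interval_covers_point_estimate(self):
        d = two_rate_cohort(4000, seed=23)
        _, ests = estimate_dfy(d, self.MC, DFYConfig(n_boot=60, seed=6), reference="B")
        for e in ests:
            assert e.ci_low <= e.years <= e.ci_high

    def test_ci_width_decreases_with_sample_size(self):
        widths = []
        for i, n in enumerate((2000, 8000, 32000)):
            d = two_rate_cohort(n, seed=30 + i)
            _, ests = estimate_dfy(d, self.MC, DFYConfig(n_boot=80, seed=7), reference="B")
            eA = next(e for e in ests if e.category == "A")
            widths.append(eA.diff_ci_high - eA.diff_ci_low)
        assert widths[0] > widths[1] > widths[2]


def test_model_dfy_agrees_with_kaplan_meier_auc():
    """Spline-model DFY vs a nonparametric KM-trapezoid oracle, 50k subjects."""
    hz = HazardSpec("gompertz", 0.011, 0.05)
    spec = CohortSpec(name="km", n=50000, sex_split=1.0, entry_age_mean=40.0,
                      entry_age_sd=1e-6, admin_followup=35.0,
                      category_prevalence={"only": 1.0}, disease_hazard={"only": hz},
                      death_hazard=HazardSpec("exponential", 1e-12),
                      female_hazard_ratio=1.0)
    d = generate_cohort(spec, 31)
    from dfyears import fit
    f = fit(d, ModelConfig(category_column="category", knot_candidates=(0, 1, 2)),
            compute_cov=False)
    model_dfy = disease_free_years(f, "only", DFYConfig(n_boot=0))
    km = KaplanMeierFitter().fit(d.exit_age, d.event)
    grid = np.linspace(40, 75, 701)
    S = np.asarray(km.survival_function_at_times(grid))
    km_auc = np.trapezoid(S, grid)
    assert abs(model_dfy - km_auc) < 0.3
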