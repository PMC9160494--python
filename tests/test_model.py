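"""Likelihood, fitting and prediction of the cumulative-hazard-scale model."""

import numpy as np
import pandas as pd
import pytest
from lifelines import WeibullFitter

from dfyears import CHModelFit, KnotSet, ModelConfig, fit, hazard_ratio, predict
from dfyears.model import CHLikelihood
from tests.conftest import weibull_data


def manual_fit(gamma, boundary=(np.log(30), np.log(80)), category="c") -> CHModelFit:
    ks = KnotSet(boundary)
    return CHModelFit(
        categories=(category,), knots={category: ks},
        gamma={category: np.asarray(gamma, float)}, beta=np.array([]),
        covariate_names=(), loglik=0.0, n_params=len(gamma), n_subjects=0,
        converged=True,
    )


def exponential_likelihood(entry, exit_, event):
    """0-knot likelihood on raw coordinates (identity transform)."""
    ks = {"c": KnotSet((np.log(30), np.log(80)))}
    return CHLikelihood(
        np.asarray(entry, float), np.asarray(exit_, float),
        np.asarray(event), np.zeros(len(event), dtype=int), ("c",), ks,
        transforms={"c": np.eye(2)},
    )


class TestLogLikelihood:
    def test_hand_computed_event_contribution(self):
        # H = 0.01 t (gamma = (ln 0.01, 1)); entry 40, exit 50, event:
        # ll = ln h(50) - [H(50) - H(40)] = ln 0.01 - 0.1
        lik = exponential_likelihood([40.0], [50.0], [1])
        ll, _ = lik.value_and_grad(np.array([np.log(0.01), 1.0]))
        assert ll == pytest.approx(np.log(0.01) - 0.1, abs=1e-10)

    def test_hand_computed_censored_contribution(self):
        lik = exponential_likelihood([40.0], [50.0], [0])
        ll, _ = lik.value_and_grad(np.array([np.log(0.01), 1.0]))
        assert ll == pytest.approx(-0.1, abs=1e-10)

    def test_risk_time_vanishes_as_entry_approaches_exit(self):
        lik = exponential_likelihood([50.0 - 1e-9], [50.0], [0])
        ll, _ = lik.value_and_grad(np.array([np.log(0.01), 1.0]))
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_gradient_matches_finite_differences(self):
        d = weibull_data(300, seed=5)
        mc = ModelConfig(category_column="cat", knot_candidates=(2,), selection="fixed")
        f = fit(d, mc, compute_cov=False)
        lik = CHLikelihood(
            d.entry_age.to_numpy(), d.exit_age.to_numpy(), d.event.to_numpy(),
            np.zeros(len(d), int), ("all",), f.knots, transforms=f.basis_transform,
        )
        rng = np.random.default_rng(6)
        theta = f.gamma["all"] + 0.05 * rng.normal(size=f.gamma["all"].shape)
        _, grad = lik.value_and_grad(theta)
        h = 1e-6
        for j in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (lik.value_and_grad(tp)[0] - lik.value_and_grad(tm)[0]) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestFit:
    def test_weibull_parameters_recovered_and_match_mle_oracle(self, weibull5000):
        mc = ModelConfig(category_column="cat", knot_candidates=(0,), selection="fixed")
        f = fit(weibull5000, mc)
        g = f.raw_gamma("all")
        T = f._transform("all")
        cov_raw = T @ f.cov[:2, :2] @ T.T  # delta method back to the raw basis
        se = np.sqrt(np.diag(cov_raw))
        # truth (-9, 2) within 3 SE; exact agreement with lifelines' Weibull MLE
        assert abs(g[0] - (-9.0)) < 3 * se[0]
        assert abs(g[1] - 2.0) < 3 * se[1]
        wf = WeibullFitter().fit(weibull5000.exit_age, weibull5000.event,
                                 entry=weibull5000.entry_age)
        oracle = np.array([-wf.rho_ * np.log(wf.lambda_), wf.rho_])
        np.testing.assert_allclose(g, oracle, atol=1e-4)

    def test_proportional_covariate_effect_recovered(self):
        rng = np.random.default_rng(7)
        n = 10000
        z = (rng.random(n) < 0.5).astype(float)
        a = 0.01 * np.exp(np.log(2) * z)  # H multiplied by 2 when z = 1
        entry = rng.uniform(40, 50, n)
        e = rng.exponential(size=n)
        t_ev = entry + e / a
        exit_ = np.minimum(t_ev, entry + 15)
        d = pd.DataFrame({"entry_age": entry, "exit_age": exit_,
                          "event": (t_ev <= exit_).astype(int), "cat": "all", "z": z})
        mc = ModelConfig(category_column="cat", knot_candidates=(0,),
                         selection="fixed", covariate_columns=("z",))
        f = fit(d, mc)
        idx = len(f.param_names) - 1
        se = np.sqrt(f.cov[idx, idx])
        assert abs(f.beta[0] - np.log(2)) < 3 * se

    def test_all_censored_category_is_an_error(self):
        d = pd.DataFrame({"entry_age": [40.0] * 10, "exit_age": [50.0] * 10,
                          "event": [0] * 10, "cat": "dead_quiet"})
        with pytest.raises(ValueError, match="no events"):
            fit(d, ModelConfig(category_column="cat", knot_candidates=(0,),
                               selection="fixed"))

    def test_loglik_nondecreasing_in_knot_count(self, gompertz_cohort):
        d, _ = gompertz_cohort
        lls = []
        for k in (0, 1, 2):
            f = fit(d, ModelConfig(category_column="category", knot_candidates=(k,),
                                   selection="fixed"), compute_cov=False)
            lls.append(f.loglik)
        for a, b in zip(lls, lls[1:]):
            assert b >= a - 1e-6 * abs(a)

    def test_zero_risk_time_rows_leave_fit_unchanged(self, weibull5000):
        mc = ModelConfig(category_column="cat", knot_candidates=(1,), selection="fixed")
        f1 = fit(weibull5000, mc, compute_cov=False)
        extra = pd.DataFrame({"entry_age": [55.0] * 20, "exit_age": [55.0] * 20,
                              "event": [0] * 20, "cat": "all"})
        f2 = fit(pd.concat([weibull5000, extra], ignore_index=True), mc,
                 knots_override=f1.knots, compute_cov=False)
        np.testing.assert_allclose(f2.raw_gamma("all"), f1.raw_gamma("all"), atol=1e-5)

    def test_accepted_fit_has_nondecreasing_cumulative_hazard(self, gompertz_cohort):
        d, _ = gompertz_cohort
        f = fit(d, ModelConfig(category_column="category"), compute_cov=False)
        ages = np.arange(float(d.entry_age.min()), float(d.exit_age.max()), 0.1)
        H = np.exp(f.spline_eta("only", ages))
        assert np.all(np.diff(H) >= -1e-9)


class TestPredict:
    def test_closed_form_exponential_prediction(self):
        f = manual_fit([np.log(0.01), 1.0])
        H, h, S = predict(f, "c", [50.0])
        assert H[0] == pytest.approx(0.5)
        assert S[0] == pytest.approx(np.exp(-0.5))
        assert h[0] == pytest.approx(0.01)

    def test_survival_near_one_at_young_age(self):
        f = manual_fit([-20.0, 1.0])
        _, _, S = predict(f, "c", [35.0])
        assert S[0] == pytest.approx(1.0, abs=1e-6)

    def test_survival_non_increasing_over_grid(self, weibull5000):
        f = fit(weibull5000, ModelConfig(category_column="cat", knot_candidates=(0, 1, 2)),
                compute_cov=False)
        _, _, S = predict(f, "all", np.linspace(40, 75, 200))
        assert np.all(np.diff(S) <= 1e-12)

    def test_nonpositive_ages_rejected(self):
        f = manual_fit([np.log(0.01), 1.0])
        with pytest.raises(ValueError):
            predict(f, "c", [0.0])


class TestHazardRatio:
    @staticmethod
    def _two_arm(n_per_arm, seed, a_ratio=2.0):
        rng = np.random.default_rng(seed)
        rows = []
        for cat, a in (("exposed", 0.02), ("reference", 0.02 / a_ratio)):
            entry = rng.uniform(40, 50, n_per_arm)
            t_ev = entry + rng.exponential(size=n_per_arm) / a
            exit_ = np.minimum(t_ev, entry + 15)
            rows.append(pd.DataFrame({
                "entry_age": entry, "exit_age": exit_,
                "event": (t_ev <= exit_).astype(int), "cat": cat}))
        return pd.concat(rows, ignore_index=True)

    def test_reference_versus_itself_is_unity(self):
        d = self._two_arm(2000, 8)
        f = fit(d, ModelConfig(category_column="cat", baseline="proportional",
                               knot_candidates=(0,), selection="fixed"))
        hr, _ = hazard_ratio(f, "exposed", "exposed")
        assert hr == 1.0

    def test_simulated_rate_ratio_recovered(self):
        d = self._two_arm(10000, 9)
        f = fit(d, ModelConfig(category_column="cat", baseline="proportional",
                               knot_candidates=(0,), selection="fixed"))
        hr, (lo, hi) = hazard_ratio(f, "reference", "exposed")
        # exposed has rate 0.02, reference 0.01: HR(reference vs exposed) = 0.5
        log_se = (np.log(hi) - np.log(lo)) / (2 * 1.959964)
        assert abs(np.log(hr) - np.log(0.5)) < 3 * log_se

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n in (1000, 4000, 16000):
            d = self._two_arm(n, 10)
            f = fit(d, ModelConfig(category_column="cat", baseline="proportional",
                                   knot_candidates=(0,), selection="fixed"))
            _, (lo, hi) = hazard_ratio(f, "exposed", "reference")
            widths.append(np.log(hi) - np.log(lo))
        assert widths[0] > widths[1] > widths[2]
        # Wald theory: width ~ 1/sqrt(n); quadrupling n should halve it, roughly
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)

    def test_per_category_fit_refuses_hazard_ratios(self, weibull5000):
        f = fit(weibull5000, ModelConfig(category_column="cat", knot_candidates=(0,),
                                         selection="fixed"), compute_cov=False)
        with pytest.raises(ValueError, match="proportional"):
            hazard_ratio(f, "all", "all2")
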