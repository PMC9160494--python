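"""DerSimonian-Laird pooling, I-squared, and the one-stage/two-stage machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from statsmodels.stats import meta_analysis as sm_meta

from dfyears import (DFYConfig, HazardSpec, ModelConfig, StudyEstimate,
                     analytic_dfy, compare_stages, dersimonian_laird,
                     first_stage, i_squared)
from dfyears.dfy import DFYEstimate
from tests.conftest import two_rate_cohort


class TestISquared:
    @pytest.mark.parametrize("Q,df,expected", [
        (0.0, 2, 0.0),
        (4.0, 2, 50.0),
        (1.0, 2, 0.0),  # truncated at zero
    ])
    def test_examples(self, Q, df, expected):
        assert i_squared(Q, df) == pytest.approx(expected)

    def test_df_zero_rejected(self):
        with pytest.raises(ValueError):
            i_squared(1.0, 0)


class TestDerSimonianLaird:
    def test_homogeneous_toy(self):
        ests = [StudyEstimate("s%d" % i, 1.0, 0.2) for i in range(3)]
        m = dersimonian_laird(ests)
        assert m.pooled == pytest.approx(1.0)
        assert m.Q == pytest.approx(0.0)
        assert m.tau2 == 0.0 and m.i2 == 0.0
        assert m.df == 2 and m.k == 3

    def test_three_study_hand_oracle(self):
        """Frozen values computed independently from the moment-estimator formulas."""
        ests = [StudyEstimate("a", 1.0, 0.2), StudyEstimate("b", 2.0, 0.3),
                StudyEstimate("c", 1.5, 0.25)]
        m = dersimonian_laird(ests)
        assert m.Q == pytest.approx(8.102345415778, abs=1e-10)
        assert m.tau2 == pytest.approx(0.185844155844, abs=1e-10)
        assert m.pooled == pytest.approx(1.466779217145, abs=1e-10)
        assert m.se_pooled == pytest.approx(0.287720793217, abs=1e-10)
        assert m.i2 == pytest.approx(75.315789473684, abs=1e-9)

    def test_matches_statsmodels_on_random_inputs(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 8)
        se = rng.uniform(0.1, 0.5, 8)
        mine = dersimonian_laird([StudyEstimate(str(i), yi, si)
                                  for i, (yi, si) in enumerate(zip(y, se))])
        ref = sm_meta.combine_effects(y, se**2, method_re="dl")
        frame = ref.summary_frame()
        assert mine.tau2 == pytest.approx(ref.tau2, abs=1e-12)
        assert mine.pooled == pytest.approx(frame.loc["random effect", "eff"], abs=1e-12)
        assert mine.se_pooled == pytest.approx(frame.loc["random effect", "sd_eff"], abs=1e-12)

    def test_duplicating_identical_studies_halves_fixed_effect_variance(self):
        ests = [StudyEstimate("a", 1.3, 0.2), StudyEstimate("b", 1.3, 0.4)]
        single = dersimonian_laird(ests)
        double = dersimonian_laird(ests + [StudyEstimate(e.study + "x", e.estimate, e.se)
                                           for e in ests])
        # identical estimates: Q = tau2 = 0 so pooled SE is the fixed-effect one
        assert double.se_pooled**2 == pytest.approx(single.se_pooled**2 / 2)

    def test_pooled_within_study_range(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            y = rng.normal(0, 2, 5)
            se = rng.uniform(0.05, 1.0, 5)
            m = dersimonian_laird([StudyEstimate(str(i), yi, si)
                                   for i, (yi, si) in enumerate(zip(y, se))])
            assert y.min() - 1e-12 <= m.pooled <= y.max() + 1e-12

    def test_i2_invariant_to_common_rescaling(self):
        ests = [StudyEstimate("a", 1.0, 0.2), StudyEstimate("b", 2.0, 0.3),
                StudyEstimate("c", 1.5, 0.25)]
        scaled = [StudyEstimate(e.study, 10 * e.estimate, 10 * e.se) for e in ests]
        assert dersimonian_laird(ests).i2 == pytest.approx(
            dersimonian_laird(scaled).i2, abs=1e-9)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError, match="2 studies"):
            dersimonian_laird([StudyEstimate("only", 1.0, 0.1)])

    def test_q_mean_near_df_under_homogeneity(self):
        rng = np.random.default_rng(14)
        k, reps = 6, 2000
        se = rng.uniform(0.1, 0.4, k)
        qs = []
        for _ in range(reps):
            y = rng.normal(0.0, se)
            qs.append(dersimonian_laird(
                [StudyEstimate(str(i), yi, si) for i, (yi, si) in enumerate(zip(y, se))]
            ).Q)
        # Q ~ chi-square(k-1) under the null: mean df, MC error ~ sqrt(2 df / reps)
        assert np.mean(qs) == pytest.approx(k - 1, abs=4 * np.sqrt(2 * (k - 1) / reps))


class TestFirstStage:
    MC = ModelConfig(category_column="category", knot_candidates=(0,), selection="fixed")

    def test_single_cohort_yields_one_estimate_per_category(self):
        d = two_rate_cohort(4000, seed=41)
        out = first_stage(d, self.MC, DFYConfig(n_boot=0, seed=1), "B", n_boot=30)
        assert set(out) == {"A"} and len(out["A"]) == 1

    def test_identical_cohorts_give_identical_estimates(self):
        d = two_rate_cohort(4000, seed=42)
        d2 = pd.concat([d, d.assign(cohort="two_b")], ignore_index=True)
        out = first_stage(d2, self.MC, DFYConfig(n_boot=0, seed=1), "B", n_boot=30)
        a, b = out["A"]
        assert a.estimate == pytest.approx(b.estimate, abs=1e-9)

    def test_common_truth_recovered_without_bias(self):
        """12 cohorts sharing a true difference of -2.0 disease-free years."""
        ref_rate = 0.01
        target = analytic_dfy(HazardSpec("exponential", ref_rate)) - 2.0
        a_exposed = optimize.brentq(
            lambda a: analytic_dfy(HazardSpec("exponential", a)) - target, 0.011, 0.05)
        frames = []
        for i in range(12):
            d = two_rate_cohort(3000, seed=500 + i, a1=a_exposed, a2=ref_rate)
            frames.append(d.assign(cohort=f"c{i:02d}"))
        data = pd.concat(frames, ignore_index=True)
        out = first_stage(data, self.MC, DFYConfig(n_boot=0, seed=2), "B", n_boot=30)
        ests = np.array([e.estimate for e in out["A"]])
        # a cohort whose bootstrap exceeds the failure budget is excluded with
        # a warning; at 3000 subjects/cohort that can happen occasionally
        assert len(ests) >= 10
        assert abs(ests.mean() - (-2.0)) < 0.2


class TestCompareStages:
    def test_identical_inputs_give_zero_differences(self):
        m = dersimonian_laird([StudyEstimate("a", -1.0, 0.2),
                               StudyEstimate("b", -1.0, 0.2)])
        one = [DFYEstimate(category="heavy", years=27.0, diff_vs_reference=m.pooled,
                           diff_ci_low=m.ci_low, diff_ci_high=m.ci_high, n_boot=10)]
        table = compare_stages({"heavy": m}, one)
        assert table.abs_difference.iloc[0] == pytest.approx(0.0)
        assert bool(table.ci_overlap.iloc[0])

    def test_disjoint_categories_rejected(self):
        m = dersimonian_laird([StudyEstimate("a", -1.0, 0.2),
                               StudyEstimate("b", -1.0, 0.2)])
        with pytest.raises(ValueError, match="shared"):
            compare_stages({"heavy": m},
                           [DFYEstimate(category="other", years=1.0)])
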