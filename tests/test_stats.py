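"""Cohort statistics: filters, ANOVA/chi-square, adjusted models, ROC,
DeLong comparison and the post hoc power formula."""

import numpy as np
import pandas as pd
import pytest

from octaquant import stats, synthetic
from octaquant.stats import PowerInputs


class TestEligibility:
    def test_enrollment_165_to_90(self):
        enrolled = synthetic.generate_enrollment(seed=0)
        included, tally = stats.apply_eligibility_filters(enrolled)
        assert len(included) == 90
        assert tally == {"fatigue": 15, "quality": 53, "eye_disease": 7}

    def test_tally_sums_to_excluded(self):
        enrolled = synthetic.generate_enrollment(
            n_fatigue=4, n_poor_quality=9, n_eye_disease=2, n_clean=30, seed=5
        )
        included, tally = stats.apply_eligibility_filters(enrolled)
        assert sum(tally.values()) == len(enrolled) - len(included)

    def test_no_flags_all_included(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "fatigue": [False, False],
                "eye_disease": [False, False],
                "signal_strength_od": [9.0, 8.0],
                "signal_strength_os": [7.5, 10.0],
            }
        )
        included, tally = stats.apply_eligibility_filters(df)
        assert len(included) == 2 and sum(tally.values()) == 0

    def test_both_eyes_below_threshold_excluded_as_quality(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a"],
                "fatigue": [False],
                "eye_disease": [False],
                "signal_strength_od": [6.0],
                "signal_strength_os": [6.0],
            }
        )
        included, tally = stats.apply_eligibility_filters(df)
        assert len(included) == 0 and tally["quality"] == 1

    def test_missing_flag_column_rejected(self):
        with pytest.raises(ValueError, match="fatigue"):
            stats.apply_eligibility_filters(pd.DataFrame({"participant_id": ["a"]}))


class TestSelectAnalysisEye:
    def test_single_eligible_eye_returned(self):
        assert stats.select_analysis_eye("p1", ["OS"], seed=0) == "OS"

    def test_deterministic_per_seed(self):
        picks = {stats.select_analysis_eye("p1", ["OD", "OS"], seed=3) for _ in range(10)}
        assert len(picks) == 1

    def test_uniform_over_participants(self):
        left = sum(
            stats.select_analysis_eye(f"p{i}", ["OD", "OS"], seed=1) == "OS"
            for i in range(10_000)
        )
        assert abs(left / 10_000 - 0.5) < 0.02

    def test_no_eligible_eye_rejected(self):
        with pytest.raises(ValueError):
            stats.select_analysis_eye("p1", [], seed=0)


class TestBaselineComparison:
    def test_identical_groups_near_null(self, rng):
        x = rng.normal(size=60)
        df = pd.DataFrame({"group": np.repeat(["AD", "MCI", "control"], 20), "v": np.tile(x[:20], 3)})
        f, p = stats.baseline_comparison(df, "v", kind="continuous")
        assert f == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_anova(self):
        # groups (1,2,3),(2,3,4),(6,7,8): SSB=42/df2, SSW=6/df6 -> F=21,
        # p = 0.001953125 by the F(2,6) survival function
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], 3),
                "v": [1, 2, 3, 2, 3, 4, 6, 7, 8],
            }
        )
        f, p = stats.baseline_comparison(df, "v", kind="continuous")
        assert f == pytest.approx(21.0)
        assert p == pytest.approx(0.001953125)

    def test_balanced_table_chi_square_zero(self):
        df = pd.DataFrame(
            {"group": np.repeat(["a", "b", "c"], 20), "v": np.tile([0, 1], 30)}
        )
        chi2, p = stats.baseline_comparison(df, "v", kind="categorical")
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_variable_defined_result(self):
        df = pd.DataFrame({"group": np.repeat(["a", "b"], 5), "v": np.ones(10)})
        f, p = stats.baseline_comparison(df, "v", kind="continuous")
        assert (f, p) == (0.0, 1.0)


class TestAdjustedModel:
    def _noise_free_cohort(self):
        rng = np.random.default_rng(0)
        n = 40
        rows = []
        for g, off in (("control", 0.0), ("MCI", -0.5), ("AD", -1.0)):
            for i in range(n):
                age = rng.normal(76, 6)
                rows.append({"group": g, "age": age, "y": 10.0 + off + 0.1 * age})
        return pd.DataFrame(rows)

    def test_exact_offsets_recovered(self):
        df = self._noise_free_cohort()
        fit = stats.fit_adjusted_model(df, "y", covariates=["age"])
        assert fit.beta["MCI"] == pytest.approx(-0.5, abs=1e-9)
        assert fit.beta["AD"] == pytest.approx(-1.0, abs=1e-9)
        assert fit.covariate_coefs["age"] == pytest.approx(0.1, abs=1e-9)

    def test_beta_equals_adjusted_mean_difference(self, small_cohort):
        tab, _ = small_cohort
        fit = stats.fit_adjusted_model(tab, "vd_scp")
        for g in ("AD", "MCI"):
            assert fit.beta[g] == pytest.approx(
                fit.adjusted_mean[g] - fit.adjusted_mean["control"], abs=1e-9
            )

    def test_ci_brackets_beta(self, small_cohort):
        tab, _ = small_cohort
        fit = stats.fit_adjusted_model(tab, "fd_scp")
        for g in ("AD", "MCI"):
            lo, hi = fit.ci[g]
            assert lo <= fit.beta[g] <= hi

    def test_collinear_columns_named(self, small_cohort):
        tab, _ = small_cohort
        tab = tab.copy()
        tab["age_twice"] = 2 * tab["age"]
        with pytest.raises(ValueError, match="age_twice"):
            stats.fit_adjusted_model(tab, "vd_scp", covariates=["age", "age_twice"])

    def test_missing_column_rejected(self, small_cohort):
        tab, _ = small_cohort
        with pytest.raises(ValueError, match="nope"):
            stats.fit_adjusted_model(tab, "vd_scp", covariates=["nope"])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,k,expect", [(0.05, 2, 0.025), (0.05, 1, 0.05), (0.06, 3, 0.02)]
    )
    def test_threshold(self, alpha, k, expect):
        assert stats.bonferroni_threshold(alpha, k) == pytest.approx(expect)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.bonferroni_threshold(0.0, 2)
        with pytest.raises(ValueError):
            stats.bonferroni_threshold(0.05, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert stats.roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_all_ties_chance(self):
        r = stats.roc_auc([5, 5, 5, 5], [0, 0, 1, 1])
        assert r.auc == 0.5

    def test_tie_example(self):
        # pairs: (2>1)+(2>1)+(3>1)+(3>2) = 4 wins, (2,2) tie = 1/2 -> 3.5/4
        assert stats.roc_auc([1, 2, 2, 3], [0, 0, 1, 1]).auc == pytest.approx(0.875)

    def test_below_chance_flagged_not_flipped(self):
        r = stats.roc_auc([4, 3, 2, 1], [0, 0, 1, 1])
        assert r.auc == 0.0 and r.below_chance

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.4).astype(int)
        a = stats.roc_auc(scores, labels).auc
        b = stats.roc_auc(np.exp(2 * scores) + 5, labels).auc
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.roc_auc([1, 2, 3], [1, 1, 1])

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.5).astype(int)
        scores[labels == 1] += 0.7
        assert stats.roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores)
        )


class TestSensitivityAtSpecificity:
    def test_perfect_classifier(self):
        assert stats.sensitivity_at_specificity([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_diagonal(self):
        got = stats.sensitivity_at_specificity([1, 1, 1, 1], [0, 0, 1, 1], 0.415)
        assert got == pytest.approx(1 - 0.415)

    def test_hand_walked_roc(self):
        # vertices (FPR,TPR): (0,0) -> (0,.5) -> (.5,1) -> (1,1); at
        # specificity .415 (FPR .585) the curve is on the flat top segment
        got = stats.sensitivity_at_specificity([1, 2, 2, 3], [0, 0, 1, 1], 0.415)
        assert got == pytest.approx(1.0)


class TestDelongPaired:
    def test_self_comparison_p_one(self):
        delta, p = stats.compare_auc_paired([1, 2, 3, 4], [1, 2, 3, 4], [0, 0, 1, 1])
        assert delta == 0.0 and p == 1.0

    def test_type_one_error_near_nominal(self, rng):
        # two equal-AUC markers on the same 200 subjects
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            labels = np.r_[np.zeros(100, int), np.ones(100, int)]
            a = rng.normal(size=200) + 0.5 * labels
            b = rng.normal(size=200) + 0.5 * labels
            _, p = stats.compare_auc_paired(a, b, labels)
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.03

    def test_informative_vs_noise_detected(self, rng):
        labels = np.r_[np.zeros(250, int), np.ones(250, int)]
        informative = rng.normal(size=500) + 1.0 * labels
        noise = rng.normal(size=500)
        _, p = stats.compare_auc_paired(informative, noise, labels)
        assert p < 0.01


class TestPosthocPower:
    def test_reported_superficial_power(self):
        # 30.54 +/- 2.86 (n=24) vs 32.60 +/- 2.36 (n=29) at alpha 5%
        got = stats.posthoc_power(PowerInputs(30.54, 2.86, 24, 32.60, 2.36, 29, 0.05))
        assert got == pytest.approx(0.805, abs=0.005)

    def test_reported_deep_power_saturates(self):
        got = stats.posthoc_power(PowerInputs(43.5, 4.0, 24, 50.9, 3.6, 29, 0.05))
        assert got >= 0.999

    def test_null_delta_equals_half_alpha(self):
        got = stats.posthoc_power(PowerInputs(10, 2, 30, 10, 2, 30, 0.05))
        assert got == pytest.approx(0.025, abs=1e-12)

    def test_monotone_in_effect_and_n(self):
        base = stats.posthoc_power(PowerInputs(10, 2, 30, 11, 2, 30))
        bigger = stats.posthoc_power(PowerInputs(10, 2, 30, 12, 2, 30))
        more_n = stats.posthoc_power(PowerInputs(10, 2, 60, 11, 2, 60))
        assert bigger > base and more_n > base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            PowerInputs(1, 0, 10, 2, 1, 10)
        with pytest.raises(ValueError):
            PowerInputs(1, 1, 1, 2, 1, 10)
        with pytest.raises(ValueError):
            PowerInputs(1, 1, 10, 2, 1, 10, alpha=1.5)
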