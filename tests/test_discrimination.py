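"""Case/noncase splitting, CRPs, AUC/ROC, and Wilcoxon comparison."""

import numpy as np
import pytest

from riskvalid import (
    CensoringSpec,
    ModelSpec,
    SimulationConfig,
    auc,
    case_risk_percentiles,
    compare_models,
    roc_and_sensitivity,
    simulate_cohort,
    split_cases,
)

from conftest import (
    make_cohort,
    pairwise_auc_oracle,
    signed_rank_enumeration_oracle,
)


def _split_from_risks(case_risks, noncase_risks):
    rows = [(2.0, "BC", float(r)) for r in case_risks]
    rows += [(11.0, "CENSORED", float(r)) for r in noncase_risks]
    return split_cases(make_cohort(rows), 10.0)


class TestSplitCases:
    def test_partition_rules(self):
        cohort = make_cohort(
            [
                (2.0, "BC", 0.1),       # case
                (12.0, "BC", 0.1),      # event after horizon -> noncase
                (9.9, "CENSORED", 0.1), # censored before horizon -> excluded
                (10.0, "CENSORED", 0.1),# observed through horizon -> noncase
                (4.0, "DEATH", 0.1),    # early death -> config-dependent
                (11.0, "DEATH", 0.1),   # survived past horizon -> noncase
            ]
        )
        s = split_cases(cohort, 10.0, death_as_noncase=True)
        assert list(s.cases) == [0]
        assert list(s.noncases) == [1, 3, 4, 5]
        assert list(s.excluded) == [2]
        s2 = split_cases(cohort, 10.0, death_as_noncase=False)
        assert list(s2.noncases) == [1, 3, 5]
        assert list(s2.excluded) == [2, 4]
        # the three sets always partition the cohort
        for sp in (s, s2):
            joined = np.concatenate([sp.cases, sp.noncases, sp.excluded])
            assert sorted(joined) == list(range(cohort.n))

    def test_degenerate_split_raises_downstream(self):
        s = _split_from_risks([], [0.1, 0.2])
        with pytest.raises(ValueError, match="degenerate"):
            case_risk_percentiles(s, "m")


class TestCaseRiskPercentiles:
    def test_case_above_all_noncases(self):
        s = _split_from_risks([0.9], [0.1, 0.2, 0.3])
        assert case_risk_percentiles(s, "m")[0] == 1.0

    def test_all_identical_risks_force_half(self):
        s = _split_from_risks([0.5, 0.5], [0.5, 0.5, 0.5])
        assert np.all(case_risk_percentiles(s, "m") == 0.5)

    def test_midrank_brute_force_example(self):
        s = _split_from_risks([0.05], [0.01, 0.05, 0.09, 0.12])
        assert case_risk_percentiles(s, "m")[0] == pytest.approx((1 + 0.5) / 4)


class TestAUC:
    def test_constant_model_gives_exactly_half(self):
        s = _split_from_risks([0.3] * 5, [0.3] * 9)
        res = auc(s, "m", n_bootstrap=50, seed=0)
        assert res.auc == 0.5

    def test_perfect_separation_gives_one(self):
        s = _split_from_risks([0.8, 0.9], [0.1, 0.2, 0.3])
        assert auc(s, "m", n_bootstrap=50, seed=0).auc == 1.0

    def test_toy_set_matches_exhaustive_pairwise_count(self):
        case_r = [0.3, 0.5, 0.1]
        noncase_r = [0.1, 0.2, 0.5, 0.4]
        s = _split_from_risks(case_r, noncase_r)
        res = auc(s, "m", n_bootstrap=50, seed=0)
        assert res.auc == pytest.approx(pairwise_auc_oracle(case_r, noncase_r))

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_mean_crp_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        case_r = rng.choice(np.linspace(0, 1, 17), rng.integers(2, 30))
        noncase_r = rng.choice(np.linspace(0, 1, 17), rng.integers(2, 60))
        s = _split_from_risks(case_r, noncase_r)
        res = auc(s, "m", n_bootstrap=20, seed=0)
        assert res.auc == np.mean(res.crps)
        from sklearn.metrics import roc_auc_score

        labels = [1] * len(case_r) + [0] * len(noncase_r)
        expected = roc_auc_score(labels, np.concatenate([case_r, noncase_r]))
        assert res.auc == pytest.approx(expected, abs=1e-12)

    def test_label_swap_maps_auc_to_complement(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(8), rng.random(13)
        auc_ab = auc(_split_from_risks(a, b), "m", n_bootstrap=10, seed=0).auc
        auc_ba = auc(_split_from_risks(b, a), "m", n_bootstrap=10, seed=0).auc
        assert auc_ab == pytest.approx(1.0 - auc_ba, abs=1e-12)

    def test_invariance_under_increasing_transform(self):
        rng = np.random.default_rng(4)
        case_r, noncase_r = rng.random(9), rng.random(21)
        before = auc(_split_from_risks(case_r, noncase_r), "m", 10, 0).auc
        after = auc(
            _split_from_risks(case_r**3 / 2, noncase_r**3 / 2), "m", 10, 0
        ).auc
        assert before == pytest.approx(after, abs=1e-12)

    def test_ci_is_seeded_and_contains_point(self):
        rng = np.random.default_rng(5)
        s = _split_from_risks(rng.random(12), rng.random(30))
        r1 = auc(s, "m", n_bootstrap=300, seed=7)
        r2 = auc(s, "m", n_bootstrap=300, seed=7)
        assert r1.auc_ci == r2.auc_ci
        assert r1.auc_ci[0] <= r1.auc <= r1.auc_ci[1]


class TestROC:
    @pytest.mark.parametrize("seed", range(4))
    def test_trapezoidal_area_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        case_r = rng.choice(np.linspace(0, 1, 11), 14)  # ties likely
        noncase_r = rng.choice(np.linspace(0, 1, 11), 25)
        s = _split_from_risks(case_r, noncase_r)
        pts, _ = roc_and_sensitivity(s, "m")
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(pairwise_auc_oracle(case_r, noncase_r), abs=1e-12)

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(11)
        s = _split_from_risks(rng.random(6), rng.random(9))
        pts, _ = roc_and_sensitivity(s, "m")
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_perfect_model_full_sensitivity_at_any_specificity(self):
        s = _split_from_risks([0.9, 0.95], [0.1, 0.2, 0.3])
        for target in (0.5, 0.8, 0.99):
            _, sens = roc_and_sensitivity(s, "m", target)
            assert sens == 1.0

    def test_constant_model_zero_sensitivity_at_80(self):
        s = _split_from_risks([0.3] * 4, [0.3] * 11)
        _, sens = roc_and_sensitivity(s, "m", 0.80)
        assert sens == 0.0

    def test_sensitivity_matches_threshold_sweep(self):
        """On tie-free risks, the reported sensitivity equals the fraction
        of cases strictly above the noncase quantile found by sweeping all
        thresholds for the smallest one achieving the target specificity."""
        rng = np.random.default_rng(12)
        case_r, noncase_r = rng.random(13), rng.random(37)
        target = 0.80
        s = _split_from_risks(case_r, noncase_r)
        _, sens = roc_and_sensitivity(s, "m", target)
        candidates = np.sort(np.concatenate([case_r, noncase_r]))
        for c in candidates:
            if np.mean(noncase_r <= c) >= target:
                break
        assert sens == pytest.approx(np.mean(case_r > c))


class TestCompareModels:
    def test_identical_crps_degenerate(self):
        r = np.array([0.2, 0.4, 0.6])
        res = compare_models(r, r)
        assert res.p_value == 1.0
        assert res.method == "degenerate"
        assert res.n_b_greater == res.n_a_greater == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        a = rng.choice(np.linspace(0, 1, 9), n)
        b = rng.choice(np.linspace(0, 1, 9), n)
        res = compare_models(a, b)
        assert res.p_value == pytest.approx(
            signed_rank_enumeration_oracle(b - a), abs=1e-12
        )

    def test_exact_agrees_with_scipy_on_tie_free_pairs(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        a = rng.random(15)
        b = rng.random(15)
        res = compare_models(a, b)
        expected = stats.wilcoxon(b - a, method="exact").pvalue
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(9)
        a = rng.random(60)
        b = a + rng.normal(0.05, 0.1, 60)
        res = compare_models(a, b)
        assert res.method == "normal-approx"
        from scipy import stats

        expected = stats.wilcoxon(
            (b - a)[b != a], correction=True, method="approx"
        ).pvalue
        assert res.p_value == pytest.approx(expected, rel=1e-6)

    def test_diagonal_counts(self):
        a = np.array([0.1, 0.5, 0.3, 0.2])
        b = np.array([0.2, 0.4, 0.3, 0.5])
        res = compare_models(a, b)
        assert res.n_b_greater == 2 and res.n_a_greater == 1

    def test_power_exceeds_size_when_one_model_discriminates_better(self):
        """Model B assigns the true risk, model A a noise-degraded copy;
        the paired Wilcoxon should reject far more often than alpha."""
        rejections = 0
        n_reps = 60
        for seed in range(n_reps):
            cfg = SimulationConfig(
                n_subjects=1200,
                model_specs={
                    "noisy": ModelSpec(noise_sd=1.2),
                    "sharp": ModelSpec(noise_sd=0.0),
                },
                censoring=CensoringSpec(admin_time=11.0, dropout_rate=0.02),
                seed=seed,
            )
            cohort = simulate_cohort(cfg).cohort
            s = split_cases(cohort, 10.0)
            crps_a = case_risk_percentiles(s, "noisy")
            crps_b = case_risk_percentiles(s, "sharp")
            if compare_models(crps_a, crps_b).p_value < 0.05:
                rejections += 1
        assert rejections / n_reps > 0.3  # well above the 5% size
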