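"""Quantile grouping, Hosmer-Lemeshow statistic, subgroup tables."""

import numpy as np
import pytest

from riskvalid import (
    AnalysisConfig,
    CalibrationGroup,
    CensoringSpec,
    ModelSpec,
    RiskDistribution,
    SimulationConfig,
    calibrate_by_quantiles,
    calibration_table,
    hosmer_lemeshow,
    quantile_groups,
    simulate_cohort,
)
from riskvalid.cohort import BC_CODE
from riskvalid.incidence import AbsoluteRiskEstimate, cumulative_incidence

from conftest import make_cohort


def _group(n, assigned, observed, label="g"):
    est = AbsoluteRiskEstimate(observed, observed, observed, n, 0, 0)
    return CalibrationGroup(
        label=label, n=n, mean_assigned=assigned, observed=est,
        ratio=observed / assigned if assigned else 0.0,
    )


class TestQuantileGroups:
    def test_eight_subjects_into_quartiles(self):
        rows = [(11.0, "CENSORED", 0.01 * (i + 1)) for i in range(8)]
        cohort = make_cohort(rows)
        parts = quantile_groups(cohort, "m", 4)
        assert [len(p) for p in parts] == [2, 2, 2, 2]
        # ascending risk order
        risks = [cohort.risks["m"][p] for p in parts]
        assert all(risks[i].max() <= risks[i + 1].min() for i in range(3))

    def test_1857_subjects_split_around_nominal_quartile_size(self):
        rng = np.random.default_rng(0)
        rows = [(11.0, "CENSORED", float(r)) for r in rng.uniform(0, 1, 1857)]
        parts = quantile_groups(make_cohort(rows), "m", 4)
        sizes = [len(p) for p in parts]
        assert sizes == [465, 464, 464, 464]
        assert np.mean(sizes) == 464.25  # the nominal 1857/4

    def test_tied_risks_break_ties_by_subject_id(self):
        rows = [(11.0, "CENSORED", 0.5)] * 6
        cohort = make_cohort(rows)
        with pytest.warns(UserWarning, match="constant"):
            parts = quantile_groups(cohort, "m", 3)
        ids = [list(cohort.subject_ids[p]) for p in parts]
        assert ids == [["s0000", "s0001"], ["s0002", "s0003"], ["s0004", "s0005"]]

    def test_every_subject_in_exactly_one_group(self):
        rng = np.random.default_rng(1)
        rows = [(11.0, "CENSORED", float(r)) for r in rng.choice([0.1, 0.2], 37)]
        parts = quantile_groups(make_cohort(rows), "m", 5)
        joined = np.concatenate(parts)
        assert sorted(joined) == list(range(37))
        assert max(len(p) for p in parts) - min(len(p) for p in parts) <= 1


class TestHosmerLemeshow:
    def test_perfect_agreement_gives_zero_statistic(self):
        groups = [_group(100, 0.05, 0.05), _group(100, 0.2, 0.2)]
        res = hosmer_lemeshow(groups)
        assert res.hl_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_direct_formula_evaluation(self):
        groups = [_group(100, 0.05, 0.08), _group(100, 0.10, 0.10)]
        res = hosmer_lemeshow(groups)
        # 100 * 0.03^2 / (0.05 * 0.95) = 1.894736...
        assert res.hl_statistic == pytest.approx(100 * 0.03**2 / (0.05 * 0.95))
        assert res.df == 2

    def test_relabeling_invariance(self):
        g = [_group(50, 0.1, 0.2, "a"), _group(70, 0.3, 0.25, "b")]
        assert (
            hosmer_lemeshow(g).hl_statistic
            == hosmer_lemeshow(list(reversed(g))).hl_statistic
        )

    def test_degenerate_mean_assigned_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            hosmer_lemeshow([_group(10, 0.0, 0.1), _group(10, 0.5, 0.5)])

    def test_mean_statistic_near_df_under_calibration(self):
        """For a perfectly calibrated assigner the HL statistic is
        approximately chi-squared with df = groups, so its mean over
        replicates is near df (slightly below: within-group risk spread)."""
        stats = []
        for seed in range(300):
            cfg = SimulationConfig(
                n_subjects=2000,
                model_specs={"m": ModelSpec()},
                seed=seed,
            )
            cohort = simulate_cohort(cfg).cohort
            stats.append(_hl_statistic_fast(cohort, "m", 4))
        se = np.sqrt(2 * 4 / 300)  # chi2 variance 2*df
        assert np.mean(stats) == pytest.approx(4.0, abs=3 * se)


def _hl_statistic_fast(cohort, model, n_groups):
    """HL without bootstrap CIs (point estimates only)."""
    groups = []
    for k, idx in enumerate(quantile_groups(cohort, model, n_groups)):
        sub = cohort.subset(idx)
        pi = cumulative_incidence(sub.time, sub.outcome, cohort.horizon)
        groups.append(_group(sub.n, float(np.mean(sub.risks[model])), pi))
    return hosmer_lemeshow(groups).hl_statistic


@pytest.fixture(scope="module")
def miscalibrated():
    cfg = SimulationConfig(
        n_subjects=20_000,
        model_specs={"half": ModelSpec(calibration_factor=0.5)},
        censoring=CensoringSpec(admin_time=12.0, dropout_rate=0.04),
        death_hazard=0.003,
        seed=13,
    )
    return simulate_cohort(cfg).cohort


class TestCalibrationTables:
    def test_half_factor_model_has_ratio_two_in_every_subgroup(self, miscalibrated):
        config = AnalysisConfig(n_bootstrap=200, seed=0)
        tables = calibration_table(
            miscalibrated,
            "half",
            {"risk_group": [["low"], ["high"]], "stratum": [["A"], ["B"]]},
            config,
        )
        for rows in tables.values():
            for g in rows:
                half_width = (g.observed.ci_high - g.observed.ci_low) / 2
                assert abs(g.ratio - 2.0) * g.mean_assigned <= half_width

    def test_whole_cohort_ratio_approaches_one_when_calibrated(self):
        cfg = SimulationConfig(
            n_subjects=50_000, model_specs={"m": ModelSpec()}, seed=3
        )
        result = simulate_cohort(cfg)
        cohort = result.cohort
        pi = cumulative_incidence(cohort.time, cohort.outcome, 10.0)
        ratio = pi / float(np.mean(cohort.risks["m"]))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_subgroup_with_zero_events_has_zero_ratio(self):
        rows = [(11.0, "CENSORED", 0.1)] * 5 + [(2.0, "BC", 0.2)] * 3
        cohort = make_cohort(rows)
        cohort.covariates["g"] = np.array(
            ["none"] * 5 + ["event"] * 3, dtype=object
        )
        config = AnalysisConfig(n_bootstrap=50, seed=0)
        tables = calibration_table(cohort, "m", {"g": [["none"], ["event"]]}, config)
        none_row = tables["g"][0]
        assert none_row.observed.pi_hat == 0.0
        assert none_row.ratio == 0.0

    def test_unknown_covariate_or_category_raises(self):
        cohort = make_cohort([(2.0, "BC", 0.1)] * 4)
        cohort.covariates["g"] = np.array(["a"] * 4, dtype=object)
        config = AnalysisConfig(n_bootstrap=10, seed=0)
        with pytest.raises(KeyError, match="unknown covariate"):
            calibration_table(cohort, "m", {"nope": [["a"]]}, config)
        with pytest.raises(KeyError, match="unknown categor"):
            calibration_table(cohort, "m", {"g": [["b"]]}, config)

    def test_quartile_pipeline_flags_underprediction(self):
        """End-to-end quartile calibration: the 0.5-factor model is flagged
        in the large-count groups and yields a small HL p-value."""
        cfg = SimulationConfig(
            n_subjects=10_000,
            model_specs={"half": ModelSpec(calibration_factor=0.5)},
            seed=29,
        )
        cohort = simulate_cohort(cfg).cohort
        config = AnalysisConfig(n_groups=4, n_bootstrap=200, seed=1)
        res = calibrate_by_quantiles(cohort, "half", config)
        assert res.p_value < 0.001
        assert all(g.assigned_outside_ci for g in res.groups)
        assert sum(g.n for g in res.groups) == 10_000
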