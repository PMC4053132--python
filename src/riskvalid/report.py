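"""End-to-end validation runs: overall + subgroup calibration and
discrimination for one or two risk models, with TSV/JSON outputs.

A run produces, per model: quantile calibration (observed vs mean assigned
risk per group with bootstrap CIs, Hosmer-Lemeshow statistic), covariate
subgroup calibration tables, and discrimination (CRPs, AUC with CI, ROC,
sensitivity at the target specificity).  With two models it adds the
case-by-case CRP pairing: scatter data, counts of cases better identified
by each model, and the paired Wilcoxon signed-rank comparison overall and
per subgroup.

Outputs (under ``out_dir``): ``calibration_quartiles.tsv``,
``calibration_subgroups.tsv``, ``discrimination_summary.json``,
``crp_pairs.tsv`` and the full-precision ``report.json``.  TSVs render
risks as percentages to two decimals; JSON keeps full precision.  Reports
carry provenance (seed, package version, cohort size) but no wall-clock
data, so a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import (
    CalibrationGroup,
    CalibrationResult,
    calibrate_by_quantiles,
    calibration_table,
    default_subgroups,
)
from .cohort import (
    AnalysisConfig,
    CohortTable,
    read_cohort,
)
from .discrimination import (
    DiscriminationResult,
    WilcoxonResult,
    auc,
    case_risk_percentiles,
    compare_models,
    split_cases,
)

__all__ = ["ValidationReport", "run_validation", "excluded_rerun"]

logger = logging.getLogger("riskvalid")


@dataclasses.dataclass
class ValidationReport:
    config: AnalysisConfig
    n_subjects: int
    n_cases: int
    n_noncases: int
    n_excluded: int
    overall_observed: dict
    calibration: dict[str, CalibrationResult]
    subgroup_calibration: dict[str, dict[str, list[CalibrationGroup]]]
    discrimination: dict[str, DiscriminationResult]
    comparison: dict | None
    subgroup_crp: list[dict]
    provenance: dict

    def to_dict(self) -> dict:
        return _plain(
            {
                "provenance": self.provenance,
                "config": self.config.to_dict(),
                "n_subjects": self.n_subjects,
                "n_cases": self.n_cases,
                "n_noncases": self.n_noncases,
                "n_excluded": self.n_excluded,
                "overall_observed": self.overall_observed,
                "calibration": self.calibration,
                "subgroup_calibration": self.subgroup_calibration,
                "discrimination": {
                    m: _discrimination_dict(d) for m, d in self.discrimination.items()
                },
                "comparison": self.comparison,
                "subgroup_crp": self.subgroup_crp,
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def _discrimination_dict(d: DiscriminationResult) -> dict:
    out = dataclasses.asdict(d)
    out["roc_points"] = d.roc_points.tolist()
    out["crps"] = d.crps.tolist()
    return out


def run_validation(
    cohort: CohortTable | str | Path,
    config: AnalysisConfig | str | Path | None = None,
    out_dir: str | Path | None = None,
    plots: bool = False,
) -> ValidationReport:
    """Run the full validation pipeline on a cohort.

    ``cohort`` and ``config`` may be in-memory objects or file paths.
    Deterministic given the config seed; when ``out_dir`` is given, the
    TSV/JSON report files (and optionally plots) are written there.
    """
    if not isinstance(cohort, CohortTable):
        cohort = read_cohort(cohort)
    if config is None:
        config = AnalysisConfig(horizon=cohort.horizon)
    elif not isinstance(config, AnalysisConfig):
        config = AnalysisConfig.from_file(config)

    models = config.models or cohort.model_names
    missing = [m for m in models if m not in cohort.risks]
    if missing:
        raise KeyError(
            f"config names risk column(s) {missing} absent from the cohort "
            f"(has {cohort.model_names})"
        )
    logger.info("cohort: %d subjects, models %s", cohort.n, models)

    from .incidence import absolute_risk_ci

    overall = absolute_risk_ci(
        cohort, config.horizon, n_bootstrap=config.n_bootstrap, seed=config.seed
    )

    subgroup_defs = config.subgroup_definitions or default_subgroups(cohort)

    calibration = {
        m: calibrate_by_quantiles(cohort, m, config) for m in models
    }
    subgroup_calibration = {
        m: calibration_table(cohort, m, subgroup_defs, config) for m in models
    }

    split = split_cases(cohort, config.horizon, config.death_as_noncase)
    logger.info(
        "discrimination split: %d cases, %d noncases, %d excluded (censored "
        "before horizon%s)",
        split.n_cases,
        split.n_noncases,
        len(split.excluded),
        "" if config.death_as_noncase else " or died within horizon",
    )
    discrimination = {
        m: auc(
            split,
            m,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            specificity_target=config.specificity_target,
        )
        for m in models
    }

    comparison = None
    subgroup_crp: list[dict] = []
    if len(models) >= 2:
        a, b = models[0], models[1]
        crps_a = discrimination[a].crps
        crps_b = discrimination[b].crps
        wx = compare_models(crps_a, crps_b)
        comparison = {
            "model_a": a,
            "model_b": b,
            "wilcoxon": dataclasses.asdict(wx),
            "n_cases_better_b": wx.n_b_greater,
            "n_cases_better_a": wx.n_a_greater,
            "crp_pairs": np.column_stack([crps_a, crps_b]).tolist(),
        }
        subgroup_crp = _subgroup_crp_table(cohort, subgroup_defs, a, b, config)

    report = ValidationReport(
        config=config,
        n_subjects=cohort.n,
        n_cases=split.n_cases,
        n_noncases=split.n_noncases,
        n_excluded=len(split.excluded),
        overall_observed=dataclasses.asdict(overall),
        calibration=calibration,
        subgroup_calibration=subgroup_calibration,
        discrimination=discrimination,
        comparison=comparison,
        subgroup_crp=subgroup_crp,
        provenance={
            "package": "riskvalid",
            "version": __version__,
            "seed": config.seed,
            "n_subjects": cohort.n,
        },
    )
    if out_dir is not None:
        _write_outputs(report, Path(out_dir), plots=plots)
    return report


def _subgroup_crp_table(
    cohort: CohortTable,
    subgroup_defs: dict[str, list[list[str]]],
    model_a: str,
    model_b: str,
    config: AnalysisConfig,
) -> list[dict]:
    """Per-subgroup mean/median CRP for both models with Wilcoxon p.

    CRPs are recomputed within each subgroup (subgroup noncases as the
    reference distribution).  Subgroups with no cases or no noncases are
    reported with null entries rather than dropped, keeping partitions
    exhaustive.
    """
    rows: list[dict] = []
    for cov, category_sets in subgroup_defs.items():
        values = cohort.covariates[cov].astype(str)
        for cats in category_sets:
            idx = np.flatnonzero(np.isin(values, list(map(str, cats))))
            label = "/".join(map(str, cats))
            sub = cohort.subset(idx)
            split = split_cases(sub, config.horizon, config.death_as_noncase)
            row: dict = {
                "covariate": cov,
                "subgroup": label,
                "n": int(len(idx)),
                "n_cases": split.n_cases,
            }
            if split.n_cases == 0 or split.n_noncases == 0:
                row.update(
                    {
                        "mean_crp_a": None,
                        "mean_crp_b": None,
                        "median_crp_a": None,
                        "median_crp_b": None,
                        "wilcoxon_p": None,
                    }
                )
            else:
                ca = case_risk_percentiles(split, model_a)
                cb = case_risk_percentiles(split, model_b)
                wx = compare_models(ca, cb)
                row.update(
                    {
                        "mean_crp_a": float(np.mean(ca)),
                        "mean_crp_b": float(np.mean(cb)),
                        "median_crp_a": float(np.median(ca)),
                        "median_crp_b": float(np.median(cb)),
                        "wilcoxon_p": wx.p_value,
                    }
                )
            rows.append(row)
    return rows


def excluded_rerun(
    cohort: CohortTable,
    exclusion_rules: dict[str, list[str]],
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> ValidationReport:
    """Re-run the validation after excluding covariate categories.

    ``exclusion_rules`` maps covariate name -> categories whose subjects
    are dropped (e.g. the strata where one model is not recommended).  The
    report's provenance records the excluded counts per rule.
    """
    keep = np.ones(cohort.n, dtype=bool)
    excluded_counts: dict[str, int] = {}
    for cov, cats in exclusion_rules.items():
        if cov not in cohort.covariates:
            raise KeyError(f"exclusion rule references unknown covariate {cov!r}")
        hit = np.isin(cohort.covariates[cov].astype(str), list(map(str, cats)))
        excluded_counts[cov] = int(np.sum(hit & keep))
        keep &= ~hit
        logger.info("exclusion %r %s: %d subjects dropped", cov, cats, int(hit.sum()))
    if not keep.any():
        raise ValueError("exclusion rules removed every subject")
    filtered = cohort.subset(np.flatnonzero(keep))
    report = run_validation(filtered, config, out_dir=out_dir)
    report.provenance["excluded_counts"] = excluded_counts
    report.provenance["n_excluded_by_rules"] = int(cohort.n - filtered.n)
    return report


# ---------------------------------------------------------------------------
# file outputs
# ---------------------------------------------------------------------------

def _pct(x: float | None) -> str:
    return "" if x is None else f"{100.0 * x:.2f}"


def _write_outputs(report: ValidationReport, out_dir: Path, plots: bool = False) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    lines = ["model\tgroup\tn\tobserved_pct\tci_low_pct\tci_high_pct\tassigned_pct\tratio"]
    for m, res in report.calibration.items():
        for g in res.groups:
            lines.append(
                f"{m}\t{g.label}\t{g.n}\t{_pct(g.observed.pi_hat)}\t"
                f"{_pct(g.observed.ci_low)}\t{_pct(g.observed.ci_high)}\t"
                f"{_pct(g.mean_assigned)}\t{g.ratio:.2f}"
            )
        lines.append(
            f"{m}\tHL\t{res.df}\t{res.hl_statistic:.2f}\t\t\t{res.p_value:.4f}\t"
        )
    (out_dir / "calibration_quartiles.tsv").write_text("\n".join(lines) + "\n")

    lines = [
        "model\tcovariate\tsubgroup\tn\tobserved_pct\tci_low_pct\tci_high_pct\t"
        "assigned_pct\tratio\tassigned_outside_ci"
    ]
    for m, tables in report.subgroup_calibration.items():
        for cov, rows in tables.items():
            for g in rows:
                lines.append(
                    f"{m}\t{cov}\t{g.label}\t{g.n}\t{_pct(g.observed.pi_hat)}\t"
                    f"{_pct(g.observed.ci_low)}\t{_pct(g.observed.ci_high)}\t"
                    f"{_pct(g.mean_assigned)}\t{g.ratio:.2f}\t{g.assigned_outside_ci}"
                )
    (out_dir / "calibration_subgroups.tsv").write_text("\n".join(lines) + "\n")

    disc = {
        m: {
            "auc": d.auc,
            "auc_ci": list(d.auc_ci),
            "sensitivity_at_target": d.sensitivity_at_target,
            "specificity_target": d.specificity_target,
            "n_cases": d.n_cases,
            "n_noncases": d.n_noncases,
        }
        for m, d in report.discrimination.items()
    }
    if report.comparison is not None:
        disc["comparison"] = _plain(
            {k: v for k, v in report.comparison.items() if k != "crp_pairs"}
        )
    (out_dir / "discrimination_summary.json").write_text(
        json.dumps(disc, indent=2, sort_keys=True) + "\n"
    )

    if report.comparison is not None:
        a = report.comparison["model_a"]
        b = report.comparison["model_b"]
        lines = [f"crp_{a}\tcrp_{b}"]
        for ca, cb in report.comparison["crp_pairs"]:
            lines.append(f"{ca:.6f}\t{cb:.6f}")
        (out_dir / "crp_pairs.tsv").write_text("\n".join(lines) + "\n")

    (out_dir / "report.json").write_text(report.to_json())

    if plots:
        _write_plots(report, out_dir)


def _write_plots(report: ValidationReport, out_dir: Path) -> None:
    """Optional calibration / ROC / CRP-scatter figures (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(report.calibration), figsize=(5 * len(report.calibration), 4))
    axes = np.atleast_1d(axes)
    for ax, (m, res) in zip(axes, report.calibration.items()):
        xs = [g.mean_assigned for g in res.groups]
        ys = [g.observed.pi_hat for g in res.groups]
        err = np.array(
            [
                [g.observed.pi_hat - g.observed.ci_low for g in res.groups],
                [g.observed.ci_high - g.observed.pi_hat for g in res.groups],
            ]
        )
        ax.errorbar(xs, ys, yerr=err, fmt="o", capsize=3)
        lim = max(max(xs), max(ys)) * 1.1
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("mean assigned risk")
        ax.set_ylabel("observed risk")
        ax.set_title(f"{m} (HL={res.hl_statistic:.1f}, p={res.p_value:.3f})")
    fig.tight_layout()
    fig.savefig(out_dir / "calibration.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for m, d in report.discrimination.items():
        pts = np.asarray(d.roc_points)
        ax.plot(pts[:, 0], pts[:, 1], label=f"{m} (AUC={100 * d.auc:.1f}%)")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "roc.png", dpi=120)
    plt.close(fig)

    if report.comparison is not None:
        pairs = np.asarray(report.comparison["crp_pairs"])
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(pairs[:, 0], pairs[:, 1], s=12)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel(f"CRP {report.comparison['model_a']}")
        ax.set_ylabel(f"CRP {report.comparison['model_b']}")
        fig.tight_layout()
        fig.savefig(out_dir / "crp_scatter.png", dpi=120)
        plt.close(fig)
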