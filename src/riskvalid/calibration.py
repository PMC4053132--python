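"""Calibration: quantile / subgroup observed-vs-assigned comparison and the
Hosmer-Lemeshow chi-squared statistic.

Subjects are grouped into near-equal quantile groups of a model's assigned
risk (quartiles by default).  For each group the mean assigned risk r_g is
compared with the observed risk pi_hat_g — the competing-risks estimate
from :mod:`riskvalid.incidence`, not a raw event proportion, so the
comparison remains valid under censoring.  The goodness-of-fit statistic is

    HL = sum_g n_g * (pi_hat_g - r_g)^2 / (r_g * (1 - r_g)),

referred to a chi-squared distribution with df = number of groups.  The
df-equals-groups convention is the external-validation one: the models
being validated were fit on other data, so no fitted-parameter correction
(groups - 2) applies.

Covariate-specific subgroup tables report, per subgroup, the observed risk
with its bootstrap CI, each model's mean assigned risk, and the
observed/assigned ratio (> 1 means the model under-predicts).  A subgroup's
miscalibration is flagged as significant when the mean assigned risk falls
outside the observed risk's 95% CI.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .cohort import AnalysisConfig, CohortTable
from .incidence import AbsoluteRiskEstimate, absolute_risk_ci

__all__ = [
    "CalibrationGroup",
    "CalibrationResult",
    "quantile_groups",
    "hosmer_lemeshow",
    "calibrate_by_quantiles",
    "calibration_table",
]


@dataclasses.dataclass
class CalibrationGroup:
    """Observed vs assigned risk for one subject group."""

    label: str
    n: int
    mean_assigned: float
    observed: AbsoluteRiskEstimate
    ratio: float
    assigned_outside_ci: bool | None = None

    @property
    def observed_risk(self) -> float:
        return self.observed.pi_hat


@dataclasses.dataclass
class CalibrationResult:
    groups: list[CalibrationGroup]
    hl_statistic: float
    df: int
    p_value: float
    model: str = ""


def quantile_groups(
    cohort: CohortTable, model: str, n_groups: int
) -> list[np.ndarray]:
    """Partition subjects into ``n_groups`` near-equal groups by ascending
    assigned risk.

    Group sizes differ by at most one (larger groups first, so 1,857
    subjects split into quartiles as 465/464/464/464 around the nominal
    1857/4 = 464.25).  Ties are broken deterministically by a stable
    (risk, subject_id) sort; a constant risk column is allowed but warned
    about, since the grouping then carries no risk information.
    """
    if model not in cohort.risks:
        raise KeyError(f"model {model!r} not in cohort (has {cohort.model_names})")
    if n_groups > cohort.n:
        raise ValueError(f"n_groups={n_groups} exceeds cohort size {cohort.n}")
    risk = cohort.risks[model]
    if cohort.n > 1 and np.all(risk == risk[0]) and n_groups > 1:
        warnings.warn(
            f"risk column {model!r} is constant; quantile groups are "
            "arbitrary (stable id order)",
            stacklevel=2,
        )
    order = np.lexsort((cohort.subject_ids.astype(str), risk))
    return [np.sort(part) for part in np.array_split(order, n_groups)]


def hosmer_lemeshow(groups: list[CalibrationGroup]) -> CalibrationResult:
    """Hosmer-Lemeshow chi-squared over pre-computed calibration groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    stat = 0.0
    for g in groups:
        r = g.mean_assigned
        if not 0.0 < r < 1.0:
            raise ValueError(
                f"group {g.label!r}: mean assigned risk {r} degenerate (must be in (0,1))"
            )
        stat += g.n * (g.observed.pi_hat - r) ** 2 / (r * (1.0 - r))
    df = len(groups)
    p = float(stats.chi2.sf(stat, df))
    return CalibrationResult(groups=list(groups), hl_statistic=float(stat), df=df, p_value=p)


def _group_result(
    cohort: CohortTable,
    index: np.ndarray,
    model: str,
    label: str,
    config: AnalysisConfig,
    seed: int,
) -> CalibrationGroup:
    sub = cohort.subset(index)
    observed = absolute_risk_ci(
        sub, config.horizon, n_bootstrap=config.n_bootstrap, seed=seed
    )
    mean_assigned = float(np.mean(sub.risks[model]))
    ratio = observed.pi_hat / mean_assigned if mean_assigned > 0 else 0.0
    outside = not (observed.ci_low <= mean_assigned <= observed.ci_high)
    return CalibrationGroup(
        label=label,
        n=sub.n,
        mean_assigned=mean_assigned,
        observed=observed,
        ratio=float(ratio),
        assigned_outside_ci=outside,
    )


def calibrate_by_quantiles(
    cohort: CohortTable, model: str, config: AnalysisConfig
) -> CalibrationResult:
    """Full quantile calibration for one model: group, estimate observed
    risks with CIs, and compute the HL statistic."""
    parts = quantile_groups(cohort, model, config.n_groups)
    groups = [
        _group_result(cohort, idx, model, f"Q{k + 1}", config, seed=config.seed + k)
        for k, idx in enumerate(parts)
    ]
    result = hosmer_lemeshow(groups)
    result.model = model
    return result


def calibration_table(
    cohort: CohortTable,
    model: str,
    subgroup_definitions: dict[str, list[list[str]]],
    config: AnalysisConfig,
) -> dict[str, list[CalibrationGroup]]:
    """Covariate-specific observed/assigned tables.

    ``subgroup_definitions`` maps covariate name -> list of category sets;
    each set of categories defines one subgroup.  Returns one list of
    :class:`CalibrationGroup` per covariate.
    """
    if model not in cohort.risks:
        raise KeyError(f"model {model!r} not in cohort")
    out: dict[str, list[CalibrationGroup]] = {}
    for cov, category_sets in subgroup_definitions.items():
        if cov not in cohort.covariates:
            raise KeyError(f"unknown covariate {cov!r} (has {list(cohort.covariates)})")
        values = cohort.covariates[cov].astype(str)
        known = set(np.unique(values))
        rows: list[CalibrationGroup] = []
        for k, cats in enumerate(category_sets):
            unknown = set(map(str, cats)) - known
            if unknown:
                raise KeyError(
                    f"covariate {cov!r}: unknown categor{'y' if len(unknown)==1 else 'ies'} {sorted(unknown)}"
                )
            idx = np.flatnonzero(np.isin(values, list(map(str, cats))))
            if len(idx) == 0:
                raise ValueError(f"covariate {cov!r}: subgroup {cats} is empty")
            label = "/".join(map(str, cats))
            rows.append(
                _group_result(cohort, idx, model, label, config, seed=config.seed + k)
            )
        out[cov] = rows
    return out


def default_subgroups(cohort: CohortTable) -> dict[str, list[list[str]]]:
    """One subgroup per observed category of every covariate."""
    return {
        cov: [[c] for c in sorted(np.unique(vals.astype(str)))]
        for cov, vals in cohort.covariates.items()
    }
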