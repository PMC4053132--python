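"""Discrimination: case risk percentiles, AUC/ROC, sensitivity at fixed
specificity, and paired Wilcoxon signed-rank comparison of two models.

Cases are subjects who developed breast cancer within the horizon; noncases
are subjects observed event-free through the horizon.  Subjects censored
before the horizon are excluded — valid when the censoring mechanism is
unrelated to the risks of breast cancer and death.  Competing deaths within
the horizon count as noncases by default (they were observed not to develop
breast cancer within h years); a config switch excludes them instead.

A case's risk percentile (CRP) is the mid-rank percentile of her assigned
risk in the noncase assigned-risk distribution.  With mid-rank tie handling
the mean CRP over cases equals the Mann-Whitney AUC exactly — the
probability that a random case outranks a random noncase, ties counting
one half — which also equals the trapezoidal area under the empirical ROC
curve.  AUC ranges from 0.5 (no discrimination) to 1 (perfect).

The paired Wilcoxon signed-rank test compares two models' CRPs over the
same cases: zero differences are dropped, tied magnitudes take mid-ranks,
the null distribution is exact (enumeration via convolution) for up to 25
nonzero pairs and a normal approximation with continuity and tie
corrections beyond.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .cohort import BC_CODE, CENSORED_CODE, DEATH_CODE, CohortTable

__all__ = [
    "CaseNoncaseSplit",
    "DiscriminationResult",
    "WilcoxonResult",
    "split_cases",
    "case_risk_percentiles",
    "auc",
    "roc_and_sensitivity",
    "compare_models",
]

EXACT_WILCOXON_MAX_N = 25


@dataclasses.dataclass
class CaseNoncaseSplit:
    """Index partition of a cohort for discrimination analyses."""

    cohort: CohortTable
    cases: np.ndarray
    noncases: np.ndarray
    excluded: np.ndarray
    horizon: float
    death_as_noncase: bool

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_noncases(self) -> int:
        return len(self.noncases)

    def risks(self, model: str) -> tuple[np.ndarray, np.ndarray]:
        r = self.cohort.risks[model]
        return r[self.cases], r[self.noncases]


@dataclasses.dataclass
class DiscriminationResult:
    model: str
    crps: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    roc_points: np.ndarray  # (k, 2) of (1 - specificity, sensitivity)
    sensitivity_at_target: float
    specificity_target: float
    n_cases: int
    n_noncases: int


@dataclasses.dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences (b - a)
    p_value: float
    n_nonzero: int
    n_b_greater: int
    n_a_greater: int
    method: str  # "exact" | "normal-approx" | "degenerate"


def split_cases(
    cohort: CohortTable, horizon: float | None = None, death_as_noncase: bool = True
) -> CaseNoncaseSplit:
    """Deterministic case / noncase / excluded partition.

    cases:    breast cancer at time <= horizon.
    noncases: observed event-free through the horizon (time >= horizon
              without breast cancer by then), plus — by default — deaths
              from other causes within the horizon.
    excluded: censored before the horizon (and, when ``death_as_noncase``
              is False, the within-horizon deaths).
    """
    h = cohort.horizon if horizon is None else horizon
    t, c = cohort.time, cohort.outcome
    is_case = (c == BC_CODE) & (t <= h)
    observed_through = (t >= h) & ~is_case  # any outcome at/after the horizon
    early_death = (c == DEATH_CODE) & (t < h)
    is_noncase = observed_through | (early_death if death_as_noncase else np.zeros_like(early_death))
    is_excluded = ~is_case & ~is_noncase
    return CaseNoncaseSplit(
        cohort=cohort,
        cases=np.flatnonzero(is_case),
        noncases=np.flatnonzero(is_noncase),
        excluded=np.flatnonzero(is_excluded),
        horizon=h,
        death_as_noncase=death_as_noncase,
    )


def _midrank_percentiles(case_risks: np.ndarray, noncase_risks: np.ndarray) -> np.ndarray:
    """CRP_i = (#noncases below + half #noncases tied) / #noncases."""
    nc = np.sort(noncase_risks)
    below = np.searchsorted(nc, case_risks, side="left")
    tied = np.searchsorted(nc, case_risks, side="right") - below
    return (below + 0.5 * tied) / len(nc)


def case_risk_percentiles(split: CaseNoncaseSplit, model: str) -> np.ndarray:
    """Mid-rank percentile of each case's assigned risk among noncases."""
    if split.n_cases == 0 or split.n_noncases == 0:
        raise ValueError(
            f"degenerate split: {split.n_cases} cases, {split.n_noncases} noncases"
        )
    case_r, noncase_r = split.risks(model)
    return _midrank_percentiles(case_r, noncase_r)


def auc(
    split: CaseNoncaseSplit,
    model: str,
    n_bootstrap: int = 2000,
    seed: int | None = 0,
    specificity_target: float = 0.80,
) -> DiscriminationResult:
    """Mann-Whitney AUC (mean CRP) with stratified-bootstrap percentile CI,
    plus the empirical ROC and sensitivity at the target specificity."""
    crps = case_risk_percentiles(split, model)
    point = float(np.mean(crps))
    case_r, noncase_r = split.risks(model)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    n1, n0 = len(case_r), len(noncase_r)
    for b in range(n_bootstrap):
        cr = case_r[rng.integers(0, n1, n1)]
        nr = noncase_r[rng.integers(0, n0, n0)]
        boot[b] = np.mean(_midrank_percentiles(cr, nr))
    lo, hi = np.quantile(boot, [0.025, 0.975])
    roc = _roc_points(case_r, noncase_r)
    sens = float(np.mean(crps > specificity_target))
    return DiscriminationResult(
        model=model,
        crps=crps,
        auc=point,
        auc_ci=(float(min(lo, point)), float(max(hi, point))),
        roc_points=roc,
        sensitivity_at_target=sens,
        specificity_target=specificity_target,
        n_cases=n1,
        n_noncases=n0,
    )


def _roc_points(case_r: np.ndarray, noncase_r: np.ndarray) -> np.ndarray:
    """Empirical ROC at every distinct threshold, classifying positive when
    risk strictly exceeds the threshold.  Includes (0,0) and (1,1); the
    trapezoidal area equals the Mann-Whitney AUC (ties trace diagonal
    segments)."""
    thresholds = np.unique(np.concatenate([case_r, noncase_r]))[::-1]
    case_s = np.sort(case_r)
    noncase_s = np.sort(noncase_r)
    n1, n0 = len(case_s), len(noncase_s)
    tpr = 1.0 - np.searchsorted(case_s, thresholds, side="right") / n1
    fpr = 1.0 - np.searchsorted(noncase_s, thresholds, side="right") / n0
    pts = np.column_stack([fpr, tpr])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    return np.unique(pts, axis=0)  # sorted lexicographically, monotone


def roc_and_sensitivity(
    split: CaseNoncaseSplit, model: str, specificity_target: float = 0.80
) -> tuple[np.ndarray, float]:
    """Empirical ROC points and sensitivity at the target specificity.

    The sensitivity is the fraction of cases whose assigned risk strictly
    exceeds the noncase upper (1 - target) quantile — equivalently (by the
    mid-rank construction) the fraction of cases with CRP above the target.
    """
    crps = case_risk_percentiles(split, model)
    case_r, noncase_r = split.risks(model)
    return _roc_points(case_r, noncase_r), float(np.mean(crps > specificity_target))


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank comparison
# ---------------------------------------------------------------------------

def _exact_signed_rank_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all sign assignments of the (mid-)ranks.

    Mid-ranks are half-integers; doubling makes every achievable W+ value
    an integer, so the null distribution is built by convolution in
    O(n * max_sum) — equivalent to enumerating all 2^n assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(np.rint(2.0 * w_plus))
    p_le = pmf[: w2 + 1].sum()
    p_ge = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_signed_rank_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with continuity correction and tie correction."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    d = w_plus - mean
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def compare_models(crps_a: np.ndarray, crps_b: np.ndarray) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of two models' CRPs on the same
    cases.

    The statistic is W+ = sum of ranks of positive differences b - a.
    Zero differences are dropped; tied absolute differences take mid-ranks.
    Exact null distribution for <= 25 nonzero pairs, otherwise a normal
    approximation with continuity correction.  All differences zero is
    degenerate: p = 1.
    """
    a = np.asarray(crps_a, dtype=float)
    b = np.asarray(crps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired CRP lists must have equal length")
    d = b - a
    n_b_greater = int(np.sum(d > 0))
    n_a_greater = int(np.sum(d < 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(
            statistic=0.0,
            p_value=1.0,
            n_nonzero=0,
            n_b_greater=0,
            n_a_greater=0,
            method="degenerate",
        )
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for tied magnitudes
    w_plus = float(np.sum(ranks[d > 0]))
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_pvalue(ranks, w_plus)
        method = "exact"
    else:
        p = _normal_signed_rank_pvalue(ranks, w_plus)
        method = "normal-approx"
    return WilcoxonResult(
        statistic=w_plus,
        p_value=p,
        n_nonzero=n,
        n_b_greater=n_b_greater,
        n_a_greater=n_a_greater,
        method=method,
    )
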