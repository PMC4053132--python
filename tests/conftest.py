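"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by brute force
(enumeration, pairwise counting, step-by-step product-limit loops) so that
they share no code path with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from riskvalid import CohortTable, Outcome, SubjectRecord


def make_cohort(rows, horizon=10.0, models=("m",)):
    """Build a CohortTable from (time, outcome, risk...) tuples.

    ``rows`` is a list of tuples ``(time, outcome, r1[, r2...])`` with
    outcome one of "BC", "DEATH", "CENSORED".
    """
    records = []
    for i, row in enumerate(rows):
        t, out, *risks = row
        records.append(
            SubjectRecord(
                subject_id=f"s{i:04d}",
                time=float(t),
                outcome=Outcome(out),
                assigned_risks={m: float(r) for m, r in zip(models, risks)},
            )
        )
    return CohortTable.from_records(records, horizon=horizon)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def aalen_johansen_oracle(subjects, horizon):
    """Step-by-step product-limit cumulative incidence.

    ``subjects``: list of (time, kind) with kind in {"bc", "death", "cens"}.
    Pure-python loop over distinct event times; risk sets counted
    explicitly.
    """
    event_times = sorted(
        {t for t, k in subjects if k in ("bc", "death") and t <= horizon}
    )
    surv = 1.0
    pi = 0.0
    for u in event_times:
        at_risk = sum(1 for t, _ in subjects if t >= u)
        d_bc = sum(1 for t, k in subjects if t == u and k == "bc")
        d_death = sum(1 for t, k in subjects if t == u and k == "death")
        pi += surv * d_bc / at_risk
        surv *= 1.0 - d_bc / at_risk - d_death / at_risk
    return pi


def pairwise_auc_oracle(case_risks, noncase_risks):
    """AUC by exhaustive pairwise comparison (ties count one half)."""
    wins = 0.0
    for c in case_risks:
        for n in noncase_risks:
            if c > n:
                wins += 1.0
            elif c == n:
                wins += 0.5
    return wins / (len(case_risks) * len(noncase_risks))


def signed_rank_enumeration_oracle(diffs):
    """Exact two-sided Wilcoxon signed-rank p by enumerating all 2^n sign
    assignments of the nonzero differences (mid-ranks for tied magnitudes)."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
    )
    p = 2.0 * min(np.mean(ws <= w_obs), np.mean(ws >= w_obs))
    return min(1.0, p)


@pytest.fixture
def four_subject_group():
    """The canonical tiny competing-risks fixture: one event of each type,
    one early censor, one subject followed past the horizon."""
    return make_cohort(
        [
            (2.0, "BC", 0.10),
            (5.0, "DEATH", 0.20),
            (8.0, "CENSORED", 0.30),
            (12.0, "CENSORED", 0.40),
        ]
    )
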