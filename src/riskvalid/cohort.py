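"""Cohort data model, delimited-file I/O, and analysis configuration.

A cohort is one row per subject with the subject's follow-up time in years
from risk assessment, an outcome code, one or more model-assigned h-year
risk probabilities, and optional categorical covariates for subgroup
analyses.

File dialect
------------
Comma-separated, UTF-8, header row required.  Canonical column layout as
written by :func:`write_cohort`::

    subject_id,time,outcome,risk_<model>...,cov_<name>...

The outcome column holds one of the literal tokens ``BC`` (breast cancer),
``DEATH`` (death from another cause before breast cancer) or ``CENSORED``
(last observed event-free).  Risks are stored as probabilities in ``[0, 1]``;
percentages appear only in the reporting layer.

Subjects observed beyond the analysis horizon without breast cancer are
entered with their *raw* observed time (outcome ``CENSORED`` at that time,
or ``BC``/``DEATH`` after the horizon); truncation at the horizon is applied
inside the analysis operations, never at I/O, so the raw data round-trips.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Outcome",
    "SubjectRecord",
    "CohortTable",
    "AnalysisConfig",
    "ColumnMapping",
    "CohortFormatError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]

#: integer outcome codes used internally (fast numpy paths)
CENSORED_CODE = 0
BC_CODE = 1
DEATH_CODE = 2

_RISK_PREFIX = "risk_"
_COV_PREFIX = "cov_"


class Outcome(enum.Enum):
    """Follow-up outcome: one of two competing events, or censoring."""

    BREAST_CANCER = "BC"
    DEATH_OTHER = "DEATH"
    CENSORED = "CENSORED"

    @property
    def code(self) -> int:
        return _OUTCOME_TO_CODE[self]


_OUTCOME_TO_CODE = {
    Outcome.CENSORED: CENSORED_CODE,
    Outcome.BREAST_CANCER: BC_CODE,
    Outcome.DEATH_OTHER: DEATH_CODE,
}
_CODE_TO_OUTCOME = {v: k for k, v in _OUTCOME_TO_CODE.items()}
_TOKEN_TO_CODE = {o.value: c for o, c in _OUTCOME_TO_CODE.items()}
_CODE_TO_TOKEN = {c: o.value for o, c in _OUTCOME_TO_CODE.items()}


class CohortFormatError(ValueError):
    """Structural problem with a cohort file (missing columns etc.)."""


class CohortValidationError(ValueError):
    """One or more rows violate the subject-record invariants.

    Attributes
    ----------
    errors : list of (row_index, message)
        Zero-based data-row indices (header excluded) with a description
        of each violation.
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.errors[:20])
        more = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


@dataclasses.dataclass
class SubjectRecord:
    """One subject's follow-up, outcome, assigned risks and covariates."""

    subject_id: str
    time: float
    outcome: Outcome
    assigned_risks: dict[str, float] = dataclasses.field(default_factory=dict)
    covariates: dict[str, str] = dataclasses.field(default_factory=dict)

    def validate(self) -> list[str]:
        problems = []
        if not np.isfinite(self.time) or self.time <= 0:
            problems.append(f"time must be a positive real, got {self.time!r}")
        if not isinstance(self.outcome, Outcome):
            problems.append(f"unknown outcome {self.outcome!r}")
        for name, r in self.assigned_risks.items():
            if not np.isfinite(r) or not 0.0 <= r <= 1.0:
                problems.append(f"risk {name!r} outside [0,1]: {r!r}")
        return problems


@dataclasses.dataclass
class CohortTable:
    """Column-oriented cohort: parallel arrays over subjects.

    Parameters
    ----------
    subject_ids : array of str
    time : array of float, follow-up years (positive)
    outcome : array of int8 codes (0 censored, 1 breast cancer, 2 death)
    risks : mapping model name -> array of assigned h-year risks in [0,1]
    covariates : mapping covariate name -> array of category labels
    horizon : risk horizon h in years
    """

    subject_ids: np.ndarray
    time: np.ndarray
    outcome: np.ndarray
    risks: dict[str, np.ndarray]
    covariates: dict[str, np.ndarray]
    horizon: float = 10.0

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.time = np.asarray(self.time, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=np.int8)
        self.risks = {k: np.asarray(v, dtype=float) for k, v in self.risks.items()}
        self.covariates = {
            k: np.asarray(v, dtype=object) for k, v in self.covariates.items()
        }

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.time)

    def __len__(self) -> int:
        return self.n

    @property
    def model_names(self) -> list[str]:
        return list(self.risks)

    # -- validation --------------------------------------------------------
    def validate(self) -> "CohortTable":
        """Check the table invariants, raising on violation."""
        if self.horizon <= 0:
            raise ValueError(f"horizon must be positive, got {self.horizon}")
        errors: list[tuple[int, str]] = []
        bad_time = ~np.isfinite(self.time) | (self.time <= 0)
        for i in np.flatnonzero(bad_time):
            errors.append((int(i), f"time must be a positive real, got {self.time[i]!r}"))
        bad_outcome = ~np.isin(self.outcome, list(_CODE_TO_OUTCOME))
        for i in np.flatnonzero(bad_outcome):
            errors.append((int(i), f"unknown outcome code {self.outcome[i]!r}"))
        for name, r in self.risks.items():
            if len(r) != self.n:
                raise CohortFormatError(
                    f"risk column {name!r} has length {len(r)}, expected {self.n}"
                )
            bad = ~np.isfinite(r) | (r < 0) | (r > 1)
            for i in np.flatnonzero(bad):
                errors.append((int(i), f"risk {name!r} outside [0,1]: {r[i]!r}"))
        ids, counts = np.unique(self.subject_ids.astype(str), return_counts=True)
        for dup in ids[counts > 1]:
            rows = np.flatnonzero(self.subject_ids.astype(str) == dup)
            for i in rows[1:]:
                errors.append((int(i), f"duplicate subject_id {dup!r}"))
        if errors:
            raise CohortValidationError(sorted(errors))
        return self

    # -- conversions -------------------------------------------------------
    def subset(self, index: np.ndarray) -> "CohortTable":
        """Return a new table restricted to the given positional index."""
        index = np.asarray(index)
        return CohortTable(
            subject_ids=self.subject_ids[index],
            time=self.time[index],
            outcome=self.outcome[index],
            risks={k: v[index] for k, v in self.risks.items()},
            covariates={k: v[index] for k, v in self.covariates.items()},
            horizon=self.horizon,
        )

    @classmethod
    def from_records(
        cls, records: Iterable[SubjectRecord], horizon: float = 10.0
    ) -> "CohortTable":
        records = list(records)
        model_names: list[str] = []
        cov_names: list[str] = []
        for r in records:
            for m in r.assigned_risks:
                if m not in model_names:
                    model_names.append(m)
            for c in r.covariates:
                if c not in cov_names:
                    cov_names.append(c)
        table = cls(
            subject_ids=np.array([r.subject_id for r in records], dtype=object),
            time=np.array([r.time for r in records], dtype=float),
            outcome=np.array([r.outcome.code for r in records], dtype=np.int8),
            risks={
                m: np.array([r.assigned_risks.get(m, np.nan) for r in records])
                for m in model_names
            },
            covariates={
                c: np.array([r.covariates.get(c, "") for r in records], dtype=object)
                for c in cov_names
            },
            horizon=horizon,
        )
        return table.validate()

    def to_records(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(
                subject_id=str(self.subject_ids[i]),
                time=float(self.time[i]),
                outcome=_CODE_TO_OUTCOME[int(self.outcome[i])],
                assigned_risks={m: float(v[i]) for m, v in self.risks.items()},
                covariates={c: str(v[i]) for c, v in self.covariates.items()},
            )
            for i in range(self.n)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular layout (the on-disk column order)."""
        data: dict[str, np.ndarray] = {
            "subject_id": self.subject_ids.astype(str),
            "time": self.time,
            "outcome": np.array([_CODE_TO_TOKEN[int(c)] for c in self.outcome]),
        }
        for m, v in self.risks.items():
            data[_RISK_PREFIX + m] = v
        for c, v in self.covariates.items():
            data[_COV_PREFIX + c] = v.astype(str)
        return pd.DataFrame(data)


@dataclasses.dataclass
class ColumnMapping:
    """Names the cohort file's columns.

    ``risks`` maps model name -> column name; ``covariates`` maps covariate
    name -> column name.  When ``None``, risk and covariate columns are
    auto-detected from the ``risk_`` / ``cov_`` prefixes of the canonical
    layout.
    """

    subject_id: str = "subject_id"
    time: str = "time"
    outcome: str = "outcome"
    risks: dict[str, str] | None = None
    covariates: dict[str, str] | None = None


@dataclasses.dataclass
class AnalysisConfig:
    """Knobs for a validation run.

    Parameters
    ----------
    horizon : risk horizon h in years.
    n_groups : number of quantile groups for calibration (4 = quartiles).
    n_bootstrap : bootstrap resamples for confidence intervals.
    seed : seed for every random element of the analysis (bootstraps).
    specificity_target : specificity at which sensitivity is reported.
    subgroup_definitions : covariate name -> list of category sets, each set
        defining one subgroup (e.g. ``{"age": [["<35"], ["35-49", "50+"]]}``).
        An empty mapping means: one subgroup per observed category of every
        covariate present in the cohort.
    death_as_noncase : whether subjects who died of other causes within the
        horizon count as noncases in discrimination analyses (they were
        observed not to develop the disease); when False they are excluded.
    models : risk columns to validate; ``None`` means all in the cohort.
    """

    horizon: float = 10.0
    n_groups: int = 4
    n_bootstrap: int = 2000
    seed: int = 0
    specificity_target: float = 0.80
    subgroup_definitions: dict[str, list[list[str]]] = dataclasses.field(
        default_factory=dict
    )
    death_as_noncase: bool = True
    models: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 < self.specificity_target < 1.0:
            raise ValueError("specificity_target must be in (0, 1)")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a YAML (or JSON — a YAML subset) config file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise CohortFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_cohort(
    path: str | Path,
    mapping: ColumnMapping | None = None,
    horizon: float = 10.0,
) -> CohortTable:
    """Read and validate a cohort CSV.

    Raises :class:`CohortFormatError` when named columns are missing and
    :class:`CohortValidationError` (listing the offending rows) when values
    violate the subject-record invariants.
    """
    mapping = mapping or ColumnMapping()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [mapping.subject_id, mapping.time, mapping.outcome]
    if mapping.risks:
        required += list(mapping.risks.values())
    if mapping.covariates:
        required += list(mapping.covariates.values())
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing column(s): {missing}")

    if mapping.risks is None:
        risk_cols = {
            c[len(_RISK_PREFIX):]: c for c in df.columns if c.startswith(_RISK_PREFIX)
        }
    else:
        risk_cols = dict(mapping.risks)
    if not risk_cols:
        raise CohortFormatError("no risk columns found (expected 'risk_<model>')")
    if mapping.covariates is None:
        cov_cols = {
            c[len(_COV_PREFIX):]: c for c in df.columns if c.startswith(_COV_PREFIX)
        }
    else:
        cov_cols = dict(mapping.covariates)

    errors: list[tuple[int, str]] = []

    def _numeric(col: str, what: str) -> np.ndarray:
        # python float(): exact strtod (pd.to_numeric's parser loses ulps)
        vals = np.empty(len(df))
        for i, cell in enumerate(df[col].to_numpy()):
            try:
                vals[i] = float(cell)
            except (TypeError, ValueError):
                vals[i] = np.nan
        for i in np.flatnonzero(~np.isfinite(vals)):
            errors.append((int(i), f"non-numeric {what} {df[col].iloc[i]!r}"))
        return vals

    time = _numeric(mapping.time, "time")
    tokens = df[mapping.outcome].to_numpy()
    outcome = np.full(len(df), -1, dtype=np.int8)
    for tok, code in _TOKEN_TO_CODE.items():
        outcome[tokens == tok] = code
    for i in np.flatnonzero(outcome == -1):
        errors.append((int(i), f"unknown outcome code {tokens[i]!r}"))

    risks = {m: _numeric(col, f"risk {m!r}") for m, col in risk_cols.items()}
    covariates = {c: df[col].to_numpy(dtype=object) for c, col in cov_cols.items()}

    # cells already flagged get benign placeholders so each violation is
    # reported exactly once
    table = CohortTable(
        subject_ids=df[mapping.subject_id].to_numpy(dtype=object),
        time=np.where(np.isfinite(time), time, 1.0),
        outcome=np.where(outcome == -1, CENSORED_CODE, outcome).astype(np.int8),
        risks={m: np.where(np.isfinite(v), v, 0.5) for m, v in risks.items()},
        covariates=covariates,
        horizon=horizon,
    )
    try:
        table.validate()
    except CohortValidationError as exc:
        errors.extend(exc.errors)
    if errors:
        # de-duplicate (a non-numeric cell is flagged once)
        raise CohortValidationError(sorted(set(errors)))
    return table


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort as canonical CSV (UTF-8, header row).

    ``read_cohort(write_cohort(c))`` is the identity: floats are written
    with 17 significant digits, which round-trips IEEE doubles exactly.
    """
    cohort.to_frame().to_csv(path, index=False, float_format=lambda v: f"{v:.17g}")


def write_sidecar(path: str | Path, payload: Mapping) -> None:
    """Write a JSON sidecar (true risks, config echo) next to a cohort."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
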