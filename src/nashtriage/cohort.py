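"""Patient data model, histological endpoint and cohort filtering.

The unit of analysis is one screened patient with paired liver histology
(fibrosis stage 0-4 and NAFLD activity score 0-8) and a fasting blood
panel. The binary endpoint throughout the package is *at-risk NASH*:
NAS >= 4 together with significant fibrosis (stage >= 2), the histological
profile associated with elevated risk of progression and liver-related
mortality. Cohort-level operations work on a ``pandas.DataFrame`` with one
row per patient (columns named exactly as the :class:`PatientRecord`
fields); single-subject operations accept a :class:`PatientRecord`, a
``Series`` or a mapping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import as_mapping, is_missing

__all__ = [
    "PatientRecord",
    "EndpointSpec",
    "CohortFilter",
    "MissingFieldError",
    "is_at_risk",
    "filter_cohort",
    "split_by_age",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]


class MissingFieldError(ValueError):
    """A required patient field is absent."""

    def __init__(self, field_name: str, patient_id: str | None = None):
        self.field_name = field_name
        self.patient_id = patient_id
        who = f" for patient {patient_id!r}" if patient_id else ""
        super().__init__(f"missing required field {field_name!r}{who}")


#: Laboratory fields that must be strictly positive when present.
_POSITIVE_LABS = (
    "bmi", "ast", "alt", "platelets", "albumin", "mir34a", "ykl40",
    "a2m", "hba1c", "ha", "piiinp", "timp1", "fpg",
)


@dataclass
class PatientRecord:
    """One subject's demographics, labs, histology and sampling-gap metadata.

    Concentrations/activities are in conventional clinical units: AST/ALT
    IU/L, platelets 10^9/L, albumin g/dL, alpha2-macroglobulin g/L, HbA1c %,
    YKL-40 / hyaluronic acid / PIIINP / TIMP-1 ng/mL, miR-34a-5p as a
    positive fold change. Any lab field may be ``None`` (missing).
    """

    patient_id: str
    age: int
    sex: str  # "female" | "male"
    fibrosis_stage: int | None = None
    nas: int | None = None
    gap_days: int = 0
    diabetes: bool | None = None
    bmi: float | None = None
    ast: float | None = None
    alt: float | None = None
    platelets: float | None = None
    albumin: float | None = None
    mir34a: float | None = None
    ykl40: float | None = None
    a2m: float | None = None
    hba1c: float | None = None
    ha: float | None = None
    piiinp: float | None = None
    timp1: float | None = None
    fpg: float | None = None  # fasting plasma glucose, mmol/L (optional)

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not is_missing(self.age) and self.age < 18:
            raise ValueError(f"age {self.age} below screening minimum of 18")
        if not is_missing(self.gap_days) and self.gap_days < 0:
            raise ValueError("gap_days must be non-negative")
        if not is_missing(self.fibrosis_stage) and self.fibrosis_stage not in range(5):
            raise ValueError(f"fibrosis_stage must be 0-4, got {self.fibrosis_stage}")
        if not is_missing(self.nas) and self.nas not in range(9):
            raise ValueError(f"nas must be 0-8, got {self.nas}")
        for name in _POSITIVE_LABS:
            v = getattr(self, name)
            if not is_missing(v) and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")

    @classmethod
    def from_row(cls, row: Mapping) -> "PatientRecord":
        kwargs = {}
        for f in dc_fields(cls):
            v = row.get(f.name, None)
            kwargs[f.name] = None if is_missing(v) else v
        for k in ("age", "gap_days", "fibrosis_stage", "nas"):
            if kwargs[k] is not None:
                kwargs[k] = int(kwargs[k])
        if kwargs["diabetes"] is not None:
            kwargs["diabetes"] = bool(kwargs["diabetes"])
        return cls(**kwargs)


COHORT_COLUMNS = [f.name for f in dc_fields(PatientRecord)]


@dataclass(frozen=True)
class EndpointSpec:
    """Histological endpoint rule: NAS >= nas_min AND fibrosis >= fibrosis_min.

    Defaults encode at-risk NASH (NAS >= 4, F >= 2); raising ``fibrosis_min``
    to 3 or 4 generalizes the endpoint to at-risk NASH with advanced
    fibrosis or cirrhosis.
    """

    nas_min: int = 4
    fibrosis_min: int = 2

    def __post_init__(self):
        if not 0 <= self.nas_min <= 8:
            raise ValueError("nas_min must be in 0..8")
        if not 0 <= self.fibrosis_min <= 4:
            raise ValueError("fibrosis_min must be in 0..4")


@dataclass(frozen=True)
class CohortFilter:
    """Cohort selection rule: biopsy-blood gap cap and complete-case policy."""

    max_gap_days: int = 90
    age_split: int = 65
    require_complete_scores: bool = True

    def __post_init__(self):
        if self.max_gap_days < 0:
            raise ValueError("max_gap_days must be non-negative")


def is_at_risk(record, spec: EndpointSpec = EndpointSpec()) -> bool:
    """True iff the subject meets the histological endpoint.

    Raises :class:`MissingFieldError` if NAS or fibrosis stage is absent —
    the endpoint is undefined without biopsy results.
    """
    get = as_mapping(record)
    nas, stage = get("nas"), get("fibrosis_stage")
    pid = get("patient_id")
    if is_missing(nas):
        raise MissingFieldError("nas", pid)
    if is_missing(stage):
        raise MissingFieldError("fibrosis_stage", pid)
    return nas >= spec.nas_min and stage >= spec.fibrosis_min


def endpoint_labels(cohort: pd.DataFrame, spec: EndpointSpec = EndpointSpec()) -> np.ndarray:
    """Vectorized endpoint: 1 = at-risk, 0 = not, for every row of a cohort."""
    for col in ("nas", "fibrosis_stage"):
        if cohort[col].isna().any():
            raise MissingFieldError(col)
    return (
        (cohort["nas"].to_numpy() >= spec.nas_min)
        & (cohort["fibrosis_stage"].to_numpy() >= spec.fibrosis_min)
    ).astype(int)


def filter_cohort(
    cohort: pd.DataFrame,
    cohort_filter: CohortFilter = CohortFilter(),
    required_fields: Iterable[str] = (),
) -> tuple[pd.DataFrame, Counter]:
    """Apply the gap filter and (optionally) complete-case selection.

    Returns the retained rows (order preserved) and a per-reason exclusion
    tally: ``gap`` for gap_days > max_gap_days and ``missing:<field>`` for
    each required field that caused an exclusion. A record failing on
    several grounds is tallied once, by the first reason encountered
    (gap first, then fields in the given order); this keeps the tally a
    partition of the excluded records.
    """
    required = list(required_fields)
    tally: Counter = Counter()
    keep = np.ones(len(cohort), dtype=bool)

    gap_bad = cohort["gap_days"].to_numpy() > cohort_filter.max_gap_days
    tally["gap"] += int(gap_bad.sum())
    keep &= ~gap_bad

    if cohort_filter.require_complete_scores:
        for name in required:
            miss = cohort[name].isna().to_numpy() & keep
            if miss.any():
                tally[f"missing:{name}"] += int(miss.sum())
                keep &= ~miss
    return cohort.loc[keep], tally


def split_by_age(cohort: pd.DataFrame, age_split: int = 65) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (age < split, age >= split); exhaustive and disjoint."""
    older = cohort["age"].to_numpy() >= age_split
    return cohort.loc[~older], cohort.loc[older]


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = [{f: getattr(r, f) for f in COHORT_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(cohort: pd.DataFrame) -> list[PatientRecord]:
    return [PatientRecord.from_row(row) for _, row in cohort.iterrows()]


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (one row per patient, empty cells = missing)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = [c for c in ("patient_id", "age", "sex") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort CSV lacks required columns: {missing_cols}")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV in the canonical column order, deterministically."""
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    out = cohort[cols].copy()
    out.to_csv(path, index=False, float_format="%.6g")
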