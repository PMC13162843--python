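"""Cohort metadata: per-patient demographics and sample availability.

The packaged fixture (``data/cohort.csv``) describes an 18-row cohort: 16
liver-metastasis patients treated with interventional-radiology
liver-directed therapy (hepatic arterial embolization, Y90
radioembolization, microwave ablation or cryoablation) plus two
negative-control rows — a healthy donor and a patient whose mapping
angiogram was not followed by treatment.

Summary conventions (deliberate, and asymmetric): the median age is
computed over *all* rows including the controls, whereas the percent-male
figure, treatment counts and sample-availability denominators cover only
the treated rows.  The underlying cohort's printed summary statistics are
mutually consistent only under exactly this pairing (the treated-only age
median differs), so both conventions are encoded as-is rather than
"fixed".
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TREATMENTS",
    "CONTROL_TREATMENTS",
    "PatientRecord",
    "CohortSummary",
    "read_cohort_csv",
    "load_packaged_cohort",
    "summarize_cohort",
]

TREATMENTS = frozenset({"HAE", "Y90", "MWA", "Cryoablation", "Mapping", "Control"})
#: rows excluded from all treatment-efficacy style counts
CONTROL_TREATMENTS = frozenset({"Mapping", "Control"})
EMBOLOTHERAPY = frozenset({"HAE", "Y90"})
ABLATION = frozenset({"MWA", "Cryoablation"})
_SEXES = frozenset({"male", "female"})


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    age: int
    cancer: str
    treatment: str
    has_biopsy: bool
    has_pre_blood: bool
    has_1mo_blood: bool
    has_3mo_blood: bool

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def is_control(self) -> bool:
        return self.treatment in CONTROL_TREATMENTS


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    n_total_rows: int
    n_treated: int
    median_age: float
    pct_male_treated: float
    counts_by_treatment: dict[str, int]
    n_with_biopsy: int
    n_with_pre: int
    n_with_1mo: int
    n_with_3mo: int

    @property
    def n_embolotherapy(self) -> int:
        return sum(self.counts_by_treatment.get(t, 0) for t in EMBOLOTHERAPY)

    @property
    def n_ablation(self) -> int:
        return sum(self.counts_by_treatment.get(t, 0) for t in ABLATION)


def _parse_flag(value, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no", ""}:
        return False
    raise ValueError(f"row {row}: cannot parse boolean {value!r} in {column!r}")


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort metadata CSV into validated patient records.

    Expected columns: ``patient_id, sex, age, cancer, treatment, biopsy,
    pre_blood, blood_1mo, blood_3mo`` (booleans as 0/1).  Unknown treatment
    or sex labels raise ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [
        "patient_id",
        "sex",
        "age",
        "cancer",
        "treatment",
        "biopsy",
        "pre_blood",
        "blood_1mo",
        "blood_3mo",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        treatment = row.treatment.strip()
        if treatment not in TREATMENTS:
            raise ValueError(f"row {i}: unknown treatment label {treatment!r}")
        records.append(
            PatientRecord(
                patient_id=row.patient_id.strip(),
                sex=row.sex.strip().lower(),
                age=int(row.age),
                cancer=row.cancer.strip(),
                treatment=treatment,
                has_biopsy=_parse_flag(row.biopsy, i, "biopsy"),
                has_pre_blood=_parse_flag(row.pre_blood, i, "pre_blood"),
                has_1mo_blood=_parse_flag(row.blood_1mo, i, "blood_1mo"),
                has_3mo_blood=_parse_flag(row.blood_3mo, i, "blood_3mo"),
            )
        )
    return records


def load_packaged_cohort() -> list[PatientRecord]:
    """The cohort fixture shipped with the package (18 rows)."""
    with resources.as_file(
        resources.files("clonotrack").joinpath("data/cohort.csv")
    ) as p:
        return read_cohort_csv(p)


def summarize_cohort(records: Iterable[PatientRecord]) -> CohortSummary:
    """Cohort summary statistics (see module docstring for conventions)."""
    recs: Sequence[PatientRecord] = list(records)
    if not recs:
        raise ValueError("empty cohort")
    treated = [r for r in recs if not r.is_control]
    counts: dict[str, int] = {}
    for r in treated:
        counts[r.treatment] = counts.get(r.treatment, 0) + 1
    n_male = sum(r.sex == "male" for r in treated)
    return CohortSummary(
        n_total_rows=len(recs),
        n_treated=len(treated),
        median_age=float(np.median([r.age for r in recs])),
        pct_male_treated=100.0 * n_male / len(treated) if treated else float("nan"),
        counts_by_treatment=counts,
        n_with_biopsy=sum(r.has_biopsy for r in treated),
        n_with_pre=sum(r.has_pre_blood for r in treated),
        n_with_1mo=sum(r.has_1mo_blood for r in treated),
        n_with_3mo=sum(r.has_3mo_blood for r in treated),
    )
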