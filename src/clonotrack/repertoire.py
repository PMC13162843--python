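"""Clonotype tables and repertoire samples.

Bulk TCR-beta sequencing reports one row per unique nucleotide rearrangement
(the clonotype identity) together with its CDR3 amino-acid translation, V/J
gene calls, a productive/non-productive status, and a template count — the
estimated number of input DNA molecules carrying that rearrangement.  This
module ingests such tables (immunoSEQ-style exports and AIRR rearrangement
TSVs via column dialects), filters non-productive sequences, and computes
clonal frequencies as ``templates / total productive templates``.

Clonotype identity is the exact nucleotide rearrangement string; an
amino-acid-level aggregation is available as a separate view
(:func:`amino_acid_view`) but is never the default.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PRODUCTIVE",
    "STOP",
    "FRAMESHIFT",
    "BLOOD",
    "TUMOR_BIOPSY",
    "ClonotypeRecord",
    "RepertoireSample",
    "ColumnDialect",
    "DIALECTS",
    "RepertoireFormatError",
    "DegenerateSampleError",
    "read_repertoire_tsv",
    "write_repertoire_tsv",
    "filter_productive",
    "compute_frequencies",
    "amino_acid_view",
]

PRODUCTIVE = "productive"
STOP = "stop"
FRAMESHIFT = "frameshift"
STATUSES = frozenset({PRODUCTIVE, STOP, FRAMESHIFT})

BLOOD = "blood"
TUMOR_BIOPSY = "tumor_biopsy"
COMPARTMENTS = frozenset({BLOOD, TUMOR_BIOPSY})

#: canonical internal column order
_COLUMNS = ["rearrangement", "cdr3_aa", "v_gene", "j_gene", "status", "templates"]


class RepertoireFormatError(ValueError):
    """The input table cannot be interpreted as a clonotype table."""


class DegenerateSampleError(ValueError):
    """Operation undefined on a sample with zero productive templates."""


@dataclasses.dataclass
class ClonotypeRecord:
    """One unique TCR-beta rearrangement with its annotation and count.

    Parameters
    ----------
    rearrangement
        Nucleotide rearrangement string; the clonotype identity key.
    cdr3_aa
        CDR3 amino-acid translation; may be empty for non-productive rows.
    v_gene, j_gene
        Gene-segment calls, or ``"unknown"``.
    status
        One of ``productive``, ``stop``, ``frameshift``.
    templates
        Non-negative template count (abundance unit).
    frequency
        Clonal frequency as a fraction in [0, 1]; ``None`` until
        :func:`compute_frequencies` has run.
    """

    rearrangement: str
    cdr3_aa: str = ""
    v_gene: str = "unknown"
    j_gene: str = "unknown"
    status: str = PRODUCTIVE
    templates: int = 0
    frequency: float | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.templates < 0:
            raise ValueError("templates must be >= 0")


class RepertoireSample:
    """One sequenced repertoire (blood or tumour biopsy) at one timepoint.

    Clonotype rows are stored internally as a :class:`pandas.DataFrame` so
    that filtering, frequency computation and sample pairing stay vectorised
    on deep repertoires (tens of thousands of clonotypes).

    Timepoints are integer days relative to the procedure day (day 0);
    negative values are pre-procedure.
    """

    def __init__(
        self,
        sample_id: str,
        subject_id: str = "",
        compartment: str = BLOOD,
        timepoint_days: int = 0,
        data: pd.DataFrame | None = None,
    ) -> None:
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        self.sample_id = str(sample_id)
        self.subject_id = str(subject_id)
        self.compartment = compartment
        self.timepoint_days = int(timepoint_days)
        if data is None:
            data = pd.DataFrame({c: pd.Series(dtype=object) for c in _COLUMNS})
        data = data.reset_index(drop=True).copy()
        for col in _COLUMNS:
            if col not in data.columns:
                raise ValueError(f"sample data missing column {col!r}")
        bad = set(data["status"]) - STATUSES
        if bad:
            raise ValueError(f"unknown status values {sorted(bad)!r}")
        templates = pd.to_numeric(data["templates"])
        if (templates < 0).any():
            raise ValueError("negative template count")
        if (templates != templates.astype("int64")).any():
            raise ValueError("non-integer template count")
        data["templates"] = templates.astype("int64")
        if data["rearrangement"].duplicated().any():
            raise ValueError("duplicate rearrangement strings within sample")
        keep = _COLUMNS + (["frequency"] if "frequency" in data.columns else [])
        self._data = data[keep]

    # -- container surface -------------------------------------------------
    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<RepertoireSample {self.sample_id!r} subject={self.subject_id!r} "
            f"{self.compartment} day={self.timepoint_days:+d} "
            f"clonotypes={len(self)} templates={self.total_templates}>"
        )

    @property
    def data(self) -> pd.DataFrame:
        """Copy of the underlying clonotype table."""
        return self._data.copy()

    @property
    def total_templates(self) -> int:
        """Sum of template counts over the retained records."""
        return int(self._data["templates"].sum())

    @property
    def has_frequencies(self) -> bool:
        return "frequency" in self._data.columns and len(self._data) > 0

    @property
    def records(self) -> list[ClonotypeRecord]:
        """Materialise the table as :class:`ClonotypeRecord` objects."""
        freq = self._data["frequency"] if "frequency" in self._data.columns else None
        out = []
        for i, row in enumerate(self._data.itertuples(index=False)):
            out.append(
                ClonotypeRecord(
                    rearrangement=row.rearrangement,
                    cdr3_aa=row.cdr3_aa,
                    v_gene=row.v_gene,
                    j_gene=row.j_gene,
                    status=row.status,
                    templates=int(row.templates),
                    frequency=None if freq is None else float(freq.iloc[i]),
                )
            )
        return out

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Iterable[ClonotypeRecord],
        sample_id: str,
        subject_id: str = "",
        compartment: str = BLOOD,
        timepoint_days: int = 0,
    ) -> "RepertoireSample":
        recs = list(records)
        data = pd.DataFrame(
            {
                "rearrangement": [r.rearrangement for r in recs],
                "cdr3_aa": [r.cdr3_aa for r in recs],
                "v_gene": [r.v_gene for r in recs],
                "j_gene": [r.j_gene for r in recs],
                "status": [r.status for r in recs],
                "templates": [r.templates for r in recs],
            }
        )
        if any(r.frequency is not None for r in recs):
            data["frequency"] = [
                np.nan if r.frequency is None else r.frequency for r in recs
            ]
        return cls(sample_id, subject_id, compartment, timepoint_days, data)

    @classmethod
    def from_counts(
        cls,
        rearrangements: Sequence[str],
        templates: Sequence[int],
        sample_id: str,
        subject_id: str = "",
        compartment: str = BLOOD,
        timepoint_days: int = 0,
        drop_zero: bool = True,
    ) -> "RepertoireSample":
        """Build an all-productive sample from parallel id/count arrays.

        Zero-count clonotypes are dropped by default: a clonotype that drew
        no templates is *undetected* in that sample.
        """
        ids = np.asarray(rearrangements, dtype=object)
        counts = np.asarray(templates, dtype="int64")
        if ids.shape != counts.shape:
            raise ValueError("rearrangements and templates must align")
        if drop_zero:
            keep = counts > 0
            ids, counts = ids[keep], counts[keep]
        data = pd.DataFrame(
            {
                "rearrangement": ids,
                "cdr3_aa": "",
                "v_gene": "unknown",
                "j_gene": "unknown",
                "status": PRODUCTIVE,
                "templates": counts,
            }
        )
        return cls(sample_id, subject_id, compartment, timepoint_days, data)


# ---------------------------------------------------------------------------
# column dialects
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ColumnDialect:
    """Maps canonical clonotype-table columns onto a vendor's column names.

    ``columns`` maps each canonical name to a tuple of accepted source
    headers (first match wins).  ``status_values`` maps lowercase source
    status strings to canonical statuses; canonical statuses are always
    accepted as-is.  ``status_out`` gives the value written for each
    canonical status on export.
    """

    name: str
    columns: dict[str, tuple[str, ...]]
    status_values: dict[str, str]
    status_out: dict[str, str]

    def resolve(self, header: Sequence[str]) -> dict[str, str]:
        """Map canonical -> actual column name, or raise naming the column."""
        mapping: dict[str, str] = {}
        for canonical, candidates in self.columns.items():
            for cand in candidates:
                if cand in header:
                    mapping[canonical] = cand
                    break
            else:
                raise RepertoireFormatError(
                    f"missing required column for {canonical!r}; "
                    f"expected one of {list(candidates)} ({self.name} dialect)"
                )
        return mapping

    def map_status(self, value: str, row: int) -> str:
        v = str(value).strip()
        if v in STATUSES:
            return v
        mapped = self.status_values.get(v.lower())
        if mapped is None:
            raise RepertoireFormatError(
                f"row {row}: cannot interpret status value {value!r} "
                f"under the {self.name!r} dialect"
            )
        return mapped


#: Built-in dialects.  "immunoseq" follows the Adaptive immunoSEQ v2 export
#: (sequenceStatus In/Out/Stop = in-frame / frameshift / premature stop);
#: "airr" follows the AIRR rearrangement schema, whose boolean `productive`
#: cannot distinguish stop from frameshift (non-productive -> frameshift
#: unless a stop_codon column is present — see read_repertoire_tsv).
DIALECTS: dict[str, ColumnDialect] = {
    "immunoseq": ColumnDialect(
        name="immunoseq",
        columns={
            "rearrangement": ("rearrangement", "nucleotide"),
            "cdr3_aa": ("aminoAcid", "amino_acid"),
            "templates": (
                "count (templates/estimate)",
                "count (templates/reads)",
                "templates",
                "count",
            ),
            "status": ("sequenceStatus", "frame_type"),
            "v_gene": ("vGeneName", "v_gene"),
            "j_gene": ("jGeneName", "j_gene"),
        },
        status_values={"in": PRODUCTIVE, "out": FRAMESHIFT, "stop": STOP},
        status_out={PRODUCTIVE: "In", FRAMESHIFT: "Out", STOP: "Stop"},
    ),
    "airr": ColumnDialect(
        name="airr",
        columns={
            "rearrangement": ("junction",),
            "cdr3_aa": ("junction_aa",),
            "templates": ("duplicate_count",),
            "status": ("productive",),
            "v_gene": ("v_call",),
            "j_gene": ("j_call",),
        },
        status_values={
            "t": PRODUCTIVE,
            "true": PRODUCTIVE,
            "1": PRODUCTIVE,
            "f": FRAMESHIFT,
            "false": FRAMESHIFT,
            "0": FRAMESHIFT,
        },
        status_out={PRODUCTIVE: "T", FRAMESHIFT: "F", STOP: "F"},
    ),
}


def _get_dialect(dialect: str | ColumnDialect) -> ColumnDialect:
    if isinstance(dialect, ColumnDialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown dialect {dialect!r}; available: {sorted(DIALECTS)}"
        ) from None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_repertoire_tsv(
    path,
    dialect: str | ColumnDialect = "immunoseq",
    *,
    sample_id: str | None = None,
    subject_id: str = "",
    compartment: str = BLOOD,
    timepoint_days: int = 0,
) -> RepertoireSample:
    """Read one clonotype table (UTF-8, tab-separated, header row).

    Rows sharing an identical rearrangement string are merged by summing
    their template counts, so re-exported or concatenated tables ingest to
    the same clonotype set.  A stored ``frequency`` column, if present, is
    carried through (summed on merge); frequencies are otherwise absent
    until :func:`compute_frequencies`.

    Raises
    ------
    RepertoireFormatError
        If a required column cannot be resolved under the dialect, or a
        status value is unrecognised.
    ValueError
        If a template count is negative or non-integer (the offending
        1-based data row is named).
    """
    path = Path(path)
    d = _get_dialect(dialect)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise RepertoireFormatError(f"{path}: empty file (no header)") from None
    mapping = d.resolve(list(raw.columns))

    n = len(raw)
    templates = np.empty(n, dtype="int64")
    for i, value in enumerate(raw[mapping["templates"]].to_numpy()):
        try:
            f = float(value)
        except (TypeError, ValueError):
            raise ValueError(
                f"row {i + 1}: template count {value!r} is not a number"
            ) from None
        if f < 0:
            raise ValueError(f"row {i + 1}: negative template count {value!r}")
        if f != int(f):
            raise ValueError(f"row {i + 1}: non-integer template count {value!r}")
        templates[i] = int(f)

    statuses = [
        d.map_status(v, i + 1) for i, v in enumerate(raw[mapping["status"]])
    ]
    data = pd.DataFrame(
        {
            "rearrangement": raw[mapping["rearrangement"]].astype(str),
            "cdr3_aa": raw[mapping["cdr3_aa"]].astype(str),
            "v_gene": raw[mapping["v_gene"]].replace("", "unknown").astype(str),
            "j_gene": raw[mapping["j_gene"]].replace("", "unknown").astype(str),
            "status": statuses,
            "templates": templates,
        }
    )
    if "frequency" in raw.columns:
        data["frequency"] = pd.to_numeric(raw["frequency"], errors="coerce")

    # merge duplicate rearrangements: counts (and stored frequencies) add
    agg = {
        "cdr3_aa": "first",
        "v_gene": "first",
        "j_gene": "first",
        "status": "first",
        "templates": "sum",
    }
    if "frequency" in data.columns:
        agg["frequency"] = "sum"
    data = data.groupby("rearrangement", as_index=False, sort=False).agg(agg)

    return RepertoireSample(
        sample_id=sample_id if sample_id is not None else path.stem,
        subject_id=subject_id,
        compartment=compartment,
        timepoint_days=timepoint_days,
        data=data,
    )


def write_repertoire_tsv(
    sample: RepertoireSample, path, dialect: str | ColumnDialect = "immunoseq"
) -> None:
    """Write the sample as a tab-separated clonotype table.

    The round trip ``read(write(s))`` reproduces the record multiset exactly
    (identities, annotation, counts; stored frequencies to full precision).
    """
    d = _get_dialect(dialect)
    cols = {canonical: names[0] for canonical, names in d.columns.items()}
    df = sample.data
    out = pd.DataFrame(
        {
            cols["rearrangement"]: df["rearrangement"],
            cols["cdr3_aa"]: df["cdr3_aa"],
            cols["templates"]: df["templates"],
            cols["status"]: [d.status_out[s] for s in df["status"]],
            cols["v_gene"]: df["v_gene"],
            cols["j_gene"]: df["j_gene"],
        }
    )
    if "frequency" in df.columns:
        out["frequency"] = df["frequency"].map(lambda x: np.format_float_scientific(x, precision=17))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering and frequencies
# ---------------------------------------------------------------------------

def filter_productive(sample: RepertoireSample) -> RepertoireSample:
    """Drop non-productive (premature stop / frameshift) clonotypes.

    Returns a new sample containing only productive records, with the total
    template count recomputed over what remains.  An all-non-productive
    input yields an empty sample and a warning, not an error.  Any stored
    frequencies are discarded: they were computed against a denominator
    that no longer applies.
    """
    data = sample.data
    data = data[data["status"] == PRODUCTIVE].reset_index(drop=True)
    data = data.drop(columns=["frequency"], errors="ignore")
    if len(data) == 0:
        warnings.warn(
            f"sample {sample.sample_id!r}: no productive records remain",
            stacklevel=2,
        )
    return RepertoireSample(
        sample.sample_id,
        sample.subject_id,
        sample.compartment,
        sample.timepoint_days,
        data,
    )


def compute_frequencies(sample: RepertoireSample) -> RepertoireSample:
    """Set each record's clonal frequency to ``templates / total_templates``.

    The denominator is the post-filter total of productive templates, so
    :func:`filter_productive` must run first; a sample still carrying
    non-productive records is rejected rather than silently included in the
    denominator.

    Raises
    ------
    DegenerateSampleError
        If the sample has zero total templates.
    """
    data = sample.data
    if (data["status"] != PRODUCTIVE).any():
        raise ValueError(
            "sample contains non-productive records; apply filter_productive "
            "before computing frequencies"
        )
    total = int(data["templates"].sum())
    if total == 0:
        raise DegenerateSampleError(
            f"sample {sample.sample_id!r} has zero templates"
        )
    data["frequency"] = data["templates"] / total
    return RepertoireSample(
        sample.sample_id,
        sample.subject_id,
        sample.compartment,
        sample.timepoint_days,
        data,
    )


def amino_acid_view(sample: RepertoireSample) -> pd.DataFrame:
    """Aggregate the sample by CDR3 amino-acid sequence (optional view).

    Clonotype identity everywhere else in this package is the nucleotide
    rearrangement; this convenience view sums templates (and frequencies,
    when present) over records sharing a CDR3 amino-acid string.
    """
    df = sample.data
    agg: dict[str, str] = {"templates": "sum"}
    if "frequency" in df.columns:
        agg["frequency"] = "sum"
    return df.groupby("cdr3_aa", as_index=False, sort=False).agg(agg)
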