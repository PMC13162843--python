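"""Longitudinal clonotype trajectories, TIL labels, and cohort summaries.

A patient timeline bundles one pre-procedure baseline blood sample, any
number of follow-up blood samples, and (optionally) a pre-procedure tumour
biopsy.  A tumour-infiltrating lymphocyte (TIL) is any clonotype detected
(at least one productive template) in the biopsy; for patients without a
biopsy TIL status is *unknown*, never coerced to false.

Expansion at every follow-up is always judged against the same
pre-procedure baseline, not against the previous follow-up; "persistent"
expansion means meeting the criteria versus baseline at both of two
timepoints.  Biopsy repertoires never contribute to the blood clonotype
union — they only label TIL status.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .expansion import (
    NONE,
    ExpansionCriteria,
    call_expansions,
)
from .repertoire import BLOOD, TUMOR_BIOPSY, PRODUCTIVE, RepertoireSample

__all__ = [
    "PatientTimeline",
    "ClonotypeTrajectory",
    "CohortExpansionStats",
    "classify_til",
    "build_trajectories",
    "persistent_expansions",
    "summarize_expansion_by_patient",
    "export_pairwise_scatter",
    "trajectories_to_frame",
]


@dataclasses.dataclass
class PatientTimeline:
    """One patient's samples: baseline blood, follow-up bloods, optional biopsy."""

    subject_id: str
    baseline: RepertoireSample
    followups: Sequence[RepertoireSample]
    biopsy: RepertoireSample | None = None

    def __post_init__(self) -> None:
        samples = [self.baseline, *self.followups]
        if self.biopsy is not None:
            samples.append(self.biopsy)
        for s in samples:
            if s.subject_id != self.subject_id:
                raise ValueError(
                    f"sample {s.sample_id!r} belongs to {s.subject_id!r}, "
                    f"not {self.subject_id!r}"
                )
        if self.baseline.compartment != BLOOD:
            raise ValueError("baseline must be a blood sample")
        if self.biopsy is not None and self.biopsy.compartment != TUMOR_BIOPSY:
            raise ValueError("biopsy sample must have compartment tumor_biopsy")
        days = [f.timepoint_days for f in self.followups]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("follow-up timepoints must be strictly increasing")
        if any(d <= self.baseline.timepoint_days for d in days):
            raise ValueError("follow-ups must postdate the baseline")

    @property
    def followup_days(self) -> list[int]:
        return [f.timepoint_days for f in self.followups]

    def followup_at(self, timepoint_days: int) -> RepertoireSample:
        for f in self.followups:
            if f.timepoint_days == timepoint_days:
                return f
        raise KeyError(
            f"subject {self.subject_id!r} has no follow-up at day {timepoint_days}"
        )


@dataclasses.dataclass
class ClonotypeTrajectory:
    """One clonotype's frequency across a patient's blood timepoints.

    ``freq_by_timepoint`` maps timepoint day -> frequency (0 when the clone
    was undetected in that draw); ``expansion_by_timepoint`` maps each
    follow-up day to its category versus baseline; ``is_til`` is ``None``
    (unknown) exactly when the patient has no biopsy.
    """

    rearrangement: str
    subject_id: str
    freq_by_timepoint: dict[int, float]
    is_til: bool | None
    expansion_by_timepoint: dict[int, str]

    def expanded_at(self, timepoint_days: int) -> bool:
        try:
            return self.expansion_by_timepoint[timepoint_days] != NONE
        except KeyError:
            raise KeyError(
                f"trajectory has no expansion call at day {timepoint_days}"
            ) from None


@dataclasses.dataclass(frozen=True)
class CohortExpansionStats:
    """Cohort-level spread of per-patient expanded-clonotype counts."""

    n_patients: int
    median: float
    minimum: int
    maximum: int
    iqr: float


def classify_til(rearrangement: str, biopsy: RepertoireSample) -> bool:
    """True iff the clonotype has >= 1 productive template in the biopsy."""
    df = biopsy.data
    hit = df[(df["rearrangement"] == rearrangement) & (df["status"] == PRODUCTIVE)]
    return bool((hit["templates"] > 0).any())


def _til_set(biopsy: RepertoireSample) -> set[str]:
    df = biopsy.data
    df = df[(df["status"] == PRODUCTIVE) & (df["templates"] > 0)]
    return set(df["rearrangement"])


def build_trajectories(
    timeline: PatientTimeline, criteria: ExpansionCriteria | None = None
) -> list[ClonotypeTrajectory]:
    """One trajectory per clonotype in the union of the blood samples.

    Every follow-up gets an expansion category versus the same baseline;
    the TIL flag comes from the biopsy when one exists and is ``None``
    otherwise.
    """
    c = criteria or ExpansionCriteria()
    blood = [timeline.baseline, *timeline.followups]

    freq_cols: dict[int, pd.Series] = {}
    union: pd.Index | None = None
    for s in blood:
        df = s.data
        ser = (
            pd.Series(df["frequency"].to_numpy(), index=df["rearrangement"])
            if s.has_frequencies
            else pd.Series(dtype=float)
        )
        freq_cols[s.timepoint_days] = ser
        union = ser.index if union is None else union.union(ser.index)
    assert union is not None

    cat_cols: dict[int, pd.Series] = {}
    for f in timeline.followups:
        res = call_expansions(timeline.baseline, f, c)
        cat_cols[f.timepoint_days] = pd.Series(
            res.calls["category"].to_numpy(), index=res.calls["rearrangement"]
        )

    tils = _til_set(timeline.biopsy) if timeline.biopsy is not None else None

    days = sorted(freq_cols)
    freq_mat = {d: freq_cols[d].reindex(union).fillna(0.0).to_numpy() for d in days}
    cat_mat = {
        d: cat_cols[d].reindex(union).fillna(NONE).to_numpy() for d in sorted(cat_cols)
    }
    out: list[ClonotypeTrajectory] = []
    for i, rearr in enumerate(union):
        out.append(
            ClonotypeTrajectory(
                rearrangement=rearr,
                subject_id=timeline.subject_id,
                freq_by_timepoint={d: float(freq_mat[d][i]) for d in days},
                is_til=None if tils is None else rearr in tils,
                expansion_by_timepoint={d: str(cat_mat[d][i]) for d in cat_mat},
            )
        )
    return out


def persistent_expansions(
    trajectories: Sequence[ClonotypeTrajectory],
    t_early: int,
    t_late: int,
) -> list[ClonotypeTrajectory]:
    """Trajectories expanded (vs baseline) at *both* timepoints.

    A clone first qualifying only at ``t_late`` is expanded there but not
    persistent.  Raises ``KeyError`` if either timepoint is absent from
    every trajectory's expansion map.
    """
    trajs = list(trajectories)
    if trajs:
        known = set().union(*(t.expansion_by_timepoint.keys() for t in trajs))
        for t in (t_early, t_late):
            if t not in known:
                raise KeyError(f"no expansion calls exist at day {t}")
    return [
        t
        for t in trajs
        if t.expansion_by_timepoint.get(t_early, NONE) != NONE
        and t.expansion_by_timepoint.get(t_late, NONE) != NONE
    ]


def summarize_expansion_by_patient(
    timelines: Sequence[PatientTimeline],
    criteria: ExpansionCriteria | None = None,
    at: int = 30,
) -> tuple[pd.DataFrame, CohortExpansionStats]:
    """Per-patient expansion counts at one follow-up day + cohort spread.

    Patients lacking a follow-up at ``at`` are skipped with a warning and
    excluded from the cohort median/range/IQR denominators (this mirrors
    per-timepoint availability in longitudinal cohorts).  TIL splits are
    reported for patients with biopsies and are null otherwise.
    """
    c = criteria or ExpansionCriteria()
    rows = []
    for tl in timelines:
        try:
            followup = tl.followup_at(at)
        except KeyError:
            warnings.warn(
                f"subject {tl.subject_id!r} has no follow-up at day {at}; skipped",
                stacklevel=2,
            )
            continue
        res = call_expansions(tl.baseline, followup, c)
        expanded = res.calls[res.calls["category"] != NONE]
        if tl.biopsy is not None:
            tils = _til_set(tl.biopsy)
            n_til = int(expanded["rearrangement"].isin(tils).sum())
            n_nontil = len(expanded) - n_til
        else:
            n_til = n_nontil = None
        rows.append(
            {
                "subject_id": tl.subject_id,
                "n_new": res.n_new,
                "n_increased": res.n_increased,
                "n_expanded": res.n_new + res.n_increased,
                "n_til_expanded": n_til,
                "n_nontil_expanded": n_nontil,
            }
        )
    if not rows:
        raise ValueError(f"no patient has a follow-up at day {at}")
    per_patient = pd.DataFrame(rows)
    counts = per_patient["n_expanded"].to_numpy(dtype=float)
    q1, q3 = np.percentile(counts, [25, 75])
    stats_ = CohortExpansionStats(
        n_patients=len(per_patient),
        median=float(np.median(counts)),
        minimum=int(counts.min()),
        maximum=int(counts.max()),
        iqr=float(q3 - q1),
    )
    return per_patient, stats_


def export_pairwise_scatter(
    timeline: PatientTimeline,
    at: int,
    criteria: ExpansionCriteria | None = None,
) -> pd.DataFrame:
    """Plot-ready baseline-vs-follow-up frequency table (in percent).

    One row per union clonotype with columns ``rearrangement,
    baseline_freq_pct, followup_freq_pct, category``; the category matches
    :func:`clonotrack.expansion.classify_expansion` under the same criteria.
    """
    c = criteria or ExpansionCriteria()
    res = call_expansions(timeline.baseline, timeline.followup_at(at), c)
    calls = res.calls
    return pd.DataFrame(
        {
            "rearrangement": calls["rearrangement"],
            "baseline_freq_pct": calls["baseline_freq"] * 100.0,
            "followup_freq_pct": calls["followup_freq"] * 100.0,
            "category": calls["category"],
        }
    )


def trajectories_to_frame(
    trajectories: Sequence[ClonotypeTrajectory],
) -> pd.DataFrame:
    """Long-format trajectory table.

    Columns: ``subject_id, rearrangement, timepoint_days, frequency,
    is_til, category`` (category empty at the baseline timepoint, which has
    no call by definition).
    """
    rows = []
    for t in trajectories:
        for day, freq in sorted(t.freq_by_timepoint.items()):
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "rearrangement": t.rearrangement,
                    "timepoint_days": day,
                    "frequency": freq,
                    "is_til": t.is_til,
                    "category": t.expansion_by_timepoint.get(day, ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "rearrangement",
            "timepoint_days",
            "frequency",
            "is_til",
            "category",
        ],
    )
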