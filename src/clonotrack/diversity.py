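"""Repertoire diversity: Simpson dominance/clonality and group comparisons.

Simpson dominance is ``sum(p_i**2)`` over clonal frequencies; Simpson
clonality is its square root, ranging from near 0 (polyclonal) to 1
(monoclonal).  No unseen-species (small-sample) correction is applied, so
values are comparable with the plain immunoSEQ "Simpson clonality"
convention.

Group comparisons use the two-tailed Wilcoxon rank-sum test, with a
Shapiro-Wilk normality p-value reported alongside for context (it never
gates the choice of test).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .repertoire import DegenerateSampleError, RepertoireSample

__all__ = [
    "ClonalitySummary",
    "GroupComparisonResult",
    "simpson_dominance",
    "simpson_clonality",
    "compare_clonality",
]

_SUM_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class ClonalitySummary:
    """Simpson diversity summary for one sample.

    ``simpson_clonality == sqrt(simpson_dominance)``; ``richness`` is the
    number of distinct productive clonotypes.  For a uniform repertoire of
    N clones the dominance is exactly 1/N (its minimum for that richness).
    """

    sample_id: str
    simpson_dominance: float
    simpson_clonality: float
    richness: int


@dataclasses.dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    p_value: float
    method: str
    normality_p: float


def simpson_dominance(frequencies) -> float:
    """Return ``sum(p_i**2)`` over a frequency vector summing to 1.

    Raises ``ValueError`` on an empty vector, negative entries, or a sum
    departing from 1 by more than 1e-9.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(f < 0):
        raise ValueError("negative frequency")
    total = float(f.sum())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"frequencies sum to {total!r}, not 1")
    return float(np.dot(f, f))


def simpson_clonality(sample: RepertoireSample) -> ClonalitySummary:
    """Simpson clonality (sqrt of Simpson dominance) of one sample.

    The sample must already be productive-filtered with frequencies
    computed (see :mod:`clonotrack.repertoire`).
    """
    if len(sample) == 0:
        raise DegenerateSampleError(
            f"sample {sample.sample_id!r} has no clonotypes"
        )
    if not sample.has_frequencies:
        raise ValueError(
            "sample has no computed frequencies; run compute_frequencies first"
        )
    dom = simpson_dominance(sample.data["frequency"].to_numpy())
    return ClonalitySummary(
        sample_id=sample.sample_id,
        simpson_dominance=dom,
        simpson_clonality=math.sqrt(dom),
        richness=len(sample),
    )


def _shapiro_p(values: np.ndarray) -> float:
    # Shapiro-Wilk needs >= 3 observations and some spread
    if values.size < 3 or np.ptp(values) == 0:
        return float("nan")
    return float(stats.shapiro(values).pvalue)


def compare_clonality(
    group_a, group_b, paired: bool = False
) -> GroupComparisonResult:
    """Two-tailed Wilcoxon comparison of two sets of clonality values.

    For independent groups (the default) this is the rank-sum
    (Mann-Whitney) test, computed exactly when both groups have at most 12
    observations and no ties occur, and by the tie-corrected normal
    approximation otherwise.  With ``paired=True`` the signed-rank test is
    used instead (groups must align element-wise).

    The Shapiro-Wilk p-value of the pooled values is reported for context
    only; it does not select the test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    normality_p = _shapiro_p(np.concatenate([a, b]))

    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length groups")
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return GroupComparisonResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            method="wilcoxon_signed_rank_two_tailed",
            normality_p=normality_p,
        )

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = a.size <= 12 and b.size <= 12 and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return GroupComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="wilcoxon_rank_sum_two_tailed",
        normality_p=normality_p,
    )
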