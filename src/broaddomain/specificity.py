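"""Cell-type-specific peak calling, specificity enrichment and cohort overlap.

A peak of the target cell type is "specific" when no peak of any other cell
type's pooled set overlaps it (presence/absence, 1-bp default).  Enrichment
of specificity among the broadest peaks is the ratio of specificity rates
(broadest vs all peaks), tested with Fisher's exact test on the 2x2 table
[[a, b-a], [c, d-c]] where a/b are specific/total among the broadest and c/d
among all peaks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_intervals import PeakSet, intersect_flags

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "call_cell_type_specific",
    "specificity_enrichment",
    "cohort_reproducibility",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 specificity enrichment: counts, rate ratio, odds ratio, Fisher p."""

    a: int  # specific among broadest
    b: int  # total broadest
    c: int  # specific among all peaks
    d: int  # total peaks
    fold: float
    odds_ratio: float
    p_value: float

    def __post_init__(self):
        if not (0 <= self.a <= self.b):
            raise ValueError("need 0 <= a <= b")
        if not (0 <= self.c <= self.d):
            raise ValueError("need 0 <= c <= d")


def call_cell_type_specific(
    target: PeakSet, others: list[PeakSet], min_bp: int = 1
) -> PeakSet:
    """Peaks of ``target`` overlapping no peak of any other cell type."""
    if not others:
        raise ValueError("need at least one other-cell-type peak set")
    if len(target) == 0:
        logger.warning("target peak set is empty; specificity call is empty")
        return PeakSet([], provenance=f"{target.provenance}|specific")
    excluded = np.zeros(len(target), dtype=bool)
    for other in others:
        excluded |= intersect_flags(target, other, min_bp=min_bp)
    return target.subset(~excluded, provenance=f"{target.provenance}|specific")


def specificity_enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Enrichment of cell-type specificity among the broadest peaks.

    fold = (a/b) / (c/d); two-sided Fisher exact p on [[a, b-a], [c, d-c]];
    the sample (unconditional) odds ratio is reported.  ``c == 0`` with
    ``a > 0`` yields fold = +inf.
    """
    if b <= 0 or d <= 0:
        raise ValueError("denominators b and d must be positive")
    if a > b or c > d:
        raise ValueError("numerators cannot exceed denominators")
    if c == 0:
        fold = math.inf if a > 0 else float("nan")
    else:
        fold = (a / b) / (c / d)
    if (b - a) == 0 or c == 0:
        odds = math.inf if a * (d - c) > 0 else float("nan")
    else:
        odds = (a * (d - c)) / ((b - a) * c)
    _, p = stats.fisher_exact([[a, b - a], [c, d - c]], alternative="two-sided")
    return EnrichmentResult(a=a, b=b, c=c, d=d, fold=fold, odds_ratio=odds,
                            p_value=float(p))


def cohort_reproducibility(
    specific_a: PeakSet, specific_b: PeakSet, min_bp: int = 1
) -> tuple[int, PeakSet]:
    """Peaks of cohort A's specific set that recur in cohort B's.

    Returns (count, the overlapping subset of A).  The symmetric count (B
    against A) is logged when it differs, since multi-overlaps can make the
    two directions disagree slightly.
    """
    flags = intersect_flags(specific_a, specific_b, min_bp=min_bp)
    count = int(flags.sum())
    reverse = int(intersect_flags(specific_b, specific_a, min_bp=min_bp).sum())
    if reverse != count:
        logger.info(
            "cohort overlap is direction-dependent: A-in-B=%d, B-in-A=%d",
            count, reverse,
        )
    shared = specific_a.subset(flags, provenance=(
        f"{specific_a.provenance}&{specific_b.provenance}"))
    return count, shared
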