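"""Cross-species conservation of broad peaks in a shared coordinate frame.

Species peak sets must already be mapped into one reference frame (liftOver
is out of scope; the synthetic generator emulates it).  ``shared_across``
keeps the peaks of the first set overlapped by every other set;
``conservation_summary`` reports how many of those shared non-human peaks
match the human broadest set, as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_intervals import PeakSet, intersect_count, intersect_flags

__all__ = ["ConservationSummary", "shared_across", "conservation_summary"]


@dataclass(frozen=True)
class ConservationSummary:
    n_shared_nonhuman: int
    n_matched_human: int

    def __post_init__(self):
        if self.n_shared_nonhuman <= 0:
            raise ValueError("shared non-human set must be nonempty")
        if not (0 <= self.n_matched_human <= self.n_shared_nonhuman):
            raise ValueError("matched count out of range")

    @property
    def percent_matched(self) -> float:
        return 100.0 * self.n_matched_human / self.n_shared_nonhuman


def shared_across(sets: Sequence[PeakSet], min_bp: int = 1) -> PeakSet:
    """Peaks of the first set overlapped by at least one peak in EVERY other set.

    Reported in the first set's coordinates.
    """
    if len(sets) < 2:
        raise ValueError("need at least two peak sets")
    first = sets[0]
    keep = np.ones(len(first), dtype=bool)
    for other in sets[1:]:
        keep &= intersect_flags(first, other, min_bp=min_bp)
    return first.subset(keep, provenance=f"{first.provenance}|shared")


def conservation_summary(
    shared_nonhuman: PeakSet, human_broadest: PeakSet, min_bp: int = 1
) -> ConservationSummary:
    """How many cross-species shared peaks match the human broadest set."""
    if len(shared_nonhuman) == 0:
        raise ValueError("shared non-human peak set is empty")
    matched = intersect_count(shared_nonhuman, human_broadest, min_bp=min_bp)
    return ConservationSummary(
        n_shared_nonhuman=len(shared_nonhuman), n_matched_human=matched
    )
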