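"""Genome-map (optical mapping) structural-variant comparison.

Insertion/deletion calls from two independent calling algorithms (a
split-and-realign caller and a global-alignment outlier caller) are reduced
to a conservative consensus (detected by both), cross-compared between cell
lines with a 50% reciprocal size-overlap cutoff to find candidate cell-line-
specific calls, and curated against single-molecule support (molecules
supporting the variant allele in the line of interest, none in any other
line).  The N50 map-contiguity statistic is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SVCall",
    "reciprocal_overlap",
    "consensus_calls",
    "find_cell_line_specific",
    "curate_specific",
    "compute_N50",
]


@dataclass(frozen=True)
class SVCall:
    """One insertion or deletion from one calling algorithm in one sample.

    ``start``/``end`` give the 0-based half-open reference span; for an
    insertion the span is the breakpoint region and ``size`` the inserted
    length, for a deletion ``size`` equals end - start.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    size: int
    svtype: str            # "insertion" | "deletion"
    algorithm: str = ""    # "split" | "global"
    call_id: str = ""
    #: optional per-sample supporting single-molecule counts
    molecule_support: Optional[Mapping[str, int]] = field(default=None, compare=False)

    def __post_init__(self):
        if self.svtype not in ("insertion", "deletion"):
            raise ValueError(f"bad svtype {self.svtype!r}")
        if self.start >= self.end and self.svtype == "deletion":
            raise ValueError("deletion requires start < end")
        if self.size <= 0:
            raise ValueError("size must be positive")


def reciprocal_overlap(
    a: SVCall,
    b: SVCall,
    cutoff: float = 0.5,
    insertion_window: int = 10_000,
) -> tuple[float, float, bool]:
    """Reciprocal size-overlap between two SV calls.

    Deletions: the reference-span intersection divided by each call's size;
    pass when min(fraction_a, fraction_b) >= cutoff.  Insertions have no
    meaningful reference span, so the size ratio min/max stands in for both
    fractions and breakpoints must additionally lie within
    ``insertion_window``.  Types and chromosomes must match.
    """
    if a.svtype != b.svtype or a.chrom != b.chrom:
        return 0.0, 0.0, False
    if a.svtype == "deletion":
        overlap = max(0, min(a.end, b.end) - max(a.start, b.start))
        fa = overlap / a.size
        fb = overlap / b.size
        return fa, fb, min(fa, fb) >= cutoff
    ratio = min(a.size, b.size) / max(a.size, b.size)
    near = abs(a.start - b.start) <= insertion_window
    return ratio, ratio, bool(near and ratio >= cutoff)


def consensus_calls(
    calls_split: Sequence[SVCall],
    calls_global: Sequence[SVCall],
    cutoff: float = 0.5,
    insertion_window: int = 10_000,
) -> list[SVCall]:
    """Conservative dual-algorithm consensus for one sample.

    A split-algorithm call is retained iff some global-algorithm call passes
    the reciprocal-overlap test with it; the retained call keeps the
    split-algorithm span.
    """
    samples = {c.sample_id for c in calls_split} | {c.sample_id for c in calls_global}
    if len(samples) > 1:
        raise ValueError(f"consensus_calls expects one sample, got {sorted(samples)}")
    out = []
    for a in calls_split:
        for b in calls_global:
            if reciprocal_overlap(a, b, cutoff, insertion_window)[2]:
                out.append(a)
                break
    return out


def find_cell_line_specific(
    consensus_by_sample: Mapping[str, Sequence[SVCall]],
    cutoff: float = 0.5,
    insertion_window: int = 10_000,
) -> list[SVCall]:
    """Calls with no reciprocal-overlap match in any other sample's set."""
    if len(consensus_by_sample) < 2:
        raise ValueError("need at least two samples to define specificity")
    out = []
    for sample, calls in consensus_by_sample.items():
        for a in calls:
            matched = any(
                reciprocal_overlap(a, b, cutoff, insertion_window)[2]
                for other, bs in consensus_by_sample.items()
                if other != sample
                for b in bs
            )
            if not matched:
                out.append(a)
    return sorted(out, key=lambda c: (c.chrom, c.start, c.end, c.sample_id))


def curate_specific(
    call: SVCall, molecule_support: Mapping[str, int]
) -> tuple[bool, str]:
    """Molecule-level curation of a candidate cell-line-specific call.

    Passes iff (a) at least one molecule supports the variant allele in the
    call's own sample, and (b) no molecule supports it in any other sample.
    Returns (passed, reason) with reason one of "", "no_support_in_line",
    "support_in_other_sample:<sample>".
    """
    if call.sample_id not in molecule_support:
        raise ValueError(f"no molecule-support entry for {call.sample_id!r}")
    if molecule_support[call.sample_id] < 1:
        return False, "no_support_in_line"
    for sample, n in molecule_support.items():
        if sample != call.sample_id and n > 0:
            return False, f"support_in_other_sample:{sample}"
    return True, ""


def compute_N50(lengths: Iterable[float]) -> float:
    """N50 of a collection of map/contig lengths.

    The largest length L in the collection such that maps of length >= L
    together cover more than half the total length.
    """
    arr = np.sort(np.asarray(list(lengths), dtype=float))[::-1]
    if arr.size == 0:
        raise ValueError("empty length list")
    if np.any(arr <= 0):
        raise ValueError("lengths must be positive")
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    idx = np.nonzero(cum > half)[0][0]
    return float(arr[idx])
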