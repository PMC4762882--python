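"""Genomic interval containers with vectorized stabbing/overlap queries.

Tracks are stored per chromosome as start-sorted arrays with a running
maximum of interval ends, which answers "does [qstart, qend) overlap
anything" by binary search and supports bulk queries over variant tables
with a couple of searchsorted calls per chromosome.  Intervals are 0-based
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = ["GenomicInterval", "IntervalIndex", "read_bed", "write_bed"]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int   # 0-based inclusive
    end: int     # 0-based exclusive
    label: str = ""
    pwm_id: Optional[str] = None

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start},{self.end})")


class IntervalIndex:
    """Immutable per-chromosome interval set supporting overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._chroms: dict[str, tuple] = {}
        self._n = 0
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._chroms[chrom] = (starts, ends, np.maximum.accumulate(ends), ivs)
            self._n += len(ivs)

    def __len__(self) -> int:
        return self._n

    def __iter__(self):
        for chrom in sorted(self._chroms):
            yield from self._chroms[chrom][3]

    @property
    def chroms(self):
        return set(self._chroms)

    def overlapping(self, chrom: str, qstart: int, qend: int) -> list[GenomicInterval]:
        """All intervals overlapping [qstart, qend), in start order."""
        if chrom not in self._chroms or qend <= qstart:
            return []
        starts, ends, cummax, ivs = self._chroms[chrom]
        hi = int(np.searchsorted(starts, qend, side="left"))
        out = []
        j = hi - 1
        while j >= 0 and cummax[j] > qstart:
            if ends[j] > qstart:
                out.append(ivs[j])
            j -= 1
        out.reverse()
        return out

    def overlaps_any(self, chroms, qstarts, qends) -> np.ndarray:
        """Vectorized: does each query interval overlap any track interval?"""
        chroms = np.asarray(chroms)
        qstarts = np.asarray(qstarts, dtype=np.int64)
        qends = np.asarray(qends, dtype=np.int64)
        hit = np.zeros(chroms.size, dtype=bool)
        for chrom in np.unique(chroms):
            if chrom not in self._chroms:
                continue
            starts, ends, cummax, _ = self._chroms[chrom]
            mask = chroms == chrom
            hi = np.searchsorted(starts, qends[mask], side="left")
            ok = hi > 0
            # for sorted non-overlapping tracks the candidate interval is
            # simply the last one starting before qend; the cummax handles
            # nested/overlapping tracks for the existence test
            sub = np.zeros(ok.size, dtype=bool)
            sub[ok] = cummax[hi[ok] - 1] > qstarts[mask][ok]
            # cummax > qstart guarantees overlap exists only when every end
            # contributing to cummax belongs to an interval starting < qend,
            # which holds by construction of hi
            hit[mask] = sub
        return hit

    def covers_points(self, chroms, pos0) -> np.ndarray:
        """Vectorized point-stabbing (0-based positions)."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        return self.overlaps_any(chroms, pos0, pos0 + 1)


def read_bed(path) -> IntervalIndex:
    """Read a BED3+ file; column 4 (if present) becomes the label and
    column 5 the PWM identifier."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            pwm = parts[4] if len(parts) > 4 and parts[4] not in (".", "") else None
            ivs.append(GenomicInterval(chrom, start, end, label, pwm))
    return IntervalIndex(ivs)


def write_bed(intervals: Iterable[GenomicInterval], path):
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.label or "."]
            if iv.pwm_id is not None:
                cols.append(iv.pwm_id)
            fh.write("\t".join(cols) + "\n")
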