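"""Viral vector integration-site detection from discordant read pairs.

An integrating vector leaves paired-end reads with one end mapped to the
host genome and the mate mapped to the vector sequence.  Host-anchored ends
of such pairs cluster around the junction; clusters with enough flanking
support (at least five reads on either end by default) are reported as
integration sites and annotated genic/intergenic against a gene track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalIndex

__all__ = ["ReadPair", "IntegrationSite", "detect_integration_sites", "annotate_sites"]

#: columns of a read-pair table
PAIR_COLUMNS = ["name", "chrom", "pos", "strand", "virus", "vpos", "vstrand", "mapq"]


@dataclass(frozen=True)
class ReadPair:
    """A host/viral discordant pair; ``pos`` is the 1-based host position."""

    name: str
    chrom: str
    pos: int
    strand: str           # host strand, "+" or "-"
    virus: str
    vpos: int = 1
    vstrand: str = "+"
    mapq: int = 60

    def __post_init__(self):
        if self.pos < 1 or self.vpos < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if self.strand not in "+-" or self.vstrand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class IntegrationSite:
    chrom: str
    window: tuple          # (start, end), 0-based half-open
    virus: str
    left_support: int      # forward-strand host anchors (upstream flank)
    right_support: int     # reverse-strand host anchors (downstream flank)
    annotation: str = "intergenic"
    gene: Optional[str] = None

    @property
    def support(self) -> int:
        return self.left_support + self.right_support


def _pairs_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs
    return pd.DataFrame([vars(p) for p in pairs], columns=PAIR_COLUMNS)


def detect_integration_sites(
    pairs,
    min_support: int = 5,
    cluster_window: int = 500,
    side_rule: str = "either",
) -> list[IntegrationSite]:
    """Cluster host-anchored pairs and report supported integration sites.

    Pairs on the same chromosome for the same virus whose host positions lie
    within ``cluster_window`` of the cluster's first (leftmost) member form
    one candidate, so a reported window never exceeds the cluster window.  A
    candidate is reported when its best-supported flank reaches
    ``min_support`` ("either"-end rule; "both" demands it of both flanks).
    Output is sorted by coordinate and independent of input order.
    """
    if cluster_window < 0:
        raise ValueError("cluster_window must be non-negative")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if side_rule not in ("either", "both"):
        raise ValueError("side_rule must be 'either' or 'both'")
    df = _pairs_frame(pairs)
    if df.empty:
        return []
    df = df.sort_values(["virus", "chrom", "pos", "strand", "name"], kind="mergesort")

    sites: list[IntegrationSite] = []
    for (virus, chrom), sub in df.groupby(["virus", "chrom"], sort=True):
        pos = sub["pos"].to_numpy()
        strand = sub["strand"].to_numpy()
        start_i = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[start_i] > cluster_window:
                cpos = pos[start_i:i]
                cstr = strand[start_i:i]
                left = int(np.sum(cstr == "+"))
                right = int(np.sum(cstr == "-"))
                ok = (max(left, right) if side_rule == "either" else min(left, right)) >= min_support
                if ok:
                    sites.append(
                        IntegrationSite(
                            chrom=chrom,
                            window=(int(cpos.min()) - 1, int(cpos.max())),
                            virus=virus,
                            left_support=left,
                            right_support=right,
                        )
                    )
                start_i = i
    sites.sort(key=lambda s: (s.chrom, s.window, s.virus))
    return sites


def annotate_sites(
    sites: Sequence[IntegrationSite], gene_track: IntervalIndex
) -> list[IntegrationSite]:
    """Mark each site genic when its window overlaps any gene interval
    (any-overlap rule), attaching the first overlapping gene's name."""
    out = []
    for s in sites:
        hits = gene_track.overlapping(s.chrom, *s.window)
        annotated = IntegrationSite(
            chrom=s.chrom,
            window=s.window,
            virus=s.virus,
            left_support=s.left_support,
            right_support=s.right_support,
            annotation="genic" if hits else "intergenic",
            gene=hits[0].label if hits else None,
        )
        out.append(annotated)
    return out
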