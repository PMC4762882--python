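"""Dual-caller merge, line-unique variant identification, exclusion filters
and confidence classification.

Two emulated callers feed this module: a multisample population caller
("hc", HaplotypeCaller-style, specificity-tuned) and a tumour-normal pairwise
caller ("mutect", sensitivity-tuned, run per derived line against the
parental fibroblast population, with a KEEP/REJECT judgment).  A variant is
*unique* to a line when that line is the only one of the ten samples (nine
derived lines plus the parental population) carrying a non-reference call at
its exact (chrom, pos, ref, alt) key.

Confidence is assigned on two independent axes, each with its own
coverage/VAF windows:

* ``caller_set`` — Set 1: called by both callers (MuTect KEEP); Set 2:
  MuTect-only with depth 20-60x and VAF 0.4-0.6; Set 3: VAF 0.2-0.4 with
  depth 30-50x.
* ``depth_vaf_class`` — HIGH: 40-60x and VAF 0.4-0.6; LOW: 20-40x and VAF
  0.4-0.6; SUBCLONAL: VAF 0.2-0.4 at 40-60x.

All windows are closed on the lower bound; where two windows abut (depth 40,
VAF 0.4) the boundary value resolves to the higher-confidence class.
Downstream burden analyses are restricted to Set 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalIndex

__all__ = [
    "VariantKey",
    "VariantCall",
    "CallerSet",
    "DepthVafClass",
    "ConfidenceLabel",
    "ClassificationWindows",
    "minimal_representation",
    "merge_caller_outputs",
    "identify_unique_variants",
    "apply_exclusion_filters",
    "classify_confidence",
    "classify_calls",
]

_BASES = set("ACGT")

#: columns of the unified per-sample call table
CALL_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_depth",
    "vaf", "vtype", "hc_called", "mutect_called", "mutect_keep", "tranche_pass",
]


@dataclass(frozen=True, order=True)
class VariantKey:
    """Site identity used for exact-coordinate intersection across callers."""

    chrom: str
    pos: int          # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _BASES:
                raise ValueError(f"invalid allele {allele!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def vtype(self) -> str:
        if len(self.alt) > len(self.ref):
            return "insertion"
        if len(self.alt) < len(self.ref):
            return "deletion"
        return "SNV"


def minimal_representation(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalize an indel to its minimal representation.

    Shared trailing then leading bases are trimmed (keeping at least one base
    in each allele), advancing ``pos`` past trimmed leading bases, so that the
    same event called with different padding intersects on an exact key.
    Full left-alignment additionally requires the reference sequence and is
    applied upstream when one is available.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


class CallerSet(str, Enum):
    SET1 = "SET1"
    SET2 = "SET2"
    SET3 = "SET3"
    UNCLASSIFIED = "UNCLASSIFIED"


class DepthVafClass(str, Enum):
    HIGH = "HIGH"
    LOW = "LOW"
    SUBCLONAL = "SUBCLONAL"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ConfidenceLabel:
    caller_set: CallerSet
    depth_vaf_class: DepthVafClass


@dataclass(frozen=True)
class ClassificationWindows:
    """Coverage/VAF windows for both classification axes.

    Each window is (low, high); lows are inclusive.  Highs are inclusive
    except where a sibling window starts at the same value, in which case the
    boundary belongs to the higher class (depth 40 is HIGH not LOW, VAF 0.4
    is clonal not subclonal).
    """

    set2_depth: tuple = (20.0, 60.0)
    set2_vaf: tuple = (0.4, 0.6)
    set3_depth: tuple = (30.0, 50.0)
    set3_vaf: tuple = (0.2, 0.4)      # upper bound open
    high_depth: tuple = (40.0, 60.0)
    low_depth: tuple = (20.0, 40.0)   # upper bound open
    clonal_vaf: tuple = (0.4, 0.6)
    subclonal_depth: tuple = (40.0, 60.0)
    subclonal_vaf: tuple = (0.2, 0.4)  # upper bound open


DEFAULT_WINDOWS = ClassificationWindows()


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample, with caller provenance flags."""

    key: VariantKey
    sample_id: str
    depth: int
    alt_depth: int
    hc_called: bool = False
    mutect_called: bool = False
    mutect_keep: bool = False
    tranche_pass: bool = True

    def __post_init__(self):
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError("require 0 <= alt_depth <= depth")

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth

    @property
    def vtype(self) -> str:
        return self.key.vtype


# ---------------------------------------------------------------------------
# merging caller outputs
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table lacks columns {missing}")


def merge_caller_outputs(
    hc_table: pd.DataFrame,
    mutect_tables_per_line: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Merge the population-caller table with per-line pairwise-caller tables
    into one record per (sample, variant key) with provenance flags.

    ``hc_table`` columns: sample_id, chrom, pos, ref, alt, depth, alt_depth,
    tranche_pass.  Each MuTect table: chrom, pos, ref, alt, depth, alt_depth,
    judgment (KEEP/REJECT).  Records from the two callers are matched only on
    exact key equality; duplicate records within one caller that disagree on
    depth are an input error.
    """
    _require_columns(hc_table, ["sample_id", "chrom", "pos", "ref", "alt",
                                "depth", "alt_depth"], "hc")
    frames = []
    hc = hc_table.copy()
    if "tranche_pass" not in hc.columns:
        hc["tranche_pass"] = True
    hc["hc_called"] = True
    hc["mutect_called"] = False
    hc["mutect_keep"] = False
    frames.append(hc)
    for sample, mt in mutect_tables_per_line.items():
        _require_columns(mt, ["chrom", "pos", "ref", "alt", "depth",
                              "alt_depth", "judgment"], f"mutect[{sample}]")
        mt = mt.copy()
        mt["sample_id"] = sample
        mt["hc_called"] = False
        mt["mutect_called"] = True
        mt["mutect_keep"] = mt["judgment"].astype(str).str.upper() == "KEEP"
        mt["tranche_pass"] = True
        frames.append(mt.drop(columns=["judgment"]))

    allc = pd.concat(frames, ignore_index=True)
    keycols = ["sample_id", "chrom", "pos", "ref", "alt"]
    dup = allc.groupby(keycols)[["depth", "alt_depth"]].nunique()
    conflict = dup[(dup > 1).any(axis=1)]
    if len(conflict):
        raise ValueError(
            f"conflicting duplicate records for {conflict.index.tolist()[:5]}"
        )
    merged = allc.groupby(keycols, as_index=False).agg(
        depth=("depth", "first"),
        alt_depth=("alt_depth", "first"),
        hc_called=("hc_called", "any"),
        mutect_called=("mutect_called", "any"),
        mutect_keep=("mutect_keep", "any"),
        tranche_pass=("tranche_pass", "all"),
    )
    merged["vaf"] = merged["alt_depth"] / merged["depth"]
    lens_a = merged["alt"].str.len()
    lens_r = merged["ref"].str.len()
    merged["vtype"] = np.select(
        [lens_a > lens_r, lens_a < lens_r], ["insertion", "deletion"], "SNV"
    )
    return merged[CALL_COLUMNS].sort_values(
        ["chrom", "pos", "ref", "alt", "sample_id"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# line-unique variants
# ---------------------------------------------------------------------------

class MissingGenotypeError(ValueError):
    pass


def identify_unique_variants(
    calls: pd.DataFrame,
    all_sample_ids: Sequence[str],
    parental_id: str,
    mode: str = "lenient",
) -> dict[str, set[VariantKey]]:
    """Map each sample to the variant keys unique to it.

    A key is unique to sample s when s is the only sample, out of all
    ``all_sample_ids`` (parental included), with a non-reference call there.
    Keys seen in two or more samples, or in the parental sample, are unique
    to nobody.  In lenient mode (default) a sample with no record at a key is
    taken as reference; strict mode demands an explicit record (alt_depth 0
    for reference calls) from every sample at every key and raises otherwise.
    """
    ids = list(all_sample_ids)
    if not ids:
        raise ValueError("empty sample list")
    if parental_id not in ids:
        raise ValueError("parental sample must be among all_sample_ids")
    if mode not in ("lenient", "strict"):
        raise ValueError("mode must be 'lenient' or 'strict'")

    nonref = calls[calls["alt_depth"] > 0]
    keycols = ["chrom", "pos", "ref", "alt"]
    if mode == "strict":
        per_key = calls.groupby(keycols)["sample_id"].nunique()
        short = per_key[per_key < len(ids)]
        if len(short):
            raise MissingGenotypeError(
                f"strict mode: {len(short)} keys lack records for every sample, "
                f"e.g. {short.index.tolist()[:3]}"
            )
    grp = nonref.groupby(keycols)["sample_id"].agg(["nunique", "first"])
    sole = grp[(grp["nunique"] == 1) & (grp["first"] != parental_id)]
    result: dict[str, set[VariantKey]] = {s: set() for s in ids if s != parental_id}
    for (chrom, pos, ref, alt), row in sole.iterrows():
        result[row["first"]].add(VariantKey(chrom, int(pos), ref, alt))
    return result


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------

def apply_exclusion_filters(
    calls: pd.DataFrame,
    low_complexity: Optional[IntervalIndex] = None,
    known_variants: Optional[Iterable[VariantKey]] = None,
    require_tranche: bool = False,
) -> pd.DataFrame:
    """Drop calls in low-complexity regions, calls present in the known-
    variant (dbSNP-style) exclusion set, and — when ``require_tranche`` —
    calls failing the recalibration tranche.  Order-preserving and
    idempotent."""
    keep = np.ones(len(calls), dtype=bool)
    if low_complexity is not None:
        ref_len = calls["ref"].str.len().to_numpy()
        start0 = calls["pos"].to_numpy() - 1
        keep &= ~low_complexity.overlaps_any(
            calls["chrom"].to_numpy(), start0, start0 + ref_len
        )
    if known_variants is not None:
        known = {
            (k.chrom, k.pos, k.ref, k.alt) if isinstance(k, VariantKey) else tuple(k)
            for k in known_variants
        }
        tuples = list(zip(calls["chrom"], calls["pos"], calls["ref"], calls["alt"]))
        keep &= np.array([t not in known for t in tuples], dtype=bool)
    if require_tranche and "tranche_pass" in calls.columns:
        keep &= calls["tranche_pass"].to_numpy(dtype=bool)
    return calls[keep]


# ---------------------------------------------------------------------------
# confidence classification
# ---------------------------------------------------------------------------

def _within(x, lo, hi, upper_open=False):
    return (x >= lo) & ((x < hi) if upper_open else (x <= hi))


def classify_calls(
    calls: pd.DataFrame, windows: ClassificationWindows = DEFAULT_WINDOWS
) -> pd.DataFrame:
    """Vectorized confidence classification; adds ``caller_set`` and
    ``depth_vaf_class`` columns."""
    d = calls["depth"].to_numpy(dtype=float)
    v = calls["vaf"].to_numpy(dtype=float)
    hc = calls["hc_called"].to_numpy(dtype=bool)
    mu = calls["mutect_called"].to_numpy(dtype=bool) & calls["mutect_keep"].to_numpy(dtype=bool)
    w = windows

    set1 = hc & mu
    set2 = (~hc) & mu & _within(d, *w.set2_depth) & _within(v, *w.set2_vaf)
    set3 = _within(v, *w.set3_vaf, upper_open=True) & _within(d, *w.set3_depth)
    caller_set = np.select(
        [set1, set2, set3],
        [CallerSet.SET1.value, CallerSet.SET2.value, CallerSet.SET3.value],
        CallerSet.UNCLASSIFIED.value,
    )

    clonal = _within(v, *w.clonal_vaf)
    high = _within(d, *w.high_depth) & clonal
    low = _within(d, *w.low_depth, upper_open=True) & clonal
    sub = _within(v, *w.subclonal_vaf, upper_open=True) & _within(d, *w.subclonal_depth)
    dv = np.select(
        [high, low, sub],
        [DepthVafClass.HIGH.value, DepthVafClass.LOW.value, DepthVafClass.SUBCLONAL.value],
        DepthVafClass.UNCLASSIFIED.value,
    )
    out = calls.copy()
    out["caller_set"] = caller_set
    out["depth_vaf_class"] = dv
    return out


def classify_confidence(
    call: VariantCall, windows: ClassificationWindows = DEFAULT_WINDOWS
) -> ConfidenceLabel:
    """Confidence label for a single call (total function on both axes)."""
    df = pd.DataFrame(
        [{
            "depth": call.depth, "vaf": call.vaf,
            "hc_called": call.hc_called,
            "mutect_called": call.mutect_called,
            "mutect_keep": call.mutect_keep,
        }]
    )
    row = classify_calls(df, windows).iloc[0]
    return ConfidenceLabel(CallerSet(row["caller_set"]), DepthVafClass(row["depth_vaf_class"]))
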