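"""Variant annotation categories and the samples x categories burden table.

Each line-unique variant is assigned a genomic consequence (coding > UTR >
intron > intergenic, by interval-membership precedence), flags for overlap
with cancer-gene intervals and clustered TFBS regions, a "damaging" flag
(harmful by any of Condel / PolyPhen / SIFT), a deleteriousness (CADD Phred)
category, and — for TFBS hits with sequence context — a position-weight-
matrix binding-affinity change.  Aggregating category memberships per sample
yields the burden table consumed by the permutation ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .callset import VariantKey
from .intervals import IntervalIndex

__all__ = [
    "PWM",
    "AnnotationRecord",
    "BurdenTable",
    "categorize_variant",
    "tfbs_affinity_change",
    "codon_effect",
    "build_burden_table",
    "DEFAULT_CATEGORIES",
    "LOCATION_CATEGORIES",
]

LOCATION_CATEGORIES = ["coding", "utr", "intron", "igr"]
DEFAULT_CATEGORIES = LOCATION_CATEGORIES + [
    "CADD>15", "damaging", "near_cancer_gene", "TFBS",
]

#: predictor designations counted as harmful (case-insensitive)
HARMFUL_LABELS = {"harmful", "damaging", "deleterious", "probably_damaging",
                  "possibly_damaging"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class PWM:
    """Log-odds position weight matrix; rows A, C, G, T."""

    motif_id: str
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[0] != 4 or scores.shape[1] < 1:
            raise ValueError("PWM scores must be a 4 x L matrix")
        if not np.all(np.isfinite(scores)):
            raise ValueError("PWM scores must be finite")
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return self.scores.shape[1]

    def score(self, seq: str) -> float:
        """Log-odds score of a window of exactly the motif length."""
        if len(seq) != self.length:
            raise ValueError("window length must equal motif length")
        return float(sum(self.scores[_ROW[b], j] for j, b in enumerate(seq)))


@dataclass
class AnnotationRecord:
    key: VariantKey
    sample_id: str
    consequence: str                      # coding | utr | intron | igr
    coding_effect: str = "none"           # synonymous | nonsynonymous | nonsense | none
    near_cancer_gene: bool = False
    tfbs_hit: bool = False
    tfbs_affinity_delta: Optional[float] = None
    damaging: bool = False
    cadd_phred: Optional[float] = None
    categories: set = field(default_factory=set)


def _best_pwm_score(pwm: PWM, seq: str, var_index: int) -> float:
    """Best window log-odds over both strands, among windows covering the
    variant base."""
    L = pwm.length
    best = -np.inf
    lo = max(0, var_index - L + 1)
    hi = min(len(seq) - L, var_index)
    for w in range(lo, hi + 1):
        window = seq[w:w + L]
        best = max(best, pwm.score(window))
        rc = window.translate(_COMPLEMENT)[::-1]
        best = max(best, pwm.score(rc))
    if not np.isfinite(best):
        raise ValueError("no window of motif length covers the variant")
    return best


def tfbs_affinity_change(
    pwm: PWM,
    ref_context: str,
    alt_allele: str,
    var_index: Optional[int] = None,
    threshold: float = 7.0,
) -> tuple[float, bool]:
    """Absolute change in best-window binding affinity caused by a SNV.

    ``ref_context`` is genomic sequence around the variant (the variant base
    at ``var_index``, defaulting to the centre) extending at least L-1 bases
    to each side.  The score of a sequence is the best motif log-odds over
    both strands among all windows covering the variant.  Returns
    (delta, high_confidence) where the flag requires delta strictly above the
    threshold (default 7 log-odds units).
    """
    ref_context = ref_context.upper()
    if var_index is None:
        var_index = len(ref_context) // 2
    L = pwm.length
    if var_index < L - 1 and var_index + L > len(ref_context):
        # not even one full window fits around the variant
        raise ValueError("ref_context shorter than the motif around the variant")
    if len(alt_allele) != 1 or alt_allele.upper() not in _ROW:
        raise ValueError("TFBS affinity change is defined for SNVs only")
    alt_context = ref_context[:var_index] + alt_allele.upper() + ref_context[var_index + 1:]
    delta = abs(_best_pwm_score(pwm, alt_context, var_index)
                - _best_pwm_score(pwm, ref_context, var_index))
    return delta, delta > threshold


def codon_effect(cds_seq: str, cds_offset: int, ref: str, alt: str) -> str:
    """Coding effect of a SNV inside a single-exon plus-strand CDS.

    Translates the affected codon before and after substitution; used for
    synthetic gene models (real-data annotation arrives as input labels).
    """
    cds_seq = cds_seq.upper()
    if cds_seq[cds_offset] != ref.upper():
        raise ValueError("reference base does not match the CDS sequence")
    codon_start = (cds_offset // 3) * 3
    codon = cds_seq[codon_start:codon_start + 3]
    if len(codon) < 3:
        return "none"
    within = cds_offset - codon_start
    alt_codon = codon[:within] + alt.upper() + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "nonsynonymous"


def _span(key: VariantKey) -> tuple[int, int]:
    """0-based half-open reference span affected by the variant."""
    start = key.pos - 1
    return start, start + len(key.ref)


def categorize_variant(
    key: VariantKey,
    sample_id: str,
    tracks: Mapping[str, IntervalIndex],
    predictor_labels: Optional[Sequence[str]] = None,
    cadd_phred: Optional[float] = None,
    coding_effect_label: str = "none",
    cadd_cutoff: float = 15.0,
    cancer_flank: int = 0,
    known_chroms: Optional[set] = None,
) -> AnnotationRecord:
    """Assign annotation categories to one variant.

    ``tracks`` maps category names (coding/utr/intron/cancer_gene/tfbs) to
    interval sets; consequence follows coding > utr > intron > igr
    precedence; ``predictor_labels`` are the Condel/PolyPhen/SIFT
    designations, harmful-by-any-one sets the damaging flag.
    """
    if known_chroms is not None and key.chrom not in known_chroms:
        raise AnnotationError(f"unknown chromosome {key.chrom!r}")
    start, end = _span(key)

    consequence = "igr"
    for cat in ("coding", "utr", "intron"):
        idx = tracks.get(cat)
        if idx is not None and idx.overlaps_any([key.chrom], [start], [end])[0]:
            consequence = cat
            break

    cancer = tracks.get("cancer_gene")
    near_cancer = bool(
        cancer is not None
        and cancer.overlaps_any([key.chrom], [start - cancer_flank], [end + cancer_flank])[0]
    )
    tfbs = tracks.get("tfbs")
    tfbs_hit = bool(tfbs is not None and tfbs.overlaps_any([key.chrom], [start], [end])[0])

    damaging = False
    if predictor_labels:
        damaging = any(str(x).lower() in HARMFUL_LABELS for x in predictor_labels)

    rec = AnnotationRecord(
        key=key,
        sample_id=sample_id,
        consequence=consequence,
        coding_effect=coding_effect_label if consequence == "coding" else "none",
        near_cancer_gene=near_cancer,
        tfbs_hit=tfbs_hit,
        damaging=damaging,
        cadd_phred=cadd_phred,
    )
    cats = {consequence}
    if cadd_phred is not None and cadd_phred > cadd_cutoff:
        cats.add("CADD>15")
    if damaging:
        cats.add("damaging")
    if near_cancer:
        cats.add("near_cancer_gene")
    if tfbs_hit:
        cats.add("TFBS")
    rec.categories = cats
    return rec


@dataclass
class BurdenTable:
    """Samples x annotation-category count matrix with method labels."""

    counts: pd.DataFrame          # index sample_id, columns categories
    totals: pd.Series             # per-sample total unique-variant count
    method_of: dict               # sample_id -> method label

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def categories(self) -> list:
        return list(self.counts.columns)

    def values_by_method(self, category: str) -> dict:
        out: dict[str, list] = {}
        col = self.counts[category] if category != "total" else self.totals
        for s in self.counts.index:
            out.setdefault(self.method_of[s], []).append(float(col[s]))
        return out

    def labels(self) -> list:
        return [self.method_of[s] for s in self.counts.index]


def build_burden_table(
    records: Iterable[AnnotationRecord],
    sample_ids: Sequence[str],
    method_of: Mapping[str, str],
    categories: Sequence[str] = tuple(DEFAULT_CATEGORIES),
) -> BurdenTable:
    """Count records per sample and category, in deterministic order.

    ``totals`` counts every record of a sample (its unique-variant total),
    whether or not it falls in a listed category.
    """
    samples = list(sample_ids)
    cats = list(categories)
    counts = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"), columns=cats)
    totals = pd.Series(0, index=counts.index, name="total")
    for rec in records:
        if rec.sample_id not in counts.index:
            raise ValueError(f"record for unknown sample {rec.sample_id!r}")
        totals[rec.sample_id] += 1
        for c in rec.categories:
            if c in counts.columns:
                counts.loc[rec.sample_id, c] += 1
    return BurdenTable(counts=counts, totals=totals,
                       method_of={s: method_of[s] for s in samples})
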