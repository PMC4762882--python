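"""Synthetic cohort generator emulating the study design.

The emulated experiment: a parental fibroblast population and nine derived
iPSC lines, three replicate lines for each of three reprogramming methods
(synthetic mRNA, integrating retrovirus, Sendai virus), whole-genome
sequenced at ~40x.  Each line carries a Poisson number of planted
line-unique variants; clonal variants sit near allele fraction 0.5 (present
in the founder cell), a configurable fraction are subclonal at VAF 0.2-0.4.
Two callers with different sensitivity/false-positive profiles are emulated
by thinning and augmenting the truth table: a specificity-tuned multisample
caller and a sensitivity-tuned pairwise caller run against the parental
sample.  The generator also plants vector integration sites with discordant
read-pair support (retroviral lines only), insertion/deletion calls from two
genome-map algorithms with per-sample molecule support, and chromatogram
trace windows, so every downstream stage is exercisable without external
data.

The default parameters are the study conditions: replicate structure 3 x 3,
mean depth 40, clonal VAF 0.5, planted unique-variant rates
(300, 1000, 1000) per method (the mRNA method yields fewer high-confidence
variants), on a deliberately small two-chromosome 2 Mbp genome so that every
stage runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import PWM, codon_effect
from .intervals import GenomicInterval, IntervalIndex
from .svcompare import SVCall
from .traces import CHANNELS, WINDOW, TraceWindow

__all__ = [
    "CohortConfig",
    "CohortDataset",
    "ConfigurationError",
    "GenerationError",
    "generate_cohort",
    "generate_annotation_tracks",
    "generate_integration_reads",
    "generate_trace",
    "generate_pwms",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: per-category (intervals per bp, mean interval length); chosen to give a
#: small genome the qualitative composition the annotation stages expect
DEFAULT_TRACK_DENSITIES: dict[str, tuple[float, float]] = {
    "coding": (3e-4, 150.0),
    "utr": (1.5e-4, 200.0),
    "intron": (2e-4, 2000.0),
    "gene": (1e-4, 5000.0),
    "cancer_gene": (2e-5, 5000.0),
    "tfbs": (2e-4, 20.0),
    "low_complexity": (5e-5, 300.0),
}


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort; defaults are the study conditions."""

    n_methods: int = 3
    replicates_per_method: int = 3
    method_names: tuple = ("mRNA", "retrovirus", "sendai")
    #: expected planted line-unique variants per line, one rate per method
    unique_rate_per_method: tuple = (300.0, 1000.0, 1000.0)
    mean_depth: float = 40.0
    clonal_vaf: float = 0.5
    subclonal_fraction: float = 0.2
    indel_fraction: float = 0.1
    transition_fraction: float = 0.66
    #: detection probability for true variants: (multisample, pairwise) caller
    caller_sensitivity: tuple = (0.90, 0.97)
    #: expected false calls per genome per sample: (multisample, pairwise)
    caller_fpr: tuple = (20.0, 50.0)
    mutect_reject_fraction: float = 0.02
    tranche_fail_fraction: float = 0.02
    genome_spec: tuple = (("chr1", 1_000_000), ("chr2", 1_000_000))
    #: expected count of parental-mosaic variants (low VAF in the parental
    #: sample, clonal in one random line); 0 disables
    mosaic_rate: float = 0.0
    mosaic_vaf: float = 0.1
    track_densities: Optional[Mapping[str, tuple]] = None
    n_known_variants: int = 50
    predictor_harmful_prob: float = 0.03
    cadd_tail_prob: float = 0.10
    # integration (retroviral lines only)
    integration_rate: float = 9.0
    integration_pairs_per_site: int = 10
    integration_noise_pairs: int = 20
    # genome-map SVs (parental + one line per method)
    sv_shared_rate: float = 30.0
    sv_specific_rate: float = 3.0
    sv_algo_sensitivity: float = 0.95
    sv_breakpoint_jitter: float = 0.02
    # traces
    n_traces: int = 24
    trace_background_mean: float = 100.0
    trace_background_sd: float = 10.0
    trace_peak: float = 300.0
    # stage toggles (speed knobs for large replicate studies)
    annotate_truth: bool = True
    emulate_callers: bool = True
    include_integrations: bool = True
    include_svs: bool = True
    include_traces: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.replicates_per_method < 1:
            raise ConfigurationError("replicates_per_method must be >= 1")
        if self.n_methods < 1 or len(self.method_names) != self.n_methods:
            raise ConfigurationError("method_names must match n_methods")
        if len(self.unique_rate_per_method) != self.n_methods:
            raise ConfigurationError("one unique rate per method required")
        if any(r < 0 for r in self.unique_rate_per_method):
            raise ConfigurationError("rates must be >= 0")
        for p in (*self.caller_sensitivity, self.subclonal_fraction,
                  self.indel_fraction, self.transition_fraction,
                  self.mutect_reject_fraction, self.tranche_fail_fraction,
                  self.cadd_tail_prob, self.predictor_harmful_prob,
                  self.sv_algo_sensitivity):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if any(f < 0 for f in self.caller_fpr) or self.mean_depth <= 0:
            raise ConfigurationError("rates must be >= 0 and mean depth > 0")
        if not self.genome_spec or any(length <= 0 for _, length in self.genome_spec):
            raise ConfigurationError("chromosome lengths must be positive")
        if not 0.0 < self.clonal_vaf <= 1.0:
            raise ConfigurationError("clonal_vaf must be in (0, 1]")

    @property
    def line_sample_ids(self) -> list[str]:
        ids = []
        prefixes = [name[:1].upper() for name in self.method_names]
        unique_prefix = len(set(prefixes)) == len(prefixes)
        for m, name in enumerate(self.method_names):
            tag = prefixes[m] if unique_prefix else name
            ids.extend(f"{tag}{j + 1}" for j in range(self.replicates_per_method))
        return ids

    @property
    def method_of(self) -> dict[str, str]:
        out = {}
        per = self.replicates_per_method
        for m, name in enumerate(self.method_names):
            for s in self.line_sample_ids[m * per:(m + 1) * per]:
                out[s] = name
        return out

    @property
    def parental_sample_id(self) -> str:
        return "F"

    @property
    def genome_length(self) -> int:
        return int(sum(length for _, length in self.genome_spec))


@dataclass
class CohortDataset:
    """Everything the pipeline consumes, plus the planted ground truth."""

    config: CohortConfig
    parental_sample_id: str
    line_sample_ids: list
    method_of: dict
    truth_variants: pd.DataFrame
    hc_calls: pd.DataFrame
    mutect_calls: dict                  # line -> DataFrame with judgment column
    annotation_tracks: dict             # category -> IntervalIndex
    pwms: dict                          # pwm_id -> PWM
    coding_seqs: dict                   # coding interval label -> sequence
    known_variants: set                 # {(chrom, pos, ref, alt)}
    predictor_table: pd.DataFrame       # key -> condel/polyphen/sift/cadd_phred
    integration_truth: pd.DataFrame
    integration_pairs: pd.DataFrame
    sv_truth: pd.DataFrame
    sv_calls: list                      # list[SVCall]
    sv_support: dict                    # truth sv id -> {sample: molecules}
    sv_samples: list
    traces: list                        # list[TraceWindow]
    trace_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_annotation_tracks(
    genome_spec: Sequence[tuple], densities: Mapping[str, tuple], seed
) -> dict[str, list[GenomicInterval]]:
    """Sorted, non-overlapping-within-category interval tracks.

    ``densities`` maps category -> (intervals per bp, mean length).  Interval
    counts per chromosome are Poisson(density x length); placement draws
    sorted uniform offsets in the free space left after reserving the
    interval lengths, so intervals never overlap and the expected count stays
    exactly density x genome length.  TFBS intervals carry a PWM identifier.
    """
    rng = _as_rng(seed)
    tracks: dict[str, list[GenomicInterval]] = {}
    for cat in sorted(densities):
        density, mean_len = densities[cat]
        if density < 0 or mean_len <= 0:
            raise ConfigurationError(f"bad density spec for {cat!r}")
        ivs: list[GenomicInterval] = []
        for chrom, clen in genome_spec:
            n = int(rng.poisson(density * clen))
            if n == 0:
                continue
            lengths = np.maximum(1, rng.poisson(mean_len, size=n))
            if cat == "coding":
                lengths = np.maximum(3, (lengths // 3) * 3)  # whole codons
            total = int(lengths.sum())
            if total > clen:
                raise GenerationError(
                    f"cannot place {n} {cat} intervals (total {total} bp) on "
                    f"{chrom} ({clen} bp); lower the density"
                )
            free = clen - total
            offsets = np.sort(rng.integers(0, free + 1, size=n))
            starts = offsets + np.concatenate([[0], np.cumsum(lengths[:-1])])
            for i, (s, ln) in enumerate(zip(starts, lengths)):
                pwm_id = f"PWM{int(rng.integers(1, 9))}" if cat == "tfbs" else None
                ivs.append(
                    GenomicInterval(chrom, int(s), int(s + ln),
                                    label=f"{cat}_{chrom}_{i}", pwm_id=pwm_id)
                )
        tracks[cat] = ivs
    return tracks


def generate_pwms(rng, n: int = 8, min_len: int = 6, max_len: int = 10) -> dict[str, PWM]:
    """A small library of random log-odds matrices standing in for curated
    motif databases."""
    pwms = {}
    for i in range(1, n + 1):
        L = int(rng.integers(min_len, max_len + 1))
        scores = rng.normal(0.0, 2.0, size=(4, L)).round(3)
        pwms[f"PWM{i}"] = PWM(motif_id=f"PWM{i}", scores=scores)
    return pwms


# ---------------------------------------------------------------------------
# read pairs for integration detection
# ---------------------------------------------------------------------------

def generate_integration_reads(
    sites: Sequence[tuple],
    coverage_per_site: int,
    noise_pairs: int,
    seed,
    genome_spec: Sequence[tuple] = (("chr1", 1_000_000), ("chr2", 1_000_000)),
    max_offset: int = 150,
    sample_id: str = "",
) -> pd.DataFrame:
    """Host/viral discordant read pairs for the given (chrom, pos, virus)
    sites plus uniform background noise pairs.

    Each site yields ``coverage_per_site`` host-anchored pairs split
    binomially between the left flank (forward strand, positions just
    upstream of the junction) and the right flank (reverse strand,
    downstream), all within ``max_offset`` of the junction.
    """
    rng = _as_rng(seed)
    if coverage_per_site < 0 or noise_pairs < 0:
        raise ConfigurationError("pair counts must be >= 0")
    chrom_len = dict(genome_spec)
    rows = []
    serial = 0
    for chrom, pos, virus in sites:
        if chrom not in chrom_len or not 1 <= pos <= chrom_len[chrom]:
            raise ConfigurationError(f"site {chrom}:{pos} outside the genome")
        n_left = int(rng.binomial(coverage_per_site, 0.5))
        for i in range(coverage_per_site):
            left = i < n_left
            off = int(rng.integers(0, max_offset + 1))
            p = pos - off if left else pos + off
            p = min(max(1, p), chrom_len[chrom])
            rows.append({
                "name": f"{sample_id}pair{serial}", "chrom": chrom, "pos": p,
                "strand": "+" if left else "-", "virus": virus,
                "vpos": int(rng.integers(1, 5_000)),
                "vstrand": rng.choice(["+", "-"]), "mapq": 60,
            })
            serial += 1
    chroms = [c for c, _ in genome_spec]
    weights = np.array([chrom_len[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    viruses = sorted({v for _, _, v in sites}) or ["vector"]
    for _ in range(noise_pairs):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        rows.append({
            "name": f"{sample_id}noise{serial}", "chrom": chrom,
            "pos": int(rng.integers(1, chrom_len[chrom] + 1)),
            "strand": rng.choice(["+", "-"]),
            "virus": viruses[int(rng.integers(0, len(viruses)))],
            "vpos": int(rng.integers(1, 5_000)),
            "vstrand": rng.choice(["+", "-"]), "mapq": 60,
        })
        serial += 1
    return pd.DataFrame(
        rows, columns=["name", "chrom", "pos", "strand", "virus", "vpos",
                       "vstrand", "mapq"],
    )


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def generate_trace(
    genotype: str,
    background_mean: float,
    background_sd: float,
    peak_amplitude: float,
    seed,
    alt_channel: str = "C",
    primary_channel: str = "A",
    variant_id: str = "trace",
    primary_amplitude: float = 1000.0,
) -> TraceWindow:
    """A 21-position four-channel trace window.

    Non-primary channels carry Normal(background_mean, background_sd) noise
    (clipped at zero); the primary channel carries a strong peak everywhere.
    For a heterozygous genotype the centre position's expected alternate
    channel is set to ``peak_amplitude``; homozygous traces get no injected
    peak.
    """
    rng = _as_rng(seed)
    if background_sd < 0:
        raise ConfigurationError("background_sd must be >= 0")
    if genotype not in ("het", "hom"):
        raise ConfigurationError("genotype must be 'het' or 'hom'")
    amp = np.clip(rng.normal(background_mean, background_sd, size=(4, WINDOW)), 0, None)
    amp[CHANNELS.index(primary_channel.upper())] = primary_amplitude
    if genotype == "het":
        amp[CHANNELS.index(alt_channel.upper()), WINDOW // 2] = peak_amplitude
    calls = tuple(primary_channel.upper() for _ in range(WINDOW))
    return TraceWindow(variant_id=variant_id, amplitudes=amp, primary_base_calls=calls)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _draw_positions(rng, genome_spec, n):
    chroms = [c for c, _ in genome_spec]
    lengths = np.array([ln for _, ln in genome_spec], dtype=float)
    probs = lengths / lengths.sum()
    which = rng.choice(len(chroms), size=n, p=probs)
    pos = rng.integers(1, lengths[which].astype(np.int64) + 1)
    return np.array(chroms, dtype=object)[which], pos.astype(np.int64)


def _draw_alleles(rng, n, transition_fraction, indel_fraction):
    refs = rng.choice(_BASES, size=n)
    is_indel = rng.random(n) < indel_fraction
    is_transition = rng.random(n) < transition_fraction
    alts = np.empty(n, dtype=object)
    refs = refs.astype(object)
    for i in range(n):
        r = refs[i]
        if is_indel[i]:
            extra = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
            if rng.random() < 0.5:
                alts[i] = r + extra            # insertion
            else:
                refs[i] = r + extra            # deletion
                alts[i] = r
        elif is_transition[i]:
            alts[i] = _TRANSITION[r]
        else:
            tv = [b for b in "ACGT" if b not in (r, _TRANSITION[r])]
            alts[i] = tv[int(rng.integers(0, 2))]
    return refs, alts


def _plant_variants(rng, config: CohortConfig) -> pd.DataFrame:
    rows = []
    per = config.replicates_per_method
    line_ids = config.line_sample_ids
    counts = []
    for m in range(config.n_methods):
        lam = config.unique_rate_per_method[m]
        for j in range(per):
            counts.append((line_ids[m * per + j], int(rng.poisson(lam))))
    frames = []
    vid = 0
    for sample, n in counts:
        if n == 0:
            continue
        chroms, pos = _draw_positions(rng, config.genome_spec, n)
        refs, alts = _draw_alleles(rng, n, config.transition_fraction,
                                   config.indel_fraction)
        subclonal = rng.random(n) < config.subclonal_fraction
        vaf = np.where(subclonal, rng.uniform(0.2, 0.4, size=n), config.clonal_vaf)
        depth = np.maximum(1, rng.poisson(config.mean_depth, size=n))
        alt_depth = rng.binomial(depth, vaf)
        frames.append(pd.DataFrame({
            "variant_id": [f"v{vid + i}" for i in range(n)],
            "origin": sample, "carrier": sample,
            "chrom": chroms, "pos": pos, "ref": refs, "alt": alts,
            "true_vaf": vaf, "subclonal": subclonal,
            "depth": depth, "alt_depth": alt_depth,
        }))
        vid += n
    # parental-mosaic variants: low VAF in the parental sample, clonal in one
    # random line — they must fail the unique-variant rule
    n_mos = int(rng.poisson(config.mosaic_rate)) if config.mosaic_rate > 0 else 0
    if n_mos:
        chroms, pos = _draw_positions(rng, config.genome_spec, n_mos)
        refs, alts = _draw_alleles(rng, n_mos, config.transition_fraction, 0.0)
        carriers = rng.choice(np.array(line_ids, dtype=object), size=n_mos)
        depth = np.maximum(1, rng.poisson(config.mean_depth, size=n_mos))
        frames.append(pd.DataFrame({
            "variant_id": [f"v{vid + i}" for i in range(n_mos)],
            "origin": "parental-mosaic", "carrier": carriers,
            "chrom": chroms, "pos": pos, "ref": refs, "alt": alts,
            "true_vaf": config.clonal_vaf, "subclonal": False,
            "depth": depth,
            "alt_depth": rng.binomial(depth, config.clonal_vaf),
        }))
    if not frames:
        return pd.DataFrame(columns=[
            "variant_id", "origin", "carrier", "chrom", "pos", "ref", "alt",
            "true_vaf", "subclonal", "depth", "alt_depth",
        ])
    truth = pd.concat(frames, ignore_index=True)
    # a line cannot carry two distinct events at one site; drop the rare
    # birthday collision on the small genome
    return truth.drop_duplicates(subset=["carrier", "chrom", "pos"],
                                 keep="first", ignore_index=True)


def _annotate_truth(rng, truth: pd.DataFrame, indexes: dict, coding_seqs: dict,
                    config: CohortConfig) -> pd.DataFrame:
    n = len(truth)
    chroms = truth["chrom"].to_numpy()
    pos0 = truth["pos"].to_numpy() - 1
    member = {}
    for cat in ("coding", "utr", "intron", "cancer_gene", "tfbs", "low_complexity"):
        idx = indexes.get(cat)
        member[cat] = idx.covers_points(chroms, pos0) if idx is not None else np.zeros(n, bool)
    consequence = np.select(
        [member["coding"], member["utr"], member["intron"]],
        ["coding", "utr", "intron"], "igr",
    )
    truth = truth.copy()
    truth["consequence"] = consequence
    truth["near_cancer_gene"] = member["cancer_gene"]
    truth["tfbs"] = member["tfbs"]
    truth["low_complexity"] = member["low_complexity"]
    truth["coding_effect"] = "none"
    truth["tfbs_pwm"] = None
    truth["context"] = None

    is_snv = (truth["ref"].str.len() == 1) & (truth["alt"].str.len() == 1)
    # coding SNVs: take the reference base from the gene sequence so the
    # codon-table effect is well defined
    for i in np.nonzero(member["coding"] & is_snv.to_numpy())[0]:
        iv = indexes["coding"].overlapping(chroms[i], pos0[i], pos0[i] + 1)[0]
        seq = coding_seqs[iv.label]
        offset = int(pos0[i] - iv.start)
        ref = seq[offset]
        alt = truth.at[i, "alt"]
        if alt == ref:
            alt = _TRANSITION[ref]
        truth.at[i, "ref"] = ref
        truth.at[i, "alt"] = alt
        truth.at[i, "coding_effect"] = codon_effect(seq, offset, ref, alt)
    # TFBS SNVs: record the motif and a sequence context for affinity scoring
    ctx_flank = 12
    for i in np.nonzero(member["tfbs"] & is_snv.to_numpy())[0]:
        iv = indexes["tfbs"].overlapping(chroms[i], pos0[i], pos0[i] + 1)[0]
        context = "".join(rng.choice(_BASES, size=2 * ctx_flank + 1))
        context = context[:ctx_flank] + truth.at[i, "ref"] + context[ctx_flank + 1:]
        truth.at[i, "tfbs_pwm"] = iv.pwm_id
        truth.at[i, "context"] = context

    harmful = rng.random((n, 3)) < config.predictor_harmful_prob
    labels = np.where(harmful, "harmful", "tolerated")
    truth["condel"], truth["polyphen"], truth["sift"] = labels.T
    tail = rng.random(n) < config.cadd_tail_prob
    truth["cadd_phred"] = np.where(
        tail, rng.uniform(15.0, 40.0, size=n), rng.uniform(0.0, 15.0, size=n)
    ).round(3)
    return truth


def _emulate_callers(rng, truth: pd.DataFrame, config: CohortConfig):
    s_hc, s_mu = config.caller_sensitivity
    hc_rows = []
    mutect: dict[str, list] = {s: [] for s in config.line_sample_ids}
    callable_mask = truth["alt_depth"].to_numpy() > 0
    det_hc = (rng.random(len(truth)) < s_hc) & callable_mask
    det_mu = (rng.random(len(truth)) < s_mu) & callable_mask
    tranche = rng.random(len(truth)) >= config.tranche_fail_fraction
    rejected = rng.random(len(truth)) < config.mutect_reject_fraction
    par_depth = np.maximum(1, rng.poisson(config.mean_depth, size=len(truth)))
    par_alt = rng.binomial(par_depth, config.mosaic_vaf)
    det_hc_par = rng.random(len(truth)) < s_hc

    cols = truth[["origin", "carrier", "chrom", "pos", "ref", "alt",
                  "depth", "alt_depth"]].to_numpy(dtype=object)
    for i, (origin, carrier, chrom, pos, ref, alt, depth, alt_depth) in enumerate(cols):
        mosaic = origin == "parental-mosaic"
        base = {"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
                "depth": int(depth), "alt_depth": int(alt_depth)}
        if det_hc[i]:
            hc_rows.append({"sample_id": carrier, **base,
                            "tranche_pass": bool(tranche[i])})
        if mosaic and det_hc_par[i] and par_alt[i] > 0:
            hc_rows.append({"sample_id": config.parental_sample_id, **base,
                            "depth": int(par_depth[i]), "alt_depth": int(par_alt[i]),
                            "tranche_pass": bool(tranche[i])})
        if det_mu[i]:
            # a mosaic variant has read support in the matched normal, so the
            # pairwise caller rejects it
            judgment = "REJECT" if (mosaic or rejected[i]) else "KEEP"
            mutect[carrier].append({**base, "judgment": judgment})

    # false positives: caller- and sample-specific random calls; positions
    # already used by the same sample are skipped so the two callers never
    # disagree on depth at one key
    fpr_hc, fpr_mu = config.caller_fpr
    all_samples = [config.parental_sample_id] + config.line_sample_ids
    used: dict[str, set] = {s: set() for s in all_samples}
    for i, (origin, carrier, chrom, pos, *_rest) in enumerate(cols):
        used[carrier].add((chrom, int(pos)))
        if origin == "parental-mosaic":
            used[config.parental_sample_id].add((chrom, int(pos)))

    def _fp_rows(sample, n_fp):
        chroms, pos = _draw_positions(rng, config.genome_spec, n_fp)
        refs, alts = _draw_alleles(rng, n_fp, config.transition_fraction, 0.0)
        depth = np.maximum(1, rng.poisson(config.mean_depth, size=n_fp))
        alt_depth = np.maximum(1, rng.binomial(depth, rng.uniform(0.05, 0.6, n_fp)))
        rows = []
        for j in range(n_fp):
            site = (chroms[j], int(pos[j]))
            if site in used[sample]:
                continue
            used[sample].add(site)
            rows.append({"chrom": chroms[j], "pos": int(pos[j]),
                         "ref": refs[j], "alt": alts[j],
                         "depth": int(depth[j]), "alt_depth": int(alt_depth[j])})
        return rows

    for sample in all_samples:
        n_fp = int(rng.poisson(fpr_hc))
        for row in _fp_rows(sample, n_fp) if n_fp else []:
            hc_rows.append({"sample_id": sample, **row, "tranche_pass": True})
    for sample in config.line_sample_ids:
        n_fp = int(rng.poisson(fpr_mu))
        for row in _fp_rows(sample, n_fp) if n_fp else []:
            mutect[sample].append({**row, "judgment": "KEEP"})

    hc_cols = ["sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_depth",
               "tranche_pass"]
    hc = pd.DataFrame(hc_rows, columns=hc_cols)
    hc = hc.sort_values(["chrom", "pos", "ref", "alt", "sample_id"],
                        ignore_index=True)
    mt_cols = ["chrom", "pos", "ref", "alt", "depth", "alt_depth", "judgment"]
    mutect_frames = {
        s: pd.DataFrame(rows, columns=mt_cols).sort_values(
            ["chrom", "pos", "ref", "alt"], ignore_index=True)
        for s, rows in mutect.items()
    }
    return hc, mutect_frames


def _generate_svs(rng, config: CohortConfig, sv_samples):
    chroms = [c for c, _ in config.genome_spec]
    chrom_len = dict(config.genome_spec)

    def draw_sv(sv_id, carriers):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        size = int(np.exp(rng.uniform(np.log(3_000), np.log(100_000))))
        svtype = "deletion" if rng.random() < 0.5 else "insertion"
        if svtype == "deletion":
            start = int(rng.integers(0, max(1, chrom_len[chrom] - size)))
            end = start + size
        else:
            start = int(rng.integers(0, chrom_len[chrom] - 1))
            end = start + 1
        support = {s: (int(rng.poisson(10)) + 1 if s in carriers else 0)
                   for s in sv_samples}
        return {"sv_id": sv_id, "chrom": chrom, "start": start, "end": end,
                "size": size, "svtype": svtype, "carriers": tuple(carriers),
                "support": support}

    truth = []
    n_shared = int(rng.poisson(config.sv_shared_rate))
    for i in range(n_shared):
        truth.append(draw_sv(f"sv_shared_{i}", list(sv_samples)))
    for s in sv_samples:
        n_spec = int(rng.poisson(config.sv_specific_rate))
        for i in range(n_spec):
            truth.append(draw_sv(f"sv_{s}_{i}", [s]))

    calls: list[SVCall] = []
    for rec in truth:
        for sample in rec["carriers"]:
            for algo in ("split", "global"):
                if rng.random() >= config.sv_algo_sensitivity:
                    continue
                jit = config.sv_breakpoint_jitter * rec["size"]
                size = max(1, int(round(rec["size"] + rng.normal(0, jit))))
                if rec["svtype"] == "deletion":
                    start = max(0, int(round(rec["start"] + rng.normal(0, jit))))
                    end = start + size
                else:
                    start = max(0, int(round(rec["start"] + rng.normal(0, jit))))
                    end = start + 1
                calls.append(SVCall(
                    sample_id=sample, chrom=rec["chrom"], start=start, end=end,
                    size=size, svtype=rec["svtype"], algorithm=algo,
                    call_id=f"{rec['sv_id']}:{sample}:{algo}",
                    molecule_support=rec["support"],
                ))
    truth_df = pd.DataFrame(
        truth, columns=["sv_id", "chrom", "start", "end", "size", "svtype",
                        "carriers", "support"],
    )
    support = {rec["sv_id"]: rec["support"] for rec in truth}
    return truth_df, calls, support


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate the full synthetic cohort for one seed.

    Identical configurations (seed included) reproduce the dataset exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    densities = dict(config.track_densities
                     if config.track_densities is not None
                     else DEFAULT_TRACK_DENSITIES)
    tracks = generate_annotation_tracks(config.genome_spec, densities, rng)
    indexes = {cat: IntervalIndex(ivs) for cat, ivs in tracks.items()}
    pwms = generate_pwms(rng)
    coding_seqs = {
        iv.label: "".join(rng.choice(_BASES, size=iv.end - iv.start))
        for iv in tracks.get("coding", [])
    }

    truth = _plant_variants(rng, config)
    if config.annotate_truth and len(truth):
        truth = _annotate_truth(rng, truth, indexes, coding_seqs, config)

    if config.emulate_callers:
        hc_calls, mutect_calls = _emulate_callers(rng, truth, config)
    else:
        hc_cols = ["sample_id", "chrom", "pos", "ref", "alt", "depth",
                   "alt_depth", "tranche_pass"]
        hc_calls = pd.DataFrame(columns=hc_cols)
        mutect_calls = {s: pd.DataFrame(columns=["chrom", "pos", "ref", "alt",
                                                 "depth", "alt_depth", "judgment"])
                        for s in config.line_sample_ids}

    # known-variant exclusion set: population-database sites unrelated to the
    # planted somatic variants
    known = set()
    if config.n_known_variants:
        chroms, pos = _draw_positions(rng, config.genome_spec, config.n_known_variants)
        refs, alts = _draw_alleles(rng, config.n_known_variants,
                                   config.transition_fraction, 0.0)
        planted = set(zip(truth["chrom"], truth["pos"].astype(int)))
        for c, p, r, a in zip(chroms, pos, refs, alts):
            if (c, int(p)) not in planted:
                known.add((c, int(p), r, a))

    pred_cols = ["chrom", "pos", "ref", "alt", "condel", "polyphen", "sift",
                 "cadd_phred"]
    if config.annotate_truth and len(truth):
        predictor_table = truth[pred_cols].copy()
    else:
        predictor_table = pd.DataFrame(columns=pred_cols)

    # integration sites: only the integrating (retroviral) vector leaves them
    pair_frames, int_rows = [], []
    if config.include_integrations:
        chrom_len = dict(config.genome_spec)
        for sample in config.line_sample_ids:
            if config.method_of[sample] != "retrovirus":
                continue
            n_sites = int(rng.poisson(config.integration_rate))
            sites = []
            for i in range(n_sites):
                chrom = [c for c, _ in config.genome_spec][
                    int(rng.integers(0, len(config.genome_spec)))]
                pos = int(rng.integers(200, chrom_len[chrom] - 200))
                sites.append((chrom, pos, "pMX"))
                int_rows.append({"sample_id": sample, "chrom": chrom,
                                 "pos": pos, "virus": "pMX"})
            pairs = generate_integration_reads(
                sites, config.integration_pairs_per_site,
                config.integration_noise_pairs, rng,
                genome_spec=config.genome_spec, sample_id=f"{sample}_",
            )
            pairs.insert(0, "sample_id", sample)
            pair_frames.append(pairs)
    pair_cols = ["sample_id", "name", "chrom", "pos", "strand", "virus",
                 "vpos", "vstrand", "mapq"]
    integration_pairs = (pd.concat(pair_frames, ignore_index=True)
                         if pair_frames else pd.DataFrame(columns=pair_cols))
    integration_truth = pd.DataFrame(
        int_rows, columns=["sample_id", "chrom", "pos", "virus"])

    # genome-map SVs for the parental sample plus one line per method
    per = config.replicates_per_method
    sv_samples = [config.parental_sample_id] + [
        config.line_sample_ids[(m + 1) * per - 1] for m in range(config.n_methods)
    ]
    if config.include_svs:
        sv_truth, sv_calls, sv_support = _generate_svs(rng, config, sv_samples)
    else:
        sv_truth = pd.DataFrame(columns=["sv_id", "chrom", "start", "end",
                                         "size", "svtype", "carriers", "support"])
        sv_calls, sv_support = [], {}

    # trace windows for a subset of planted variants, plus homozygous controls
    traces, trace_rows = [], []
    if config.include_traces and len(truth):
        n_tr = min(config.n_traces, len(truth))
        pick = rng.choice(len(truth), size=n_tr, replace=False)
        for i in sorted(pick):
            row = truth.iloc[i]
            ref, alt = row["ref"][0], row["alt"][0]
            if ref == alt:
                alt = _TRANSITION[ref]
            vid = f"{row['variant_id']}_het"
            traces.append(generate_trace(
                "het", config.trace_background_mean, config.trace_background_sd,
                config.trace_peak, rng, alt_channel=alt, primary_channel=ref,
                variant_id=vid,
            ))
            trace_rows.append({"variant_id": vid, "genotype": "het",
                               "alt_channel": alt})
        for j in range(n_tr // 2):
            ref = str(rng.choice(_BASES))
            alt = _TRANSITION[ref]
            vid = f"hom_control_{j}"
            traces.append(generate_trace(
                "hom", config.trace_background_mean, config.trace_background_sd,
                config.trace_peak, rng, alt_channel=alt, primary_channel=ref,
                variant_id=vid,
            ))
            trace_rows.append({"variant_id": vid, "genotype": "hom",
                               "alt_channel": alt})
    trace_truth = pd.DataFrame(
        trace_rows, columns=["variant_id", "genotype", "alt_channel"])

    return CohortDataset(
        config=config,
        parental_sample_id=config.parental_sample_id,
        line_sample_ids=config.line_sample_ids,
        method_of=config.method_of,
        truth_variants=truth,
        hc_calls=hc_calls,
        mutect_calls=mutect_calls,
        annotation_tracks=indexes,
        pwms=pwms,
        coding_seqs=coding_seqs,
        known_variants=known,
        predictor_table=predictor_table,
        integration_truth=integration_truth,
        integration_pairs=integration_pairs,
        sv_truth=sv_truth,
        sv_calls=sv_calls,
        sv_support=sv_support,
        sv_samples=sv_samples,
        traces=traces,
        trace_truth=trace_truth,
    )
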