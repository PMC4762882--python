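# mutburden

Tools for comparing the somatic mutational burden of induced pluripotent
stem cell (iPSC) lines derived by different reprogramming methods — the
setting where a single fibroblast population is reprogrammed with
integrating retrovirus, non-integrating Sendai virus, or synthetic mRNA
(three replicate clonal lines per method, plus the parental population),
whole-genome sequenced at roughly 40×, and asked: *does the reprogramming
method change how many, and what kind of, mutations the lines acquire?*

The package is aimed at analysts who have per-sample variant calls (not raw
reads) and want the complete downstream machinery: confidence tiering of
line-unique variants, annotation-category burden tables, exact
small-design inference, power estimates, vector integration-site detection,
optical-map structural-variant (SV) comparison, and chromatogram-trace
validation. A bundled synthetic-cohort generator emulates the whole study
design so every stage is testable without any external data.

## What it computes

**Line-unique variants and confidence tiers.** Calls from two complementary
callers — a specificity-tuned multisample population caller and a
sensitivity-tuned tumour/normal-style pairwise caller run per line against
the parental population — are intersected on exact `(chrom, pos, ref, alt)`
keys. A variant is *unique* to a line when that line is the only one of the
ten samples with a non-reference call at its key. Unique variants are
filtered against low-complexity regions and a known-variant (dbSNP-style)
set, then tiered on two axes: by caller provenance (Set 1 = both callers;
Set 2 = pairwise-only at 20–60× and VAF 0.4–0.6; Set 3 = VAF 0.2–0.4 at
30–50×) and by coverage/VAF window (HIGH 40–60× & VAF 0.4–0.6, LOW 20–40×,
SUBCLONAL VAF 0.2–0.4 at 40–60×). Downstream analysis uses Set 1.

**Exact permutation ANOVA.** For each annotation category *c* the burden of
sample *s* is the count `n_{s,c}` (or the relative rate `n_{s,c}/n_s`). The
one-way F statistic over the three method groups is referenced against its
exact permutation null: every distinct partition of the nine lines into
three unlabeled groups of three —

    9! / (3!^3 · 3!) = 280 partitions,

so `p = #{partitions with F* ≥ F_obs}/280`, an exact multiple of 1/280 with
p ≥ 1/280. One-vs-all planned contrasts `c = (−2,1,1)`, `(1,−2,1)`,
`(1,1,−2)` are tested with the pooled-MSE t statistic (df = 6) and, for the
permutation version, over all C(9,3) = 84 focal-triple splits. Per-group
sample sizes for 80% ANOVA power are derived from a noncentral-F
calculation with noncentrality `k·n·s²_between/MSE`. Kruskal–Wallis
comparisons (tie-corrected) handle deleteriousness-score distributions.

**Structural variants and integrations.** Genome-map insertion/deletion
calls from two algorithms are reduced to a dual-algorithm consensus,
cross-compared between cell lines with a 50% reciprocal size-overlap
cutoff, and candidate line-specific calls are curated against per-sample
single-molecule support (≥1 molecule in the line, 0 in every other sample).
The N50 map-contiguity statistic is included. Vector integration sites are
detected by clustering read pairs with one host-mapped and one viral-mapped
end, reported at ≥5 supporting reads on a flank, and annotated
genic/intergenic. A two-standard-deviation background rule calls candidate
heterozygous variants from 21-position chromatogram trace windows.

## Worked example

The per-line counts of variants falling in binding sites of one
transcription factor (EZH2), for the mRNA / retroviral / Sendai triplets
`(13, 11, 6) / (1, 7, 2) / (3, 0, 3)`:

```python
from mutburden import permutation_anova, contrast_test, sample_size_for_power

ezh2 = [13, 11, 6, 1, 7, 2, 3, 0, 3]
labels = ["mRNA"]*3 + ["retrovirus"]*3 + ["sendai"]*3

res = permutation_anova(ezh2, labels, category="EZH2_tfbs")
c = contrast_test([ezh2[:3], ezh2[3:6], ezh2[6:]], (-2, 1, 1))
```

gives:

```
F_obs = 6.2785
p_permutation = 0.06429  (18/280 partitions)
contrast (-2,1,1): estimate = -14.667, se = 4.1899, t = -3.5005 (df 6), p = 0.0128, p_perm = 0.0238
```

Reading: the observed between-method F of 6.28 is matched or exceeded by 18
of the 280 possible relabellings (exact p = 0.064), while the focused
mRNA-vs-all contrast `−2·x̄_mRNA + x̄_retro + x̄_sendai = −14.67` is
individually significant (t = −3.50, p ≈ 0.013) — the mRNA lines carry
*more* EZH2-site variants than the other two methods. The corresponding power helper on the coding-region counts
`(27,16,9)/(16,20,24)/(12,9,5)` reports between-group variance 35.1, pooled
MSE 36.9, and 5 samples per group for 80% power at α = 0.05.

A full synthetic run, from cohort simulation to every report:

```bash
mutburden run --outdir demo_run --seed 1
```

writes `demo_run/cohort/` (VCFs, BED tracks, TSVs, YAML manifest) and
`demo_run/results/` (unique variants, burden table, statistics report,
integration sites, SV candidates, trace validation) plus `report.json`, and
prints per-stage record counts — e.g. with seed 1: 6,698 planted truth
variants, 5,528 Set-1 unique variants after filtering, 24 integration sites
(all in retroviral lines), 10 curated line-specific SVs, and 24/24
heterozygous traces validated with 0/12 homozygous controls falsely called.
Re-running with the same seed reproduces every output byte-for-byte.

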