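# Methods

This note documents the models, conventions and deliberate design choices
behind each stage, in the order the pipeline runs them. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design being modelled

A mosaic parental fibroblast population and nine derived iPSC lines: three
replicate clonal lines for each of three reprogramming methods (synthetic
mRNA, integrating retrovirus, Sendai virus), all whole-genome sequenced at a
mean depth near 40×. The quantity of interest is the per-line burden of
*line-unique* somatic variants, overall and within annotation categories,
compared across methods. With only three replicates per method, inference is
exact-permutation-based rather than asymptotic.

## Synthetic cohort generator

The generator (`mutburden.synthetic`) produces every input the pipeline
consumes, with the statistical structure the analysis assumes.

* **Genome**: two chromosomes of 1 Mbp each by default. This is a deliberate
  desk-scale miniature — every stage runs in seconds — and positions are
  uniform, so it reproduces the *sampling* structure (Poisson counts,
  binomial allele depths, interval overlaps) but not sequence-dependent
  features of real genomes (mutational signatures, mappability, GC effects).
  Passing tests therefore validate the analysis machinery, not any claim
  about real mutational processes.
* **Planted variants**: each line receives Poisson(λ_m) unique variants,
  default λ = (300, 1000, 1000) for (mRNA, retrovirus, Sendai) — the mRNA
  method is modelled as producing roughly a third the burden of the others,
  matching the cohort structure the inference is designed to detect. Clonal
  variants have true VAF 0.5; a `subclonal_fraction` (default 0.2) instead
  draws VAF ~ U(0.2, 0.4). Depth ~ Poisson(40) truncated at ≥1 (the simplest
  overdispersion-free model consistent with a stated mean depth); alt depth
  ~ Binomial(depth, VAF). Substitutions are transitions with probability
  0.66; 10% of events are short (1–3 bp) insertions/deletions.
* **Two callers** are emulated by thinning/augmenting the truth table, not
  by reimplementing calling: the multisample caller detects a true variant
  with probability 0.90 and the pairwise caller with 0.97 (independent), and
  each adds Poisson false calls per genome (20 and 50 respectively) at
  uniform positions with VAF ~ U(0.05, 0.6). 2% of pairwise detections carry
  a REJECT judgment and 2% of multisample calls fail the recalibration
  tranche. False-positive sites never collide with a sample's existing
  calls, and same-line planted duplicates at one site are dropped, so the
  two callers always agree on depth at a shared key.
* **Parental mosaicism** (off by default, `mosaic_rate`): a mosaic variant
  is clonal in one random line but present at VAF 0.1 in the parental
  sample; the pairwise caller, seeing alt reads in its matched normal,
  always rejects it. This exercises the specificity of the unique-variant
  rule: such variants are excluded whenever the parental sample sampled at
  least one alt read.
* **Annotation tracks**: per category, interval counts are Poisson(density ×
  chromosome length) and placement draws sorted uniform offsets in the free
  space after reserving interval lengths — non-overlapping within category
  by construction with the expected count exactly density × length. Coding
  intervals have whole-codon lengths and carry a generated sequence so that
  coding effects are computed from an actual codon table; TFBS intervals
  carry an identifier into a small library of random log-odds matrices.
* **Integrations, SVs, traces**: only retroviral lines receive integration
  sites (Poisson(9) per line, 10 discordant pairs each within 150 bp of the
  junction, plus 20 uniform noise pairs). Genome-map SVs exist for the
  parental sample and one line per method: a shared founder set plus
  line-specific calls, each detected by the two algorithms independently
  with probability 0.95 and breakpoint jitter of 2% of the SV size;
  molecule support is Poisson(10)+1 in carriers and 0 elsewhere. Trace
  windows use background Normal(100, 10) with a heterozygous centre peak of
  300 (clearly separable; the boundary behaviour is tested with explicit
  peaks at mean + 3 sd).

All randomness flows through one `numpy` generator seeded from the config,
so identical configurations reproduce datasets — and serialized cohorts —
byte-for-byte.

## Variant classification

Unique-variant identification requires the variant key to be non-reference
in exactly one of the ten samples; a record with alt depth 0 is an explicit
reference call. In the default *lenient* mode a sample with no record at a
key counts as reference; *strict* mode demands explicit per-sample records
and raises otherwise. Indel keys are reduced to minimal representation
(shared trailing then leading bases trimmed) before intersection; full
left-alignment would additionally need the reference sequence and is left to
upstream normalization.

Confidence is labelled on two independent axes because the tiering used for
validation (Set 1/2/3, with Set 3 at 30–50×) and the coverage/VAF scheme
(HIGH/LOW/SUBCLONAL, subclonal at 40–60×) circulate with different window
definitions; both are retained and configurable
(`ClassificationWindows`). Boundary convention: windows are closed on the
lower bound; where two windows abut (depth 40, VAF 0.4) the shared value
resolves to the higher-confidence class. This makes classification total
and deterministic.

## Annotation and burden table

Consequence follows interval-membership precedence coding > UTR > intron >
intergenic; a 1-based SNV at position p overlaps [start, end) iff
start ≤ p−1 < end, and an indel overlaps if any affected reference base
does. "Damaging" is a disjunction over the three predictor designations
(Condel, PolyPhen, SIFT — supplied as input labels; the predictors
themselves are out of scope). "Near cancer gene" is interval overlap with a
supplied cancer-gene track, with a configurable flank defaulting to 0 bp
(plain overlap), since "near" has no established distance. The CADD-style
deleteriousness category uses a strict > 15 cutoff.

TFBS binding-affinity change is computed from a position weight matrix as
|best-window log-odds(alt) − best-window log-odds(ref)|, best over both
strands and all windows covering the variant base; the high-confidence flag
requires the change to exceed 7 strictly. The threshold's unit is log-odds
and configurable — the conventional value is retained but its original
scale is not documented anywhere authoritative.

Interval stabbing uses a start-sorted array per chromosome with a running
maximum of ends (`IntervalIndex`), giving vectorized bulk queries over call
tables; it is brute-force-checked in the tests.

## Inference

* **Permutation ANOVA**: the F statistic is label-invariant, so the null
  enumerates *unlabeled* partitions — 280 for nine samples into three
  groups of three (labeled assignments would be 1680). The p-value counts
  `F* ≥ F_obs − 1e−12`, guaranteeing the observed partition is counted and
  p ≥ 1/280, and making p an exact multiple of 1/280 even under duplicated
  F values. Degenerate inputs: all-equal group means give F = 0; zero
  within-variance with unequal means returns +inf (and such partitions
  compare correctly against any F_obs).
* **Contrasts**: estimate Σcᵢx̄ᵢ, standard error √(MSE·Σcᵢ²/nᵢ), t on
  N − k = 6 df, two-sided parametric p (sidedness of the original analysis
  is not documented; two-sided is the conservative default). The exact
  permutation version of a one-vs-all contrast collapses the design to
  (focal 3, rest 6): the contrast estimate depends only on which three
  samples are focal, but the three-group MSE would depend on an arbitrary
  split of the six non-focal samples, so the permuted statistic is the
  pooled two-group t over all C(9,3) = 84 splits, with the observed
  statistic computed identically. Only one-vs-all contrasts get a
  permutation p; general contrasts report the parametric p alone.
* **Reporting filter**: categories with fewer than 10 variants summed over
  samples are dropped from the statistical report (their counts remain in
  the burden table).
* **Rates**: relative rates divide by per-sample totals and refuse
  zero-total samples explicitly rather than emitting NaN.
* **Kruskal–Wallis**: scipy's tie-corrected H; the all-identical case is
  defined as H = 0, p = 1. Two modes: within-method replicate comparison,
  and pairwise method comparison after pooling replicates.
* **Power**: power(n) = P(F′(k−1, k(n−1), λ) > F_crit(α)) with
  λ = k·n·s²_between/MSE, where s²_between is the k−1-divisor sample
  variance of the group means. Note this treats the observed spread of
  means as estimating a between-group variance component; it is modestly
  larger than the fixed-effects noncentrality n·(k−1)·s²_between/MSE that a
  plug-in of the observed means would give, so the returned sample sizes
  are the more optimistic of the two conventions. `sample_size_for_power`
  returns the smallest n ≥ 2 reaching the target (power is monotone in n);
  zero between-group variance yields an explicitly undefined result rather
  than an exception.

## Integrations, SVs, traces

* **Integration detection**: host-anchored pairs for one virus on one
  chromosome are clustered greedily from the leftmost member, so a cluster
  window never exceeds `cluster_window` (default 500 bp, a conventional
  discordant-pair clustering scale). Forward-strand anchors count as left
  (upstream) support, reverse-strand as right — the standard junction
  orientation heuristic, configurable. A site is reported when its
  best-supported flank reaches `min_support` (default 5); requiring both
  flanks is available (`side_rule="both"`). Mapping quality is carried but
  not filtered by default. Output is coordinate-sorted and independent of
  input order.
* **Reciprocal overlap**: deletions pass when the span intersection covers
  ≥ 50% of *both* calls (inclusive at the boundary, as "50% cutoff"
  conventionally is); matching also requires equal SV type and chromosome.
  Insertions occupy no reference span, so the size ratio min/max stands in
  for both fractions and breakpoints must lie within 10 kbp. Cross-algorithm
  consensus applies the same cutoff (exact matching would be defeated by
  breakpoint jitter between algorithms) and keeps the split-algorithm span.
  Cell-line-specific candidates have no passing match in any other sample;
  curation passes only with ≥1 supporting molecule in the owning line and 0
  in every other sample.
* **N50**: the largest length L in the collection such that maps of length
  ≥ L together cover strictly more than half the total length.
* **Trace rule**: background = the 20 flanking amplitudes on the expected
  alternate channel (flanks are assumed homozygous, so alternate-channel
  signal there is noise); threshold = mean + 2·sd with the n−1 divisor;
  a variant requires the centre amplitude strictly above the threshold.
  A pooled mode averages over all non-primary channels instead. The rule is
  scale-equivariant. Because the threshold is estimated from 20 samples, the
  exact false-call rate on homozygous traces is P(T₁₉ > 2/√(1+1/20)) ≈
  3.3%, not the naive normal 2.3%; the tests check against the exact rate.

## Pipeline

Stages communicate only through files named in the cohort manifest, so each
stage is independently re-runnable; per-stage input/output counts and
elapsed times are logged (counts, but not times, also land in
`report.json`, keeping the report bundle byte-reproducible). A stage
failure aborts with the stage name; the CLI maps configuration errors to
exit code 2 and stage failures to 3.

## Problem sizes used in the test and acceptance suites

Calibration suites regenerate cohorts at reduced scale chosen once for the
property under test: type-I error uses 500 null cohorts at λ = 25 per line
on a 0.4 Mbp genome (counts-only generation); deficit recovery uses 200
cohorts at λ = (300, 1000, 1000); the permutation Monte-Carlo cross-check
uses 10⁵ draws; trace and integration recovery use 1000 and 100 seeds. The
end-to-end pipeline tests run the full default cohort on a 0.8 Mbp genome.

## Known limitations

* The generator's uniform-position, signature-free mutation model cannot
  probe sequence-context-dependent behaviour.
* Coding-effect evaluation handles single-exon, plus-strand gene models
  only (synthetic mode); real-data consequence labels are consumed as
  inputs.
* The contrast permutation null is defined only for one-vs-all patterns;
  unbalanced designs beyond the collapsed (3, 6) case are out of scope.
* Binary chromatogram container formats are not parsed; traces enter as
  TSV amplitude windows.
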