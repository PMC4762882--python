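"""Inferential machinery for burden comparisons across reprogramming methods.

The study design is a balanced one-way layout: three methods x three replicate
cell lines.  Because the design is tiny, significance is assessed *exactly* by
recomputing the ANOVA F statistic over every distinct relabelling of samples
to methods (280 partitions for nine samples into three unlabeled groups of
three), rather than by asymptotic reference distributions.  One-vs-all planned
contrasts, relative mutation rates, Kruskal-Wallis comparison of deleterious-
ness score distributions, and noncentral-F power / sample-size estimation
round out the toolkit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "ContrastResult",
    "PowerEstimate",
    "enumerate_partitions",
    "n_partitions",
    "anova_F",
    "permutation_anova",
    "contrast_test",
    "relative_rates",
    "filter_reportable",
    "kruskal_wallis_scores",
    "cadd_comparison",
    "sample_size_for_power",
]

#: tolerance used when counting null statistics at least as extreme as the
#: observed one, so the observed partition is always counted even after
#: floating-point round-off
TIE_EPS = 1e-12


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Exact permutation ANOVA result for one burden category."""

    category: str
    F_obs: float
    null_F: np.ndarray
    p_value: float
    n_partitions: int


@dataclass
class ContrastResult:
    """A planned contrast on group means with pooled within-group error."""

    contrast: tuple
    estimate: float
    se: float
    t: float
    df: int
    p_parametric: float
    p_permutation: Optional[float] = None


@dataclass
class PowerEstimate:
    """Per-group sample size needed for a target ANOVA power.

    ``n_per_group`` is None when the between-group variance is zero, in which
    case no finite sample size attains the target power.
    """

    between_var: float
    within_var: float
    alpha: float
    target_power: float
    n_per_group: Optional[int]
    achieved_power: Optional[float] = None


# ---------------------------------------------------------------------------
# partition enumeration
# ---------------------------------------------------------------------------

def enumerate_partitions(sample_ids: Sequence, group_sizes: Sequence[int]):
    """Enumerate every distinct partition of ``sample_ids`` into unlabeled
    groups of the given sizes.

    Groups of equal size are interchangeable, so for nine samples split
    (3, 3, 3) there are 9!/(3!^3 * 3!) = 280 partitions; for a one-vs-all
    split (3, 6) the sizes differ and the count is C(9,3) = 84.

    Returns a list of partitions; each partition is a tuple of tuples of
    sample ids, groups ordered by their smallest member.
    """
    sizes = list(group_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("group sizes must be positive")
    ids = tuple(sample_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be distinct")
    if sum(sizes) != len(ids):
        raise ValueError(
            f"group sizes {sizes} do not sum to the number of samples {len(ids)}"
        )
    return list(_partitions(tuple(sorted(ids, key=_sort_key)), tuple(sorted(sizes))))


def _sort_key(x):
    return (str(type(x)), x)


def _partitions(ids, sizes):
    # The smallest remaining id always leads the next group; for groups of
    # equal size this canonical choice yields each unordered partition once.
    if not ids:
        yield ()
        return
    first, rest = ids[0], ids[1:]
    for size in sorted(set(sizes)):
        remaining = list(sizes)
        remaining.remove(size)
        for members in combinations(rest, size - 1):
            group = (first,) + members
            taken = set(members)
            leftover = tuple(x for x in rest if x not in taken)
            for sub in _partitions(leftover, tuple(remaining)):
                yield (group,) + sub


def n_partitions(group_sizes: Sequence[int]) -> int:
    """Closed-form count: (sum n_i)! / (prod n_i! * prod m_s!) where m_s is
    the multiplicity of each distinct group size s."""
    sizes = list(group_sizes)
    total = math.factorial(sum(sizes))
    denom = 1
    for s in sizes:
        denom *= math.factorial(s)
    for s in set(sizes):
        denom *= math.factorial(sizes.count(s))
    return total // denom


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def anova_F(values_by_group: Sequence[Sequence[float]]) -> float:
    """One-way ANOVA F = MS_between / MS_within.

    Returns 0.0 when all group means are equal, and +inf when the within-group
    variance is zero but the means differ (the degenerate noiseless case).
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    n_total = sum(g.size for g in groups)
    k = len(groups)
    if n_total - k < 1:
        raise ValueError("need at least one within-group degree of freedom")
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    if msw == 0.0:
        return 0.0 if msb <= TIE_EPS else math.inf
    return msb / msw


@lru_cache(maxsize=64)
def _partition_indices(n: int, sizes: tuple) -> np.ndarray:
    """Index form of enumerate_partitions(range(n), sizes) for balanced
    designs: an array (n_partitions, k, n_per_group) of sample indices."""
    parts = enumerate_partitions(range(n), sizes)
    return np.asarray(parts, dtype=np.intp)


def _null_F_balanced(values: np.ndarray, k: int, n_per: int) -> np.ndarray:
    """F statistic for every distinct partition of ``values`` into k unlabeled
    groups of size n_per, vectorized over partitions."""
    idx = _partition_indices(values.size, tuple([n_per] * k))
    grouped = values[idx]                      # (P, k, n_per)
    gmeans = grouped.mean(axis=2)              # (P, k)
    grand = values.mean()
    ssb = n_per * ((gmeans - grand) ** 2).sum(axis=1)
    ssw = ((grouped - gmeans[:, :, None]) ** 2).sum(axis=(1, 2))
    dfb, dfw = k - 1, values.size - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F = np.where(ssw == 0.0, np.where(ssb <= TIE_EPS, 0.0, np.inf), F)
    return F


def permutation_anova(values, labels, category: str = "") -> PermutationResult:
    """Exact permutation one-way ANOVA.

    ``values`` are per-sample burdens and ``labels`` the method of each
    sample; the null distribution is the F statistic over every distinct
    partition of the samples into unlabeled groups matching the observed
    group sizes.  The p-value is the fraction of partitions with
    F >= F_obs - 1e-12, so the observed labelling is always counted and
    p >= 1/n_partitions.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise ValueError("values and labels differ in length")
    uniq, inverse = np.unique(labels, return_inverse=True)
    groups = [values[inverse == i] for i in range(uniq.size)]
    sizes = [g.size for g in groups]
    F_obs = anova_F(groups)
    if len(set(sizes)) == 1:
        null_F = _null_F_balanced(values, len(sizes), sizes[0])
    else:
        null_F = np.array(
            [
                anova_F([values[list(g)] for g in part])
                for part in enumerate_partitions(range(values.size), sizes)
            ]
        )
    p = float(np.mean(null_F >= F_obs - TIE_EPS))
    return PermutationResult(
        category=category,
        F_obs=float(F_obs),
        null_F=null_F,
        p_value=p,
        n_partitions=int(null_F.size),
    )


# ---------------------------------------------------------------------------
# planned contrasts
# ---------------------------------------------------------------------------

def _one_vs_all_focus(contrast: np.ndarray) -> Optional[int]:
    """Index of the singled-out group if the contrast is one-vs-all shaped
    (one coefficient of one sign, the rest equal and of the other), else None."""
    k = contrast.size
    for i in range(k):
        others = np.delete(contrast, i)
        if np.all(others == others[0]) and others[0] != 0 and contrast[i] == -(k - 1) * others[0]:
            return i
    return None


def contrast_test(
    values_by_group: Sequence[Sequence[float]],
    contrast: Sequence[float],
    permutation: bool = True,
) -> ContrastResult:
    """Planned contrast on group means with pooled MSE error.

    estimate = sum(c_i * mean_i); se = sqrt(MSE * sum(c_i^2 / n_i));
    t = estimate/se on N - k degrees of freedom, two-sided parametric p.

    For one-vs-all contrasts (e.g. (-2, 1, 1)) an exact permutation p is also
    computed.  Because the contrast estimate depends only on the focal group,
    the design collapses to two groups (focal vs rest) and the null enumerates
    every C(N, n_focal) split, using the pooled two-group t statistic for both
    the observed and permuted data (the permuted three-group MSE would depend
    on an arbitrary split of the non-focal samples).
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    c = np.asarray(contrast, dtype=float)
    if c.size != len(groups):
        raise ValueError("one contrast coefficient per group required")
    if abs(c.sum()) > 1e-9:
        raise ValueError(f"contrast {tuple(contrast)} does not sum to zero")
    n = np.array([g.size for g in groups])
    if any(n < 2):
        raise ValueError("each group needs at least two observations")
    k = len(groups)
    N = int(n.sum())
    means = np.array([g.mean() for g in groups])
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = N - k
    mse = ssw / df
    estimate = float(c @ means)
    se = math.sqrt(mse * float((c**2 / n).sum()))
    t = estimate / se if se > 0 else math.copysign(math.inf, estimate) if estimate else 0.0
    p_par = float(2 * sps.t.sf(abs(t), df)) if math.isfinite(t) else 0.0

    p_perm = None
    focus = _one_vs_all_focus(c)
    if permutation and focus is not None:
        values = np.concatenate(groups)
        p_perm = _one_vs_all_permutation_p(values, int(n[focus]))
    return ContrastResult(
        contrast=tuple(contrast),
        estimate=estimate,
        se=se,
        t=float(t),
        df=df,
        p_parametric=p_par,
        p_permutation=p_perm,
    )


def _two_group_t(values: np.ndarray, focal_idx: np.ndarray) -> float:
    mask = np.zeros(values.size, dtype=bool)
    mask[focal_idx] = True
    a, b = values[mask], values[~mask]
    va = ((a - a.mean()) ** 2).sum()
    vb = ((b - b.mean()) ** 2).sum()
    sp2 = (va + vb) / (values.size - 2)
    se = math.sqrt(sp2 * (1 / a.size + 1 / b.size))
    diff = a.mean() - b.mean()
    if se == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / se


def _one_vs_all_permutation_p(values: np.ndarray, n_focal: int) -> float:
    """Exact two-sided permutation p for focal-group-vs-rest, over all
    C(N, n_focal) labeled splits of the samples."""
    obs = abs(_two_group_t(values, np.arange(n_focal)))
    stats = []
    for idx in combinations(range(values.size), n_focal):
        stats.append(abs(_two_group_t(values, np.asarray(idx))))
    stats = np.asarray(stats)
    return float(np.mean(stats >= obs - TIE_EPS))


# ---------------------------------------------------------------------------
# rates and reporting filters
# ---------------------------------------------------------------------------

def relative_rates(counts: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    """Per-sample category counts divided by the sample's total variant count.

    Raises on a zero total rather than emitting silent NaN rows.
    """
    totals = totals.reindex(counts.index)
    if totals.isna().any():
        missing = list(counts.index[totals.isna()])
        raise ValueError(f"no totals for samples {missing}")
    zero = list(totals.index[totals == 0])
    if zero:
        raise ValueError(f"zero total variant count for samples {zero}")
    return counts.div(totals, axis=0)


def filter_reportable(counts: pd.DataFrame, min_total: int = 10) -> list:
    """Categories whose summed count across samples reaches ``min_total``
    (at least 10 variants by default)."""
    sums = counts.sum(axis=0)
    return [c for c in counts.columns if sums[c] >= min_total]


# ---------------------------------------------------------------------------
# score-distribution comparison
# ---------------------------------------------------------------------------

def kruskal_wallis_scores(score_sets: Sequence[Sequence[float]]):
    """Tie-corrected Kruskal-Wallis H over the given score groups.

    Returns (H, p).  All-identical observations give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in score_sets]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty score group")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def cadd_comparison(scores_by_sample: dict, method_of: dict, mode: str = "pooled") -> pd.DataFrame:
    """Compare deleteriousness (e.g. CADD) score distributions.

    mode="replicates": one Kruskal-Wallis test per method across its replicate
    lines (checks within-method homogeneity).
    mode="pooled": pairwise method comparisons after pooling each method's
    replicates into a single distribution.
    """
    methods: dict[str, list] = {}
    for sample, m in method_of.items():
        methods.setdefault(m, []).append(sample)
    rows = []
    if mode == "replicates":
        for m, samples in methods.items():
            H, p = kruskal_wallis_scores([scores_by_sample[s] for s in samples])
            rows.append({"comparison": m, "H": H, "p": p})
    elif mode == "pooled":
        pooled = {
            m: np.concatenate([np.asarray(scores_by_sample[s], dtype=float) for s in samples])
            for m, samples in methods.items()
        }
        for a, b in combinations(sorted(pooled), 2):
            H, p = kruskal_wallis_scores([pooled[a], pooled[b]])
            rows.append({"comparison": f"{a} vs {b}", "H": H, "p": p})
    else:
        raise ValueError("mode must be 'replicates' or 'pooled'")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

def anova_power(
    n_per_group: int,
    k: int,
    between_var: float,
    within_var: float,
    alpha: float = 0.05,
) -> float:
    """Power of the balanced one-way ANOVA at per-group size n.

    Noncentral-F formulation with noncentrality k * n * between_var /
    within_var, where between_var is the sample variance (divisor k-1) of the
    group means — the convention of standard ANOVA power calculators.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    df1 = k - 1
    df2 = k * (n_per_group - 1)
    ncp = k * n_per_group * between_var / within_var
    fcrit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, ncp))


def sample_size_for_power(
    group_values: Sequence[Sequence[float]],
    alpha: float = 0.05,
    target_power: float = 0.80,
    max_n: int = 100_000,
) -> PowerEstimate:
    """Smallest per-group n for which the ANOVA on groups with the observed
    means and pooled variance reaches the target power.

    Between-group variance is the sample variance of the group means
    (divisor k-1); within-group variance is the pooled one-way MSE.  A zero
    between-group variance yields an undefined (None) sample size.
    """
    groups = [np.asarray(g, dtype=float) for g in group_values]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    k = len(groups)
    means = np.array([g.mean() for g in groups])
    between = float(np.var(means, ddof=1))
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    within = float(ssw / (sum(g.size for g in groups) - k))
    if between == 0.0 or within == 0.0:
        return PowerEstimate(between, within, alpha, target_power, None)
    for n in range(2, max_n + 1):
        power = anova_power(n, k, between, within, alpha)
        if power >= target_power:
            return PowerEstimate(between, within, alpha, target_power, n, power)
    return PowerEstimate(between, within, alpha, target_power, None)
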