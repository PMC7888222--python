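"""Hypothesis tests and correlations for activity patterns and image assays.

Repeated-measures rhythm testing follows the nonparametric route: a
tie-corrected Friedman test across sessions (time points) within neurons,
Dunn's post hoc against a reference time point, and a randomization control
that permutes each neuron's scores across sessions 1000 times to build an
empirical null of the Friedman p value.  Pattern similarity between mean
activity curves is Pearson correlation.  Between-group image quantifications
use Mann-Whitney, Kruskal-Wallis + Dunn, one-way ANOVA + Dunnett, or two-way
ANOVA + Tukey, mirroring the standard assignments for these assay designs.

Conventions fixed here:

* Friedman p values are exact (full within-row permutation enumeration)
  whenever (k!)^n <= ``exact_limit`` (default 1e6), else the chi-square
  approximation on k-1 df.  All-tied data gives statistic 0, p 1.
* Dunn's comparisons are two-sided z tests on rank(-sum) differences with
  tie-corrected variance, Bonferroni-adjusted over the many-to-one family.
* The randomization null permutes session labels independently within each
  neuron, preserving each neuron's score multiset; its 1000 p values use the
  chi-square approximation (the designs involved are far beyond enumeration)
  and are adjusted by Bonferroni by default (Benjamini-Hochberg optional).
* Rank tests switch from exact to asymptotic at n > 8 per group (or on ties).
* Unbalanced two-way ANOVA uses Type II sums of squares.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .traces import ActivityPattern

__all__ = [
    "FriedmanResult",
    "PosthocComparison",
    "RandomizationResult",
    "CorrelationResult",
    "GroupComparisonResult",
    "friedman_test",
    "dunn_posthoc",
    "randomization_null",
    "pattern_correlation",
    "split_half_correlation",
    "mann_whitney",
    "kruskal_dunn",
    "anova_dunnett",
    "anova2_tukey",
]

EXACT_ENUMERATION_LIMIT = 1_000_000


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    n_subjects: int
    n_conditions: int
    method: str = "chi2"  # "chi2" or "exact"


@dataclass(frozen=True)
class PosthocComparison:
    condition_index: int
    reference_index: int
    rank_difference: float
    z: float
    p_value: float
    adjusted_p: float
    significant: bool
    label: str = ""


@dataclass
class RandomizationResult:
    n_reps: int
    seed: int | None
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    alpha: float
    fraction_raw_significant: float
    fraction_adjusted_significant: float
    observed: FriedmanResult


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass
class GroupComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    comparisons: list[PosthocComparison] = field(default_factory=list)
    group_summaries: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def _summaries(groups, labels) -> pd.DataFrame:
    rows = []
    for lab, g in zip(labels, groups):
        g = np.asarray(g, dtype=float)
        sem = g.std(ddof=1) / math.sqrt(g.size) if g.size > 1 else float("nan")
        rows.append({"group": lab, "n": g.size, "mean": g.mean(), "sem": sem})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Friedman test


def _as_matrix(pattern) -> np.ndarray:
    if isinstance(pattern, ActivityPattern):
        return np.asarray(pattern.scores, dtype=float)
    x = np.asarray(pattern, dtype=float)
    if x.ndim != 2:
        raise ValueError("pattern must be a 2-D (subjects x conditions) array")
    return x


def _row_ranks(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Within-row mid-ranks and the total tie term sum(t^3 - t) over rows."""
    ranks = sps.rankdata(x, axis=1)
    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    return ranks, tie_term


def _friedman_statistic(col_rank_sums: np.ndarray, n: int, k: int, tie_term: float) -> float:
    """Tie-corrected Friedman chi-square from column rank sums."""
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0  # every row fully tied: no information
    a = 12.0 / (n * k * (k + 1)) * float(np.sum(col_rank_sums**2)) - 3.0 * n * (k + 1)
    return max(a / correction, 0.0)


def _exact_friedman_p(ranks: np.ndarray, n: int, k: int, tie_term: float, observed: float) -> float:
    """P(statistic >= observed) by dynamic programming over all within-row
    permutations of the observed rank vectors ((k!)^n relabelings)."""
    eps = 1e-9
    # distribution over column rank-sum vectors, built row by row
    dist: dict[tuple, int] = {tuple([0.0] * k): 1}
    for row in ranks:
        row_perms = [tuple(p) for p in itertools.permutations(row)]
        new: dict[tuple, int] = {}
        for sums, cnt in dist.items():
            for perm in row_perms:
                key = tuple(s + r for s, r in zip(sums, perm))
                new[key] = new.get(key, 0) + cnt
        dist = new
    total = 0
    hits = 0
    for sums, cnt in dist.items():
        total += cnt
        if _friedman_statistic(np.array(sums), n, k, tie_term) >= observed - eps:
            hits += cnt
    return hits / total


def friedman_test(
    pattern,
    method: str = "auto",
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> FriedmanResult:
    """Friedman repeated-measures rank test over a complete subjects × conditions matrix.

    ``method``: "auto" (exact enumeration when (k!)^n <= exact_limit, else
    chi-square), "exact", or "chi2".  All-tied data returns statistic 0, p 1.
    """
    x = _as_matrix(pattern)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix must be complete and finite")
    ranks, tie_term = _row_ranks(x)
    stat = _friedman_statistic(ranks.sum(axis=0), n, k, tie_term)
    n_relabelings = math.factorial(k) ** n
    use_exact = method == "exact" or (method == "auto" and n_relabelings <= exact_limit)
    if method not in ("auto", "exact", "chi2"):
        raise ValueError(f"unknown method {method!r}")
    if use_exact:
        if n_relabelings > exact_limit:
            raise ValueError("design too large for exact enumeration")
        p = _exact_friedman_p(ranks, n, k, tie_term, stat)
        how = "exact"
    else:
        p = 1.0 if stat == 0.0 else float(sps.chi2.sf(stat, k - 1))
        how = "chi2"
    return FriedmanResult(float(stat), k - 1, float(p), n, k, how)


# ---------------------------------------------------------------------------
# Dunn's post hoc (repeated measures, vs a reference condition)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method in ("bh", "fdr_bh"):
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def dunn_posthoc(
    pattern,
    reference_index: int = 0,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> list[PosthocComparison]:
    """Dunn's many-to-one comparisons after a Friedman test.

    Each non-reference condition is compared with the reference by the
    difference in mean within-row ranks, standardized with the tie-corrected
    variance k(k+1)/(6n) × C, and two-sided normal p values adjusted over the
    (k-1)-comparison family.
    """
    x = _as_matrix(pattern)
    n, k = x.shape
    if not 0 <= reference_index < k:
        raise ValueError("reference_index out of range")
    ranks, tie_term = _row_ranks(x)
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n) * max(correction, 0.0))
    out = []
    raw = []
    diffs = []
    zs = []
    idx = [j for j in range(k) if j != reference_index]
    for j in idx:
        diff = mean_ranks[j] - mean_ranks[reference_index]
        z = diff / se if se > 0 else 0.0
        p = 1.0 if se == 0 else float(2 * sps.norm.sf(abs(z)))
        diffs.append(diff)
        zs.append(z)
        raw.append(p)
    adj = _adjust(np.array(raw), adjust)
    for j, diff, z, p, ap in zip(idx, diffs, zs, raw, adj):
        out.append(
            PosthocComparison(
                condition_index=j,
                reference_index=reference_index,
                rank_difference=float(diff),
                z=float(z),
                p_value=float(p),
                adjusted_p=float(ap),
                significant=bool(ap < alpha),
            )
        )
    return out


# ---------------------------------------------------------------------------
# randomization null


def _permuted_friedman_pvalues(
    ranks: np.ndarray, tie_term: float, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Chi-square p of the Friedman statistic for ``n_reps`` independent
    within-row shuffles of the rank matrix.

    Permuting a neuron's scores across sessions permutes its rank vector the
    same way, so the ranks (and the tie term) can be computed once.
    """
    n, k = ranks.shape
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        return np.ones(n_reps)
    # independent column shuffles per row per rep via argsort of random keys
    keys = rng.random((n_reps, n, k))
    order = np.argsort(keys, axis=2)
    permuted = np.take_along_axis(np.broadcast_to(ranks, (n_reps, n, k)), order, axis=2)
    col_sums = permuted.sum(axis=1)  # (n_reps, k)
    a = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2, axis=1) - 3.0 * n * (k + 1)
    stat = np.maximum(a / correction, 0.0)
    return sps.chi2.sf(stat, k - 1)


def randomization_null(
    pattern,
    n_reps: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> RandomizationResult:
    """Permutation control for the Friedman test on an activity pattern.

    For each of ``n_reps`` repetitions every neuron's scores are shuffled
    across sessions (destroying any common temporal structure while keeping
    each neuron's score distribution), the Friedman test is re-run, and the
    resulting p values are adjusted for the repeated testing.  A genuine
    population rhythm shows up as an observed p value below the whole null
    cloud and no adjusted permuted p below ``alpha``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    x = _as_matrix(pattern)
    n, k = x.shape
    ranks, tie_term = _row_ranks(x)
    stat = _friedman_statistic(ranks.sum(axis=0), n, k, tie_term)
    obs_p = 1.0 if stat == 0.0 else float(sps.chi2.sf(stat, k - 1))
    observed = FriedmanResult(stat, k - 1, obs_p, n, k, "chi2")
    rng = np.random.default_rng(seed)
    raw = _permuted_friedman_pvalues(ranks, tie_term, n_reps, rng)
    adjusted = _adjust(raw, adjust)
    return RandomizationResult(
        n_reps=n_reps,
        seed=seed,
        raw_p=raw,
        adjusted_p=adjusted,
        alpha=alpha,
        fraction_raw_significant=float(np.mean(raw < alpha)),
        fraction_adjusted_significant=float(np.mean(adjusted < alpha)),
        observed=observed,
    )


# ---------------------------------------------------------------------------
# correlations


def pattern_correlation(x, y) -> CorrelationResult:
    """Pearson r between two mean-activity curves, two-sided t-based p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def split_half_correlation(pattern, window_h: float = 32.0) -> CorrelationResult:
    """Correlate the mean activity curve of the first ``window_h`` hours with
    the next ``window_h`` hours, matched by offset within the window."""
    if not isinstance(pattern, ActivityPattern):
        raise TypeError("split_half_correlation needs an ActivityPattern")
    t = pattern.session_times_h
    steps = np.diff(t)
    if t.size < 2 or np.ptp(steps) > 1e-9:
        raise ValueError("sessions must be evenly spaced")
    cadence = float(steps[0])
    n_per = int(round(window_h / cadence))
    span = t[-1] - t[0] + cadence  # total covered time
    if span < 2 * window_h or t.size < 2 * n_per:
        raise ValueError(
            f"recording span {span:g} h too short for two {window_h:g} h windows"
        )
    means = pattern.mean_scores()
    return pattern_correlation(means[:n_per], means[n_per : 2 * n_per])


# ---------------------------------------------------------------------------
# between-group tests

EXACT_RANK_N = 8  # per-group size at or below which rank tests enumerate exactly


def mann_whitney(a, b) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both groups have n <= 8 and there are no ties
    across the pooled sample; tie-corrected normal approximation (with
    continuity correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= EXACT_RANK_N and b.size <= EXACT_RANK_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparisonResult(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=_summaries([a, b], ["a", "b"]),
        extra={"method": method},
    )


def _kruskal_h(groups_ranks: list[np.ndarray], n_total: int, tie_term: float) -> float:
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:
        return 0.0
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        r.sum() ** 2 / r.size for r in groups_ranks
    ) - 3 * (n_total + 1)
    return max(h / correction, 0.0)


def _exact_kruskal_p(all_ranks: np.ndarray, sizes: list[int], tie_term: float, observed: float) -> float:
    """Exact permutation p of the Kruskal-Wallis H by enumerating all distinct
    assignments of the pooled ranks to groups."""
    eps = 1e-9
    n_total = all_ranks.size
    idx = list(range(n_total))

    hits = 0
    total = 0

    def recurse(remaining: tuple, size_i: int, chosen: list):
        nonlocal hits, total
        if size_i == len(sizes) - 1:
            groups = chosen + [np.array([all_ranks[i] for i in remaining])]
            h = _kruskal_h(groups, n_total, tie_term)
            total += 1
            if h >= observed - eps:
                hits += 1
            return
        for combo in itertools.combinations(remaining, sizes[size_i]):
            rest = tuple(i for i in remaining if i not in set(combo))
            recurse(rest, size_i + 1, chosen + [np.array([all_ranks[i] for i in combo])])

    recurse(tuple(idx), 0, [])
    return hits / total


def _n_kruskal_assignments(sizes: list[int]) -> int:
    n = sum(sizes)
    total = 1
    for s in sizes[:-1]:
        total *= math.comb(n, s)
        n -= s
    return total


def kruskal_dunn(
    groups,
    reference_index: int = 0,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    method: str = "auto",
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
    labels=None,
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus (tie-corrected) with Dunn's many-to-one post hoc.

    ``method`` "auto" enumerates the exact permutation distribution of H when
    the number of distinct group assignments is <= ``exact_limit``; otherwise
    the chi-square approximation is used.  Dunn z statistics use the pooled
    mean-rank difference with tie-corrected variance and Bonferroni family
    adjustment against the reference group.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if not 0 <= reference_index < len(groups):
        raise ValueError("reference_index out of range")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    group_ranks = [ranks[bounds[i] : bounds[i + 1]] for i in range(len(groups))]
    h = _kruskal_h(group_ranks, n_total, tie_term)
    n_assign = _n_kruskal_assignments(sizes)
    use_exact = method == "exact" or (method == "auto" and n_assign <= exact_limit)
    if use_exact:
        if n_assign > exact_limit:
            raise ValueError("design too large for exact enumeration")
        p = _exact_kruskal_p(ranks, sizes, tie_term, h)
        how = "exact"
    else:
        p = 1.0 if h == 0.0 else float(sps.chi2.sf(h, len(groups) - 1))
        how = "chi2"
    # Dunn's z comparisons vs the reference group
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks = [gr.mean() for gr in group_ranks]
    comparisons = []
    raw = []
    zs = []
    idx = [j for j in range(len(groups)) if j != reference_index]
    for j in idx:
        se = math.sqrt(var_base * (1.0 / sizes[j] + 1.0 / sizes[reference_index]))
        diff = mean_ranks[j] - mean_ranks[reference_index]
        z = diff / se if se > 0 else 0.0
        raw.append(1.0 if se == 0 else float(2 * sps.norm.sf(abs(z))))
        zs.append(z)
    adj = _adjust(np.array(raw), adjust)
    for j, z, pr, ap in zip(idx, zs, raw, adj):
        comparisons.append(
            PosthocComparison(
                condition_index=j,
                reference_index=reference_index,
                rank_difference=float(mean_ranks[j] - mean_ranks[reference_index]),
                z=float(z),
                p_value=float(pr),
                adjusted_p=float(ap),
                significant=bool(ap < alpha),
                label=f"{labels[j]} vs {labels[reference_index]}",
            )
        )
    return GroupComparisonResult(
        test_name="kruskal_dunn",
        statistic=float(h),
        p_value=float(p),
        comparisons=comparisons,
        group_summaries=_summaries(groups, labels),
        extra={"method": how},
    )


def anova_dunnett(
    groups,
    reference_index: int = 0,
    alpha: float = 0.05,
    seed: int | None = 0,
    labels=None,
) -> GroupComparisonResult:
    """One-way ANOVA with Dunnett's many-to-one comparisons.

    Omnibus F from scipy; Dunnett adjusted p values from the multivariate-t
    reference distribution (seeded, reproducible draws).  With two groups the
    Dunnett family reduces to a plain two-sample t test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if not 0 <= reference_index < len(groups):
        raise ValueError("reference_index out of range")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(groups))]
    pooled_var = np.concatenate([g - g.mean() for g in groups]).var(ddof=0)
    means = [g.mean() for g in groups]
    if pooled_var == 0:
        # degenerate: no within-group variance
        distinct = len(set(round(m, 12) for m in means)) > 1
        f = math.inf if distinct else 0.0
        p = 0.0 if distinct else 1.0
        comparisons = []
        idx = [j for j in range(len(groups)) if j != reference_index]
        for j in idx:
            same = means[j] == means[reference_index]
            comparisons.append(
                PosthocComparison(
                    condition_index=j,
                    reference_index=reference_index,
                    rank_difference=float(means[j] - means[reference_index]),
                    z=0.0 if same else math.inf,
                    p_value=1.0 if same else 0.0,
                    adjusted_p=1.0 if same else 0.0,
                    significant=not same,
                    label=f"{labels[j]} vs {labels[reference_index]}",
                )
            )
        return GroupComparisonResult(
            "anova_dunnett", f, p, comparisons, _summaries(groups, labels)
        )
    f_res = sps.f_oneway(*groups)
    control = groups[reference_index]
    others = [g for j, g in enumerate(groups) if j != reference_index]
    idx = [j for j in range(len(groups)) if j != reference_index]
    rng = np.random.default_rng(seed)
    d_res = sps.dunnett(*others, control=control, random_state=rng)
    comparisons = []
    for pos, j in enumerate(idx):
        diff = means[j] - means[reference_index]
        ap = float(d_res.pvalue[pos])
        comparisons.append(
            PosthocComparison(
                condition_index=j,
                reference_index=reference_index,
                rank_difference=float(diff),
                z=float(d_res.statistic[pos]),
                p_value=ap,  # Dunnett p values are family-adjusted by construction
                adjusted_p=ap,
                significant=bool(ap < alpha),
                label=f"{labels[j]} vs {labels[reference_index]}",
            )
        )
    return GroupComparisonResult(
        test_name="anova_dunnett",
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        comparisons=comparisons,
        group_summaries=_summaries(groups, labels),
    )


def anova2_tukey(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Two-way ANOVA with interaction (Type II sums of squares) and Tukey HSD
    over the cell means.

    ``table`` is a long-format frame with one observation per row.  Every
    factor-level combination must be observed, and at least one cell must be
    replicated, otherwise the interaction term is not estimable.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[value, factor_a, factor_b]].copy()
    df.columns = ["value", "fa", "fb"]
    levels_a = sorted(df["fa"].astype(str).unique())
    levels_b = sorted(df["fb"].astype(str).unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    df["fa"] = df["fa"].astype(str)
    df["fb"] = df["fb"].astype(str)
    counts = df.groupby(["fa", "fb"]).size()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index:
                raise ValueError(f"empty cell: ({la}, {lb})")
    n_cells = len(levels_a) * len(levels_b)
    if len(df) - n_cells <= 0:
        raise ValueError("no residual degrees of freedom: replicate at least one cell")
    model = smf.ols("value ~ C(fa) * C(fb)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    p_a = float(aov.loc["C(fa)", "PR(>F)"])
    p_b = float(aov.loc["C(fb)", "PR(>F)"])
    p_ab = float(aov.loc["C(fa):C(fb)", "PR(>F)"])
    # Tukey over cells
    cell_labels = []
    cell_samples = []
    for la in levels_a:
        for lb in levels_b:
            cell_labels.append(f"{la}:{lb}")
            cell_samples.append(df.loc[(df.fa == la) & (df.fb == lb), "value"].to_numpy())
    comparisons = []
    if all(len(c) >= 2 for c in cell_samples):
        t_res = sps.tukey_hsd(*cell_samples)
        for i in range(len(cell_samples)):
            for j in range(i + 1, len(cell_samples)):
                ap = float(t_res.pvalue[i, j])
                comparisons.append(
                    PosthocComparison(
                        condition_index=j,
                        reference_index=i,
                        rank_difference=float(
                            np.mean(cell_samples[j]) - np.mean(cell_samples[i])
                        ),
                        z=float(t_res.statistic[i, j]),
                        p_value=ap,  # Tukey p values are family-adjusted by construction
                        adjusted_p=ap,
                        significant=bool(ap < alpha),
                        label=f"{cell_labels[j]} vs {cell_labels[i]}",
                    )
                )
    return GroupComparisonResult(
        test_name="anova2_tukey",
        statistic=float(aov.loc["C(fa):C(fb)", "F"]),
        p_value=p_ab,
        comparisons=comparisons,
        group_summaries=_summaries(cell_samples, cell_labels),
        extra={
            "p_factor_a": p_a,
            "p_factor_b": p_b,
            "p_interaction": p_ab,
            "anova_table": aov,
        },
    )


def results_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """Flatten test results to one row per test / comparison for CSV export."""
    rows = []
    for res in results:
        rows.append(
            {
                "test": res.test_name,
                "comparison": "omnibus",
                "statistic": res.statistic,
                "p": res.p_value,
                "adjusted_p": np.nan,
            }
        )
        for c in res.comparisons:
            rows.append(
                {
                    "test": res.test_name,
                    "comparison": c.label or f"{c.condition_index} vs {c.reference_index}",
                    "statistic": c.z,
                    "p": c.p_value,
                    "adjusted_p": c.adjusted_p,
                }
            )
    return pd.DataFrame(rows)
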