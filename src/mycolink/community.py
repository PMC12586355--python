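"""ASV-table preprocessing and community-level permutation statistics.

An ASV table is a pandas DataFrame of nonnegative integer counts indexed by
ASV id with one column per sample.  The functions here cover the standard
amplicon workflow upstream of network construction — rarefaction to a common
depth, relative abundance, prevalence filtering — together with the
community statistics used throughout the analysis: Bray-Curtis distances,
Anosim, the Mantel test, Venn presence partitions, log response ratios, and
one-way ANOVA with Tukey's HSD and a compact letter display.

Mantel and Anosim are permutation tests.  Both are implemented as vectorised
permutation engines (all permutations evaluated in one pass over the
condensed distance vector) so that null-calibration experiments with
hundreds of replicates stay cheap.  p-values use the add-one estimator
``(1 + #{perm >= obs}) / (1 + n_perm)`` and are therefore never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

__all__ = [
    "rarefy",
    "relative_abundance",
    "prevalence_filter",
    "bray_curtis",
    "euclidean_1d",
    "mantel",
    "mantel_many",
    "anosim",
    "venn_partition",
    "response_ratio",
    "one_way_anova",
    "tukey_hsd",
    "TukeyResult",
]


def _check_counts(table: pd.DataFrame) -> None:
    if table.index.has_duplicates:
        raise ValueError("duplicate ASV ids in table")
    if table.columns.has_duplicates:
        raise ValueError("duplicate sample ids in table")
    if (table.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")


# ---------------------------------------------------------------------------
# Preprocessing


def rarefy(table: pd.DataFrame, depth: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample without replacement to a common depth.

    ``depth=None`` uses the minimum sample total.  Samples with fewer than
    ``depth`` reads are dropped with a logged warning.  Subsampling is
    multivariate hypergeometric, i.e. exact sampling without replacement.
    """
    _check_counts(table)
    totals = table.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    keep = totals[totals >= depth].index
    dropped = [s for s in table.columns if s not in set(keep)]
    if not len(keep):
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        col = table[s].to_numpy(dtype=np.int64)
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    res = pd.DataFrame(out, index=table.index)[list(keep)]
    return res


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1."""
    totals = table.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    return table / totals


def prevalence_filter(table: pd.DataFrame, min_prevalence: float = 0.20) -> pd.DataFrame:
    """Keep ASVs present (count > 0) in strictly more than ``min_prevalence``
    of samples.

    The rule is strict: with 33 samples and the default 20 % threshold an ASV
    needs presence in at least 7 samples (7/33 = 21.2 % > 20 %); 6/33 is
    removed.
    """
    n = table.shape[1]
    present = (table > 0).sum(axis=1)
    return table.loc[present > min_prevalence * n]


# ---------------------------------------------------------------------------
# Distances


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis distances between samples (columns) of an abundance table."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = table.to_numpy(dtype=float).T  # samples x ASVs
    if (x.sum(axis=1) == 0).any():
        bad = [s for s, tot in zip(table.columns, x.sum(axis=1)) if tot == 0]
        raise ValueError(f"Bray-Curtis undefined for all-zero sample(s): {bad}")
    condensed = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(c) for c in table.columns])


def euclidean_1d(values: pd.Series) -> DistanceMatrix:
    """Absolute-difference distance matrix of one (usually standardised) variable."""
    v = values.to_numpy(dtype=float)
    return DistanceMatrix(np.abs(v[:, None] - v[None, :]), ids=[str(i) for i in values.index])


def _condensed(dm: DistanceMatrix) -> np.ndarray:
    return squareform(np.asarray(dm.data), checks=False)


def _perm_condensed(data: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Condensed vectors of ``data`` under each row/column permutation.

    ``perms`` has shape (n_perm, n); returns (n_perm, n*(n-1)/2).
    """
    n = data.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return data[perms[:, iu], perms[:, ju]]


def _pearson_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with vector ``y``."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rc @ yc) / denom


# ---------------------------------------------------------------------------
# Mantel


def _align(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices cover different sample sets")
    d2 = d2.filter(d1.ids)
    return np.asarray(d1.data), np.asarray(d2.data)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test: Pearson correlation between two distance matrices.

    The statistic is the Pearson correlation of the strictly-lower-triangle
    vectors; the null distribution comes from simultaneous row/column
    permutations of ``d1``.
    """
    r, p = mantel_many(d1, [d2], n_perm=n_perm, seed=seed, alternative=alternative)
    return float(r[0]), float(p[0])


def mantel_many(
    d1: DistanceMatrix,
    others: Sequence[DistanceMatrix],
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[np.ndarray, np.ndarray]:
    """Mantel tests of ``d1`` against several matrices with one shared
    permutation set.

    Sharing the permutations makes the tests comparable across the second
    matrices (common random numbers) and lets the permuted condensed vectors
    of ``d1`` be reused, which is what makes module-by-variable linkage
    grids cheap.
    """
    if alternative not in {"greater", "less", "two-sided"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m1 = np.asarray(d1.data)
    n = m1.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 samples")
    vecs = []
    for d2 in others:
        _, m2 = _align(d1, d2)
        vecs.append(squareform(m2, checks=False))
    y = np.stack(vecs, axis=1)  # (npairs, nvars)
    v1 = squareform(m1, checks=False)
    if v1.std() == 0 or (y.std(axis=0) == 0).any():
        raise ValueError("constant distance matrix: Mantel r undefined")

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    pv = _perm_condensed(m1, perms)  # (n_perm, npairs)

    def corr(rows: np.ndarray) -> np.ndarray:
        rc = rows - rows.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=0, keepdims=True)
        denom = np.sqrt((rc ** 2).sum(axis=1)[:, None] * (yc ** 2).sum(axis=0)[None, :])
        return (rc @ yc) / denom

    r_obs = corr(v1[None, :])[0]
    r_null = corr(pv)
    if alternative == "greater":
        exceed = (r_null >= r_obs[None, :]).sum(axis=0)
    elif alternative == "less":
        exceed = (r_null <= r_obs[None, :]).sum(axis=0)
    else:
        exceed = (np.abs(r_null) >= np.abs(r_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return r_obs, p


# ---------------------------------------------------------------------------
# Anosim


def anosim(
    dist: DistanceMatrix,
    labels: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Anosim: are between-group distances larger than within-group ones?

    R = (mean between-group rank - mean within-group rank) / (N(N-1)/4) on
    the ranked condensed distances; the p-value comes from label
    permutations (one-sided, large R).
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    ids = list(dist.ids)
    missing = [i for i in ids if i not in labels.index]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    grouping = labels.loc[ids].to_numpy()
    if len(np.unique(grouping)) < 2:
        raise ValueError("Anosim needs at least 2 groups")
    n = len(ids)
    v = _condensed(dist)
    ranks = scipy.stats.rankdata(v)  # average ranks for ties
    iu, ju = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4.0

    codes = pd.factorize(grouping)[0]

    def stat(code_rows: np.ndarray) -> np.ndarray:
        within = code_rows[:, iu] == code_rows[:, ju]
        nw = within.sum(axis=1)
        nb = within.shape[1] - nw
        rw = (ranks[None, :] * within).sum(axis=1) / nw
        rb = (ranks[None, :] * ~within).sum(axis=1) / nb
        return (rb - rw) / denom

    r_obs = float(stat(codes[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    r_null = stat(codes[perms])
    p = float((1.0 + (r_null >= r_obs).sum()) / (1.0 + n_perm))
    return r_obs, p


# ---------------------------------------------------------------------------
# Presence partitions and response ratios


def venn_partition(tables_by_group: Mapping[str, pd.DataFrame]) -> dict:
    """Shared/unique ASV counts across groups.

    An ASV is "present" in a group when it has a nonzero count in any of the
    group's samples.  Returns the count present in every group, the count
    exclusive to each group, and the total number of distinct ASVs.
    """
    if len(tables_by_group) < 2:
        raise ValueError("need at least 2 groups")
    present = {
        g: set(t.index[(t > 0).any(axis=1)]) for g, t in tables_by_group.items()
    }
    universe = set().union(*present.values())
    shared = set.intersection(*present.values())
    unique = {
        g: len(s - set().union(*(o for h, o in present.items() if h != g)))
        for g, s in present.items()
    }
    return {"shared": len(shared), "unique": unique, "total": len(universe)}


def response_ratio(
    treatment: Sequence[float], control: Sequence[float]
) -> tuple[float, float]:
    """Log response ratio ln(mean_t / mean_c) with its delta-method SE.

    Positive values mean the property is higher under treatment.  SE is
    sqrt(sd_t^2 / (n_t m_t^2) + sd_c^2 / (n_c m_c^2)).
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be nonempty")
    mt, mc = t.mean(), c.mean()
    if mt <= 0 or mc <= 0:
        raise ValueError("response ratio requires strictly positive group means")
    rr = float(np.log(mt / mc))
    vt = t.var(ddof=1) / (t.size * mt ** 2) if t.size > 1 else 0.0
    vc = c.var(ddof=1) / (c.size * mc ** 2) if c.size > 1 else 0.0
    return rr, float(np.sqrt(vt + vc))


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def one_way_anova(values: Sequence[float], labels: Sequence[str]) -> tuple[float, float]:
    """Classical one-way ANOVA F test across groups."""
    s = pd.Series(np.asarray(values, dtype=float), index=list(labels))
    groups = [g.to_numpy() for _, g in s.groupby(level=0)]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("zero within-group variance in every group")
    f, p = scipy.stats.f_oneway(*groups)
    return float(f), float(p)


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise Tukey HSD decisions plus a compact letter display."""

    pairwise: pd.DataFrame  # columns group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]  # group -> letter string; shared letter = not distinct
    group_means: dict[str, float]


def tukey_hsd(values: Sequence[float], labels: Sequence[str], alpha: float = 0.05) -> TukeyResult:
    """Tukey honestly-significant-difference comparisons with letters.

    Groups whose means are not significantly different share at least one
    letter.  Letters are assigned with the insert-and-absorb algorithm on
    groups ordered by ascending mean, which makes the display deterministic.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray([str(l) for l in labels])
    res = pairwise_tukeyhsd(vals, labs, alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    pairwise = pd.DataFrame({
        "group1": table["group1"].astype(str),
        "group2": table["group2"].astype(str),
        "meandiff": table["meandiff"].astype(float),
        "p_adj": table["p-adj"].astype(float),
        "reject": table["reject"].astype(bool),
    })
    means = {g: float(vals[labs == g].mean()) for g in np.unique(labs)}
    distinct = {
        frozenset((r.group1, r.group2)) for r in pairwise.itertuples() if r.reject
    }
    letters = _compact_letters(means, distinct)
    return TukeyResult(pairwise=pairwise, letters=letters, group_means=means)


def _compact_letters(
    means: Mapping[str, float], distinct_pairs: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Start from one column holding every group; for each significantly
    different pair split any column containing both; absorb columns that
    became subsets of others.  Ties are broken by ascending group mean.
    """
    order = sorted(means, key=lambda g: (means[g], g))
    columns: list[set[str]] = [set(order)]
    for pair in sorted(distinct_pairs, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb
        columns = [
            c for c in columns
            if c and not any(c < o for o in columns if o is not c)
        ]
        # drop duplicates
        seen, uniq = set(), []
        for c in columns:
            key = frozenset(c)
            if key not in seen:
                seen.add(key)
                uniq.append(c)
        columns = uniq
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for i, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters
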