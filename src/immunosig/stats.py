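"""Nonparametric group comparisons, FDR control, and hierarchical clustering.

Group differences in expression are assessed rank-based throughout:
Kruskal-Wallis across strata, Wilcoxon rank-sum for two groups, and
Dunn's z post hoc (on the pooled Kruskal-Wallis ranks, tie-corrected,
Benjamini-Hochberg adjusted across pairs) when more than two groups are
compared.  Clustering is complete-linkage on 1 - Pearson r.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


def _split_groups(values: pd.Series, labels: pd.Series) -> dict[str, np.ndarray]:
    labels = labels.loc[values.index]
    groups = {g: values[labels == g].to_numpy(dtype=float)
              for g in pd.unique(labels)}
    for g, arr in groups.items():
        if arr.size == 0:
            raise ValidationError(f"empty group {g!r}")
    return groups


def _kw_h(arrays: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H for a list of group arrays."""
    pooled = np.concatenate(arrays)
    if len(np.unique(pooled)) == 1:
        return 0.0
    n = pooled.size
    ranks = ss.rankdata(pooled)
    h = 0.0
    start = 0
    for arr in arrays:
        r = ranks[start:start + arr.size]
        h += r.sum() ** 2 / arr.size
        start += arr.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    correction = 1.0 - (t ** 3 - t).sum() / (n ** 3 - n)
    return h / correction if correction > 0 else 0.0


def kruskal_wallis(
    values: pd.Series, labels: pd.Series, method: str = "auto"
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square or exact p.

    ``method="auto"`` enumerates the exact permutation null when the
    pooled sample is small (n <= 9), otherwise uses the chi-square
    reference with k-1 df; ``"asymptotic"`` and ``"exact"`` force
    either path.
    """
    groups = _split_groups(values, labels)
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    sizes = [a.size for a in arrays]
    h = _kw_h(arrays)
    if len(np.unique(pooled)) == 1:
        return 0.0, 1.0
    exact = method == "exact" or (method == "auto" and pooled.size <= 9)
    if not exact:
        p = float(ss.chi2.sf(h, len(arrays) - 1))
        return float(h), min(p, 1.0)
    # enumerate all distinct assignments of pooled indices to group sizes
    count = total = 0
    for split in _multiset_splits(tuple(range(pooled.size)), sizes):
        arrs = [pooled[list(part)] for part in split]
        total += 1
        if _kw_h(arrs) >= h - 1e-12:
            count += 1
    return float(h), count / total


def _multiset_splits(indices: tuple, sizes: list[int]):
    """Yield every split of ``indices`` into consecutive groups of ``sizes``."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for first in itertools.combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in set(first))
        for tail in _multiset_splits(rest, sizes[1:]):
            yield (first,) + tail


def wilcoxon_rank_sum(
    a: np.ndarray | pd.Series, b: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups are small and
    untied, the normal approximation otherwise (scipy's ``auto`` rule).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty group in rank-sum test")
    if a.size == 1 or b.size == 1:
        log.warning("rank-sum comparison with a singleton group: low power")
    if np.array_equal(np.sort(a), np.sort(b)):
        return float(a.size * b.size / 2.0), 1.0
    u, p = ss.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(u), float(min(p, 1.0))


@dataclass
class DunnResult:
    """Pairwise Dunn z statistics with raw and BH-adjusted p-values."""

    table: pd.DataFrame  # columns: group_a, group_b, z, p, q


def dunn_posthoc(values: pd.Series, labels: pd.Series) -> DunnResult:
    """Dunn's multiple-comparison post hoc on pooled ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt(tie_corrected_var * (1/n_i + 1/n_j));
    two-sided p from the standard normal, BH-adjusted across pairs.
    """
    groups = _split_groups(values, labels)
    names = list(groups.keys())
    pooled = np.concatenate([groups[g] for g in names])
    n = pooled.size
    ranks = ss.rankdata(pooled)
    offsets = np.cumsum([0] + [groups[g].size for g in names])
    mean_rank = {g: ranks[offsets[i]:offsets[i + 1]].mean()
                 for i, g in enumerate(names)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for ga, gb in itertools.combinations(names, 2):
        na, nb = groups[ga].size, groups[gb].size
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = 0.0 if se == 0 else (mean_rank[ga] - mean_rank[gb]) / se
        p = 2.0 * ss.norm.sf(abs(z))
        rows.append((ga, gb, z, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    return DunnResult(table)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ClusterResult:
    """Complete-linkage clustering of one matrix axis."""

    linkage: np.ndarray        # scipy linkage matrix
    order: list[str]           # dendrogram leaf order
    item_ids: list[str]
    dropped: list[str]         # zero-variance items removed pre-clustering
    zscores: pd.DataFrame      # per-gene z-scored values for heatmap export


def hierarchical_cluster(m: ExpressionMatrix, axis: str = "samples") -> ClusterResult:
    """Complete-linkage clustering with d = 1 - Pearson correlation.

    Zero-variance items (undefined correlation) are dropped with a
    warning.  The returned z-scores are per-gene standardized values of
    the full matrix, the conventional heatmap scaling.
    """
    if axis not in ("samples", "genes"):
        raise ValidationError(f"axis must be samples/genes, got {axis!r}")
    data = m.values.T if axis == "samples" else m.values
    ids = list(data.index)
    if len(ids) < 2:
        raise ValidationError("need >= 2 items to cluster")
    var = data.var(axis=1, ddof=0)
    dropped = list(data.index[var == 0])
    if dropped:
        log.warning("dropping %d zero-variance item(s) before clustering",
                    len(dropped))
        data = data.loc[var > 0]
        ids = list(data.index)
    x = data.to_numpy(dtype=float)
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce symmetry
    condensed = dist[np.triu_indices(len(ids), k=1)]
    linkage = sch.linkage(condensed, method="complete")
    order = [ids[i] for i in sch.leaves_list(linkage)]
    mu = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=0).replace(0.0, np.nan)
    z = m.values.sub(mu, axis=0).div(sd, axis=0)
    return ClusterResult(linkage, order, ids, dropped, z)
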