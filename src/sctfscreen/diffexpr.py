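"""Marker and two-cluster differential expression.

Genes are tested with the Wilcoxon rank-sum test on normalized values
(exact mid-rank permutation enumeration for tiny groups, tie-corrected
normal approximation otherwise), fold changes follow the de-logged
cluster-mean convention with a pseudocount of 1, and multiplicity is
controlled by Benjamini-Hochberg FDR over the tested gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .preprocess import NormalizedMatrix

__all__ = [
    "wilcoxon_test",
    "fold_change",
    "find_markers",
    "deg_between",
    "DegTiers",
]

DEG_COLUMNS = [
    "gene_id",
    "group",
    "log_fc",
    "fold_change",
    "pct_in",
    "pct_out",
    "p_value",
    "fdr",
    "direction",
]


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments of the
    pooled mid-ranks. Feasible for small groups only."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    n = x.size
    w_obs = ranks[:n].sum()
    mu = ranks.sum() * n / ranks.size
    dev = abs(w_obs - mu)
    total = 0
    extreme = 0
    for comb in combinations(range(ranks.size), n):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= dev - 1e-9:
            extreme += 1
    return extreme / total


def _approx_rank_sum_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized two-sided normal-approximation rank-sum p-values.

    ``x``: (n_a, G), ``y``: (n_b, G). Tie-corrected variance and continuity
    correction; a gene whose pooled values are all tied gets p = 1.
    """
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            x, y, axis=0, alternative="two-sided", method="asymptotic"
        )
        p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def wilcoxon_test(x, y, exact_max: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses exact permutation enumeration when both groups have at most
    ``exact_max`` observations, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty")
    if x.size <= exact_max and y.size <= exact_max:
        return min(1.0, _exact_rank_sum_p(x, y))
    return float(_approx_rank_sum_p(x[:, None], y[:, None])[0])


def _group_stats(nm: NormalizedMatrix, idx: np.ndarray):
    """De-logged mean + 1 and detection fraction per gene over a cell set."""
    sub = nm.values[idx]
    sub_e = sub.copy()
    sub_e.data = np.expm1(sub_e.data)
    expm1_sum = np.asarray(sub_e.sum(axis=0)).ravel()
    mean_plus1 = expm1_sum / idx.size + 1.0
    pct = sub.getnnz(axis=0) / idx.size  # normalized value > 0 iff count > 0
    return mean_plus1, pct


def fold_change(nm: NormalizedMatrix, group_a, group_b, gene: int):
    """(log_fc, fold_change, pct_a, pct_b) for one gene.

    fold_change = (mean_a(expm1) + 1) / (mean_b(expm1) + 1), log_fc its
    natural log; pct = fraction of group cells expressing the gene.
    """
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise DataError("groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise DataError("groups must be disjoint")
    ma, pa = _group_stats(nm, a)
    mb, pb = _group_stats(nm, b)
    fc = ma[gene] / mb[gene]
    return float(np.log(fc)), float(fc), float(pa[gene]), float(pb[gene])


def _deg_table(
    nm: NormalizedMatrix,
    in_idx: np.ndarray,
    out_idx: np.ndarray,
    group_label: str,
    min_pct: float,
) -> pd.DataFrame:
    """Test all genes passing the detection prefilter between two cell sets.

    Prefilter: pct_in > min_pct OR pct_out > min_pct. FDR is computed over
    the tested set only.
    """
    mean_in, pct_in = _group_stats(nm, in_idx)
    mean_out, pct_out = _group_stats(nm, out_idx)
    tested = (pct_in > min_pct) | (pct_out > min_pct)
    genes = np.flatnonzero(tested)
    if genes.size == 0:
        return pd.DataFrame(columns=DEG_COLUMNS)
    fc = mean_in[genes] / mean_out[genes]
    log_fc = np.log(fc)
    X = np.asarray(nm.values[np.ix_(in_idx, genes)].todense())
    Y = np.asarray(nm.values[np.ix_(out_idx, genes)].todense())
    p = _approx_rank_sum_p(X, Y)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": [nm.gene_ids[g] for g in genes],
            "group": group_label,
            "log_fc": log_fc,
            "fold_change": fc,
            "pct_in": pct_in[genes],
            "pct_out": pct_out[genes],
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(log_fc > 0, "up", "down"),
        }
    )


def find_markers(
    nm: NormalizedMatrix,
    clusters,
    cluster_id: int,
    min_pct: float = 0.25,
    min_fc: float = 1.5,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Up-regulated marker genes of one cluster against all other cells.

    Keeps genes with fold_change > min_fc and BH-FDR < max_fdr, sorted by
    ascending p then descending fold change.
    """
    labels = np.asarray(clusters.labels)
    if np.unique(labels).size < 2:
        raise DataError("marker calling needs at least two clusters")
    in_idx = np.flatnonzero(labels == cluster_id)
    out_idx = np.flatnonzero(labels != cluster_id)
    if in_idx.size == 0:
        raise DataError(f"cluster {cluster_id} is empty")
    tab = _deg_table(nm, in_idx, out_idx, f"cluster{cluster_id}", min_pct)
    tab = tab[(tab["fold_change"] > min_fc) & (tab["fdr"] < max_fdr)]
    tab = tab.sort_values(
        ["p_value", "fold_change"], ascending=[True, False], kind="mergesort"
    )
    return tab.reset_index(drop=True)


@dataclass
class DegTiers:
    """Tiered DEG sets between the lowest- and highest-TF clusters.

    ``table`` holds every tested gene; the tier frames are filtered views:
    tier_strong is a subset of tier_up, which is a subset of tier_all.
    """

    table: pd.DataFrame
    tier_all: pd.DataFrame  # |fold change| beyond min_fc either way, FDR ok
    tier_up: pd.DataFrame  # up in the high-TF cluster
    tier_strong: pd.DataFrame  # up more than strong_fc

    def ids(self, tier: str) -> set[str]:
        return set(getattr(self, tier)["gene_id"])


def deg_between(
    nm: NormalizedMatrix,
    clusters,
    cluster_lo: int,
    cluster_hi: int,
    min_pct: float = 0.25,
    min_fc: float = 1.5,
    max_fdr: float = 0.05,
    strong_fc: float = 2.0,
) -> DegTiers:
    """Differential expression between two clusters, tiered by effect size.

    The comparison is high-TF cluster vs low-TF cluster; tier_all contains
    genes changed more than ``min_fc``-fold in either direction at
    FDR < ``max_fdr``, tier_up its up-regulated subset, tier_strong the
    genes more than ``strong_fc``-fold higher in the high cluster.
    """
    if cluster_lo == cluster_hi:
        raise ConfigError("cluster_lo and cluster_hi must differ")
    labels = np.asarray(clusters.labels)
    hi_idx = np.flatnonzero(labels == cluster_hi)
    lo_idx = np.flatnonzero(labels == cluster_lo)
    if hi_idx.size == 0 or lo_idx.size == 0:
        raise DataError("both clusters must be non-empty")
    tab = _deg_table(nm, hi_idx, lo_idx, f"c{cluster_hi}_vs_c{cluster_lo}", min_pct)
    sig = tab["fdr"] < max_fdr
    changed = (tab["fold_change"] > min_fc) | (tab["fold_change"] < 1 / min_fc)
    tier_all = tab[sig & changed]
    tier_up = tier_all[tier_all["fold_change"] > min_fc]
    tier_strong = tier_up[tier_up["fold_change"] > strong_fc]
    return DegTiers(
        table=tab.reset_index(drop=True),
        tier_all=tier_all.reset_index(drop=True),
        tier_up=tier_up.reset_index(drop=True),
        tier_strong=tier_strong.reset_index(drop=True),
    )
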