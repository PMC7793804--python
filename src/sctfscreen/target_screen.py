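"""The core inference: cluster-profile correlation screen and overlap call.

With transiently transfected cells receiving heterogeneous TF plasmid doses,
clusters stratify cells by TF expression. Candidate targets are genes whose
cluster-mean expression tracks the TF's across clusters (Pearson R^2 above a
threshold, positive by default) AND that are strongly up-regulated between
the lowest- and highest-TF clusters. The final call is the intersection of
the two evidence sets; the TF itself is never called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, NoTFContrastError
from .preprocess import NormalizedMatrix

__all__ = [
    "ClusterProfile",
    "cluster_profiles",
    "extreme_clusters",
    "correlation_screen",
    "default_candidate_pool",
    "call_targets",
]

CORR_COLUMNS = ["gene_id", "r", "r_squared", "n_clusters", "pass", "fail_reason"]


@dataclass
class ClusterProfile:
    """Genes x clusters matrix of mean normalized expression."""

    means: np.ndarray  # genes x clusters
    gene_ids: list[str]
    cluster_sizes: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.means.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.means[self.gene_ids.index(gene_id)]
        except ValueError:
            raise DataError(f"gene {gene_id!r} not in profile") from None


def cluster_profiles(nm: NormalizedMatrix, clusters) -> ClusterProfile:
    """Mean normalized expression of every gene in every cluster."""
    labels = np.asarray(clusters.labels)
    ids = np.unique(labels)
    means = np.empty((nm.n_genes, ids.size))
    sizes = np.empty(ids.size, dtype=int)
    for j, c in enumerate(ids):
        idx = np.flatnonzero(labels == c)
        sizes[j] = idx.size
        means[:, j] = np.asarray(nm.values[idx].mean(axis=0)).ravel()
    return ClusterProfile(means, list(nm.gene_ids), sizes)


def extreme_clusters(profile: ClusterProfile, tf_gene: str) -> tuple[int, int]:
    """Clusters with the lowest and highest TF mean expression.

    Ties break to the lowest cluster label. A constant TF row means the
    transfection-dose contrast the method needs is absent, which is a
    premise failure, not an empty result.
    """
    if profile.n_clusters < 2:
        raise DataError("need at least 2 clusters")
    row = profile.row(tf_gene)
    if np.ptp(row) == 0:
        raise NoTFContrastError(
            f"TF {tf_gene!r} has a constant cluster-mean profile: no "
            "expression contrast to screen against"
        )
    lo = int(np.argmin(row))  # argmin/argmax take the first (lowest) label
    hi = int(np.argmax(row))
    return lo, hi


def correlation_screen(
    profile: ClusterProfile,
    tf_gene: str,
    candidates,
    r2_min: float = 0.7,
    require_positive: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of each candidate's cluster-mean profile with the
    TF's, over all clusters.

    A candidate passes iff r^2 > ``r2_min`` and (r > 0 when
    ``require_positive``). Candidates with zero variance across clusters are
    recorded with missing r and fail_reason ``degenerate`` — never coerced
    to r = 0.
    """
    if profile.n_clusters < 3:
        raise DataError("correlation screen needs at least 3 clusters")
    candidates = [c for c in candidates if c != tf_gene]
    tf_row = profile.row(tf_gene)
    if np.ptp(tf_row) == 0:
        raise NoTFContrastError(
            f"TF {tf_gene!r} cluster-mean profile is constant"
        )
    tf_c = tf_row - tf_row.mean()
    tf_ss = float(tf_c @ tf_c)
    rows = []
    for gid in candidates:
        y = profile.row(gid)
        y_c = y - y.mean()
        ss = float(y_c @ y_c)
        if ss == 0:
            rows.append((gid, np.nan, np.nan, profile.n_clusters, False, "degenerate"))
            continue
        r = float(tf_c @ y_c / np.sqrt(tf_ss * ss))
        r = min(1.0, max(-1.0, r))
        r2 = r * r
        if r2 <= r2_min:
            rows.append((gid, r, r2, profile.n_clusters, False, "low_r2"))
        elif require_positive and r <= 0:
            rows.append((gid, r, r2, profile.n_clusters, False, "negative_r"))
        else:
            rows.append((gid, r, r2, profile.n_clusters, True, "none"))
    return pd.DataFrame(rows, columns=CORR_COLUMNS)


def default_candidate_pool(
    nm: NormalizedMatrix, tf_gene: str, min_cells_frac: float = 0.10, exclude=()
) -> list[str]:
    """Genes detected (count > 0) in more than ``min_cells_frac`` of cells,
    minus exclusions and always minus the TF."""
    prevalence = nm.values.getnnz(axis=0) / nm.n_cells
    drop = set(exclude) | {tf_gene}
    pool = [
        gid
        for gid, p in zip(nm.gene_ids, prevalence)
        if p > min_cells_frac and gid not in drop
    ]
    if not pool:
        raise DataError("candidate pool is empty")
    return pool


def call_targets(
    corr: pd.DataFrame, deg_strong: pd.DataFrame, tf_gene: str
) -> pd.DataFrame:
    """Overlap call: final_call = correlation pass AND strong DEG tier.

    Every gene appearing in either evidence set gets a row (evidence
    transparency); the TF is never called. Sorted by descending r_squared
    (missing last), ties by gene_id.
    """
    strong_ids = set(deg_strong["gene_id"]) if len(deg_strong) else set()
    strong_stats = (
        deg_strong.set_index("gene_id")[["fold_change", "fdr"]]
        if len(deg_strong)
        else pd.DataFrame(columns=["fold_change", "fdr"])
    )
    rows = []
    seen = set()
    for gid, r, r2, _nc, passed, _reason in corr[CORR_COLUMNS].itertuples(
        index=False, name=None
    ):
        seen.add(gid)
        in_strong = gid in strong_ids
        final = bool(passed and in_strong and gid != tf_gene)
        fc = strong_stats["fold_change"].get(gid, np.nan)
        fdr = strong_stats["fdr"].get(gid, np.nan)
        rows.append((gid, bool(passed), in_strong, final, r, r2, fc, fdr))
    for gid in sorted(strong_ids - seen):
        if gid == tf_gene:
            continue
        rows.append(
            (gid, False, True, False, np.nan, np.nan,
             strong_stats["fold_change"].get(gid, np.nan),
             strong_stats["fdr"].get(gid, np.nan))
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "in_correlation_set",
            "in_deg_strong_set",
            "final_call",
            "r",
            "r_squared",
            "fold_change",
            "fdr",
        ],
    )
    out = out.sort_values(
        ["r_squared", "gene_id"], ascending=[False, True],
        na_position="last", kind="mergesort",
    )
    return out.reset_index(drop=True)
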