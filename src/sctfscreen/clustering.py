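"""Shared-nearest-neighbor graph construction and Louvain clustering.

Cells are connected by the Jaccard overlap of their k-nearest-neighbor sets
in PC space (edges below a prune threshold removed), then partitioned by
multi-level (Louvain) optimization of resolution-parameterized modularity

    Q(gamma) = (1/2m) sum_ij [A_ij - gamma k_i k_j / (2m)] delta(c_i, c_j).

The local-moving phase visits nodes in a seeded random order and breaks gain
ties by the lowest candidate community id, making the partition a
deterministic function of (graph, resolution, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, DataError
from .preprocess import PCAEmbedding

__all__ = [
    "SNNGraph",
    "ClusterAssignment",
    "build_snn_graph",
    "louvain_cluster",
    "modularity",
    "embed_2d",
]


@dataclass
class SNNGraph:
    """Symmetric weighted graph over cells; weights are Jaccard overlaps in
    (0, 1], no self-loops."""

    adjacency: sparse.csr_matrix
    k: int
    prune: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-cell label in [0, n_clusters)
    resolution: float
    n_clusters: int
    sizes: np.ndarray  # per-cluster cell counts, decreasing


def build_snn_graph(
    e: PCAEmbedding, dims_use: int, k: int = 20, prune: float = 1 / 15
) -> SNNGraph:
    """Shared-nearest-neighbor graph in PC space.

    Each cell's neighborhood is itself plus its ``k`` nearest other cells by
    Euclidean distance in the first ``dims_use`` PCs (the cell's own index is
    excluded from the k nearest, then re-included in the shared set — the
    convention under which identical cells get weight exactly 1). Edge weight
    is |N(i) n N(j)| / |N(i) u N(j)|; edges below ``prune`` are removed.
    """
    X = np.asarray(e.scores[:, :dims_use])
    n = X.shape[0]
    if k >= n:
        raise ConfigError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    # k nearest others (self may not come first among exact duplicates),
    # then the cell itself joins its own neighborhood set
    rows, cols = [], []
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        neigh.append(i)
        rows.extend([i] * len(neigh))
        cols.extend(neigh)
    B = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    inter = (B @ B.T).tocoo()
    mask = inter.row != inter.col
    r, c, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    w = shared / (2 * (k + 1) - shared)  # |union| = 2(k+1) - |intersection|
    keep = w >= prune
    adj = sparse.csr_matrix((w[keep], (r[keep], c[keep])), shape=(n, n))
    adj = adj.maximum(adj.T)  # symmetric by construction; enforce exactly
    return SNNGraph(adj, k=k, prune=prune)


def _one_level(
    A: sparse.csr_matrix,
    self_w: np.ndarray,
    resolution: float,
    order: np.ndarray,
    rng=None,
) -> tuple[np.ndarray, bool]:
    """One Louvain level: local moving until no node improves.

    ``A`` is the (possibly aggregated) off-diagonal adjacency; ``self_w[i]``
    is A_ii. Returns the node->community labels (not renumbered) and whether
    any node moved. Each node moves to its max-gain community, ties (within
    1e-12) broken by lowest community id. With ``rng`` given, one initial
    diversification sweep instead moves each node to a uniformly chosen
    strictly-improving community (every accepted move still increases
    modularity), letting restarts explore different basins at near-greedy
    cost before converging greedily. Detaching a node into an empty community
    (gain exactly 0) is a considered move, which matters at resolution > 1.
    """
    n = A.shape[0]
    indptr, indices, data = A.indptr, A.indices, A.data
    k = np.asarray(A.sum(axis=1)).ravel() + self_w
    two_m = k.sum()
    if two_m == 0:
        return np.arange(n), False
    comm = np.arange(n)
    tot = k.copy()
    size = np.ones(n, dtype=np.int64)
    empty: set[int] = set()  # freed community ids
    improved = False

    def attempt(v: int, randomized: bool = False) -> bool:
        cur = comm[v]
        nbr = indices[indptr[v] : indptr[v + 1]]
        w = data[indptr[v] : indptr[v + 1]]
        cc = comm[nbr]
        # weight from v to each neighboring community
        w_all = np.bincount(cc, weights=w)
        cands = np.unique(cc)  # ascending, so ties resolve to lowest id
        tot[cur] -= k[v]
        size[cur] -= 1
        gain_factor = resolution * k[v] / two_m
        w_cur = w_all[cur] if cur < w_all.size else 0.0
        stay_gain = w_cur - gain_factor * tot[cur]
        gains = w_all[cands] - gain_factor * tot[cands]
        if not randomized:  # greedy
            best_gain = max(gains.max(initial=-np.inf), stay_gain)
            tied = cands[gains >= best_gain - 1e-12]
            best_c = int(tied.min()) if tied.size else cur
            if stay_gain >= best_gain - 1e-12:
                best_c = min(best_c, cur)
            if empty and best_gain < -1e-12:
                best_c = min(empty)  # detach: gain exactly 0
        else:  # uniform among strictly improving moves
            improving = cands[(gains > stay_gain + 1e-12) & (cands != cur)]
            options = list(improving)
            if empty and 0.0 > stay_gain + 1e-12:
                options.append(min(empty))
            best_c = options[rng.integers(len(options))] if options else cur
        comm[v] = best_c
        tot[best_c] += k[v]
        size[best_c] += 1
        if best_c != cur:
            if size[cur] == 0:
                empty.add(cur)
            empty.discard(best_c)
            return True
        return False

    # randomized restarts: explore other basins with uniformly chosen
    # improving moves. Small graphs iterate to convergence (cost is trivial
    # and local optima matter most there); large graphs randomize the first
    # sweep only to bound cost.
    if rng is not None:
        max_sweeps = np.inf if n <= 512 else 1
        sweeps = 0
        moved_rand = True
        while moved_rand and sweeps < max_sweeps:
            moved_rand = False
            sweeps += 1
            for v in order:
                if attempt(v, randomized=True):
                    improved = True
                    moved_rand = True

    # queue phase: revisit only neighbors of moved nodes
    from collections import deque

    queue = deque(int(v) for v in order)
    in_queue = np.ones(n, dtype=bool)
    while queue:
        v = queue.popleft()
        in_queue[v] = False
        if attempt(v):
            improved = True
            new_c = comm[v]
            for j in indices[indptr[v] : indptr[v + 1]]:
                if not in_queue[j] and comm[j] != new_c:
                    queue.append(int(j))
                    in_queue[j] = True
    # verification sweeps: full passes until no node improves
    moved = True
    while moved:
        moved = False
        for v in order:
            if attempt(v):
                moved = True
                improved = True
    return comm, improved


def _aggregate(
    A: sparse.csr_matrix, self_w: np.ndarray, labels: np.ndarray
) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
    """Collapse communities to nodes; returns (A', self_w', relabel map)."""
    uniq, relabel = np.unique(labels, return_inverse=True)
    nc = uniq.size
    P = sparse.csr_matrix(
        (np.ones(A.shape[0]), (np.arange(A.shape[0]), relabel)),
        shape=(A.shape[0], nc),
    )
    M = (P.T @ A @ P).tocsr()
    new_self = np.bincount(relabel, weights=self_w, minlength=nc) + M.diagonal()
    M.setdiag(0.0)
    M.eliminate_zeros()
    return M, new_self, relabel


def _louvain_once(
    A: sparse.csr_matrix, n: int, resolution: float, rng, randomized: bool = False
) -> np.ndarray:
    """One full multi-level pass from a singleton partition."""
    self_w = np.zeros(A.shape[0])
    labels = np.arange(n)
    while True:
        order = rng.permutation(A.shape[0])
        comm, improved = _one_level(
            A, self_w, resolution, order, rng if randomized else None
        )
        if not improved:
            break
        A, self_w, relabel = _aggregate(A, self_w, comm)
        labels = relabel[labels]  # current node -> new aggregated node
        if A.shape[0] == 1:
            break
    return labels


def louvain_cluster(
    g: SNNGraph, resolution: float = 1.4, seed: int = 0,
    n_starts: int | None = None, group_singletons: bool = False,
) -> ClusterAssignment:
    """Multi-level modularity optimization at the given resolution.

    Runs several seeded starts (the first greedy, the rest with randomized
    move selection) and keeps the partition with the highest modularity —
    the restart convention of the single-cell clustering tools this pipeline
    mirrors — so the result is a deterministic function of (graph,
    resolution, seed). Randomized restarts are the defense against local
    optima and their cost scales with graph size, so the default ``n_starts``
    is 100 for graphs of at most 512 nodes and 10 above. Labels are
    renumbered by decreasing cluster size (ties by lowest original label).
    A graph with no edges yields one singleton cluster per cell, with a
    warning.

    ``group_singletons`` reassigns each single-cell cluster to its most
    strongly connected neighboring cluster after optimization (isolated
    cells stay their own cluster). This mirrors the default behavior of the
    single-cell clustering ecosystem and keeps downstream two-group tests
    powered, at the price of no longer being the exact modularity optimum;
    it is off here and enabled by the pipeline.
    """
    n = g.n_nodes
    if n == 0:
        raise DataError("empty graph")
    if n_starts is None:
        n_starts = 100 if n <= 512 else 10
    if g.adjacency.nnz == 0:
        warnings.warn("graph has no edges; every cell is its own cluster")
        labels = np.arange(n)
        return ClusterAssignment(labels, resolution, n, np.ones(n, dtype=int))

    rng = np.random.default_rng(seed)
    A0 = g.adjacency.tocsr().copy()
    A0.setdiag(0.0)
    A0.eliminate_zeros()
    labels, best_q = None, -np.inf
    for start in range(max(1, n_starts)):
        cand = _louvain_once(A0, n, resolution, rng, randomized=start > 0)
        q = modularity(g, cand, resolution)
        if q > best_q + 1e-12:
            labels, best_q = cand, q

    # group singleton clusters into their most-connected neighbor cluster;
    # isolated nodes stay their own cluster
    uniq, counts = np.unique(labels, return_counts=True)
    singles = set(uniq[counts == 1]) if group_singletons else set()
    if singles:
        indptr, indices, data = A0.indptr, A0.indices, A0.data
        for v in np.flatnonzero(np.isin(labels, list(singles))):
            nbr = indices[indptr[v] : indptr[v + 1]]
            w = data[indptr[v] : indptr[v + 1]]
            outside = labels[nbr] != labels[v]
            if not outside.any():
                continue
            w_c = np.bincount(labels[nbr[outside]], weights=w[outside])
            labels[v] = int(np.flatnonzero(w_c == w_c.max())[0])

    # renumber by decreasing size, ties by lowest original label
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.lexsort((uniq, -counts))
    remap = {int(old): new for new, old in enumerate(uniq[order])}
    final = np.array([remap[int(l)] for l in labels])
    sizes = counts[order]
    return ClusterAssignment(final, resolution, int(uniq.size), sizes)


def modularity(g: SNNGraph, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Resolution-parameterized modularity of a labeling of ``g``."""
    A = g.adjacency
    labels = np.asarray(labels)
    k = np.asarray(A.sum(axis=1)).ravel()
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += A[mask][:, mask].sum() / two_m
        q -= resolution * (k[mask].sum() / two_m) ** 2
    return float(q)


def embed_2d(e: PCAEmbedding, dims_use: int, seed: int = 0) -> np.ndarray:
    """Two-dimensional layout for visualization only: the first two principal
    components. Deterministic; no downstream computation may read it."""
    if e.scores.shape[0] < 3:
        raise DataError("need at least 3 cells for a 2-D embedding")
    dims = min(max(dims_use, 2), e.scores.shape[1])
    out = np.zeros((e.scores.shape[0], 2))
    out[:, : min(2, dims)] = e.scores[:, : min(2, dims)]
    return out
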