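"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops / exhaustive
enumeration, independent of the package's implementations.
"""

from itertools import combinations
from math import fsum, sqrt

import numpy as np
from scipy.stats import rankdata


def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_modularity(A: np.ndarray, gamma: float) -> float:
    """Exhaustive-search maximum of resolution-modularity on a dense
    symmetric adjacency with zero diagonal."""
    k = A.sum(axis=1)
    two_m = k.sum()
    best = -np.inf
    for part in set_partitions(list(range(A.shape[0]))):
        q = 0.0
        for block in part:
            b = np.array(block)
            q += A[np.ix_(b, b)].sum() / two_m - gamma * (k[b].sum() / two_m) ** 2
        best = max(best, q)
    return best


def exact_rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments of the
    pooled mid-ranks."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    n = len(x)
    mu = ranks.sum() * n / len(ranks)
    dev = abs(ranks[:n].sum() - mu)
    extreme = total = 0
    for comb in combinations(range(len(ranks)), n):
        total += 1
        if abs(sum(ranks[i] for i in comb) - mu) >= dev - 1e-9:
            extreme += 1
    return extreme / total


def pearson_sum_formula(x, y) -> float:
    """Pearson r via the raw-sums formula with compensated summation."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    sx, sy = fsum(x), fsum(y)
    sxx = fsum(v * v for v in x)
    syy = fsum(v * v for v in y)
    sxy = fsum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = sqrt(n * sxx - sx * sx) * sqrt(n * syy - sy * sy)
    return num / den


def brute_knn_jaccard(X: np.ndarray, k: int) -> dict[tuple[int, int], float]:
    """Jaccard weights over shared-neighbor sets by a double loop: each
    cell's set is itself plus its k nearest other cells (distance ties broken
    by index, matching a stable argsort)."""
    n = X.shape[0]
    knn = []
    for i in range(n):
        d = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        knn.append(set(np.argsort(d, kind="stable")[:k]) | {i})
    weights = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            inter = len(knn[i] & knn[j])
            if inter:
                weights[(i, j)] = inter / len(knn[i] | knn[j])
    return weights


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_motif_count(seq: str) -> int:
    """Forward-strand CGT[GA] occurrences by a character loop."""
    n = 0
    for i in range(len(seq) - 3):
        if seq[i] == "C" and seq[i + 1] == "G" and seq[i + 2] == "T" and seq[i + 3] in "GA":
            n += 1
    return n


def brute_band_mask(values, k_sd: float) -> list[bool]:
    values = [float(v) for v in values]
    n = len(values)
    mean = fsum(values) / n
    var = fsum((v - mean) ** 2 for v in values) / (n - 1)
    sd = sqrt(var)
    if sd == 0:
        return [True] * n
    lo, hi = mean - k_sd * sd, mean + k_sd * sd
    return [lo <= v <= hi for v in values]
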