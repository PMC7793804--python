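"""Depth normalization, variable-gene selection, scaling and PCA.

Normalization follows the standard log-normalize convention for droplet
data: per-cell counts are scaled to a common depth (default 10,000) and
ln(1+x)-transformed, which preserves sparsity. Variable genes are ranked by
variance-stabilized standardized variance (trend of log10 variance on log10
mean fitted over genes, standardized counts clipped at sqrt(n_cells)); an
optional simpler dispersion statistic is available. PCA runs on the
centered, unit-variance, clipped matrix of selected genes with a
deterministic component-sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .errors import ConfigError, DataError
from .matrix_io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "VariableGeneSet",
    "PCAEmbedding",
    "log_normalize",
    "select_variable_genes",
    "scale_and_pca",
]


@dataclass
class NormalizedMatrix:
    """Cells x genes matrix of ln(1 + count/cell_total * scale_factor)."""

    values: sparse.csr_matrix
    scale_factor: float
    barcodes: list[str]
    gene_ids: list[str]

    @property
    def n_cells(self):
        return self.values.shape[0]

    @property
    def n_genes(self):
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise DataError(f"gene {gene_id!r} not present") from None


@dataclass
class VariableGeneSet:
    """Gene indices ordered by decreasing standardized variance."""

    indices: np.ndarray
    mean: np.ndarray  # per selected gene, in index order
    variance: np.ndarray
    standardized_variance: np.ndarray
    n_selected: int


@dataclass
class PCAEmbedding:
    scores: np.ndarray  # cells x n_components
    loadings: np.ndarray  # genes(selected) x n_components
    explained_variance: np.ndarray
    gene_indices: np.ndarray  # which genes of the parent matrix were used


def log_normalize(m: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """value = ln(1 + count * scale_factor / cell_total); zero counts stay
    exactly zero. Cells with zero total are a contract violation (QC removes
    them) and raise."""
    if scale_factor <= 0:
        raise ConfigError("scale_factor must be positive")
    counts = m.counts.tocsr().astype(np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise DataError("cell with zero total counts; run QC first")
    out = counts.copy()
    # scale each row then log1p on the stored (nonzero) entries only
    row_scale = scale_factor / totals
    out.data = out.data * np.repeat(row_scale, np.diff(out.indptr))
    out.data = np.log1p(out.data)
    return NormalizedMatrix(out, scale_factor, list(m.barcodes), m.gene_ids)


def _fit_variance_trend(mean: np.ndarray, variance: np.ndarray) -> np.ndarray:
    """Degree-2 polynomial fit of log10(variance) on log10(mean); returns the
    trend-predicted variance for every gene (clipped to positive)."""
    ok = (mean > 0) & (variance > 0)
    if ok.sum() < 3:
        raise DataError("too few genes with positive mean and variance")
    lm, lv = np.log10(mean[ok]), np.log10(variance[ok])
    coef = np.polyfit(lm, lv, deg=2)
    pred = np.full(mean.size, np.nan)
    pred[mean > 0] = 10 ** np.polyval(coef, np.log10(mean[mean > 0]))
    return pred


def select_variable_genes(
    m: CountMatrix, n: int = 500, method: str = "vst"
) -> VariableGeneSet:
    """Rank genes by standardized variance and return the top ``n``.

    ``vst`` (default): raw-count variance standardized by the mean-variance
    trend, with standardized values clipped at sqrt(n_cells). ``dispersion``:
    variance/mean of the raw counts. Ties broken by gene index.
    """
    counts = m.counts.tocsc()
    n_cells = m.n_cells
    mean = np.asarray(counts.mean(axis=0)).ravel()
    sq = counts.copy()
    sq.data = sq.data.astype(np.float64) ** 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    variance = (ex2 - mean**2) * n_cells / max(n_cells - 1, 1)

    if method == "vst":
        trend_var = _fit_variance_trend(mean, variance)
        sd_pred = np.sqrt(trend_var)
        clip = np.sqrt(n_cells)
        std_var = np.zeros(m.n_genes)
        # variance of clipped standardized counts, computed per gene from the
        # sparse structure: nonzero entries explicitly, zeros in closed form
        for g in range(m.n_genes):
            if not np.isfinite(sd_pred[g]) or sd_pred[g] == 0:
                continue
            col = counts.data[counts.indptr[g] : counts.indptr[g + 1]]
            if col.size == n_cells and col.min() == col.max():
                continue  # constant gene: exactly zero, not float noise
            z_nz = np.clip((col - mean[g]) / sd_pred[g], -clip, clip)
            z0 = float(np.clip(-mean[g] / sd_pred[g], -clip, clip))
            n_zero = n_cells - col.size
            s1 = z_nz.sum() + z0 * n_zero
            s2 = (z_nz**2).sum() + z0**2 * n_zero
            std_var[g] = (s2 - s1**2 / n_cells) / max(n_cells - 1, 1)
    elif method == "dispersion":
        with np.errstate(invalid="ignore", divide="ignore"):
            std_var = np.where(mean > 0, variance / mean, 0.0)
    else:
        raise ConfigError(f"unknown variable-gene method {method!r}")

    positive = std_var > 0
    if positive.sum() < n:
        warnings.warn(
            f"only {int(positive.sum())} genes with positive standardized "
            f"variance; returning all of them"
        )
        n = int(positive.sum())
    # order: decreasing standardized variance, ties by ascending gene index
    order = np.lexsort((np.arange(m.n_genes), -std_var))
    top = order[:n]
    return VariableGeneSet(
        indices=top,
        mean=mean[top],
        variance=variance[top],
        standardized_variance=std_var[top],
        n_selected=n,
    )


def scale_and_pca(
    nm: NormalizedMatrix,
    genes: VariableGeneSet,
    n_components: int = 100,
    clip: float = 10.0,
    seed: int | None = None,
) -> PCAEmbedding:
    """Center/unit-variance scale the selected genes (clipped at +/-``clip``
    standard deviations) and take a truncated SVD.

    Uses a deterministic LAPACK decomposition, so identical inputs give
    bitwise-identical output regardless of ``seed`` (accepted for interface
    symmetry). Component signs are fixed by making each component's largest-
    magnitude loading positive.
    """
    idx = np.asarray(genes.indices)
    max_rank = min(nm.n_cells - 1, idx.size)
    if n_components > max_rank:
        raise ConfigError(
            f"n_components={n_components} exceeds min(cells-1, n_selected)={max_rank}"
        )
    X = np.asarray(nm.values[:, idx].todense(), dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s) among selected; zeroed")
    sd_safe = np.where(const, 1.0, sd)
    X = (X - mu) / sd_safe
    X[:, const] = 0.0
    np.clip(X, -clip, clip, out=X)

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(n_components):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U * S
    explained = S**2 / max(nm.n_cells - 1, 1)
    return PCAEmbedding(scores, Vt.T, explained, idx)
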