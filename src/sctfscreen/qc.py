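"""Cell-level quality control.

Cells are gated on three metrics computed from the raw counts: total UMIs,
number of detected genes, and mitochondrial count fraction. The UMI and gene
gates assume an approximately Gaussian metric distribution and keep cells
inside mean +/- k standard deviations (default k=2); the mitochondrial gate
fails cells whose mito fraction exceeds a fixed ceiling (default 10%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix_io import CountMatrix

__all__ = ["CellQCMetrics", "QCReport", "compute_cell_metrics", "gaussian_band_filter", "apply_qc"]


@dataclass
class CellQCMetrics:
    """Per-cell QC metrics, aligned with the CountMatrix barcode order."""

    total_umi: np.ndarray
    n_genes_detected: np.ndarray
    mito_fraction: np.ndarray

    def to_frame(self, barcodes=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "total_umi": self.total_umi,
                "n_genes_detected": self.n_genes_detected,
                "mito_fraction": self.mito_fraction,
            }
        )
        if barcodes is not None:
            df.insert(0, "barcode", list(barcodes))
        return df


@dataclass
class QCReport:
    """Realized thresholds and per-cell pass/fail outcome of one QC pass."""

    per_cell: pd.DataFrame  # barcode, metrics, pass, reasons
    thresholds: dict
    n_cells_in: int
    n_cells_retained: int
    n_genes_in: int
    n_genes_retained: int
    dropped_genes: list[str]


def compute_cell_metrics(m: CountMatrix) -> CellQCMetrics:
    """Total UMIs, detected genes (count > 0) and mitochondrial fraction per
    cell. Cells with zero total counts get mito_fraction 0."""
    counts = m.counts
    total = np.asarray(counts.sum(axis=1)).ravel()
    n_det = counts.getnnz(axis=1)
    mito_total = np.asarray(counts[:, m.mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    return CellQCMetrics(total.astype(np.int64), n_det.astype(np.int64), mito_frac)


def gaussian_band_filter(values, k_sd: float = 2.0) -> np.ndarray:
    """Keep-mask for values inside [mean - k*sd, mean + k*sd].

    Mean and sd (sample, n-1 denominator) are computed on the raw values over
    all cells; the interval is closed, so boundary values are kept and a
    zero-sd (constant) vector keeps everything.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DataError("band filter needs at least 2 cells")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return np.ones(values.size, dtype=bool)
    return (values >= mean - k_sd * sd) & (values <= mean + k_sd * sd)


def apply_qc(
    m: CountMatrix,
    umi_k: float = 2.0,
    gene_k: float = 2.0,
    mito_max: float = 0.10,
) -> tuple[CountMatrix, QCReport]:
    """Apply the three gates jointly in one pass.

    A cell is retained iff it lies inside the UMI band AND the detected-gene
    band AND its mito fraction is <= ``mito_max`` (strictly greater fails).
    Both bands are estimated on the full pre-filter population. Genes with
    zero counts across the retained cells are dropped and reported.
    """
    metrics = compute_cell_metrics(m)
    keep_umi = gaussian_band_filter(metrics.total_umi, umi_k)
    keep_gene = gaussian_band_filter(metrics.n_genes_detected, gene_k)
    keep_mito = metrics.mito_fraction <= mito_max
    keep = keep_umi & keep_gene & keep_mito

    reasons = []
    for ku, kg, km in zip(keep_umi, keep_gene, keep_mito):
        r = []
        if not ku:
            r.append("total_umi")
        if not kg:
            r.append("n_genes_detected")
        if not km:
            r.append("mito_fraction")
        reasons.append(";".join(r))

    if not keep.any():
        raise DataError("empty after QC: every cell failed at least one gate")

    filtered = m.subset(cell_mask=keep)
    gene_totals = np.asarray(filtered.counts.sum(axis=0)).ravel()
    gene_keep = gene_totals > 0
    dropped = [g for g, k in zip(filtered.gene_ids, gene_keep) if not k]
    filtered = filtered.subset(gene_mask=gene_keep)

    per_cell = metrics.to_frame(m.barcodes)
    per_cell["pass"] = keep
    per_cell["reasons"] = reasons

    umi_mean, umi_sd = metrics.total_umi.mean(), metrics.total_umi.std(ddof=1)
    gene_mean, gene_sd = (
        metrics.n_genes_detected.mean(),
        metrics.n_genes_detected.std(ddof=1),
    )
    report = QCReport(
        per_cell=per_cell,
        thresholds={
            "umi_k": umi_k,
            "gene_k": gene_k,
            "mito_max": mito_max,
            "umi_band": [umi_mean - umi_k * umi_sd, umi_mean + umi_k * umi_sd],
            "gene_band": [gene_mean - gene_k * gene_sd, gene_mean + gene_k * gene_sd],
        },
        n_cells_in=m.n_cells,
        n_cells_retained=filtered.n_cells,
        n_genes_in=m.n_genes,
        n_genes_retained=filtered.n_genes,
        dropped_genes=dropped,
    )
    return filtered, report
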