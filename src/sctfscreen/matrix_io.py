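"""Readers and writers for the pipeline's on-disk formats.

10x-style triplet count matrices (Matrix Market + barcodes.tsv +
features.tsv), promoter FASTA, and TSV result tables. The in-memory count
container is :class:`CountMatrix`, oriented cells x genes regardless of the
on-disk orientation.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import sparse
from scipy.io import mmread, mmwrite

from .errors import DataError, FormatError

__all__ = [
    "CountMatrix",
    "PromoterSet",
    "read_10x_triplet",
    "write_10x_triplet",
    "read_fasta",
    "write_fasta",
    "write_table",
]

_IUPAC = set("ACGTUNRYSWKMBDHV")


@dataclass
class CountMatrix:
    """Sparse cells x genes UMI count matrix with named axes.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, one row per cell.
    barcodes
        Unique cell identifiers, in row order.
    genes
        DataFrame with columns ``gene_id`` and ``gene_name``, in column order.
    mito_mask
        Boolean flag per gene marking mitochondrial genes.
    """

    counts: sparse.csr_matrix
    barcodes: list[str]
    genes: pd.DataFrame
    mito_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.counts = sparse.csr_matrix(self.counts)
        if self.mito_mask is None:
            self.mito_mask = np.zeros(self.counts.shape[1], dtype=bool)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.barcodes) != n_cells:
            raise DataError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix rows"
            )
        if len(self.genes) != n_genes:
            raise DataError(f"{len(self.genes)} genes for {n_genes} matrix columns")
        if self.mito_mask.shape != (n_genes,):
            raise DataError("mito_mask length does not match gene count")
        if len(set(self.barcodes)) != n_cells:
            raise DataError("duplicate barcodes")
        if self.genes["gene_id"].duplicated().any():
            raise DataError("duplicate gene ids")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer counts")
        self.counts.data = np.asarray(np.round(self.counts.data), dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero((self.genes["gene_id"] == gene_id).to_numpy())
        if idx.size == 0:
            raise DataError(f"gene {gene_id!r} not present")
        return int(idx[0])

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        return CountMatrix(
            counts=self.counts[cm][:, gm],
            barcodes=[b for b, keep in zip(self.barcodes, cm) if keep],
            genes=self.genes.loc[gm].reset_index(drop=True),
            mito_mask=self.mito_mask[gm],
        )


@dataclass
class PromoterSet:
    """Ordered promoter sequences (upstream-of-TSS nucleotide strings)."""

    records: list[tuple[str, str]]

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate sequence ids")
        for sid, seq in self.records:
            if not seq:
                raise DataError(f"empty sequence for {sid!r}")
            bad = set(seq) - _IUPAC
            if bad:
                raise FormatError(f"non-IUPAC characters {sorted(bad)} in {sid!r}")

    def __len__(self):
        return len(self.records)

    def ids(self) -> list[str]:
        return [r[0] for r in self.records]


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_lines(path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        return [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip()]


def read_10x_triplet(
    matrix_path,
    barcodes_path,
    features_path,
    mito_prefixes: Sequence[str] = (),
    orientation: str | None = None,
) -> CountMatrix:
    """Read a 10x-style triplet (matrix.mtx + barcodes.tsv + features.tsv).

    The on-disk matrix may be genes x cells (the 10x convention) or
    cells x genes; orientation is detected by matching the Matrix Market
    header dimensions against the barcode and feature line counts. A square
    matrix with equal axis lengths is ambiguous and requires an explicit
    ``orientation`` of ``"genes_x_cells"`` or ``"cells_x_genes"``.

    ``mito_prefixes`` flags a gene as mitochondrial when its gene_id or
    gene_name starts with any of the given prefixes.
    """
    try:
        with _open_maybe_gzip(matrix_path) as fh:
            mat = mmread(io.StringIO(fh.read()))
    except Exception as exc:  # scipy raises ValueError on malformed files
        raise FormatError(f"cannot parse Matrix Market file: {exc}") from exc
    mat = sparse.coo_matrix(mat)
    if mat.data.size and (np.any(mat.data < 0) or not np.allclose(mat.data, np.round(mat.data))):
        raise FormatError("matrix values must be non-negative integers")

    barcodes = _read_lines(barcodes_path)
    feat_lines = _read_lines(features_path)
    feats = [ln.split("\t") for ln in feat_lines]
    genes = pd.DataFrame(
        {
            "gene_id": [f[0] for f in feats],
            "gene_name": [f[1] if len(f) > 1 else f[0] for f in feats],
        }
    )
    n_cells, n_genes = len(barcodes), len(genes)

    if orientation is None:
        if mat.shape == (n_genes, n_cells) and mat.shape != (n_cells, n_genes):
            orientation = "genes_x_cells"
        elif mat.shape == (n_cells, n_genes) and mat.shape != (n_genes, n_cells):
            orientation = "cells_x_genes"
        elif mat.shape == (n_genes, n_cells):  # square, ambiguous
            raise FormatError(
                "square matrix with equal barcode/feature counts: pass "
                "orientation='genes_x_cells' or 'cells_x_genes'"
            )
        else:
            raise FormatError(
                f"matrix shape {mat.shape} matches neither (genes={n_genes}, "
                f"cells={n_cells}) nor its transpose"
            )
    if orientation == "genes_x_cells":
        if mat.shape != (n_genes, n_cells):
            raise FormatError(f"matrix shape {mat.shape} != ({n_genes}, {n_cells})")
        mat = mat.T
    elif orientation == "cells_x_genes":
        if mat.shape != (n_cells, n_genes):
            raise FormatError(f"matrix shape {mat.shape} != ({n_cells}, {n_genes})")
    else:
        raise FormatError(f"unknown orientation {orientation!r}")

    mito = np.zeros(n_genes, dtype=bool)
    for prefix in mito_prefixes:
        mito |= genes["gene_id"].str.startswith(prefix).to_numpy()
        mito |= genes["gene_name"].str.startswith(prefix).to_numpy()
    return CountMatrix(sparse.csr_matrix(mat), barcodes, genes, mito)


def write_10x_triplet(m: CountMatrix, out_dir) -> dict[str, Path]:
    """Write ``matrix.mtx`` (genes x cells, integer), ``barcodes.tsv`` and
    ``features.tsv`` so that :func:`read_10x_triplet` inverts exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "barcodes": out_dir / "barcodes.tsv",
        "features": out_dir / "features.tsv",
    }
    gxc = sparse.coo_matrix(m.counts.T).astype(np.int64)
    mmwrite(str(paths["matrix"]), gxc, field="integer")
    paths["barcodes"].write_text("".join(b + "\n" for b in m.barcodes))
    feat_lines = [
        f"{gid}\t{gname}\tGene Expression\n"
        for gid, gname in zip(m.genes["gene_id"], m.genes["gene_name"])
    ]
    paths["features"].write_text("".join(feat_lines))
    return paths


def read_fasta(path) -> PromoterSet:
    """Read promoter sequences from FASTA; sequences are uppercased and
    whitespace-joined across lines. Duplicate ids raise; an empty file warns
    and yields an empty set."""
    with _open_maybe_gzip(path) as fh:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        warnings.warn(f"no sequences in {path}", stacklevel=2)
    return PromoterSet(records)


def write_fasta(promoters: PromoterSet, path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sid, seq in promoters.records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_table(records: pd.DataFrame, path) -> Path:
    """Write a result table as TSV with a header row; floats rendered with
    6 significant digits."""
    path = Path(path)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
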