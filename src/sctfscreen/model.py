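"""Model/Results interface tying the stages into one reproducible fit.

:class:`TFTargetModel` is built from a :class:`~sctfscreen.matrix_io.CountMatrix`
(or a 10x triplet directory, or a dense DataFrame) plus the id of the
over-expressed TF; :meth:`TFTargetModel.fit` runs QC, normalization,
variable-gene selection, PCA, SNN-graph Louvain clustering, the extreme-
cluster DEG tiers, the cluster-profile correlation screen and the overlap
call, and returns a :class:`TFTargetResults` carrying every intermediate
statistic, a stage-by-stage manifest and a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, diffexpr, preprocess, qc, target_screen
from .errors import ConfigError, DataError, NoTFContrastError
from .matrix_io import CountMatrix, read_10x_triplet, write_table

__all__ = ["RunConfig", "TFTargetModel", "TFTargetResults", "run_pipeline", "derive_seed"]

# fixed stage order; also the spawn keys of the per-stage seed derivation
STAGES = (
    "qc",
    "normalize",
    "hvg",
    "pca",
    "snn",
    "cluster",
    "profiles",
    "extremes",
    "deg",
    "screen",
    "call",
)


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed: SeedSequence(seed, spawn_key=(stage index,)), folded
    below 2**31 so stages are individually reproducible from the global seed."""
    key = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run, serializable to YAML."""

    tf_gene: str = "TF"
    # QC gates
    umi_k: float = 2.0
    gene_k: float = 2.0
    mito_max: float = 0.10
    # normalization / HVG / PCA
    scale_factor: float = 1e4
    hvg_n: int = 500
    hvg_method: str = "vst"
    pca_n_components: int = 100
    pca_dims_use: int = 30
    pca_clip: float = 10.0
    # graph + clustering
    knn_k: int = 20
    snn_prune: float = 1 / 15
    resolution: float = 1.4
    # differential expression
    min_pct: float = 0.25
    min_fc: float = 1.5
    max_fdr: float = 0.05
    strong_fc: float = 2.0
    # correlation screen
    r2_min: float = 0.7
    require_positive: bool = True
    pool: str = "prevalence"  # or "markers"
    pool_min_cells_frac: float = 0.10
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.pool not in ("prevalence", "markers"):
            raise ConfigError(f"unknown pool mode {self.pool!r}")
        if self.hvg_method not in ("vst", "dispersion"):
            raise ConfigError(f"unknown hvg method {self.hvg_method!r}")
        for name in ("scale_factor", "resolution", "min_fc", "strong_fc"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


class TFTargetModel:
    """TF-target prediction model over a transient-overexpression count matrix.

    Parameters
    ----------
    counts
        Raw cells x genes UMI count matrix.
    tf_gene
        gene_id of the over-expressed transcription factor.
    config
        Optional :class:`RunConfig`; its ``tf_gene``/``seed`` are overridden
        by the explicit arguments when given.
    """

    def __init__(self, counts: CountMatrix, tf_gene: str | None = None,
                 config: RunConfig | None = None):
        self.config = config or RunConfig()
        if tf_gene is not None:
            self.config.tf_gene = tf_gene
        self.config.validate()
        self.counts = counts
        if self.config.tf_gene not in counts.gene_ids:
            raise DataError(
                f"TF gene {self.config.tf_gene!r} not present in the matrix"
            )

    @classmethod
    def from_10x(cls, matrix_path, barcodes_path, features_path, tf_gene,
                 mito_prefixes=("MT-",), config=None) -> "TFTargetModel":
        m = read_10x_triplet(matrix_path, barcodes_path, features_path,
                             mito_prefixes=mito_prefixes)
        return cls(m, tf_gene=tf_gene, config=config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, tf_gene, mito_prefixes=("MT-",),
                       config=None) -> "TFTargetModel":
        """Build from a dense cells x genes DataFrame (index = barcodes,
        columns = gene ids)."""
        genes = pd.DataFrame({"gene_id": df.columns, "gene_name": df.columns})
        mito = np.zeros(len(genes), bool)
        for p in mito_prefixes:
            mito |= genes["gene_id"].str.startswith(p).to_numpy()
        m = CountMatrix(df.to_numpy(), list(df.index.astype(str)), genes, mito)
        return cls(m, tf_gene=tf_gene, config=config)

    def fit(self, seed: int | None = None) -> "TFTargetResults":
        """Run the full pipeline; deterministic given (data, config, seed)."""
        cfg = self.config
        if seed is not None:
            cfg.seed = seed
        manifest: list[dict] = []

        def record(stage, caught, **info):
            entry = {"stage": stage, "params": {}, **info}
            if caught:
                entry["warnings"] = [str(w.message) for w in caught]
            manifest.append(entry)

        with warnings.catch_warnings(record=True) as cw:
            warnings.simplefilter("always")
            filtered, qc_report = qc.apply_qc(
                self.counts, umi_k=cfg.umi_k, gene_k=cfg.gene_k, mito_max=cfg.mito_max
            )
        record("qc", cw,
               params={"umi_k": cfg.umi_k, "gene_k": cfg.gene_k,
                       "mito_max": cfg.mito_max,
                       "realized": qc_report.thresholds},
               n_cells=filtered.n_cells, n_genes=filtered.n_genes)
        if cfg.tf_gene not in filtered.gene_ids:
            # the TF was dropped as all-zero: the expression contrast the
            # screen is built on does not exist in this dataset
            raise NoTFContrastError(
                f"TF gene {cfg.tf_gene!r} has no counts in QC-passing cells"
            )

        nm = preprocess.log_normalize(filtered, scale_factor=cfg.scale_factor)
        record("normalize", None, params={"scale_factor": cfg.scale_factor},
               n_cells=nm.n_cells, n_genes=nm.n_genes)

        with warnings.catch_warnings(record=True) as cw:
            warnings.simplefilter("always")
            hvg = preprocess.select_variable_genes(
                filtered, n=min(cfg.hvg_n, filtered.n_genes), method=cfg.hvg_method
            )
        record("hvg", cw, params={"n": cfg.hvg_n, "method": cfg.hvg_method},
               n_selected=int(hvg.n_selected))

        n_comp = min(cfg.pca_n_components, filtered.n_cells - 1, hvg.n_selected)
        with warnings.catch_warnings(record=True) as cw:
            warnings.simplefilter("always")
            emb = preprocess.scale_and_pca(
                nm, hvg, n_components=n_comp, clip=cfg.pca_clip,
                seed=derive_seed(cfg.seed, "pca"),
            )
        record("pca", cw, params={"n_components": n_comp, "clip": cfg.pca_clip,
                                  "dims_use": cfg.pca_dims_use})

        dims = min(cfg.pca_dims_use, emb.scores.shape[1])
        graph = clustering.build_snn_graph(
            emb, dims_use=dims, k=cfg.knn_k, prune=cfg.snn_prune
        )
        record("snn", None, params={"k": cfg.knn_k, "prune": cfg.snn_prune,
                                    "dims_use": dims},
               n_edges=graph.n_edges)

        with warnings.catch_warnings(record=True) as cw:
            warnings.simplefilter("always")
            clusters = clustering.louvain_cluster(
                graph, resolution=cfg.resolution,
                seed=derive_seed(cfg.seed, "cluster"),
                group_singletons=True,
            )
        record("cluster", cw, params={"resolution": cfg.resolution},
               n_clusters=clusters.n_clusters,
               sizes=clusters.sizes.tolist())

        profile = target_screen.cluster_profiles(nm, clusters)
        record("profiles", None, n_clusters=profile.n_clusters)

        lo, hi = target_screen.extreme_clusters(profile, cfg.tf_gene)
        record("extremes", None, lo_cluster=lo, hi_cluster=hi)

        tiers = diffexpr.deg_between(
            nm, clusters, cluster_lo=lo, cluster_hi=hi, min_pct=cfg.min_pct,
            min_fc=cfg.min_fc, max_fdr=cfg.max_fdr, strong_fc=cfg.strong_fc,
        )
        record("deg", None,
               params={"min_pct": cfg.min_pct, "min_fc": cfg.min_fc,
                       "max_fdr": cfg.max_fdr, "strong_fc": cfg.strong_fc},
               n_all=len(tiers.tier_all), n_up=len(tiers.tier_up),
               n_strong=len(tiers.tier_strong))

        if cfg.pool == "prevalence":
            pool = target_screen.default_candidate_pool(
                nm, cfg.tf_gene, min_cells_frac=cfg.pool_min_cells_frac
            )
        else:  # union of all cluster marker genes
            pool_set: set[str] = set()
            for c in range(clusters.n_clusters):
                mk = diffexpr.find_markers(
                    nm, clusters, c, min_pct=cfg.min_pct,
                    min_fc=cfg.min_fc, max_fdr=cfg.max_fdr,
                )
                pool_set |= set(mk["gene_id"])
            pool_set.discard(cfg.tf_gene)
            if not pool_set:
                raise DataError("marker-based candidate pool is empty")
            pool = sorted(pool_set)
        corr = target_screen.correlation_screen(
            profile, cfg.tf_gene, pool, r2_min=cfg.r2_min,
            require_positive=cfg.require_positive,
        )
        record("screen", None,
               params={"pool": cfg.pool, "r2_min": cfg.r2_min,
                       "require_positive": cfg.require_positive},
               n_candidates=len(pool), n_pass=int(corr["pass"].sum()))

        calls = target_screen.call_targets(corr, tiers.tier_strong, cfg.tf_gene)
        record("call", None, n_final=int(calls["final_call"].sum()))

        return TFTargetResults(
            model=self, config=RunConfig(**cfg.to_dict()), qc_report=qc_report,
            filtered=filtered, normalized=nm, hvg=hvg, embedding=emb,
            graph=graph, clusters=clusters, profile=profile,
            lo_cluster=lo, hi_cluster=hi, deg_tiers=tiers,
            correlation=corr, candidate_pool=pool, target_calls=calls,
            manifest=manifest,
        )


@dataclass
class TFTargetResults:
    """Fitted pipeline state: every intermediate product plus the final calls."""

    model: TFTargetModel
    config: RunConfig
    qc_report: qc.QCReport
    filtered: CountMatrix
    normalized: preprocess.NormalizedMatrix
    hvg: preprocess.VariableGeneSet
    embedding: preprocess.PCAEmbedding
    graph: clustering.SNNGraph
    clusters: clustering.ClusterAssignment
    profile: target_screen.ClusterProfile
    lo_cluster: int
    hi_cluster: int
    deg_tiers: diffexpr.DegTiers
    correlation: pd.DataFrame
    candidate_pool: list[str]
    target_calls: pd.DataFrame
    manifest: list = field(default_factory=list)

    @property
    def called_targets(self) -> list[str]:
        return self.target_calls.loc[
            self.target_calls["final_call"], "gene_id"
        ].tolist()

    def embedding_2d(self) -> np.ndarray:
        """Visualization-only 2-D layout (never used by the inference)."""
        return clustering.embed_2d(
            self.embedding, self.config.pca_dims_use,
            seed=derive_seed(self.config.seed, "cluster"),
        )

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "TF target screen results",
            "=" * 60,
            f"TF gene:                    {cfg.tf_gene}",
            f"Cells in / after QC:        {self.qc_report.n_cells_in} / "
            f"{self.qc_report.n_cells_retained}",
            f"Genes in / after QC:        {self.qc_report.n_genes_in} / "
            f"{self.qc_report.n_genes_retained}",
            f"Clusters (resolution {cfg.resolution}): {self.clusters.n_clusters} "
            f"(sizes {self.clusters.sizes.min()}..{self.clusters.sizes.max()})",
            f"Extreme TF clusters:        lo={self.lo_cluster} hi={self.hi_cluster}",
            f"DEG tiers (fc>{cfg.min_fc}, FDR<{cfg.max_fdr}): "
            f"all={len(self.deg_tiers.tier_all)} up={len(self.deg_tiers.tier_up)} "
            f"strong(fc>{cfg.strong_fc})={len(self.deg_tiers.tier_strong)}",
            f"Correlation screen (R^2>{cfg.r2_min}): "
            f"{int(self.correlation['pass'].sum())} of {len(self.correlation)} candidates",
            f"Final target calls:         {len(self.called_targets)}",
        ]
        if self.called_targets:
            lines.append("Called targets (desc. R^2):")
            head = self.target_calls[self.target_calls["final_call"]]
            for row in head.itertuples(index=False):
                lines.append(
                    f"  {row.gene_id:20s} r={row.r:+.3f} r2={row.r_squared:.3f} "
                    f"fc={row.fold_change:.2f} fdr={row.fdr:.2e}"
                )
        return "\n".join(lines)

    def write_tables(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["qc"] = write_table(self.qc_report.per_cell, out_dir / "qc_report.tsv")
        paths["clusters"] = write_table(
            pd.DataFrame(
                {"barcode": self.filtered.barcodes, "cluster": self.clusters.labels}
            ),
            out_dir / "clusters.tsv",
        )
        paths["hvg"] = write_table(
            pd.DataFrame(
                {
                    "gene_id": [self.filtered.gene_ids[i] for i in self.hvg.indices],
                    "mean": self.hvg.mean,
                    "variance": self.hvg.variance,
                    "standardized_variance": self.hvg.standardized_variance,
                }
            ),
            out_dir / "variable_genes.tsv",
        )
        paths["explained_variance"] = write_table(
            pd.DataFrame(
                {
                    "component": np.arange(1, self.embedding.explained_variance.size + 1),
                    "explained_variance": self.embedding.explained_variance,
                }
            ),
            out_dir / "explained_variance.tsv",
        )
        paths["deg"] = write_table(self.deg_tiers.table, out_dir / "deg_table.tsv")
        paths["correlation"] = write_table(
            self.correlation, out_dir / "correlation.tsv"
        )
        paths["targets"] = write_table(
            self.target_calls, out_dir / "target_calls.tsv"
        )
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        paths["manifest"] = out_dir / "manifest.json"
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh)
        paths["config"] = out_dir / "config.yaml"
        return paths


def _file_sha(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(
    cfg: RunConfig,
    matrix_path,
    barcodes_path,
    features_path,
    out_dir,
    mito_prefixes=("MT-",),
) -> TFTargetResults:
    """Read a 10x triplet, fit the model, and write all output tables.

    The manifest records the input file hashes so a run is traceable to its
    exact inputs.
    """
    model = TFTargetModel.from_10x(
        matrix_path, barcodes_path, features_path, tf_gene=cfg.tf_gene,
        mito_prefixes=mito_prefixes, config=cfg,
    )
    res = model.fit()
    res.manifest.insert(
        0,
        {
            "stage": "read",
            "inputs": {
                str(p): _file_sha(p)
                for p in (matrix_path, barcodes_path, features_path)
            },
            "n_cells": model.counts.n_cells,
            "n_genes": model.counts.n_genes,
        },
    )
    res.write_tables(out_dir)
    return res
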