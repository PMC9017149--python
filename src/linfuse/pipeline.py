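"""End-to-end pipeline: read -> QC -> normalize -> HVG -> PCA -> per-modality
distances -> alpha scaling -> L-infinity fusion -> clustering -> embedding ->
purity report.  Deterministic given (config, seed)."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .adt_distance import SigmoidParams, adt_distance_matrix
from .cluster_embed import ClusterResult, cluster_distance, embed
from .datamodel import (DistanceMatrix, MultimodalDataset, write_embedding,
                        write_labels)
from .fusion import FusionResult, fuse, solve_alpha
from .preprocess import (QCConfig, normalize_adt_clr, normalize_rna,
                         pca_reduce, qc_filter, scale_genes, select_hvg)
from .purity import PurityConfig, purity_report

logger = logging.getLogger("linfuse")


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run; serializable to/from dict."""

    qc: QCConfig = field(default_factory=QCConfig)
    apply_qc: bool = True
    mito_prefix: str = "MT-"
    scale_factor: float = 1e4
    n_hvg: int = 2000
    n_pcs: int = 20
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    adt_scale: bool = False  # z-score CLR values (off: keeps k/c meaningful)
    norm: str = "linf"
    alpha: float = None  # None -> solved
    exclude_adt: tuple = ()
    modality: str = "joint"  # joint | rna | adt
    k_neighbors: int = 20
    resolution: float = 0.9
    seed: int = 42
    embed_method: str = "tsne"  # tsne | umap | mds | none
    purity: PurityConfig = field(default_factory=PurityConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["purity"].pop("ds_estimator", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCConfig(**d["qc"])
        if "sigmoid" in d and isinstance(d["sigmoid"], dict):
            d["sigmoid"] = SigmoidParams(**d["sigmoid"])
        if "purity" in d and isinstance(d["purity"], dict):
            d["purity"] = PurityConfig(**d["purity"])
        if "exclude_adt" in d:
            d["exclude_adt"] = tuple(d["exclude_adt"])
        return cls(**d)


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: MultimodalDataset
    labels: np.ndarray
    clustering: ClusterResult
    distances: dict  # modality tag -> DistanceMatrix
    fusion: FusionResult
    embedding: np.ndarray
    purity: "object"
    qc_report: dict


def rna_distance_matrix(dataset: MultimodalDataset,
                        config: PipelineConfig) -> DistanceMatrix:
    """Euclidean distances between cells on the top PCs of scaled HVGs."""
    lognorm = dataset.layers.get("rna_lognorm")
    if lognorm is None:
        lognorm = normalize_rna(dataset.rna, config.scale_factor,
                                dataset.cell_barcodes)
        dataset.layers["rna_lognorm"] = lognorm
    hvg = select_hvg(lognorm, config.n_hvg)
    scaled = scale_genes(lognorm[hvg])
    n_pcs = min(config.n_pcs, min(scaled.shape[0], dataset.n_cells))
    if n_pcs < config.n_pcs:
        logger.info("n_pcs reduced to %d for a small input", n_pcs)
    pcs = pca_reduce(scaled, n_pcs)
    return DistanceMatrix(pdist(pcs), dataset.cell_barcodes, "RNA")


def adt_clr_matrix(dataset: MultimodalDataset, config: PipelineConfig):
    """CLR-normalized ADT block with configured features excluded."""
    keep = ~np.isin(dataset.adt_ids, list(config.exclude_adt))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluded %d ADT features: %s", n_dropped,
                    sorted(set(config.exclude_adt) & set(dataset.adt_ids)))
    clr = normalize_adt_clr(dataset.adt[keep])
    if config.adt_scale:
        sd = clr.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        clr = (clr - clr.mean(axis=1, keepdims=True)) / sd
    return clr


def run_pipeline(dataset: MultimodalDataset, config: PipelineConfig = None,
                 outdir=None) -> PipelineResult:
    """Run the full pipeline on an in-memory dataset.

    With ``outdir`` the labels TSV, embedding CSV, purity CSV, fusion
    metadata JSON (alpha, contributions) and resolved config are written
    there; a rerun with the same config and seed is bit-identical.
    """
    config = config or PipelineConfig()
    qc_report = {}
    if "n_genes_detected" not in dataset.cell_meta:
        dataset.compute_qc_metrics(config.mito_prefix)
    if config.apply_qc:
        dataset, qc_report = qc_filter(dataset, config.qc)

    d_rna = rna_distance_matrix(dataset, config)
    clr = adt_clr_matrix(dataset, config)
    dataset.layers["adt_clr"] = clr
    d_adt = adt_distance_matrix(clr, dataset.cell_barcodes, config.sigmoid)

    fusion = None
    if config.modality == "joint":
        alpha = config.alpha
        if alpha is None:
            alpha = solve_alpha(d_rna, d_adt)
        fusion = fuse(d_rna, d_adt, alpha, config.norm)
        d_cluster = fusion.d_joint
    elif config.modality == "rna":
        d_cluster = d_rna
    elif config.modality == "adt":
        d_cluster = d_adt
    else:
        raise ValueError(f"unknown modality {config.modality!r}")

    clustering = cluster_distance(d_cluster, config.k_neighbors,
                                  config.resolution, config.seed)
    labels = clustering.labels
    embedding = None
    if config.embed_method and config.embed_method != "none":
        embedding = embed(d_cluster, config.embed_method, config.seed)

    purity = purity_report(dataset.layers["rna_lognorm"], clr, labels,
                           config.purity)

    result = PipelineResult(
        config=config, dataset=dataset, labels=labels, clustering=clustering,
        distances={"RNA": d_rna, "ADT": d_adt, "joint": getattr(fusion, "d_joint", None)},
        fusion=fusion, embedding=embedding, purity=purity, qc_report=qc_report,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bc = result.dataset.cell_barcodes
    write_labels(outdir / "labels.tsv", bc, result.labels)
    if result.embedding is not None:
        write_embedding(outdir / "embedding.csv", bc, result.embedding)
    result.purity.to_csv(outdir / "purity.csv", index=False,
                         float_format="%.6f")
    meta = {"qc": result.qc_report,
            "n_cells": int(result.dataset.n_cells),
            "n_clusters": int(result.labels.max()) + 1}
    if result.fusion is not None:
        meta["fusion"] = {
            "alpha": result.fusion.alpha,
            "norm": result.fusion.norm,
            "contribution_rna": result.fusion.contribution_rna,
            "contribution_adt": result.fusion.contribution_adt,
        }
    (outdir / "fusion.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    (outdir / "config.json").write_text(
        json.dumps(result.config.to_dict(), indent=2, sort_keys=True, default=str))
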