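"""Quality control, normalization, feature selection and PCA.

The pre-processing stage follows the standard droplet single-cell recipe:
cells are filtered on detected-gene counts and mitochondrial fraction (with
a soft, percentile-based mitochondrial threshold sealed at a hard cap), RNA
counts are log-normalized per cell, ADT counts get a centered log-ratio
(CLR) transform per cell, highly variable genes are picked by binned
standardized dispersion, and the scaled HVG matrix is reduced by PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .datamodel import MultimodalDataset

logger = logging.getLogger("linfuse")


@dataclass
class QCConfig:
    """Cell quality-control thresholds.

    Cells with detected-gene counts outside ``[min_genes, max_genes]``
    (bounds inclusive: the exclusion rule is strictly below / strictly
    above) are removed, as are cells whose mitochondrial fraction exceeds
    the soft threshold ``min(quantile(mito, mito_quantile), mito_cap)``.
    """

    min_genes: int = 200
    max_genes: int = 2500
    mito_quantile: float = 0.95
    mito_cap: float = 0.10

    def __post_init__(self):
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0 < self.mito_quantile < 1:
            raise ValueError("mito_quantile must be in (0, 1)")
        if not 0 < self.mito_cap <= 1:
            raise ValueError("mito_cap must be in (0, 1]")


def soft_mito_threshold(mito_fractions, config: QCConfig = None) -> float:
    """Soft mitochondrial threshold: dataset percentile sealed at a hard cap.

    Returns ``min(quantile(mito_fractions, q), cap)`` with the default 95th
    percentile and 10% cap, adapting to each dataset's quality while never
    admitting grossly damaged cells.
    """
    config = config or QCConfig()
    x = np.asarray(mito_fractions, dtype=float)
    if x.size == 0:
        raise ValueError("empty mito_fractions vector")
    if ((x < 0) | (x > 1)).any():
        raise ValueError("mito fractions must lie in [0, 1]")
    return float(min(np.quantile(x, config.mito_quantile), config.mito_cap))


def qc_filter(dataset: MultimodalDataset, config: QCConfig = None):
    """Remove low-quality cells; returns ``(filtered_dataset, report)``.

    The report counts removals per criterion (a cell failing several is
    counted under each).  Both modalities are subset identically and cell
    order is preserved.
    """
    config = config or QCConfig()
    meta = dataset.cell_meta
    if "n_genes_detected" not in meta or "mito_fraction" not in meta:
        raise ValueError("cell_meta lacks QC metrics; call compute_qc_metrics first")
    genes = meta["n_genes_detected"].to_numpy()
    mito = meta["mito_fraction"].to_numpy(dtype=float)
    thr = soft_mito_threshold(mito, config)
    low = genes < config.min_genes
    high = genes > config.max_genes
    mito_bad = mito > thr
    keep = ~(low | high | mito_bad)
    if not keep.any():
        raise ValueError(
            "QC removed every cell; review min_genes/max_genes/mito thresholds"
        )
    report = {
        "n_input": dataset.n_cells,
        "n_kept": int(keep.sum()),
        "removed_low_genes": int(low.sum()),
        "removed_high_genes": int(high.sum()),
        "removed_mito": int(mito_bad.sum()),
        "mito_threshold": thr,
    }
    logger.info("QC kept %d/%d cells (mito threshold %.4f)",
                report["n_kept"], report["n_input"], thr)
    return dataset.subset_cells(keep), report


def normalize_rna(rna_counts, scale_factor: float = 1e4, barcodes=None):
    """Per-cell log normalization: ``x -> ln(1 + x * s / cell_total)``.

    Accepts a sparse or dense genes-by-cells matrix; zero entries stay zero.
    A cell with zero total counts is an error (it should have failed QC).
    """
    X = sp.csr_matrix(rna_counts, dtype=float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = np.flatnonzero(totals == 0)
        name = barcodes[bad[0]] if barcodes is not None else f"column {bad[0]}"
        raise ValueError(f"cell with zero total counts: {name}")
    out = X.tocsc(copy=True)
    # scale per column, then log1p the stored (nonzero) entries only
    factors = np.repeat(scale_factor / totals, np.diff(out.indptr))
    out.data = np.log1p(out.data * factors)
    return out.tocsr()


def normalize_adt_clr(adt_counts):
    """Centered log-ratio transform of ADT counts, per cell across features.

    ``y_i = ln((x_i + 1) / geometric_mean_j(x_j + 1))``; each cell's
    transformed values sum to zero.  The +1 pseudocount keeps zeros finite
    and the output on the natural-log scale the sigmoid thresholds assume.
    """
    X = np.asarray(adt_counts, dtype=float)
    logx = np.log1p(X)
    return logx - logx.mean(axis=0, keepdims=True)


def select_hvg(rna_lognorm, n_hvg: int = 2000, n_bins: int = 20):
    """Rank genes by standardized dispersion and return the top ``n_hvg`` indices.

    Dispersion = variance / mean of the log-normalized expression, z-scored
    within ``n_bins`` equal-occupancy bins of mean expression so that highly
    expressed genes do not dominate.  If fewer genes exist than requested,
    all are returned, ranked.  Ties break by gene index (stable).
    """
    X = sp.csr_matrix(rna_lognorm)
    n_genes, n_cells = X.shape
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n_cells / max(n_cells - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    # equal-occupancy bins over mean expression; keep bins populated enough
    # for a meaningful within-bin z-score
    order = np.argsort(mean, kind="stable")
    n_bins = max(1, min(n_bins, n_genes // 10))
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)

    z = np.zeros(n_genes)
    for b in np.unique(bins):
        mask = bins == b
        d = disp[mask]
        sd = d.std()
        z[mask] = (d - d.mean()) / sd if sd > 0 else 0.0
    ranked = np.argsort(-z, kind="stable")
    return ranked[: min(n_hvg, n_genes)]


def scale_genes(matrix, clip: float = 10.0):
    """Per-gene z-score (rows), clipped at ``±clip``; constant genes map to 0."""
    X = np.asarray(sp.csr_matrix(matrix).todense(), dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return np.clip((X - mu) / sd, -clip, clip)


def pca_reduce(scaled, n_pcs: int = 20):
    """PCA of a genes-by-cells scaled matrix; returns a cells × n_pcs embedding.

    Components are ordered by decreasing explained variance.  For
    reproducibility the sign of each component is fixed so that its
    largest-magnitude loading is positive.
    """
    X = np.asarray(scaled, dtype=float).T  # cells x genes
    limit = min(X.shape)
    if n_pcs > limit:
        raise ValueError(f"n_pcs={n_pcs} exceeds min(#genes, #cells)={limit}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(X)
    flips = np.ones(n_pcs)
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            flips[j] = -1.0
    return emb * flips
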