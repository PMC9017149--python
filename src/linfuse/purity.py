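"""Cluster purity scores for CITE-seq: variance-based ADT score,
entropy-based RNA score, geometric-mean combination.

ADT score.  For a cluster, per-feature standard deviations ``SD_i`` are
raised to an integer rank ``n`` and summed; the score compares that sum with
the same quantity over the entire dataset (``K_ADT``):

    S_ADT = 1 - sum_i SD_i^n / (sum_i SD_i^n + K_ADT).

The score lies in [0, 1], equals exactly 0.5 when a cluster's variation
matches the whole dataset's, and increases as the cluster becomes more
homogeneous.  Raising the rank emphasizes the single most variable features;
the heuristic ``rank = floor(ln(#features))`` (clamped to >= 1) grows the
rank with panel size.

RNA score.  A cluster's transcriptome purity is scored on the same
``1 - S/(S+K)`` form with ``S`` the sum of significant per-gene entropy
reductions ``ds``: genes whose expression "entropy" falls significantly
below the level expected for their mean expression indicate substructure.
The default ``ds`` estimator here fits expected entropy against log-mean
expression with lowess and takes significant positive residuals
(Benjamini-Hochberg at 0.05); it is a documented approximation — supplying
precomputed ``ds`` values from a dedicated entropy model is the
higher-fidelity path.

The combined score is the geometric mean of the per-modality scores and
extends to any number of modalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm as normal_dist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


@dataclass
class PurityConfig:
    """rank: SD exponent of the ADT score (None -> suggest_rank);
    k_rna: the pre-set constant K of the RNA score (technology dependent);
    sd_kind: sample (n-1 denominator) or population SDs;
    ds_estimator: callable(matrix_genes_x_cells) -> significant ds array."""

    rank: int = None
    k_rna: float = 1.0
    sd_kind: str = "sample"
    ds_estimator: callable = None
    sig_level: float = 0.05

    def __post_init__(self):
        if self.rank is not None and self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.k_rna <= 0:
            raise ValueError("k_rna must be > 0")
        if self.sd_kind not in ("sample", "population"):
            raise ValueError("sd_kind must be 'sample' or 'population'")


def suggest_rank(n_features: int) -> int:
    """Heuristic ADT rank: ``max(1, floor(ln(n_features)))``."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return max(1, math.floor(math.log(n_features)))


def _sds(X, ddof):
    """Per-row SDs; a single column yields all-zero SDs (a singleton is pure)."""
    if X.shape[1] <= ddof:
        return np.zeros(X.shape[0])
    return X.std(axis=1, ddof=ddof)


def adt_purity(adt_normalized, labels, config: PurityConfig = None) -> pd.DataFrame:
    """Per-cluster ADT purity scores.

    ``adt_normalized`` is features × cells (the same normalized matrix and
    SD convention are used for the clusters and for ``K_ADT``).  Returns a
    DataFrame with columns cluster, n_cells, S_ADT and attrs ``k_adt`` and
    ``rank``.
    """
    config = config or PurityConfig()
    X = np.asarray(adt_normalized, dtype=float)
    labels = np.asarray(labels)
    if X.shape[1] != labels.size:
        raise ValueError("labels length does not match cell count")
    ddof = 1 if config.sd_kind == "sample" else 0
    rank = config.rank if config.rank is not None else suggest_rank(X.shape[0])
    k_adt = float((_sds(X, ddof) ** rank).sum())
    rows = []
    for cl in pd.unique(labels):
        mask = labels == cl
        num = float((_sds(X[:, mask], ddof) ** rank).sum())
        rows.append({
            "cluster": cl,
            "n_cells": int(mask.sum()),
            "S_ADT": 1.0 - num / (num + k_adt) if (num + k_adt) > 0 else 1.0,
        })
    out = pd.DataFrame(rows)
    out.attrs["k_adt"] = k_adt
    out.attrs["rank"] = rank
    return out


def entropy_reduction_ds(expr, sig_level: float = 0.05, lowess_frac: float = 0.5):
    """Default per-gene entropy-reduction estimator for one cluster.

    ``expr`` is a genes × cells log-normalized matrix.  Per gene, the
    observed entropy proxy is ``mean_c ln(1 + x)`` on the de-logged
    normalized scale; the expected value is a lowess fit against
    ``ln(1 + mean expression)``.  ``ds = expected - observed``; genes with
    BH-adjusted one-sided normal p < sig_level on the residuals are deemed
    significant.  Returns the array of significant ds values (possibly
    empty).
    """
    X = np.asarray(sp.csr_matrix(expr).todense(), dtype=float)
    x = np.expm1(X)
    mean = x.mean(axis=1)
    expressed = mean > 0
    if expressed.sum() < 5:
        return np.array([])
    m = np.log1p(mean[expressed])
    h = np.log1p(x[expressed]).mean(axis=1)
    fit = lowess(h, m, frac=lowess_frac, return_sorted=False)
    ds = fit - h  # positive: less entropy than expected for this mean
    sd = ds.std(ddof=1)
    if sd == 0:
        return np.array([])
    pvals = normal_dist.sf(ds / sd)
    sig = multipletests(pvals, alpha=sig_level, method="fdr_bh")[0] & (ds > 0)
    return ds[sig]


def rna_purity(rna_lognorm=None, labels=None, config: PurityConfig = None,
               ds_by_cluster: dict = None) -> pd.DataFrame:
    """Per-cluster RNA purity ``S_RNA = 1 - S/(S + K)``.

    Either pass a log-normalized genes × cells matrix plus labels (the
    configured ``ds_estimator`` computes significant entropy reductions per
    cluster), or pass ``ds_by_cluster`` mapping cluster id to an array of
    precomputed significant ds values (the fidelity path).
    """
    config = config or PurityConfig()
    estimator = config.ds_estimator or (
        lambda X: entropy_reduction_ds(X, sig_level=config.sig_level))
    rows = []
    if ds_by_cluster is not None:
        items = ds_by_cluster.items()
        sizes = {cl: None for cl, _ in items}
        for cl, ds in items:
            s = float(np.asarray(ds, dtype=float).sum())
            rows.append({"cluster": cl, "n_cells": sizes[cl],
                         "S_RNA": 1.0 - s / (s + config.k_rna)})
        return pd.DataFrame(rows)
    X = sp.csr_matrix(rna_lognorm)
    labels = np.asarray(labels)
    if X.shape[1] != labels.size:
        raise ValueError("labels length does not match cell count")
    for cl in pd.unique(labels):
        mask = labels == cl
        ds = np.asarray(estimator(X[:, np.flatnonzero(mask)]), dtype=float)
        s = float(ds.sum())
        rows.append({"cluster": cl, "n_cells": int(mask.sum()),
                     "S_RNA": 1.0 - s / (s + config.k_rna)})
    return pd.DataFrame(rows)


def combined_purity(scores) -> float:
    """Geometric mean of per-modality purity scores, any number of modalities."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores supplied")
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("purity scores must lie in [0, 1]")
    return float(np.prod(scores) ** (1.0 / scores.size))


def purity_report(rna_lognorm, adt_normalized, labels,
                  config: PurityConfig = None) -> pd.DataFrame:
    """Full per-cluster report: cluster, n_cells, S_RNA, S_ADT, S (geometric
    mean), with the K_ADT and rank used in ``DataFrame.attrs``."""
    config = config or PurityConfig()
    adt = adt_purity(adt_normalized, labels, config)
    rna = rna_purity(rna_lognorm, labels, config)
    out = adt.merge(rna.drop(columns="n_cells"), on="cluster")
    out["S"] = [combined_purity([a, r]) for a, r in zip(out["S_ADT"], out["S_RNA"])]
    out.attrs.update(adt.attrs)
    return out[["cluster", "n_cells", "S_RNA", "S_ADT", "S"]]
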