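"""Convex scaling and L-infinity fusion of per-modality distance matrices.

RNA and ADT distances live on incomparable scales (different feature counts
and normalizations), so before fusing them the two condensed matrices are
rescaled by a single convex weight alpha minimizing

    (1 / 2m) * || alpha * D_RNA - (1 - alpha) * D_ADT ||^2,   alpha in [0, 1],

with ``m = N*(N-1)/2`` cell pairs.  The joint distance is then the
entrywise maximum (L-infinity norm) of the scaled matrices — each cell pair
keeps whichever modality separates it more strongly — with L1 (sum) and L2
(root-sum-square) available as comparator norms.

Because the L-infinity joint entry *equals* one (or both) of the scaled
inputs, each modality's contribution can be quantified as the percentage of
cell pairs whose joint distance equals that modality's scaled distance;
ties count for both, so the two percentages sum to at least 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import DistanceMatrix

logger = logging.getLogger("linfuse")

NORMS = ("linf", "l1", "l2")

# relative tie tolerance for the "joint equals scaled modality" count; an
# exact-zero comparison is numerically fragile
TIE_RTOL = 1e-12


@dataclass
class FusionResult:
    alpha: float
    d_rna_scaled: DistanceMatrix
    d_adt_scaled: DistanceMatrix
    d_joint: DistanceMatrix
    norm: str
    contribution_rna: float = None  # percent, Linf only
    contribution_adt: float = None


def _check_pair(d_rna: DistanceMatrix, d_adt: DistanceMatrix):
    if d_rna.m != d_adt.m:
        raise ValueError(f"mismatched pair counts: {d_rna.m} vs {d_adt.m}")


def solve_alpha(d_rna: DistanceMatrix, d_adt: DistanceMatrix,
                tol: float = 1e-8, method: str = "closed_form") -> float:
    """Solve the convex scaling problem for alpha in [0, 1].

    ``method="closed_form"`` (default) evaluates the minimizer directly:
    ``alpha* = clip( sum(d_a * (d_r + d_a)) / sum((d_r + d_a)^2), 0, 1 )``.
    ``method="gradient"`` runs projected gradient descent on the objective
    (step 0.1 / Lipschitz estimate, stop at |delta alpha| < tol); it agrees
    with the closed form and is retained as the iterative reference.
    """
    _check_pair(d_rna, d_adt)
    if tol <= 0:
        raise ValueError("tol must be > 0")
    r = d_rna.values
    a = d_adt.values
    s = r + a
    denom = float((s**2).sum())
    if denom == 0.0:
        logger.warning("both distance matrices are all-zero; objective constant, alpha=0.5")
        return 0.5
    if method == "closed_form":
        return float(np.clip((a * s).sum() / denom, 0.0, 1.0))
    if method != "gradient":
        raise ValueError(f"unknown method {method!r}")

    m = r.size
    lipschitz = denom / m  # second derivative of the (1/2m)-scaled objective
    step = 0.1 / lipschitz
    alpha = 0.5
    for _ in range(10_000):
        grad = float((s * (alpha * s - a)).sum()) / m
        new = float(np.clip(alpha - step * grad, 0.0, 1.0))
        if abs(new - alpha) < tol:
            return new
        alpha = new
    return alpha


def fuse(d_rna: DistanceMatrix, d_adt: DistanceMatrix,
         alpha: float = None, norm: str = "linf") -> FusionResult:
    """Scale the two matrices by (alpha, 1-alpha) and fuse entrywise.

    If ``alpha`` is None it is solved by :func:`solve_alpha`.  Norms:
    ``linf`` -> max(a, b) (default), ``l1`` -> a + b, ``l2`` ->
    sqrt(a^2 + b^2).  For Linf the per-modality contribution percentages
    are filled in.
    """
    _check_pair(d_rna, d_adt)
    if norm not in NORMS:
        raise ValueError(f"norm must be one of {NORMS}")
    if alpha is None:
        alpha = solve_alpha(d_rna, d_adt)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rs = alpha * d_rna.values
    as_ = (1.0 - alpha) * d_adt.values
    if norm == "linf":
        joint = np.maximum(rs, as_)
    elif norm == "l1":
        joint = rs + as_
    else:
        joint = np.sqrt(rs**2 + as_**2)
    result = FusionResult(
        alpha=float(alpha),
        d_rna_scaled=DistanceMatrix(rs, d_rna.barcodes, "RNA"),
        d_adt_scaled=DistanceMatrix(as_, d_rna.barcodes, "ADT"),
        d_joint=DistanceMatrix(joint, d_rna.barcodes, "joint"),
        norm=norm,
    )
    if norm == "linf":
        result.contribution_rna, result.contribution_adt = modality_contributions(result)
    return result


def _pair_mask(labels, n, group_a, group_b, pairs="between"):
    """Condensed-index mask for the pairs linking two named clusters.

    ``pairs="between"`` selects pairs with one cell in each cluster;
    ``pairs="union"`` selects every pair among the union of the two.
    """
    labels = np.asarray(labels)
    iu, ju = np.triu_indices(n, 1)
    la, lb = labels[iu], labels[ju]
    if pairs == "between":
        return ((la == group_a) & (lb == group_b)) | ((la == group_b) & (lb == group_a))
    if pairs == "union":
        in_ab = np.isin(labels, [group_a, group_b])
        return in_ab[iu] & in_ab[ju]
    raise ValueError("pairs must be 'between' or 'union'")


def modality_contributions(result: FusionResult, labels=None,
                           between=None, pairs="between"):
    """Percentage of cell pairs each scaled modality attains the joint max on.

    Counts entries where ``d_joint`` equals the scaled modality matrix
    within a relative tie tolerance, divided by the pair count, times 100.
    Ties count for both, so the two percentages sum to >= 100.  With
    ``between=(A, B)`` (and the cluster ``labels``) the count is restricted
    to pairs linking clusters A and B (or all pairs within their union,
    ``pairs="union"``).
    """
    if result.norm != "linf":
        raise ValueError("contributions are defined for Linf fusion only")
    joint = result.d_joint.values
    mask = slice(None)
    if between is not None:
        if labels is None:
            raise ValueError("labels required when restricting to cluster pairs")
        mask = _pair_mask(labels, result.d_joint.n_cells, *between, pairs=pairs)
        if not np.count_nonzero(mask):
            raise ValueError(f"no cell pairs between clusters {between}")
    j = joint[mask]
    tol = TIE_RTOL * np.maximum(1.0, j)
    m = j.size
    contrib_rna = 100.0 * np.count_nonzero(
        np.abs(j - result.d_rna_scaled.values[mask]) <= tol) / m
    contrib_adt = 100.0 * np.count_nonzero(
        np.abs(j - result.d_adt_scaled.values[mask]) <= tol) / m
    return float(contrib_rna), float(contrib_adt)
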