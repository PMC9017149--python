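"""Multimodal CITE-seq containers and readers/writers for the standard formats.

A CITE-seq experiment measures, for every cell, whole-transcriptome RNA
counts and a small panel of antibody-derived tags (ADTs) reporting surface
protein abundance.  :class:`MultimodalDataset` keeps the two count blocks
over an identical, identically ordered set of cells; every downstream stage
relies on that alignment.

Pairwise cell-cell dissimilarities are carried as condensed upper-triangle
vectors (:class:`DistanceMatrix`) of length ``m = N*(N-1)/2`` in
:func:`scipy.spatial.distance.pdist` order, which bounds memory at one float
per cell pair.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.spatial.distance import squareform

logger = logging.getLogger("linfuse")

GENE_EXPRESSION = "Gene Expression"
ANTIBODY_CAPTURE = "Antibody Capture"


@dataclass
class MultimodalDataset:
    """Paired RNA and ADT count matrices over one ordered set of cells.

    Parameters
    ----------
    rna : scipy.sparse.csr_matrix
        Gene-by-cell raw counts (sparse: the RNA block is large and mostly
        zero).
    adt : numpy.ndarray
        ADT-feature-by-cell raw counts (dense: panels are <= ~50 features and
        constant-time feature access matters).
    gene_ids, adt_ids, cell_barcodes : numpy.ndarray
        Unique identifiers for each axis.
    cell_meta : pandas.DataFrame
        Per-cell table indexed by barcode; ``n_genes_detected`` and
        ``mito_fraction`` are filled by :meth:`compute_qc_metrics`.
    layers : dict
        Named normalized/scaled matrices, keyed e.g. ``"rna_lognorm"``,
        ``"adt_clr"``.
    info : dict
        Free-form provenance (e.g. planted effect sizes of a simulation).
    """

    rna: sp.csr_matrix
    adt: np.ndarray
    gene_ids: np.ndarray
    adt_ids: np.ndarray
    cell_barcodes: np.ndarray
    cell_meta: pd.DataFrame = None
    layers: dict = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rna = sp.csr_matrix(self.rna)
        self.adt = np.asarray(self.adt, dtype=float)
        if self.adt.ndim == 1:
            self.adt = self.adt.reshape(0, self.rna.shape[1])
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.adt_ids = np.asarray(self.adt_ids, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_barcodes, name="barcode"))
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self):
        """Check the container invariants; raise ``ValueError`` on violation."""
        n = self.rna.shape[1]
        if self.adt.shape[1] != n:
            raise ValueError(
                f"RNA and ADT blocks disagree on cell count: {n} vs {self.adt.shape[1]}"
            )
        if len(self.cell_barcodes) != n:
            raise ValueError("cell_barcodes length does not match cell count")
        if len(self.gene_ids) != self.rna.shape[0]:
            raise ValueError("gene_ids length does not match RNA rows")
        if len(self.adt_ids) != self.adt.shape[0]:
            raise ValueError("adt_ids length does not match ADT rows")
        for name, ids in (("gene_ids", self.gene_ids),
                          ("adt_ids", self.adt_ids),
                          ("cell_barcodes", self.cell_barcodes)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} contains duplicates")
        if self.rna.nnz and self.rna.data.min() < 0:
            raise ValueError("negative RNA counts")
        if self.adt.size and self.adt.min() < 0:
            raise ValueError("negative ADT counts")
        if "mito_fraction" in self.cell_meta:
            mf = self.cell_meta["mito_fraction"].to_numpy(dtype=float)
            if ((mf < 0) | (mf > 1)).any():
                raise ValueError("mito_fraction outside [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.rna.shape[1]

    @property
    def n_genes(self) -> int:
        return self.rna.shape[0]

    @property
    def n_adt(self) -> int:
        return self.adt.shape[0]

    # ------------------------------------------------------------------ #
    def compute_qc_metrics(self, mito_prefix: str = "MT-") -> "MultimodalDataset":
        """Fill ``n_genes_detected`` and ``mito_fraction`` in ``cell_meta``.

        Mitochondrial genes are recognized by a configurable identifier
        prefix (case-insensitive); ``mito_fraction`` is their share of each
        cell's total RNA counts (0 for cells with zero counts).
        """
        csc = self.rna.tocsc()
        self.cell_meta["n_genes_detected"] = np.diff(csc.indptr)
        totals = np.asarray(self.rna.sum(axis=0)).ravel()
        is_mito = np.array(
            [str(g).upper().startswith(mito_prefix.upper()) for g in self.gene_ids]
        )
        mito = (
            np.asarray(self.rna[is_mito].sum(axis=0)).ravel()
            if is_mito.any()
            else np.zeros(self.n_cells)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        self.cell_meta["mito_fraction"] = frac
        return self

    def subset_cells(self, index) -> "MultimodalDataset":
        """Return a new dataset over ``index`` (boolean mask or positions),
        preserving cell order and keeping the modalities aligned."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        ds = MultimodalDataset(
            rna=self.rna[:, index],
            adt=self.adt[:, index] if self.adt.size else self.adt[:, index],
            gene_ids=self.gene_ids,
            adt_ids=self.adt_ids,
            cell_barcodes=self.cell_barcodes[index],
            cell_meta=self.cell_meta.iloc[index].copy(),
            info=dict(self.info),
        )
        ds.layers = {k: v[:, index] for k, v in self.layers.items()}
        return ds


@dataclass
class DistanceMatrix:
    """Condensed pairwise cell-cell distances for one modality or the joint view.

    ``values`` is the upper triangle in pdist order, length
    ``m = N*(N-1)/2``; the implied diagonal is zero and the matrix is
    symmetric by construction.
    """

    values: np.ndarray
    barcodes: np.ndarray
    modality: str  # "RNA" | "ADT" | "joint"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n = len(self.barcodes)
        if self.values.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"condensed length {self.values.size} inconsistent with {n} cells"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative distances")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def m(self) -> int:
        """Number of cell pairs, N*(N-1)/2."""
        return self.values.size

    def to_square(self) -> np.ndarray:
        return squareform(self.values)


# ---------------------------------------------------------------------- #
# Readers / writers
# ---------------------------------------------------------------------- #

def _resolve(directory: Path, stem: str) -> Path:
    """Find ``stem`` or ``stem.gz`` in ``directory``."""
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rb")
    return open(path, "rb")


def read_10x_mtx(directory) -> MultimodalDataset:
    """Read a 10x-style Matrix Market triplet directory.

    Expects ``matrix.mtx[.gz]``, ``features.tsv[.gz]`` (id, name, feature
    type) and ``barcodes.tsv[.gz]``.  Rows typed "Gene Expression" populate
    the RNA block and rows typed "Antibody Capture" the ADT block; cell order
    follows the barcodes file.  A features file with only two columns is
    treated as all-RNA.  Missing Antibody Capture rows yield an empty ADT
    block and a logged warning.
    """
    directory = Path(directory)
    mtx_path = _resolve(directory, "matrix.mtx")
    feat_path = _resolve(directory, "features.tsv")
    bc_path = _resolve(directory, "barcodes.tsv")

    with _open_maybe_gz(mtx_path) as fh:
        mat = sp.csr_matrix(scipy.io.mmread(fh))
    features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].to_numpy()

    if mat.shape[0] != len(features):
        raise ValueError(
            f"matrix has {mat.shape[0]} rows but features file lists {len(features)}"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[1]} columns but barcodes file lists {len(barcodes)}"
        )

    names = features[1] if features.shape[1] > 1 else features[0]
    if features.shape[1] >= 3:
        ftype = features[2].to_numpy()
    else:
        ftype = np.full(len(features), GENE_EXPRESSION)
    is_adt = ftype == ANTIBODY_CAPTURE
    is_rna = ~is_adt
    if not is_adt.any():
        logger.warning("%s: no Antibody Capture features; ADT block is empty", directory)

    return MultimodalDataset(
        rna=mat[is_rna],
        adt=np.asarray(mat[is_adt].todense(), dtype=float),
        gene_ids=names[is_rna].to_numpy(),
        adt_ids=names[is_adt].to_numpy(),
        cell_barcodes=barcodes,
    )


def write_10x_mtx(dataset: MultimodalDataset, directory) -> None:
    """Write a dataset back out as an (uncompressed) 10x triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stacked = sp.vstack([dataset.rna, sp.csr_matrix(dataset.adt)]).tocoo()
    scipy.io.mmwrite(str(directory / "matrix.mtx"), stacked, field="integer"
                     if np.allclose(stacked.data, np.round(stacked.data)) else "real")
    ids = np.concatenate([dataset.gene_ids, dataset.adt_ids])
    types = [GENE_EXPRESSION] * dataset.n_genes + [ANTIBODY_CAPTURE] * dataset.n_adt
    pd.DataFrame({0: ids, 1: ids, 2: types}).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(dataset.cell_barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_dense(rna_path, adt_path, cells_in_columns: bool = True) -> MultimodalDataset:
    """Read dense CSV/TSV count tables for the two modalities.

    Both tables need a header row and a leading identifier column.  With
    ``cells_in_columns`` (the dense-distribution convention) columns are
    cells and rows features; pass ``False`` for the transposed layout.  Cells
    are intersected by barcode, preserving the RNA table's order; the number
    of dropped barcodes is logged.
    """

    def _read(path):
        sep = "\t" if str(path).endswith((".tsv", ".tsv.gz", ".txt", ".txt.gz")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if not cells_in_columns:
            df = df.T
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
        return df.index.to_numpy(), df.columns.to_numpy(), values

    gene_ids, rna_cells, rna = _read(rna_path)
    adt_ids, adt_cells, adt = _read(adt_path)

    keep = [bc for bc in rna_cells if bc in set(adt_cells)]
    if not keep:
        raise ValueError("no shared cell barcodes between RNA and ADT tables")
    dropped = (len(rna_cells) - len(keep)) + (len(adt_cells) - len(keep))
    if dropped:
        logger.info("dropped %d barcodes absent from one modality", dropped)
    rna_pos = {bc: i for i, bc in enumerate(rna_cells)}
    adt_pos = {bc: i for i, bc in enumerate(adt_cells)}
    ri = [rna_pos[bc] for bc in keep]
    ai = [adt_pos[bc] for bc in keep]
    return MultimodalDataset(
        rna=sp.csr_matrix(rna[:, ri]),
        adt=adt[:, ai],
        gene_ids=gene_ids,
        adt_ids=adt_ids,
        cell_barcodes=np.asarray(keep, dtype=object),
    )


# ---------------------------------------------------------------------- #
# Small tabular outputs
# ---------------------------------------------------------------------- #

def write_labels(path, barcodes, labels) -> None:
    pd.DataFrame({"barcode": barcodes, "cluster": labels}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_embedding(path, barcodes, coords) -> None:
    coords = np.asarray(coords)
    pd.DataFrame(
        {"barcode": barcodes, "dim1": coords[:, 0], "dim2": coords[:, 1]}
    ).to_csv(path, index=False)


def save_distance(path, d: DistanceMatrix) -> None:
    """Condensed distance vector as .npy plus a JSON sidecar (N, modality, checksum)."""
    path = Path(path)
    np.save(path, d.values)
    npy = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    sidecar = {
        "n_cells": d.n_cells,
        "modality": d.modality,
        "checksum": hashlib.sha256(d.values.tobytes()).hexdigest(),
        "barcodes": list(map(str, d.barcodes)),
    }
    npy.with_suffix(".json").write_text(json.dumps(sidecar))


def load_distance(path) -> DistanceMatrix:
    path = Path(path)
    npy = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    values = np.load(npy)
    meta = json.loads(npy.with_suffix(".json").read_text())
    if hashlib.sha256(values.tobytes()).hexdigest() != meta["checksum"]:
        raise ValueError(f"checksum mismatch for {npy}")
    return DistanceMatrix(values, np.asarray(meta["barcodes"], dtype=object), meta["modality"])
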