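import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from linfuse.datamodel import MultimodalDataset
from linfuse.preprocess import (QCConfig, normalize_adt_clr, normalize_rna,
                                pca_reduce, qc_filter, scale_genes,
                                select_hvg, soft_mito_threshold)


class TestSoftMitoThreshold:
    def test_percentile_below_cap_is_used(self, rng):
        fractions = rng.uniform(0, 0.04, 100)
        expected = np.quantile(fractions, 0.95)
        assert soft_mito_threshold(fractions) == pytest.approx(expected)

    def test_cap_seals_poor_quality_datasets(self, rng):
        fractions = rng.uniform(0.1, 0.4, 200)
        assert soft_mito_threshold(fractions) == 0.10

    def test_all_zero(self):
        assert soft_mito_threshold(np.zeros(10)) == 0.0

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError):
            soft_mito_threshold([])


def _dataset_with_meta(gene_counts, mito):
    n = len(gene_counts)
    ds = MultimodalDataset(
        rna=sp.csr_matrix(np.ones((2, n))), adt=np.ones((1, n)),
        gene_ids=["g1", "g2"], adt_ids=["p1"],
        cell_barcodes=[f"c{i}" for i in range(n)])
    ds.cell_meta["n_genes_detected"] = gene_counts
    ds.cell_meta["mito_fraction"] = mito
    return ds


class TestQCFilter:
    def test_gene_count_boundaries_inclusive(self):
        ds = _dataset_with_meta([150, 200, 1000, 2500, 3000], np.zeros(5))
        kept, report = qc_filter(ds)
        assert kept.n_cells == 3
        assert list(kept.cell_barcodes) == ["c1", "c2", "c3"]
        assert report["removed_low_genes"] == 1
        assert report["removed_high_genes"] == 1

    def test_high_mito_cell_removed(self):
        ds = _dataset_with_meta([1000] * 20, [0.01] * 19 + [0.5])
        kept, report = qc_filter(ds)
        assert kept.n_cells == 19
        assert report["removed_mito"] == 1

    def test_clean_dataset_unchanged(self):
        ds = _dataset_with_meta([1000, 1200], [0.0, 0.0])
        kept, report = qc_filter(ds)
        assert kept.n_cells == 2
        assert report["removed_low_genes"] == report["removed_high_genes"] == 0

    def test_all_removed_raises(self):
        ds = _dataset_with_meta([10, 20], [0.0, 0.0])
        with pytest.raises(ValueError, match="threshold"):
            qc_filter(ds)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            QCConfig(min_genes=3000, max_genes=2500)


class TestNormalizeRNA:
    def test_single_expressed_gene(self):
        counts = sp.csr_matrix(np.array([[10.0], [0.0]]))
        out = normalize_rna(counts, scale_factor=1e4).toarray()
        assert out[0, 0] == pytest.approx(np.log(10001))
        assert out[1, 0] == 0.0

    def test_depth_invariance(self, rng):
        counts = rng.integers(0, 20, (30, 4)).astype(float)
        counts[:, 0] += 1  # avoid a zero-count cell
        doubled = counts.copy()
        doubled[:, 0] *= 2
        a = normalize_rna(sp.csr_matrix(counts)).toarray()
        b = normalize_rna(sp.csr_matrix(doubled)).toarray()
        np.testing.assert_allclose(a[:, 0], b[:, 0], rtol=1e-12)

    def test_zero_count_cell_names_barcode(self):
        counts = sp.csr_matrix(np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError, match="bad_cell"):
            normalize_rna(counts, barcodes=np.array(["ok", "bad_cell"]))


class TestCLR:
    def test_equal_counts_map_to_zero(self):
        out = normalize_adt_clr(np.array([[1.0], [1.0], [1.0]]))
        np.testing.assert_allclose(out, 0.0)

    def test_hand_computed_cell(self):
        out = normalize_adt_clr(np.array([[3.0], [0.0], [0.0]]))
        np.testing.assert_allclose(out.ravel(), [0.9242, -0.4621, -0.4621],
                                   atol=5e-5)

    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=30))
    def test_per_cell_zero_mean(self, counts):
        out = normalize_adt_clr(np.array(counts, dtype=float)[:, None])
        assert abs(out.mean()) < 1e-9


class TestHVG:
    def test_clamped_when_few_genes(self, rng):
        X = sp.csr_matrix(rng.random((5, 20)))
        assert len(select_hvg(X, n_hvg=2000)) == 5

    def test_constant_gene_ranked_last(self, rng):
        X = rng.random((10, 50)) + 0.5
        X[3] = 1.0
        assert select_hvg(sp.csr_matrix(X), n_hvg=10)[-1] == 3

    def test_planted_high_dispersion_gene_first(self, rng):
        X = np.abs(rng.normal(1.0, 0.05, (40, 60)))
        X[17] = np.abs(rng.normal(1.0, 2.0, 60))
        assert select_hvg(sp.csr_matrix(X), n_hvg=5)[0] == 17

    def test_permutation_equivariance(self, rng):
        X = rng.random((30, 40))
        perm = rng.permutation(30)
        base = select_hvg(sp.csr_matrix(X), n_hvg=10)
        shuffled = select_hvg(sp.csr_matrix(X[perm]), n_hvg=10)
        assert set(perm[shuffled]) == set(base)


class TestPCA:
    def test_rank_one_input_single_dominant_component(self):
        t = np.linspace(0, 1, 20)
        X = np.outer(np.array([1.0, 2.0, 3.0]), t)  # genes x cells on a line
        emb = pca_reduce(X - X.mean(axis=1, keepdims=True), n_pcs=2)
        var = emb.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_full_rank_pca_preserves_distances(self, rng):
        X = rng.normal(size=(6, 15))  # genes x cells
        Xc = X - X.mean(axis=1, keepdims=True)
        emb = pca_reduce(Xc, n_pcs=6)
        np.testing.assert_allclose(pdist(emb), pdist(Xc.T), rtol=1e-8)

    def test_two_blob_separation_on_pc1(self, rng):
        X = rng.normal(size=(10, 40)) * 0.1
        X[:, 20:] += 5.0
        emb = pca_reduce(scale_genes(X), n_pcs=3)
        assert (emb[:20, 0].max() < emb[20:, 0].min()
                or emb[20:, 0].max() < emb[:20, 0].min())

    def test_too_many_components_raises(self, rng):
        with pytest.raises(ValueError, match="n_pcs"):
            pca_reduce(rng.random((4, 10)), n_pcs=5)


def test_scale_genes_zscores_and_clips(rng):
    X = rng.normal(2.0, 3.0, (5, 100))
    out = scale_genes(X, clip=10.0)
    np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
    assert np.abs(out).max() <= 10.0
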