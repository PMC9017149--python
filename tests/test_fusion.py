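import numpy as np
import pytest
from scipy.spatial.distance import pdist

from linfuse.datamodel import DistanceMatrix
from linfuse.fusion import fuse, modality_contributions, solve_alpha

from conftest import condensed


def as_adt(d):
    return DistanceMatrix(d.values, d.barcodes, "ADT")


class TestSolveAlpha:
    def test_identical_inputs_balance(self, rng):
        v = rng.random(10) + 0.1
        assert solve_alpha(condensed(v), as_adt(condensed(v))) == pytest.approx(0.5)

    def test_zero_adt_gives_zero(self, rng):
        r = condensed(rng.random(6) + 0.1)
        a = as_adt(condensed(np.zeros(6)))
        assert solve_alpha(r, a) == 0.0

    def test_printed_formula_hand_case(self):
        # single pair, d_r=1, d_a=2: alpha* = 2*3/3^2 = 2/3
        assert solve_alpha(condensed([1.0]), as_adt(condensed([2.0]))) \
            == pytest.approx(2 / 3)
        assert solve_alpha(condensed([1.0]), as_adt(condensed([2.0])),
                           method="gradient") == pytest.approx(2 / 3, abs=1e-6)

    def test_all_zero_inputs_fall_back_to_half(self):
        z = condensed(np.zeros(3))
        assert solve_alpha(z, as_adt(condensed(np.zeros(3)))) == 0.5

    def test_gradient_descent_agrees_with_closed_form(self, rng):
        for _ in range(20):
            m = 10 * 9 // 2
            r = condensed(rng.random(m))
            a = as_adt(condensed(rng.random(m)))
            assert solve_alpha(r, a, method="gradient") == pytest.approx(
                solve_alpha(r, a), abs=1e-6)

    def test_mismatched_sizes_raise(self):
        with pytest.raises(ValueError):
            solve_alpha(condensed([1.0]), as_adt(condensed([1.0, 2.0, 3.0])))


class TestFuse:
    def test_linf_is_entrywise_max(self):
        r = condensed([6.0, 2.0, 4.0])
        a = as_adt(condensed([10.0, 1.0, 8.0]))
        res = fuse(r, a, alpha=0.5, norm="linf")
        np.testing.assert_allclose(res.d_joint.values, [5.0, 1.0, 4.0])

    def test_equal_scaled_entries_under_all_norms(self):
        r = condensed([2.0])
        a = as_adt(condensed([2.0]))
        assert fuse(r, a, 0.5, "linf").d_joint.values[0] == pytest.approx(1.0)
        assert fuse(r, a, 0.5, "l1").d_joint.values[0] == pytest.approx(2.0)
        assert fuse(r, a, 0.5, "l2").d_joint.values[0] == pytest.approx(np.sqrt(2))

    def test_linf_matches_loop_oracle_on_random_instances(self, rng):
        m = 6 * 5 // 2
        for _ in range(10):
            r, a = rng.random(m), rng.random(m)
            alpha = rng.random()
            res = fuse(condensed(r), as_adt(condensed(a)), alpha, "linf")
            expected = np.array([max(alpha * r[i], (1 - alpha) * a[i])
                                 for i in range(m)])
            np.testing.assert_allclose(res.d_joint.values, expected, atol=1e-12)

    def test_linf_joint_of_metrics_satisfies_triangle_inequality(self, rng):
        for _ in range(10):
            pts_r = rng.normal(size=(7, 3))
            pts_a = rng.normal(size=(7, 2))
            res = fuse(condensed(pdist(pts_r)), as_adt(condensed(pdist(pts_a))),
                       alpha=rng.random(), norm="linf")
            D = res.d_joint.to_square()
            n = D.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_scale_consistency(self, rng):
        m = 10
        r, a = rng.random(m), rng.random(m)
        base = fuse(condensed(r), as_adt(condensed(a)), 0.3, "linf")
        scaled = fuse(condensed(3.0 * r), as_adt(condensed(3.0 * a)), 0.3, "linf")
        np.testing.assert_allclose(scaled.d_joint.values,
                                   3.0 * base.d_joint.values, rtol=1e-12)

    def test_solved_alpha_used_when_not_given(self, rng):
        r = condensed(rng.random(10))
        a = as_adt(condensed(rng.random(10)))
        res = fuse(r, a)
        assert res.alpha == pytest.approx(solve_alpha(r, a))

    def test_invalid_norm_and_alpha(self):
        r, a = condensed([1.0]), as_adt(condensed([1.0]))
        with pytest.raises(ValueError):
            fuse(r, a, 0.5, "l3")
        with pytest.raises(ValueError):
            fuse(r, a, 1.5, "linf")


class TestContributions:
    def test_rna_dominant_everywhere(self):
        res = fuse(condensed([4.0, 4.0, 4.0]), as_adt(condensed([1.0, 1.0, 1.0])),
                   alpha=0.5, norm="linf")
        assert res.contribution_rna == 100.0

    def test_ties_count_for_both(self):
        res = fuse(condensed([2.0, 2.0, 2.0]), as_adt(condensed([2.0, 2.0, 2.0])),
                   alpha=0.5, norm="linf")
        assert res.contribution_rna == 100.0
        assert res.contribution_adt == 100.0

    def test_single_differing_entry(self):
        # m=3, exactly one entry where ADT wins: RNA (3-1)/3
        res = fuse(condensed([4.0, 4.0, 1.0]), as_adt(condensed([1.0, 1.0, 4.0])),
                   alpha=0.5, norm="linf")
        assert res.contribution_rna == pytest.approx(100 * 2 / 3)

    def test_sum_is_at_least_hundred(self, rng):
        for _ in range(20):
            res = fuse(condensed(rng.random(15)), as_adt(condensed(rng.random(15))),
                       alpha=rng.random(), norm="linf")
            assert res.contribution_rna + res.contribution_adt >= 100.0

    def test_matches_loop_oracle(self, rng):
        m = 6 * 5 // 2
        r, a = rng.random(m), rng.random(m)
        res = fuse(condensed(r), as_adt(condensed(a)), 0.5, "linf")
        joint = res.d_joint.values
        n_rna = sum(abs(joint[i] - 0.5 * r[i]) <= 1e-12 for i in range(m))
        assert res.contribution_rna == pytest.approx(100 * n_rna / m, abs=1e-12)

    def test_restricted_to_cluster_pairs(self):
        # 4 cells, clusters [A, A, B, B]; pairs (0,1),(0,2),(0,3),(1,2),(1,3),(2,3)
        labels = np.array(["A", "A", "B", "B"])
        r = condensed([1.0, 9.0, 9.0, 9.0, 9.0, 1.0])
        a = as_adt(condensed([5.0, 1.0, 1.0, 1.0, 1.0, 5.0]))
        res = fuse(r, a, alpha=0.5, norm="linf")
        cr, ca = modality_contributions(res, labels, between=("A", "B"))
        assert cr == 100.0 and ca == 0.0  # RNA wins all 4 inter-cluster pairs
        cr_u, ca_u = modality_contributions(res, labels, between=("A", "B"),
                                            pairs="union")
        assert cr_u == pytest.approx(100 * 4 / 6)
        assert ca_u == pytest.approx(100 * 2 / 6)

    def test_contributions_require_linf(self):
        res = fuse(condensed([1.0]), as_adt(condensed([1.0])), 0.5, "l1")
        with pytest.raises(ValueError, match="Linf"):
            modality_contributions(res)
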