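import numpy as np
import pytest

from sswas.io import GenotypePanel, Pedigree
from sswas.relationships import (
    HInverse,
    SNPWeights,
    blend_G,
    build_A22,
    build_A_inverse,
    build_G,
    build_H_inverse,
    center_gene_content,
    inbreeding_coefficients,
    lambda_scale,
    tabular_A,
)
from sswas.simulate import SimConfig, simulate_dataset

from .conftest import binomial_panel, random_pedigree


class TestAInverse:
    def test_unrelated_founders_identity(self):
        ped = Pedigree.from_records([("A", "0", "0"), ("B", "0", "0")])
        Ainv = build_A_inverse(ped).toarray()
        np.testing.assert_allclose(Ainv, np.eye(2))

    def test_trio_exact_values(self, trio):
        Ainv = build_A_inverse(trio).toarray()
        expect = np.array(
            [[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]]
        )
        np.testing.assert_allclose(Ainv, expect)
        # oracle: invert the dense trio A
        A = np.array([[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]])
        np.testing.assert_allclose(Ainv, np.linalg.inv(A), atol=1e-12)

    def test_inverse_of_tabular_A_random_pedigree(self, rng):
        ped = random_pedigree(200, rng)
        A = tabular_A(ped)
        Ainv = build_A_inverse(ped).toarray()
        np.testing.assert_allclose(Ainv @ A, np.eye(200), atol=1e-8)

    def test_inverse_with_inbreeding(self, rng):
        # mating of full sibs produces inbred offspring; Henderson's rules
        # without the inbreeding correction would fail this check
        recs = [("A", "0", "0"), ("B", "0", "0"), ("C", "A", "B"),
                ("D", "A", "B"), ("E", "C", "D"), ("G", "E", "C")]
        ped = Pedigree.from_records(recs)
        F = inbreeding_coefficients(ped)
        assert F[ped.index["E"]] == pytest.approx(0.25)
        A = tabular_A(ped)
        np.testing.assert_allclose(np.diag(A) - 1.0, F, atol=1e-12)
        Ainv = build_A_inverse(ped).toarray()
        np.testing.assert_allclose(Ainv @ A, np.eye(ped.n), atol=1e-8)

    def test_single_parent_known(self):
        ped = Pedigree.from_records([("A", "0", "0"), ("C", "A", "0")])
        A = tabular_A(ped)
        Ainv = build_A_inverse(ped).toarray()
        np.testing.assert_allclose(Ainv @ A, np.eye(2), atol=1e-10)

    def test_at_most_nine_nonzeros_per_animal(self, rng):
        ped = random_pedigree(100, rng)
        Ainv = build_A_inverse(ped)
        # each animal contributes to at most a 3x3 block
        assert Ainv.nnz <= 9 * ped.n


class TestA22:
    def test_single_founder(self, trio):
        A22 = build_A22(trio, ["A"])
        np.testing.assert_allclose(A22, [[1.0]])

    def test_fullsib_offdiagonal(self):
        ped = Pedigree.from_records(
            [("A", "0", "0"), ("B", "0", "0"), ("C", "A", "B"), ("D", "A", "B")]
        )
        A22 = build_A22(ped, ["C", "D"])
        assert A22[0, 1] == pytest.approx(0.5)
        assert A22[0, 0] == pytest.approx(1.0)

    def test_matches_tabular_submatrix(self, rng):
        ped = random_pedigree(200, rng)
        genotyped = [ped.ids[i] for i in rng.choice(200, 50, replace=False)]
        A = tabular_A(ped)
        idx = [ped.index[a] for a in genotyped]
        np.testing.assert_allclose(
            build_A22(ped, genotyped), A[np.ix_(idx, idx)], atol=1e-12
        )

    def test_empty_set_errors(self, trio):
        with pytest.raises(ValueError):
            build_A22(trio, [])


class TestG:
    def test_hand_case_one_snp(self):
        panel = GenotypePanel(
            ["i1", "i2"], ["s"], np.array([[0.0], [2.0]]),
            np.array([1]), np.array([100]),
        )
        G = build_G(panel)  # p = 0.5, sum 2pq = 0.5, Z = [-1, 1]
        np.testing.assert_allclose(G, [[2, -2], [-2, 2]])

    def test_weight_scale_invariance_via_normalization(self, rng):
        panel = binomial_panel(20, 50, rng)
        w = SNPWeights(rng.uniform(0.5, 2.0, 50), 50.0).normalized()
        w2 = SNPWeights(2.0 * w.d, 50.0).normalized()
        np.testing.assert_allclose(
            build_G(panel, w), build_G(panel, w2), atol=1e-12
        )

    def test_allele_flip_invariance(self, rng):
        panel = binomial_panel(30, 40, rng)
        G1 = build_G(panel)
        flipped = GenotypePanel(
            list(panel.animal_ids), list(panel.snp_ids),
            2.0 - panel.gene_content, panel.chrom.copy(), panel.pos.copy(),
        )
        np.testing.assert_allclose(build_G(flipped), G1, atol=1e-10)

    def test_mean_diagonal_near_one_in_equilibrium(self):
        rng = np.random.default_rng(42)
        panel = binomial_panel(500, 1000, rng, maf_low=0.05)
        G = build_G(panel)
        assert abs(float(np.mean(np.diag(G))) - 1.0) < 0.1

    def test_monomorphic_panel_errors(self):
        panel = GenotypePanel(
            ["i1", "i2"], ["s"], np.array([[2.0], [2.0]]),
            np.array([1]), np.array([100]),
        )
        with pytest.raises(ValueError):
            build_G(panel)

    def test_trace_conserved_after_normalization(self, rng):
        d = rng.uniform(0, 5, 200) + 1e-6
        w = SNPWeights(d, 200.0).normalized()
        assert w.d.sum() == pytest.approx(200.0, rel=1e-10)


class TestBlend:
    def test_beta_zero_identity(self, rng):
        panel = binomial_panel(10, 100, rng)
        # external frequencies keep raw G nonsingular
        G = build_G(panel, p=np.full(100, 0.3))
        np.testing.assert_allclose(blend_G(G, np.eye(10), beta=0.0), G)

    def test_singular_G_fixed_by_blending(self, rng):
        panel = binomial_panel(10, 50, rng)
        g = panel.gene_content
        g[1] = g[0]  # duplicated animal rows
        panel = GenotypePanel(
            list(panel.animal_ids), list(panel.snp_ids), g,
            panel.chrom.copy(), panel.pos.copy(),
        )
        G = build_G(panel)  # observed-frequency centering: singular
        with pytest.raises(ValueError):
            blend_G(G, np.eye(10), beta=0.0)
        A22 = np.eye(10)
        Gs = blend_G(G, A22, beta=0.05)
        assert np.all(np.linalg.eigvalsh(Gs) > 0)

    def test_eigenvalue_floor(self, rng):
        panel = binomial_panel(50, 300, rng)
        G = build_G(panel)
        ped = random_pedigree(80, rng)
        A22 = build_A22(ped, [ped.ids[i] for i in range(50)])
        Gs = blend_G(G, A22, beta=0.05)
        assert np.min(np.linalg.eigvalsh(Gs)) >= 0.05 * np.min(
            np.linalg.eigvalsh(A22)
        ) - 1e-10


class TestHInverse:
    def test_empty_genotyped_equals_A_inverse(self, rng):
        ped = random_pedigree(100, rng)
        Ainv = build_A_inverse(ped)
        H = build_H_inverse(Ainv, None, None, np.array([], dtype=int))
        for _ in range(5):
            v = rng.standard_normal(100)
            np.testing.assert_allclose(H @ v, Ainv @ v, atol=1e-12)
        np.testing.assert_allclose(H.materialize(), Ainv.toarray())

    def test_G_equal_A22_reduces_to_A_inverse(self, rng):
        ped = random_pedigree(60, rng)
        genotyped = [ped.ids[i] for i in range(40, 60)]
        idx = np.array([ped.index[a] for a in genotyped])
        A22 = build_A22(ped, genotyped)
        Ainv = build_A_inverse(ped)
        H = build_H_inverse(Ainv, A22.copy(), A22, idx)
        np.testing.assert_allclose(H.materialize(), Ainv.toarray(), atol=1e-8)

    def test_materialized_matches_dense_H_oracle(self):
        # Dense oracle: build H itself from its partitioned definition
        # (pedigree animals conditioned on the genotyped block), invert it,
        # and compare with the sparse-plus-correction assembly.
        cfg = SimConfig(n_founders=30, n_generations=2, n_snps=300, seed=3)
        ds = simulate_dataset(cfg)
        ped = ds.pedigree
        panel = ds.panel.subset_animals(np.arange(min(30, ds.panel.n_animals)))
        idx = np.array([ped.index[a] for a in panel.animal_ids])
        A = tabular_A(ped)
        A22 = A[np.ix_(idx, idx)]
        Gs = blend_G(build_G(panel), A22, 0.05)
        Hinv = build_H_inverse(build_A_inverse(ped), Gs, A22, idx)
        # oracle H: A with the genotyped block replaced by
        # G* + conditional adjustment: H = A + P' (G* - A22) P structure
        rest = np.setdiff1d(np.arange(ped.n), idx)
        order = np.concatenate([rest, idx])
        Ao = A[np.ix_(order, order)]
        n1 = rest.size
        A11, A12, A22o = Ao[:n1, :n1], Ao[:n1, n1:], Ao[n1:, n1:]
        B = A12 @ np.linalg.inv(A22o)
        H22 = Gs
        H11 = A11 + B @ (H22 - A22o) @ B.T
        H12 = B @ H22
        Ho = np.block([[H11, H12], [H12.T, H22]])
        H_dense = np.linalg.inv(Ho)
        got = Hinv.materialize()[np.ix_(order, order)]
        np.testing.assert_allclose(got, H_dense, atol=1e-6)

    def test_duplicate_genotyped_rejected(self, rng):
        ped = random_pedigree(10, rng)
        with pytest.raises(ValueError, match="duplicate"):
            build_H_inverse(
                build_A_inverse(ped), np.eye(2), np.eye(2), np.array([3, 3])
            )

    def test_diagonal_matches_materialized(self, rng):
        ped = random_pedigree(50, rng)
        genotyped = [ped.ids[i] for i in range(30, 50)]
        idx = np.array([ped.index[a] for a in genotyped])
        A22 = build_A22(ped, genotyped)
        panel = binomial_panel(20, 100, rng)
        Gs = blend_G(build_G(panel), A22, 0.05)
        H = build_H_inverse(build_A_inverse(ped), Gs, A22, idx)
        np.testing.assert_allclose(H.diagonal(), np.diag(H.materialize()))


def test_lambda_scale_and_centering(rng):
    panel = binomial_panel(10, 5, rng)
    p = panel.freqs
    assert lambda_scale(p) == pytest.approx(1.0 / np.sum(2 * p * (1 - p)))
    Z = center_gene_content(panel)
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
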