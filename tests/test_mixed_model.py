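import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from sswas.io import Pedigree
from sswas.mixed_model import (
    ModelSpec,
    VarianceComponents,
    build_design,
    estimate_aireml,
    heritability,
    solve_mme,
)
from sswas.relationships import (
    blend_G,
    build_A22,
    build_A_inverse,
    build_G,
    build_H_inverse,
)
from sswas.simulate import SimConfig, simulate_dataset

from .conftest import random_pedigree


def _empty_H(ped):
    return build_H_inverse(build_A_inverse(ped), None, None, np.array([], dtype=int))


def _sim_H(ds):
    ped = ds.pedigree
    idx = np.array([ped.index[a] for a in ds.panel.animal_ids])
    A22 = build_A22(ped, ds.panel.animal_ids)
    Gs = blend_G(build_G(ds.panel), A22, 0.05)
    return build_H_inverse(build_A_inverse(ped), Gs, A22, idx), idx


class TestDesign:
    def test_one_factor_two_levels(self, trio):
        phenos = pd.DataFrame(
            {"animal_id": ["A", "B"], "y": [1.0, 2.0], "grp": ["u", "v"]}
        )
        y, X, Z = build_design(phenos, ModelSpec("y", ["grp"], []), trio)
        assert X.shape == (2, 2)  # intercept + one contrast column
        np.testing.assert_array_equal(X[:, 0], [1, 1])
        assert Z.shape == (2, 3)

    def test_unknown_animal_errors(self, trio):
        phenos = pd.DataFrame({"animal_id": ["Z"], "y": [1.0]})
        with pytest.raises(ValueError, match="absent"):
            build_design(phenos, ModelSpec("y", [], []), trio)

    def test_xtx_matches_crosstab_oracle(self, rng):
        ped = random_pedigree(50, rng, p_founder=1.0)
        levels = rng.choice(["a", "b", "c"], 50)
        phenos = pd.DataFrame(
            {"animal_id": ped.ids, "y": rng.standard_normal(50), "grp": levels}
        )
        _, X, _ = build_design(phenos, ModelSpec("y", ["grp"], []), ped)
        # oracle: cell counts from a cross-tabulation
        counts = pd.crosstab(levels, levels)
        xtx = X.T @ X
        assert xtx[0, 0] == 50
        for k, lv in enumerate(["b", "c"], start=1):
            assert xtx[k, k] == counts.loc[lv, lv]
        assert xtx[1, 2] == 0  # disjoint dummy columns

    def test_covariate_centered(self, rng):
        ped = random_pedigree(30, rng, p_founder=1.0)
        phenos = pd.DataFrame(
            {
                "animal_id": ped.ids,
                "y": rng.standard_normal(30),
                "age": rng.uniform(20, 80, 30),
            }
        )
        _, X, _ = build_design(phenos, ModelSpec("y", [], ["age"]), ped)
        assert abs(X[:, 1].sum()) < 1e-9

    def test_confounded_design_rejected(self, rng):
        ped = random_pedigree(20, rng, p_founder=1.0)
        phenos = pd.DataFrame(
            {
                "animal_id": ped.ids,
                "y": rng.standard_normal(20),
                "g1": ["a"] * 10 + ["b"] * 10,
                "g2": ["u"] * 10 + ["v"] * 10,  # perfectly aliased with g1
            }
        )
        with pytest.raises(ValueError, match="rank"):
            build_design(phenos, ModelSpec("y", ["g1", "g2"], []), ped)


class TestSolveMME:
    def _dense_solution(self, y, X, Z, Hinv_mat, k):
        Zd = Z.toarray()
        C = np.block(
            [[X.T @ X, X.T @ Zd], [Zd.T @ X, Zd.T @ Zd + k * Hinv_mat]]
        )
        rhs = np.concatenate([X.T @ y, Zd.T @ y])
        return np.linalg.solve(C, rhs)

    def test_pedigree_blup_matches_dense_oracle(self, rng):
        ped = random_pedigree(150, rng)
        phenos = pd.DataFrame(
            {
                "animal_id": [ped.ids[i] for i in range(50, 150)],
                "y": rng.standard_normal(100),
                "grp": rng.choice(["a", "b"], 100),
            }
        )
        y, X, Z = build_design(phenos, ModelSpec("y", ["grp"], []), ped)
        H = _empty_H(ped)
        vc = VarianceComponents(0.3, 0.7)
        sol = solve_mme(y, X, Z, H, vc)
        assert sol.converged
        dense = self._dense_solution(y, X, Z, H.materialize(), 0.7 / 0.3)
        np.testing.assert_allclose(
            np.concatenate([sol.b_hat, sol.a_hat]), dense, atol=1e-6
        )

    def test_single_step_matches_dense_oracle(self):
        ds = simulate_dataset(SimConfig(n_founders=40, n_generations=2, n_snps=200, seed=5))
        H, idx = _sim_H(ds)
        spec = ModelSpec("trait")
        y, X, Z = build_design(ds.phenotypes, spec, ds.pedigree)
        vc = VarianceComponents(0.3, 0.7)
        sol = solve_mme(y, X, Z, H, vc, genotyped_index=idx)
        Zd = Z.toarray()
        k = 0.7 / 0.3
        Hm = H.materialize()
        C = np.block([[X.T @ X, X.T @ Zd], [Zd.T @ X, Zd.T @ Zd + k * Hm]])
        dense = np.linalg.solve(C, np.concatenate([X.T @ y, Zd.T @ y]))
        got = np.concatenate([sol.b_hat, sol.a_hat])
        np.testing.assert_allclose(got, dense, atol=1e-8 * np.abs(dense).max())

    def test_zero_additive_variance_limit(self, rng):
        ped = random_pedigree(30, rng)
        phenos = pd.DataFrame(
            {"animal_id": ped.ids, "y": rng.standard_normal(30)}
        )
        y, X, Z = build_design(phenos, ModelSpec("y", [], []), ped)
        sol = solve_mme(y, X, Z, _empty_H(ped), VarianceComponents(0.0, 1.0))
        np.testing.assert_array_equal(sol.a_hat, 0.0)

    def test_intercept_shift_leaves_breeding_values(self, rng):
        ped = random_pedigree(80, rng)
        phenos = pd.DataFrame(
            {"animal_id": ped.ids, "y": rng.standard_normal(80)}
        )
        spec = ModelSpec("y", [], [])
        y, X, Z = build_design(phenos, spec, ped)
        vc = VarianceComponents(0.4, 0.6)
        H = _empty_H(ped)
        s1 = solve_mme(y, X, Z, H, vc)
        s2 = solve_mme(y + 5.0, X, Z, H, vc)
        assert s2.b_hat[0] - s1.b_hat[0] == pytest.approx(5.0, abs=1e-7)
        np.testing.assert_allclose(s2.a_hat, s1.a_hat, atol=1e-8)


class TestAIREML:
    def test_scale_equivariance(self):
        ds = simulate_dataset(SimConfig(seed=11))
        y, X, Z = build_design(ds.phenotypes, ModelSpec("trait"), ds.pedigree)
        H, _ = _sim_H(ds)
        vc1 = estimate_aireml(y, X, Z, H)
        vc2 = estimate_aireml(2.0 * y, X, Z, H)
        assert vc2.sigma2_a == pytest.approx(4 * vc1.sigma2_a, rel=1e-4)
        assert vc2.sigma2_e == pytest.approx(4 * vc1.sigma2_e, rel=1e-4)
        assert vc2.h2 == pytest.approx(vc1.h2, abs=1e-6)

    def test_pure_noise_estimates_near_zero(self):
        # h2 = 0: phenotype is noise; ~2000 records
        cfg = SimConfig(
            n_founders=500, n_generations=2, offspring_per_mating=4,
            h2_true=0.0, n_qtl=0, qtl_var_fracs=(), n_snps=400, seed=13,
        )
        ds = simulate_dataset(cfg)
        y, X, Z = build_design(ds.phenotypes, ModelSpec("trait"), ds.pedigree)
        vc = estimate_aireml(y, X, Z, _empty_H(ds.pedigree))
        assert vc.h2 <= 0.05

    def test_balanced_halfsib_matches_anova_oracle(self):
        # 80 sires x 15 progeny, unknown dams: sire variance = sigma2_a/4
        rng = np.random.default_rng(17)
        n_sires, n_prog = 80, 15
        s2a, s2e = 0.4, 0.6
        recs = [(f"S{i}", "0", "0") for i in range(n_sires)]
        ids, sire_of = [], {}
        for i in range(n_sires):
            for j in range(n_prog):
                a = f"P{i}_{j}"
                recs.append((a, f"S{i}", "0"))
                ids.append(a)
                sire_of[a] = i
        ped = Pedigree.from_records(recs)
        u_s = rng.standard_normal(n_sires) * np.sqrt(s2a / 4)
        yv = np.array(
            [u_s[sire_of[a]] for a in ids]
        ) + rng.standard_normal(len(ids)) * np.sqrt(3 * s2a / 4 + s2e)
        phenos = pd.DataFrame({"animal_id": ids, "y": yv})
        y, X, Z = build_design(phenos, ModelSpec("y", [], []), ped)
        vc = estimate_aireml(y, X, Z, _empty_H(ped))
        # ANOVA oracle on the same data
        ym = yv.reshape(n_sires, n_prog)
        msb = n_prog * np.var(ym.mean(axis=1), ddof=1)
        msw = np.mean(np.var(ym, axis=1, ddof=1))
        s2s_anova = (msb - msw) / n_prog
        assert vc.sigma2_a == pytest.approx(4 * s2s_anova, abs=0.15)

    def test_se_h2_finite_positive(self):
        ds = simulate_dataset(SimConfig(seed=19))
        y, X, Z = build_design(ds.phenotypes, ModelSpec("trait"), ds.pedigree)
        H, _ = _sim_H(ds)
        vc = estimate_aireml(y, X, Z, H)
        assert np.isfinite(vc.se_h2) and vc.se_h2 > 0


class TestHeritability:
    @pytest.mark.parametrize(
        "s2a,s2e,expect",
        [(669.04, 2128.1, 0.24), (32.47, 113.04, 0.22), (8.95, 20.31, 0.31),
         (1.19, 2.15, 0.36), (1.0272, 2.9209, 0.26)],
    )
    def test_reported_carcass_trait_components(self, s2a, s2e, expect):
        assert round(heritability(s2a, s2e), 2) == expect

    def test_zero_additive(self):
        assert heritability(0.0, 1.3) == 0.0

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)


def test_gebv_accuracy_single_step_beats_pedigree_only():
    """cor(a_hat, a_true) among genotyped animals is higher under H than
    under A, paired across seeds."""
    wins = 0
    diffs = []
    for seed in range(10):
        cfg = SimConfig(n_founders=120, n_generations=3, n_snps=600,
                        prop_genotyped=0.4, seed=100 + seed)
        ds = simulate_dataset(cfg)
        y, X, Z = build_design(ds.phenotypes, ModelSpec("trait"), ds.pedigree)
        vc = VarianceComponents(0.3, 0.7)
        Hss, idx = _sim_H(ds)
        Hped = _empty_H(ds.pedigree)
        a_true = ds.truth.true_breeding_values[idx]
        acc_h = np.corrcoef(
            solve_mme(y, X, Z, Hss, vc).a_hat[idx], a_true
        )[0, 1]
        acc_a = np.corrcoef(
            solve_mme(y, X, Z, Hped, vc).a_hat[idx], a_true
        )[0, 1]
        diffs.append(acc_h - acc_a)
        wins += acc_h > acc_a
    assert np.mean(diffs) > 0
    assert wins >= 8
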