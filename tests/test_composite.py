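"""Effect-matrix PCA, loading rescaling, and composite summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compmr import (
    EffectMatrix,
    PhenoCorr,
    SimConfig,
    build_effect_matrix,
    composite_sumstats,
    composite_variance,
    estimate_pheno_corr,
    export_ld_panel,
    fit_linear_combination,
    fit_pca,
    rescale_loadings,
    run_gwas,
    simulate_cohort,
)
from compmr.simcohort import normalized_traits
from compmr.workflow import per_trait_gwas

from conftest import make_sumstats


def random_corr(rng, t):
    A = rng.standard_normal((t, t + 3))
    K = np.corrcoef(A)
    return K


def toy_effect_matrix(B):
    B = np.asarray(B, float)
    M, T = B.shape
    return EffectMatrix(
        B,
        np.full((M, T), 0.01),
        np.zeros((M, T), bool),
        tuple(f"rs{i}" for i in range(M)),
        tuple(f"t{j}" for j in range(T)),
    )


class TestPhenoCorr:
    def test_rejects_asymmetric_and_non_unit_diagonal(self):
        with pytest.raises(ValueError):
            PhenoCorr(np.array([[1.0, 0.5], [0.2, 1.0]]), ("a", "b"))
        with pytest.raises(ValueError):
            PhenoCorr(np.array([[2.0, 0.0], [0.0, 1.0]]), ("a", "b"))

    def test_rejects_indefinite(self):
        K = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            PhenoCorr(K, ("a", "b", "c"))


class TestFitPCA:
    def test_rank_one_matrix_single_component(self):
        rng = np.random.default_rng(0)
        direction = rng.standard_normal(5)
        B = np.outer(rng.standard_normal(30), direction)
        load = fit_pca(toy_effect_matrix(B), n_components=3)
        assert load.explained_variance[0] == pytest.approx(1.0)
        r = np.corrcoef(load.w[:, 0], direction)[0, 1]
        assert abs(r) > 1 - 1e-10

    def test_weights_unit_norm_and_orthogonal(self):
        rng = np.random.default_rng(1)
        load = fit_pca(toy_effect_matrix(rng.standard_normal((40, 6))), 4)
        np.testing.assert_allclose(load.w.T @ load.w, np.eye(4), atol=1e-10)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(2)
        load = fit_pca(toy_effect_matrix(rng.standard_normal((40, 6))), 4)
        for i in range(4):
            assert load.w[np.abs(load.w[:, i]).argmax(), i] > 0

    def test_planted_two_factor_recovery(self):
        rng = np.random.default_rng(3)
        t = 8
        q, _ = np.linalg.qr(rng.standard_normal((t, 2)))
        scores = rng.standard_normal((200, 2)) * [2.0, 1.0]
        B = scores @ q.T + 0.02 * rng.standard_normal((200, t))
        load = fit_pca(toy_effect_matrix(B), 2)
        for i in range(2):
            r = np.corrcoef(load.w[:, i], q[:, i])[0, 1]
            assert abs(r) > 0.95

    def test_fewer_snps_than_traits_warns(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="fewer SNPs"):
            fit_pca(toy_effect_matrix(rng.standard_normal((3, 6))), 2)


class TestRescaleLoadings:
    def test_identity_corr_keeps_unit_weights(self):
        rng = np.random.default_rng(5)
        load = fit_pca(toy_effect_matrix(rng.standard_normal((30, 4))), 2)
        K = PhenoCorr(np.eye(4), load.trait_names)
        out = rescale_loadings(load, K)
        np.testing.assert_allclose(out.v, out.w, atol=1e-12)

    def test_two_trait_hand_arithmetic(self):
        # w = (1/sqrt2, 1/sqrt2), K off-diagonal 0.5: w'Kw = 1.5, v = w/sqrt(1.5)
        load = fit_pca(toy_effect_matrix(np.outer(np.ones(10), [1.0, 1.0])), 1)
        K = PhenoCorr(np.array([[1.0, 0.5], [0.5, 1.0]]), ("t0", "t1"))
        out = rescale_loadings(load, K)
        np.testing.assert_allclose(out.w[:, 0], [1 / np.sqrt(2)] * 2, atol=1e-12)
        np.testing.assert_allclose(out.v[:, 0], [1 / np.sqrt(3)] * 2, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rescaled_composite_variance_is_one(self, seed):
        rng = np.random.default_rng(seed)
        t = int(rng.integers(2, 8))
        K = PhenoCorr(random_corr(rng, t), tuple(f"t{j}" for j in range(t)))
        load = fit_pca(toy_effect_matrix(rng.standard_normal((3 * t, t))), min(3, t))
        out = rescale_loadings(load, K)
        for i in range(out.v.shape[1]):
            assert composite_variance(out.v[:, i], K) == pytest.approx(1.0, abs=1e-10)


class TestCompositeVariance:
    def test_indicator_weight_gives_one(self):
        K = PhenoCorr(np.array([[1.0, 0.3], [0.3, 1.0]]), ("a", "b"))
        assert composite_variance([1.0, 0.0], K) == pytest.approx(1.0)

    def test_hand_value(self):
        K = PhenoCorr(np.array([[1.0, 0.5], [0.5, 1.0]]), ("a", "b"))
        assert composite_variance([1.0, 1.0], K) == pytest.approx(3.0)

    def test_matches_empirical_composite_variance(self, small_cohort):
        K = estimate_pheno_corr(small_cohort)
        rng = np.random.default_rng(6)
        w = rng.standard_normal(K.matrix.shape[0])
        Y = normalized_traits(small_cohort).to_numpy()
        empirical = (Y @ w).var(ddof=1)
        assert composite_variance(w, K) == pytest.approx(empirical, rel=0.05)


@pytest.fixture(scope="module")
def gwas_inputs(small_cohort):
    ss = per_trait_gwas(small_cohort, "combined")
    return ss, export_ld_panel(small_cohort)


@pytest.fixture(scope="module")
def setup(small_cohort):
    ss = per_trait_gwas(small_cohort, "combined")
    K = estimate_pheno_corr(small_cohort)
    return small_cohort, ss, K


class TestBuildEffectMatrix:
    def test_missing_entries_zeroed_and_masked(self):
        a = make_sumstats(n=5, beta=[0.5] * 5, se=[0.02] * 5, trait="a")
        # trait b lacks rs3 entirely
        b = make_sumstats(n=5, beta=[0.4] * 5, se=[0.02] * 5, trait="b")
        b.table = b.table[b.table["variant"] != "rs3"].reset_index(drop=True)
        variants = a.table[["variant", "chrom", "pos"]]
        from compmr.sumstats import LDPanel

        panel = LDPanel.from_pairs(pd.DataFrame(columns=["id_a", "id_b", "r2"]), variants)
        E = build_effect_matrix([a, b], panel)
        i = E.snp_ids.index("rs3")
        j = E.trait_names.index("b")
        assert E.effects[i, j] == 0.0
        assert E.missing[i, j]
        assert not E.missing[i, E.trait_names.index("a")]

    def test_shared_snp_set_has_no_mask(self, gwas_inputs):
        ss, panel = gwas_inputs
        E = build_effect_matrix(ss, panel)
        assert not E.missing.any()
        assert E.effects.shape[1] == 14

    def test_row_count_equals_brute_force_pruned_union(self, gwas_inputs):
        ss, panel = gwas_inputs
        E = build_effect_matrix(ss, panel)
        from compmr.sumstats import multi_trait_priority, prune

        pmat = pd.concat(
            {s.trait: s.indexed()["pval"] for s in ss}, axis=1
        ).fillna(1.0)
        expected = prune(list(multi_trait_priority(pmat).index), panel)
        assert set(E.snp_ids) == set(expected)

    def test_no_significant_snps_is_error(self):
        a = make_sumstats(n=4, beta=[0.001] * 4, se=[0.02] * 4, trait="a")
        b = make_sumstats(n=4, beta=[0.001] * 4, se=[0.02] * 4, trait="b")
        variants = a.table[["variant", "chrom", "pos"]]
        from compmr.sumstats import LDPanel

        panel = LDPanel.from_pairs(pd.DataFrame(columns=["id_a", "id_b", "r2"]), variants)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="significant"):
                build_effect_matrix([a, b], panel)


class TestCompositeSumstats:
    def test_indicator_loading_returns_trait_statistics(self, setup):
        cohort, ss, K = setup
        T = len(ss)
        w = np.zeros((T, 1))
        t_idx = 3
        w[t_idx, 0] = 1.0
        from compmr.composite import Loadings

        load = Loadings(w, np.array([1.0]), tuple(s.trait for s in ss), ("PC1",))
        Kid = PhenoCorr(np.eye(T), load.trait_names)
        load = rescale_loadings(load, Kid)
        out = composite_sumstats(ss, load, Kid, component=0)
        np.testing.assert_allclose(out.table["beta"], ss[t_idx].table["beta"], atol=1e-12)
        np.testing.assert_allclose(out.table["se"], ss[t_idx].table["se"], atol=1e-12)

    def test_identity_corr_reduces_to_diagonal_se(self, setup):
        cohort, ss, _ = setup
        T = len(ss)
        rng = np.random.default_rng(8)
        from compmr.composite import Loadings

        w = rng.standard_normal((T, 1))
        w /= np.linalg.norm(w)
        load = Loadings(w, np.array([1.0]), tuple(s.trait for s in ss), ("PC1",))
        Kid = PhenoCorr(np.eye(T), load.trait_names)
        load = rescale_loadings(load, Kid)
        out = composite_sumstats(ss, load, Kid, component=0)
        S = np.column_stack([s.table["se"] for s in ss])
        expected = np.sqrt((S**2) @ (load.v[:, 0] ** 2))
        np.testing.assert_allclose(out.table["se"], expected, rtol=1e-10)

    def test_matches_individual_level_composite_gwas(self, setup):
        # summary-level combination == direct GWAS on the individual-level
        # composite phenotype, exactly for betas, closely for SEs
        cohort, ss, K = setup
        load = rescale_loadings(fit_pca_from(ss), K)
        out = composite_sumstats(ss, load, K, component=0)
        v = load.v[:, 0]
        yC = normalized_traits(cohort).to_numpy() @ v
        G = cohort.genotypes.astype(float)
        gc = G - G.mean(axis=0)
        yc = yC - yC.mean()
        ssg = (gc**2).sum(axis=0)
        beta_direct = gc.T @ yc / ssg
        se_direct = np.sqrt(
            np.maximum(yc @ yc - beta_direct**2 * ssg, 0) / (len(yc) - 2) / ssg
        )
        np.testing.assert_allclose(out.table["beta"], beta_direct, atol=1e-10)
        assert np.corrcoef(out.table["se"], se_direct)[0, 1] > 0.99

    def test_permutation_equivariance(self, setup):
        cohort, ss, K = setup
        load = rescale_loadings(fit_pca_from(ss), K)
        out = composite_sumstats(ss, load, K, component=1)
        perm = np.random.default_rng(9).permutation(len(ss))
        ss_p = [ss[i] for i in perm]
        from compmr.composite import Loadings

        load_p = Loadings(
            load.w[perm],
            load.explained_variance,
            tuple(load.trait_names[i] for i in perm),
            load.component_labels,
            v=load.v[perm],
        )
        K_p = PhenoCorr(K.matrix[np.ix_(perm, perm)], load_p.trait_names)
        out_p = composite_sumstats(ss_p, load_p, K_p, component=1)
        np.testing.assert_allclose(out.table["beta"], out_p.table["beta"], atol=1e-12)
        np.testing.assert_allclose(out.table["se"], out_p.table["se"], atol=1e-12)


def fit_pca_from(ss):
    B = np.column_stack([s.table["beta"] for s in ss])
    S = np.column_stack([s.table["se"] for s in ss])
    E = EffectMatrix(
        B,
        S,
        np.zeros(B.shape, bool),
        tuple(ss[0].table["variant"]),
        tuple(s.trait for s in ss),
    )
    return fit_pca(E, 2)


class TestEstimatePhenoCorr:
    def test_duplicated_trait_perfect_correlation(self, small_cohort):
        import copy

        cohort = copy.copy(small_cohort)
        cohort.traits = small_cohort.traits.copy()
        cohort.traits["dup"] = cohort.traits["bmi"]
        K = estimate_pheno_corr(cohort)
        i = K.trait_names.index("bmi")
        j = K.trait_names.index("dup")
        assert K.matrix[i, j] == pytest.approx(1.0, abs=1e-6)

    def test_independent_traits_near_zero(self):
        cfg = SimConfig(
            n_individuals=4000,
            n_snps=20,
            n_latent_factors=2,
            factor_heritabilities=[0.0, 0.0],
            trait_loading_matrix=np.zeros((3, 2)),
            trait_names=("a", "b", "c"),
            sex_amplification=[1.0, 1.0],
            outcome_specs=[],
            seed=10,
        )
        cohort = simulate_cohort(cfg)
        K = estimate_pheno_corr(cohort)
        off = K.matrix[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(4000)

    def test_matches_analytic_correlation(self):
        L = np.array([[0.7, 0.0], [0.0, 0.7], [0.5, 0.5]])
        cfg = SimConfig(
            n_individuals=12_000,
            n_snps=30,
            n_latent_factors=2,
            trait_loading_matrix=L,
            trait_names=("a", "b", "c"),
            sex_amplification=[1.0, 1.0],
            outcome_specs=[],
            seed=11,
        )
        cohort = simulate_cohort(cfg)
        K = estimate_pheno_corr(cohort)
        cov = L @ L.T + np.diag(1 - (L**2).sum(axis=1))
        d = np.sqrt(np.diag(cov))
        expected = cov / np.outer(d, d)
        assert np.abs(K.matrix - expected).max() < 0.04

    def test_too_few_individuals(self, small_cohort):
        import copy

        cohort = copy.copy(small_cohort)
        cohort.traits = small_cohort.traits.iloc[:2]
        with pytest.raises(ValueError):
            estimate_pheno_corr(cohort)


class TestFitLinearCombination:
    def test_target_equals_basis_trait(self, small_cohort):
        w, r2 = fit_linear_combination(small_cohort, "bmi", ["bmi", "height"])
        np.testing.assert_allclose(w, [1.0, 0.0], atol=1e-10)
        assert r2 == pytest.approx(1.0)

    def test_recovers_generative_weights(self, small_cohort):
        import copy

        cohort = copy.copy(small_cohort)
        cohort.traits = small_cohort.traits.copy()
        rng = np.random.default_rng(12)
        target = (
            0.6 * cohort.traits["height"]
            + 0.8 * cohort.traits["weight"]
            + rng.normal(0, 0.5, len(cohort.traits))
        )
        cohort.traits["dxa"] = target
        w, r2 = fit_linear_combination(cohort, "dxa", ["height", "weight"])
        assert w[0] == pytest.approx(0.6, abs=0.1)
        assert w[1] == pytest.approx(0.8, abs=0.1)
        var_signal = np.var(0.6 * cohort.traits["height"] + 0.8 * cohort.traits["weight"])
        assert r2 == pytest.approx(var_signal / (var_signal + 0.25), abs=0.05)

    def test_independent_target_r2_near_zero(self, small_cohort):
        import copy

        cohort = copy.copy(small_cohort)
        cohort.traits = small_cohort.traits.copy()
        cohort.traits["noise"] = np.random.default_rng(13).standard_normal(
            len(cohort.traits)
        )
        _, r2 = fit_linear_combination(cohort, "noise", ["height", "weight"])
        assert r2 < 0.01

    def test_collinear_basis_warns(self, small_cohort):
        import copy

        cohort = copy.copy(small_cohort)
        cohort.traits = small_cohort.traits.copy()
        cohort.traits["bmi2"] = cohort.traits["bmi"]
        with pytest.warns(UserWarning, match="collinear"):
            fit_linear_combination(cohort, "height", ["bmi", "bmi2"])
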