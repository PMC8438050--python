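"""Simulation studies validating the pipeline's statistical properties.

Each function sets up a fully specified synthetic study — sample sizes,
genetic architectures, replicate counts are fixed design choices
documented in the methods note — runs the relevant part of the pipeline
from scratch, and returns the measured quantities. The test suite
asserts on these numbers; the reproduction script reports them.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .composite import (
    EffectMatrix,
    build_effect_matrix,
    composite_sumstats,
    estimate_pheno_corr,
    fit_pca,
    rescale_loadings,
)
from .mr import cross_sex_meta, ivw, remove_outliers, select_ivs, theoretical_bias
from .predict import auc, delong_test, single_trait_predictor
from .simcohort import (
    OutcomeSpec,
    SimConfig,
    export_ld_panel,
    normalized_traits,
    run_gwas,
    simulate_cohort,
    simulate_iv_set,
)
from .workflow import train_component_predictor


def _seeds(seed: int, label: int, n: int) -> np.ndarray:
    """Independent child seeds below 2**31, reproducible from (seed, label)."""
    ss = np.random.SeedSequence([int(seed), label])
    return ss.generate_state(n) % (2**31 - 1)


def bias_equal_weights_pct() -> float:
    """Cross-sex meta bias (percent) for 1.37-fold effects, equal arm weights."""
    return 100.0 * theoretical_bias(1.37, 1.0)


def bias_downweighted_pct() -> float:
    """Cross-sex meta bias (percent) for 2.2-fold effects, 6.8-fold variance."""
    return 100.0 * theoretical_bias(2.2, 6.8)


def composite_oracle_study(seed: int, n: int = 5000, m: int = 2000) -> dict:
    """Summary-level composite GWAS vs the individual-level oracle.

    Simulates one cohort, combines the per-trait GWAS into a composite
    using the rescaled leading component, and compares with a direct
    GWAS on the individual-level composite phenotype built from the same
    normalized traits. Betas should agree to numerical precision; the
    correlation-aware SEs should track the direct SEs closely.
    """
    cfg = SimConfig(
        n_individuals=n,
        n_snps=m,
        seed=int(_seeds(seed, 3, 1)[0]),
        factor_heritabilities=[0.4, 0.3, 0.2, 0.2],
    )
    cohort = simulate_cohort(cfg)
    ss = [run_gwas(cohort, "combined", t) for t in cfg.trait_names]
    K = estimate_pheno_corr(cohort)
    B = np.column_stack([s.table["beta"] for s in ss])
    S = np.column_stack([s.table["se"] for s in ss])
    E = EffectMatrix(
        B,
        S,
        np.zeros(B.shape, bool),
        tuple(cohort.variants["variant"]),
        tuple(cfg.trait_names),
    )
    loadings = rescale_loadings(fit_pca(E, 2), K)
    out = composite_sumstats(ss, loadings, K, component=0)

    v = loadings.v[:, 0]
    y = normalized_traits(cohort).to_numpy() @ v
    G = cohort.genotypes.astype(float)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ssg = (gc**2).sum(axis=0)
    beta_direct = gc.T @ yc / ssg
    se_direct = np.sqrt(
        np.maximum(yc @ yc - beta_direct**2 * ssg, 0.0) / (len(yc) - 2) / ssg
    )
    return {
        "max_abs_beta_diff": float(np.abs(out.table["beta"].to_numpy() - beta_direct).max()),
        "se_correlation": float(np.corrcoef(out.table["se"], se_direct)[0, 1]),
        "n": n,
    }


def rescaling_identity_study(seed: int, n_draws: int = 1000) -> dict:
    """Max deviation of v'Kv from 1 over random weight/correlation draws."""
    rng = np.random.default_rng(int(_seeds(seed, 4, 1)[0]))
    worst = 0.0
    for _ in range(n_draws):
        t = int(rng.integers(2, 15))
        K = np.corrcoef(rng.standard_normal((t, t + 4)))
        w = rng.standard_normal(t)
        q = float(w @ K @ w)
        if q <= 1e-12:
            continue
        v = w / np.sqrt(q)
        worst = max(worst, abs(float(v @ K @ v) - 1.0))
    return {"max_abs_deviation": worst, "n": n_draws}


def factor_recovery_study(seed: int, n: int = 40_000, m: int = 150) -> dict:
    """Uncentered PCA recovery of four planted orthogonal genetic factors.

    The effect matrix is built through the full selection pipeline
    (per-trait significance, priority ordering, LD pruning); recovered
    loadings are matched against the generating trait-factor columns.
    """
    cfg = SimConfig(
        n_individuals=n,
        n_snps=m,
        seed=int(_seeds(seed, 5, 1)[0]),
        factor_heritabilities=[0.9, 0.8, 0.7, 0.6],
        causal_snps_per_factor=15,
        sex_amplification=[1.0] * 4,
    )
    cohort = simulate_cohort(cfg)
    ss = [run_gwas(cohort, "combined", t) for t in cfg.trait_names]
    panel = export_ld_panel(cohort)
    E = build_effect_matrix(ss, panel)
    loadings = fit_pca(E, 4)
    L = cfg.trait_loading_matrix
    corr = np.abs(np.corrcoef(np.hstack([loadings.w, L]), rowvar=False)[:4, 4:])
    matches = corr.argmax(axis=1)
    return {
        "cumulative_explained_pct": 100.0 * float(loadings.explained_variance.sum()),
        "min_abs_match_corr": float(corr.max(axis=1).min()),
        "one_to_one": bool(sorted(matches) == [0, 1, 2, 3]),
        "n": n,
    }


def mr_calibration_study(seed: int, n_rep: int = 500, n_iv: int = 50) -> dict:
    """Coverage and type-I error of IVW under valid two-sample instruments."""
    rng = np.random.default_rng(int(_seeds(seed, 6, 1)[0]))
    alpha_true = 0.2
    covered = rejected = 0
    for _ in range(n_rep):
        est = ivw(simulate_iv_set(n_iv, alpha_true, rng))
        covered += est.beta - 1.96 * est.se <= alpha_true <= est.beta + 1.96 * est.se
        est0 = ivw(simulate_iv_set(n_iv, 0.0, rng))
        rejected += est0.pval < 0.05
    return {
        "coverage": covered / n_rep,
        "type_i_error": rejected / n_rep,
        "n": n_rep,
    }


def overlap_bias_study(seed: int, n_rep: int = 300) -> dict:
    """One-sample vs cross-sex IVW under a confounder and a null causal effect.

    The exposure trait and a continuous outcome share a confounder, and
    the true causal effect is zero. Instruments are selected in the male
    exposure GWAS; the outcome effects come either from the same male
    sample (full overlap, correlated errors) or from the female sample
    (disjoint, the cross-sex arm). Reports the Monte-Carlo z of each
    mean estimate against zero.
    """
    same, cross = [], []
    for s in _seeds(seed, 7, n_rep):
        cfg = SimConfig(
            n_individuals=3000,
            n_snps=80,
            n_latent_factors=1,
            factor_heritabilities=[0.6],
            causal_snps_per_factor=30,
            trait_loading_matrix=np.array([[0.8]]),
            trait_names=("exposure_trait",),
            sex_amplification=[1.0],
            outcome_specs=[OutcomeSpec("health", "continuous", [0.0])],
            confounder_strength=0.5,
            seed=int(s),
        )
        cohort = simulate_cohort(cfg)
        exp_m = run_gwas(cohort, "male", "exposure_trait")
        out_m = run_gwas(cohort, "male", "health")
        out_f = run_gwas(cohort, "female", "health")
        ivs_same = select_ivs(exp_m, out_m)
        ivs_cross = select_ivs(exp_m, out_f)
        if len(ivs_same) < 3 or len(ivs_cross) < 3:
            continue
        same.append(ivw(ivs_same).beta)
        cross.append(ivw(ivs_cross).beta)
    same = np.asarray(same)
    cross = np.asarray(cross)

    def mc_z(x):
        return float(x.mean() / (x.std(ddof=1) / np.sqrt(len(x))))

    return {
        "same_sex_mean": float(same.mean()),
        "same_sex_z": mc_z(same),
        "cross_sex_mean": float(cross.mean()),
        "cross_sex_z": mc_z(cross),
        "n": len(same),
    }


def outlier_removal_study(seed: int, n_rep: int = 100) -> dict:
    """Detection of a planted pleiotropic instrument by iterative Q filtering."""
    rng = np.random.default_rng(int(_seeds(seed, 8, 1)[0]))
    alpha_true = 0.2
    first = exact = clean = 0
    for _ in range(n_rep):
        ivs = simulate_iv_set(30, alpha_true, rng, n_outliers=1)
        resid = np.abs(ivs.table["beta_out"] - alpha_true * ivs.table["beta_exp"])
        planted = ivs.table["id"].iloc[int(np.argmax(resid))]
        _, removed, _ = remove_outliers(ivs)
        first += len(removed) > 0 and removed[0] == planted
        exact += removed == (planted,)
        ivs0 = simulate_iv_set(30, alpha_true, rng)
        _, removed0, _ = remove_outliers(ivs0)
        clean += len(removed0) == 0
    return {
        "planted_first_removed_rate": first / n_rep,
        "planted_exactly_removed_rate": exact / n_rep,
        "clean_no_removal_rate": clean / n_rep,
        "n": n_rep,
    }


def prediction_additivity_study(
    seed: int, n_rep: int = 50, n_train: int = 16_000, n_holdout: int = 4000
) -> dict:
    """Multi-component predictor vs single-trait predictors, in and out of sample.

    The disease is caused by two independent latent factors. Each
    replicate runs the full pipeline — GWAS, effect-matrix PCA,
    per-component cross-sex MR, inverse-variance-weighted combination —
    and scores the trained predictor against the single trait most
    loaded on each causal factor, with DeLong significance.
    """
    win_in = win_out = 0
    aucs = {"components": [], "trait_1": [], "trait_2": []}
    for s in _seeds(seed, 9, n_rep):
        cfg = SimConfig(
            n_individuals=n_train,
            n_snps=120,
            factor_heritabilities=[0.8, 0.8, 0.5, 0.5],
            causal_snps_per_factor=10,
            sex_amplification=[1.0] * 4,
            outcome_specs=[
                OutcomeSpec("disease", "binary", [0.7, 0.7, 0.0, 0.0], prevalence=0.25)
            ],
            seed=int(s),
        )
        train = simulate_cohort(cfg)
        holdout = simulate_cohort(
            dataclasses.replace(cfg, n_individuals=n_holdout, seed=int(s) + 500_000)
        )
        model = train_component_predictor(train, "disease")
        pred = model.predictor

        L = cfg.trait_loading_matrix
        traits = list(cfg.trait_names)
        t1 = traits[int(np.argmax(np.abs(L[:, 0])))]
        t2 = traits[int(np.argmax(np.abs(L[:, 1])))]

        ok = {}
        for tag, cohort in (("in", train), ("out", holdout)):
            y = cohort.outcomes["disease"].to_numpy()
            d = pred.score(cohort.traits)
            all_beat = True
            for key, tr in (("trait_1", t1), ("trait_2", t2)):
                single = single_trait_predictor(
                    tr, 1.0, 1.0, pred.train_means, pred.train_sds, pred.trait_names
                )
                a_comp, a_single, p = delong_test(d, single.score(cohort.traits), y)
                all_beat &= (a_comp > a_single) and (p < 0.05)
                if tag == "out":
                    aucs[key].append(a_single)
            if tag == "out":
                aucs["components"].append(auc(d, y))
            ok[tag] = all_beat
        win_in += ok["in"]
        win_out += ok["out"]
    return {
        "win_rate_in_sample": win_in / n_rep,
        "win_rate_out_of_sample": win_out / n_rep,
        "mean_auc_components": float(np.mean(aucs["components"])),
        "mean_auc_trait_1": float(np.mean(aucs["trait_1"])),
        "mean_auc_trait_2": float(np.mean(aucs["trait_2"])),
        "n": n_rep,
    }
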