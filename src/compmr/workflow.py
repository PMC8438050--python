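"""End-to-end orchestration: cohort -> composites -> MR -> predictor.

Thin glue over the six core modules, mirroring how the pieces are meant
to be chained on real summary statistics: combined-sex GWAS feeds the
effect-matrix PCA, per-sex GWAS feeds the composite summary statistics,
each component's causal effect on an outcome is estimated by cross-sex
IVW MR, and the per-component effects become an inverse-variance-
weighted risk predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composite import (
    Loadings,
    PhenoCorr,
    build_effect_matrix,
    composite_sumstats,
    estimate_pheno_corr,
    fit_pca,
    rescale_loadings,
)
from .mr import MREstimate, cross_sex_mr
from .predict import Predictor
from .simcohort import Cohort, export_ld_panel, run_gwas
from .sumstats import GWS, LDPanel, SumStats, standardize_binary


def per_trait_gwas(cohort: Cohort, sex_group: str) -> list[SumStats]:
    """GWAS of every trait in one sex group."""
    return [run_gwas(cohort, sex_group, t) for t in cohort.traits.columns]


def outcome_gwas(cohort: Cohort, sex_group: str, outcome: str) -> SumStats:
    """Outcome GWAS on the SD scale (binary outcomes standardized by sqrt(p(1-p)))."""
    ss = run_gwas(cohort, sex_group, outcome)
    if ss.scale == "raw-binary":
        prev = float(cohort.outcomes.loc[cohort.mask(sex_group), outcome].mean())
        ss = standardize_binary(ss, prev * (1.0 - prev))
    return ss


@dataclass
class TrainedModel:
    """Fitted composite model plus the per-component causal estimates."""

    predictor: Predictor
    loadings: Loadings
    pheno_corr: PhenoCorr
    component_estimates: dict[str, MREstimate]
    ld_panel: LDPanel


def train_component_predictor(
    train: Cohort,
    outcome: str,
    n_components: int = 4,
    gws: float = GWS,
    **mr_kwargs,
) -> TrainedModel:
    """Fit the full pipeline on a training cohort.

    Combined-sex per-trait GWAS builds the SNP x trait effect matrix;
    its uncentered PCA gives the component loadings, rescaled against
    the phenotypic correlation so each composite has unit variance.
    Per-sex composite summary statistics then drive cross-sex MR of
    every component on the outcome, and the meta-analyzed effects
    (gamma_i, sigma_i) define the risk predictor. A component whose MR
    is skipped for lack of instruments enters with zero weight (gamma 0,
    huge sigma) rather than being silently dropped.
    """
    ss_comb = per_trait_gwas(train, "combined")
    panel = export_ld_panel(train)
    K = estimate_pheno_corr(train)
    E = build_effect_matrix(ss_comb, panel, gws=gws)
    loadings = rescale_loadings(fit_pca(E, n_components), K)

    ss_m = per_trait_gwas(train, "male")
    ss_f = per_trait_gwas(train, "female")
    out_m = outcome_gwas(train, "male", outcome)
    out_f = outcome_gwas(train, "female", outcome)

    gamma = np.zeros(n_components)
    sigma = np.full(n_components, 1e6)  # ~zero weight for skipped components
    estimates: dict[str, MREstimate] = {}
    for i, label in enumerate(loadings.component_labels):
        pc_m = composite_sumstats(ss_m, loadings, K, component=i)
        pc_f = composite_sumstats(ss_f, loadings, K, component=i)
        est = cross_sex_mr(pc_m, pc_f, out_m, out_f, ld=panel, gws=gws, **mr_kwargs)["meta"]
        estimates[label] = est
        if est.ok:
            gamma[i], sigma[i] = est.beta, est.se

    mu = train.traits.mean().to_numpy()
    sd = train.traits.std(ddof=0).to_numpy()
    predictor = Predictor(
        loadings.w,
        gamma,
        sigma,
        mu,
        sd,
        tuple(train.traits.columns),
        outcome=outcome,
        name=f"{n_components}-component",
    )
    return TrainedModel(predictor, loadings, K, estimates, panel)
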