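"""Train and evaluate a multi-component disease-risk predictor.

Runs the full pipeline on a training cohort — GWAS, effect-matrix PCA,
per-component cross-sex MR — combines the component scores with
inverse-variance weights d = sum_i gamma_i p_i / sigma_i^2, and
compares its out-of-sample discrimination against single-trait
predictors with DeLong's test.
"""

import dataclasses

from compmr import OutcomeSpec, SimConfig, simulate_cohort, train_component_predictor
from compmr.predict import evaluate_out_of_sample

cfg = SimConfig(
    n_individuals=16_000,
    n_snps=120,
    factor_heritabilities=[0.8, 0.8, 0.5, 0.5],
    causal_snps_per_factor=10,
    sex_amplification=[1.0] * 4,
    outcome_specs=[
        OutcomeSpec("disease", "binary", [0.7, 0.7, 0.0, 0.0], prevalence=0.25)
    ],
    seed=2024,
)
train = simulate_cohort(cfg)
holdout = simulate_cohort(dataclasses.replace(cfg, n_individuals=5000, seed=777))

model = train_component_predictor(train, "disease")
print("per-component causal effects on disease (cross-sex IVW meta):")
for label, est in model.component_estimates.items():
    if est.ok:
        print(f"  {label}: gamma = {est.beta:+.3f} (se {est.se:.3f}), "
              f"{est.n_instruments} instruments")
    else:
        print(f"  {label}: {est.status}")

table = evaluate_out_of_sample(
    model.predictor,
    holdout,
    single_trait_effects={"weight": (1.0, 1.0), "body_fat_pct": (1.0, 1.0)},
)
print("\nout-of-sample discrimination (holdout of 5000, trait scaling from training):")
print(table.round(4).to_string(index=False))
print("\nThe disease is driven by two independent latent factors; no single")
print("trait captures both, so the component predictor's AUC exceeds each")
print("single-trait AUC (DeLong p-values test those differences).")
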