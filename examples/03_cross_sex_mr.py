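"""Cross-sex Mendelian randomization of a composite trait on a disease.

Estimates the causal effect of the adiposity-driven composite on a
binary disease using male summary statistics as exposure against the
female outcome and vice versa, then meta-analyzes the two arms. The
same-sample (one-sample) estimate is shown for contrast, and the
analytic bias formula illustrates what sex-divergent instrument
effects would do to the meta-analyzed estimate.
"""

from compmr import (
    OutcomeSpec,
    SimConfig,
    cross_sex_mr,
    estimate_pheno_corr,
    export_ld_panel,
    build_effect_matrix,
    composite_sumstats,
    fit_pca,
    ivw,
    mr_pipeline,
    rescale_loadings,
    select_ivs,
    simulate_cohort,
    theoretical_bias,
)
from compmr.workflow import outcome_gwas, per_trait_gwas

cfg = SimConfig(
    n_individuals=16_000,
    n_snps=120,
    factor_heritabilities=[0.8, 0.8, 0.5, 0.5],
    causal_snps_per_factor=10,
    sex_amplification=[1.0] * 4,
    outcome_specs=[
        OutcomeSpec("disease", "binary", [0.0, 0.45, 0.0, 0.0], prevalence=0.25)
    ],
    seed=99,
)
cohort = simulate_cohort(cfg)

panel = export_ld_panel(cohort)
K = estimate_pheno_corr(cohort)
loadings = rescale_loadings(
    fit_pca(build_effect_matrix(per_trait_gwas(cohort, "combined"), panel), 4), K
)

ss_m = per_trait_gwas(cohort, "male")
ss_f = per_trait_gwas(cohort, "female")
out_m = outcome_gwas(cohort, "male", "disease")
out_f = outcome_gwas(cohort, "female", "disease")

# the component aligned with the adiposity factor carries the causal signal
for label in loadings.component_labels:
    pc_m = composite_sumstats(ss_m, loadings, K, component=label)
    pc_f = composite_sumstats(ss_f, loadings, K, component=label)
    res = cross_sex_mr(pc_m, pc_f, out_m, out_f, ld=panel)
    meta = res["meta"]
    if meta.ok:
        print(f"{label}: beta = {meta.beta:+.3f} (se {meta.se:.3f}), "
              f"p = {meta.pval:.2e}, {meta.n_instruments} instruments "
              f"[{meta.status}]")
    else:
        print(f"{label}: skipped ({meta.status})")

print("\nEffects are SD change in (standardized) disease liability per SD of")
print("the composite; the generator gave only the adiposity factor a causal")
print("effect, so one component should stand out and the others sit near 0.")

# one-sample contrast: male exposure on male outcome shares every individual
pc_m2 = composite_sumstats(ss_m, loadings, K, component=1)
one_sample = mr_pipeline(select_ivs(pc_m2, out_m, ld=panel))
if one_sample.ok:
    print(f"\none-sample (male-on-male) estimate: {one_sample.beta:+.3f} "
          f"(se {one_sample.se:.3f}) — overlap correlates the errors and is")
    print("what the cross-sex design removes.")

print(f"\nanalytic cross-sex bias, 1.37-fold sex difference, equal arms: "
      f"{100 * theoretical_bias(1.37, 1.0):+.1f}%")
print(f"analytic bias, 2.2-fold difference with 6.8-fold variance inflation: "
      f"{100 * theoretical_bias(2.2, 6.8):+.1f}% (toward the null)")
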