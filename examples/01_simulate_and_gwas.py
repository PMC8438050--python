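"""Simulate a latent-factor cohort and run a per-sex GWAS.

Builds a small cohort of 14 correlated anthropometric traits driven by
four latent genetic factors (the third factor's genetics 2.2x stronger
in women), runs a combined-sex GWAS of waist-to-hip ratio, and prints
the strongest associations.
"""

import numpy as np

from compmr import SimConfig, run_gwas, simulate_cohort

cfg = SimConfig(n_individuals=4000, n_snps=100, seed=42)
cohort = simulate_cohort(cfg)

print(f"cohort: {cohort.n} individuals, {cfg.n_snps} variants, "
      f"{cfg.n_traits} traits, disease prevalence "
      f"{cohort.outcomes['disease'].mean():.3f}")

ss = run_gwas(cohort, "combined", "whr")
top = ss.table.nsmallest(5, "pval")[["variant", "chrom", "pos", "beta", "se", "pval"]]
print("\nstrongest waist-to-hip-ratio associations (SD change per allele):")
print(top.to_string(index=False))

n_gws = int((ss.table["pval"] < 5e-8).sum())
print(f"\n{n_gws} variants reach genome-wide significance (p < 5e-8); their betas")
print("are effects of one allele on the inverse-rank-normalized trait, so a")
print("beta of 0.1 means a tenth of a phenotypic standard deviation.")

# sex-specific contrast on the amplified factor's causal variants
m = run_gwas(cohort, "male", "whr").table["beta"]
f = run_gwas(cohort, "female", "whr").table["beta"]
causal3 = np.abs(cohort.factor_snp_effects[:, 2]) > 0
ratio = np.abs(f[causal3]).mean() / np.abs(m[causal3]).mean()
print(f"\nfemale/male mean |effect| ratio at fat-distribution variants: {ratio:.2f}")
print("(the generator amplifies that factor's genetics 2.2-fold in women)")
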