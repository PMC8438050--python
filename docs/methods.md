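# Methods

This note documents the statistical model behind `compmr`, the design
choices that were genuinely open, the synthetic data generator's
assumptions, and the numerical conventions. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Composite traits from summary statistics

All effects are on the standardized (SD/SD) scale: per-allele effects on
inverse-rank-normalized continuous traits, or binary-trait effects divided
by √(p(1−p)). On that scale, per-variant OLS is linear in the phenotype, so
for any weighted trait combination y_C = Σ_t w_t y_t the GWAS coefficient is
β̂_C = Σ_t w_t β̂_t. A combination of unit-variance traits does not itself
have unit variance — Var(y_C) = wᵀKw with K the phenotypic correlation
matrix — so loadings are rescaled to v = w / √(wᵀKw), making the composite's
statistics those of a standardized trait. The SE of the combined estimate
uses the variance of a weighted sum of correlated estimators,
σ̂²_C,j = vᵀ Σ_j K Σ_j v, where Σ_j is the diagonal matrix of per-trait SEs
of SNP j; because all per-trait statistics come from one cohort, the
correlation of the estimators reduces to the phenotypic correlation. The
rescaled v (not the raw w) enters the SE formula so that the SEs match the
unit-variance composite the betas describe. When K is misspecified the
betas are unaffected (they do not involve K) and only SE accuracy degrades;
the composite-oracle study measures SE agreement against an
individual-level GWAS (correlation > 0.99 under a correct K).

**SNP selection.** The effect matrix contains the union of per-trait
genome-wide-significant SNPs (p < 5×10⁻⁸). To stop a single well-powered
trait from dominating, SNPs are prioritized by their best within-trait rank:
each trait ranks its significant SNPs by ascending p; a SNP's priority is
its best rank anywhere; ties break by smallest p, then variant id (the tie
rule is a reproducibility choice; any deterministic rule would do). Pruning
is greedy in priority order; two variants are independent if on different
chromosomes, separated by more than 10 Mb, or with r² < 0.01 — an OR of the
distance and LD conditions, taken as stated even though many pipelines use
the conjunction. Cross-chromosome pairs are always independent. The MAF
floor removes variants below 0.001 (boundary kept), and the MHC/HLA region
(chr6:28,477,797–33,448,354, GRCh37, treated as 1-based inclusive on both
ends per coordinate convention) is excluded because its long-range LD breaks
the independence assumptions.

**PCA.** The SNP × trait matrix is neither centered nor scaled:
standardized effects have essentially zero mean, and a trait's effect
variance is informative. Components are right singular vectors; the
explained-variance fraction of component i is defined as σᵢ²/Σσ², the
squared-singular-value share of the total sum of squares (the natural
denominator for uncentered data). Signs are fixed so each component's
largest-|loading| trait is positive. Four components are retained by
default; in the factor-recovery study four components capture > 99% of the
sum of squares by construction.

## Cross-sex Mendelian randomization

Fixed-effect IVW throughout: β_MR = Σ β_exp β_out/σ_out² / Σ β_exp²/σ_out²,
σ_MR = (Σ β_exp²/σ_out²)^{-1/2} — the zero-intercept WLS slope of outcome on
exposure effects. Exposure-side noise is ignored (the standard NOME
convention), which makes difference tests between two MR estimates mildly
over-dispersed; the test suite accounts for this where it asserts
calibration of such differences.

With full sample overlap and a confounder, the errors of β̂_exp and β̂_out
are correlated, biasing the one-sample IVW estimate in the direction of the
phenotypic correlation even under a null causal effect. Using male
statistics as exposure against female outcome (and vice versa) makes the
two error sources independent; the arms are combined by inverse-variance
meta-analysis. The overlap study verifies both halves of this claim
empirically (Monte-Carlo z of the null estimate ≫ 3 one-sample, < 3
cross-sex).

If instrument effects on the exposure are r-fold stronger in one sex, the
strong-exposure arm estimates α/r and the weak arm α·r, so the equal-weight
meta estimate is α(r + 1/r)/2 — never closer to the null. In practice the
weak arm has fewer significant instruments and a ρ-fold inflated variance,
giving weights (1, 1/ρ)/(1 + 1/ρ); `theoretical_bias(r, ρ)` returns the
signed relative bias w_strong/r + w_weak·r − 1. With (r=1.37, ρ=1) this is
+5.0%; with (r=2.2, ρ=6.8) it is −32.2%, i.e. toward the null — the
down-weighting of the noisy overestimating arm dominates.

**Instrument hygiene.** Instruments are exposure-GWS, LD-pruned, and must
number ≥ 10 after a reverse-causality screen (one-sided normal test of
|β_out| > |β_exp| at p < 0.05; a normal rather than t reference because
summary statistics carry no per-instrument degrees of freedom and
biobank-scale n makes the distinction vacuous). Heterogeneity uses the
per-instrument Cochran's Q against the fitted model, with the denominator
carrying all four error terms (σ_out², β_exp²σ_MR², β_MR²σ_exp²,
σ_MR²σ_exp²); Q ~ χ²₁ under homogeneity. If any instrument has Q-p < 10⁻³
the single most heterogeneous one is removed and the model refitted,
iterating to convergence — iteration rather than a single pass was chosen
so the stopping rule is deterministic; the audit trail of removed ids is
retained — but never shrinking the set below 5 (the attempt is flagged
instead). The weighted-median estimator interpolates the per-instrument
ratio at cumulative weight 0.5 with IVW weights; its SE comes from a seeded
parametric bootstrap (1000 replicates by default) since no analytic SE is
standard. Bonferroni labeling for a category pair uses
0.05/(n_exposures × n_outcomes) and never alters estimates.

## Sex-specificity screens

Homogeneity of instrument effects across sexes is tested two ways on paired
effects: (i) two-sided Wilcoxon signed-rank on |effects| — exact enumeration
up to 25 pairs, normal approximation with continuity correction beyond
(unspecified in the usual descriptions; this split is the scipy-conventional
one); (ii) zero-intercept total least squares, the principal axis of the
uncentered 2×2 second-moment matrix, assuming equal error variance on both
axes (the error-variance ratio is fixed at 1; configurable generalizations
were deliberately not built). The slope is reported through its angle,
which is symmetric under axis swap (θ ↦ 90°−θ), with a leave-one-out
jackknife SE and a two-sided normal test against 45°. Note orthogonal
regression is exactly scale-equivariant only for noiseless proportional
data; with scatter the equivariance is approximate, and the magnitude test
is blind to sign flips — the TLS screen covers that case. An exposure is
homogeneous only if both tests are non-significant at a nominal 0.05
(unadjusted; configurable). Only homogeneous exposures proceed to
sex-specific estimation (opposite-sex exposure on sex-of-interest outcome);
heterogeneous ones return an explicit "unsuitable" status.

## Prediction

Individual component scores use the raw orthonormal loadings w on
training-standardized traits. The rescaled v would only multiply each score
by a constant, which the per-component weights γᵢ/σᵢ² absorb; since AUC is
rank-invariant, the choice is immaterial for discrimination and w matches
the standard PC-projection convention. All components enter
d = Σ γᵢ pᵢ/σᵢ² regardless of significance — a non-significant component's
small γ and large σ already down-weight it; a component skipped for lack of
instruments enters with γ=0 and effectively infinite σ. Out-of-sample
evaluation always scales by the training sample's trait means/SDs; with
matched distributions the holdout-scaled alternative changes AUCs
negligibly (asserted as a robustness property, not a number). AUC is the
Mann–Whitney probability with ties at ½, higher score = higher risk;
DeLong's placement-value covariance estimator handles paired comparisons
(its variance is cross-checked against a paired bootstrap in the tests).

## Synthetic cohort generator

The generator emulates the *structure* of a biobank anthropometric dataset
at desk scale, not its content. Genotypes are binomial Hardy–Weinberg draws
with MAF ~ U(0.05, 0.5) and no LD by default (an optional Gaussian-copula
block mode correlates adjacent variants so pruning has work to do); variant
coordinates live on a synthetic genome of 22 chromosomes, 1-based, 1 Mb
spacing. Each latent factor f receives a disjoint causal SNP set whose
standardized effects satisfy ‖u_f‖² = h²_f; per-variant effects have fixed
magnitude and random sign by default (`snp_effect_dist="fixed"`), so the
number of discoverable instruments per factor is the stated design
parameter rather than a draw from a heavy-tailed lottery; a normal option
exists. Factor scores are amp·(G_std u_f) + e with unit unamplified
variance; the default amplification multiplies the third factor's genetic
component by 2.2 in women, emulating the empirically female-stronger
genetics of abdominal fat distribution. Traits are L·z plus an optional
scalar confounder plus correlated Gaussian noise filling the variance to 1;
the 14-trait default loading matrix is a QR-orthogonalized structured draft
(size, adiposity, fat-distribution contrast, lean/fat contrast) with
decreasing column norms. Binary outcomes threshold a liability
(Σ γ_f z_f + confounder + N(0,1)) at the empirical quantile of the
requested prevalence, so realized prevalence is essentially exact.
Inverse-rank normalization uses the Blom offset (rank − 3/8)/(n + ¼) with
ties broken in seeded random order; binary outcomes are analyzed by linear
regression on the 0/1 indicator (matching how biobank phenome-wide
statistics are produced) and standardized downstream. GWAS p-values use the
normal reference — the convention of the large-sample statistics being
emulated — keeping them consistent with beta/se at any n.

What the generator does **not** emulate: realistic human LD maps,
imputation uncertainty, relatedness, population stratification beyond the
single scalar confounder, covariate structures (age, sex interactions,
genetic PCs — a generic covariate hook exists but no synthetic counterpart
of the real covariate set is attempted), assortative mating, or
heavy-tailed effect-size distributions under the default settings. Passing
tests therefore demonstrate the *statistical machinery* — linearity,
calibration, bias removal, recovery — under the stated model, not
robustness to every failure mode of real biobank data.

## Validation-study designs

Fixed problem sizes, chosen once as the smallest designs that measure each
property with comfortable Monte-Carlo resolution:

- **Composite oracle:** one cohort, n = 5000, 2000 variants; max |Δβ|
  against the individual-level GWAS and the SE correlation.
- **Rescaling identity:** 1000 random (w, K) draws, 2–14 traits.
- **Factor recovery:** n = 40,000, 150 variants, 15 causal per factor,
  h² = 0.9/0.8/0.7/0.6 — "negligible-noise" conditions under which the
  top-4 uncentered PCs should capture > 99% of the sum of squares.
- **IVW calibration:** 500 replicates of 50 valid two-sample instruments
  (effect scale 0.1, exposure SE 0.005, outcome SE 0.02), α = 0.2 for
  coverage and α = 0 for type-I error.
- **Overlap bias:** 300 replicates, n = 3000, one factor (h² = 0.6, 30
  causal SNPs), confounder strength 0.5, zero causal effect; one-sample vs
  cross-sex IVW on instruments selected in the male exposure GWAS.
- **Outlier removal:** 100 replicates of 30 instruments with one planted
  10-combined-SD pleiotropic outlier (and 100 clean sets).
- **Prediction additivity:** 50 replicates; training n = 16,000, holdout
  4000, disease prevalence 0.25 caused by two factors (effects 0.7 each);
  full pipeline per replicate; win = component predictor beats both
  single-trait comparators with DeLong p < 0.05.

Instrument-level studies (calibration, outlier removal) simulate at the
summary-statistic level — drawing instrument effects directly — because the
properties under test concern the estimators, not the GWAS; the cohort-level
generator is exercised end-to-end by the composite, overlap, recovery and
prediction studies.

## Known limitations

- Fixed-effect IVW only; no MR-Egger, MR-PRESSO, multivariable MR, or exact
  Q statistics.
- No allele harmonization (strand flips, palindromes) or genome-build
  liftover: synthetic data shares one allele frame, and real inputs must
  arrive harmonized.
- K is a phenotypic correlation; cross-cohort effect-estimate covariance
  (which would require LD-score-regression-style intercepts) is out of
  scope.
- The homogeneity screen's 0.05 threshold is nominal, not
  multiplicity-adjusted; the underpowered flag fires below 6 pairs but does
  not change the verdict.
- In-sample prediction is plain within-sample evaluation; cross-validation
  is not built in.
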