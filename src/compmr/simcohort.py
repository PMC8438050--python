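"""Synthetic cohort generation and per-sex GWAS.

The generator emulates, at desk scale, the structure of a biobank-style
anthropometric dataset: a panel of correlated body traits driven by a
small number of latent genetic factors (overall size, adiposity, fat
distribution, lean/fat contrast), with one factor's genetic effects
amplified in one sex — mirroring the empirically stronger female
genetics of abdominal fat distribution — and downstream health outcomes
that are causally affected by the factors, not by the traits themselves.

Genotypes are binomial Hardy–Weinberg draws with no LD by default (an
optional block-LD mode correlates adjacent variants so pruning has
something to do). Traits are inverse-rank-normalized at GWAS time, and
binary outcomes are analyzed by linear regression on the 0/1 indicator,
matching how biobank phenome-wide summary statistics are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import COLUMNS, LDPanel, SumStats

DEFAULT_TRAIT_NAMES = (
    "height",
    "weight",
    "bmi",
    "whr",
    "waist",
    "hip",
    "body_fat_pct",
    "arm_fat",
    "leg_fat",
    "trunk_fat",
    "arm_lean",
    "leg_lean",
    "trunk_lean",
    "bmr",
)

FACTOR_NAMES = ("body_size", "adiposity", "fat_distribution", "lean_mass")


def default_trait_loadings(n_traits: int = 14, n_factors: int = 4) -> np.ndarray:
    """Structured traits x factors loading matrix with orthogonal columns.

    Column 1 is an overall-size factor loading on everything; column 2
    loads on adiposity measures; column 3 contrasts abdominal against
    gluteofemoral fat; column 4 contrasts lean against fat mass. The
    structured draft is QR-orthogonalized (preserving the leading
    structure) and columns are scaled to decreasing norms so the factors
    contribute distinct shares of trait variance.
    """
    draft = np.array(
        [
            # size  adiposity  fat-distrib  lean
            [0.9, -0.1, 0.0, 0.3],  # height
            [0.9, 0.4, 0.0, 0.2],  # weight
            [0.5, 0.7, 0.1, 0.0],  # bmi
            [0.2, 0.3, 0.9, -0.1],  # whr
            [0.6, 0.5, 0.6, 0.0],  # waist
            [0.7, 0.4, -0.3, 0.1],  # hip
            [0.2, 0.9, 0.0, -0.5],  # body_fat_pct
            [0.3, 0.7, -0.1, -0.4],  # arm_fat
            [0.3, 0.7, -0.5, -0.3],  # leg_fat
            [0.3, 0.8, 0.4, -0.3],  # trunk_fat
            [0.7, 0.0, 0.0, 0.6],  # arm_lean
            [0.7, 0.0, -0.2, 0.6],  # leg_lean
            [0.7, 0.1, 0.2, 0.6],  # trunk_lean
            [0.8, 0.1, 0.0, 0.5],  # bmr
        ]
    )[:n_traits, :n_factors]
    q, r = np.linalg.qr(draft)
    q = q * np.sign(np.diag(r))  # keep the draft's column orientation
    norms = np.array([1.0, 0.85, 0.65, 0.5])[:n_factors]
    out = q * norms
    # per-trait genetic share must leave room for noise
    row_ss = (out**2).sum(axis=1)
    if row_ss.max() >= 0.95:
        out = out * np.sqrt(0.9 / row_ss.max())
    return out


@dataclass
class OutcomeSpec:
    """One downstream outcome: continuous, or binary via liability threshold."""

    name: str
    kind: Literal["continuous", "binary"]
    factor_effects: Sequence[float]
    prevalence: float | None = None

    def __post_init__(self) -> None:
        self.factor_effects = np.asarray(self.factor_effects, dtype=float)
        if self.kind == "binary":
            if self.prevalence is None or not (0.01 < self.prevalence <= 0.5):
                raise ValueError(
                    f"binary outcome {self.name!r} needs prevalence in (0.01, 0.5]"
                )


def _default_outcomes(n_factors: int) -> list[OutcomeSpec]:
    e1 = np.zeros(n_factors)
    e1[min(1, n_factors - 1)] = 0.3  # adiposity raises disease risk
    e2 = np.zeros(n_factors)
    e2[0] = 0.2
    return [
        OutcomeSpec("disease", "binary", e1, prevalence=0.1),
        OutcomeSpec("biomarker", "continuous", e2),
    ]


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort.

    The defaults describe the reference condition: 14 traits driven by 4
    latent factors, the third factor's genetic effects 2.2x stronger in
    women, and a binary disease of 10% prevalence caused by the
    adiposity factor.
    """

    n_individuals: int = 2000
    n_snps: int = 200
    n_latent_factors: int = 4
    maf_range: tuple[float, float] = (0.05, 0.5)
    factor_heritabilities: Sequence[float] | None = None  # default 0.5 each
    trait_loading_matrix: np.ndarray | None = None
    trait_names: Sequence[str] | None = None
    trait_noise_corr: np.ndarray | None = None
    sex_amplification: Sequence[float] | None = None  # female multiplier per factor
    outcome_specs: Sequence[OutcomeSpec] | None = None
    confounder_strength: float = 0.0
    overlap_mode: Literal["full", "split", "none"] = "full"
    seed: int = 0
    chrom_length_bp: int = 100_000_000
    n_chromosomes: int = 22
    variant_spacing_bp: int = 1_000_000
    causal_snps_per_factor: int | None = None
    snp_effect_dist: Literal["fixed", "normal"] = "fixed"
    ld_block_size: int = 1  # >1 correlates adjacent variants (block LD)
    ld_block_rho: float = 0.0

    def __post_init__(self) -> None:
        F = self.n_latent_factors
        if self.factor_heritabilities is None:
            self.factor_heritabilities = np.full(F, 0.5)
        self.factor_heritabilities = np.asarray(self.factor_heritabilities, dtype=float)
        if len(self.factor_heritabilities) != F:
            raise ValueError("factor_heritabilities length must equal n_latent_factors")
        if np.any(self.factor_heritabilities < 0) or np.any(self.factor_heritabilities >= 1):
            raise ValueError("factor heritabilities must lie in [0, 1)")
        if self.trait_loading_matrix is None:
            self.trait_loading_matrix = default_trait_loadings(14, F)
        self.trait_loading_matrix = np.asarray(self.trait_loading_matrix, dtype=float)
        if not np.all(np.isfinite(self.trait_loading_matrix)):
            raise ValueError("trait loading matrix must be finite")
        if self.trait_loading_matrix.shape[1] != F:
            raise ValueError("trait_loading_matrix must have n_latent_factors columns")
        T = self.trait_loading_matrix.shape[0]
        if self.trait_names is None:
            self.trait_names = (
                DEFAULT_TRAIT_NAMES[:T]
                if T <= len(DEFAULT_TRAIT_NAMES)
                else tuple(f"trait_{i}" for i in range(T))
            )
        if len(self.trait_names) != T:
            raise ValueError("trait_names length must match loading-matrix rows")
        if self.trait_noise_corr is None:
            self.trait_noise_corr = np.eye(T)
        self.trait_noise_corr = np.asarray(self.trait_noise_corr, dtype=float)
        if self.trait_noise_corr.shape != (T, T):
            raise ValueError("trait_noise_corr must be traits x traits")
        if self.sex_amplification is None:
            amp = np.ones(F)
            if F >= 3:
                amp[2] = 2.2  # fat-distribution genetics stronger in women
            self.sex_amplification = amp
        self.sex_amplification = np.asarray(self.sex_amplification, dtype=float)
        if len(self.sex_amplification) != F:
            raise ValueError("sex_amplification length must equal n_latent_factors")
        if self.outcome_specs is None:
            self.outcome_specs = _default_outcomes(F)
        for spec in self.outcome_specs:
            if len(np.asarray(spec.factor_effects)) != F:
                raise ValueError(f"outcome {spec.name!r} factor_effects length mismatch")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        row_ss = (self.trait_loading_matrix**2).sum(axis=1) + self.confounder_strength**2
        if row_ss.max() >= 1:
            raise ValueError(
                "per-trait genetic + confounder variance share must stay below 1"
            )

    @property
    def n_traits(self) -> int:
        return self.trait_loading_matrix.shape[0]


@dataclass
class Cohort:
    """Simulated individual-level data plus the generating ground truth."""

    genotypes: np.ndarray  # individuals x variants, dosages 0/1/2
    variants: pd.DataFrame  # variant, chrom, pos, maf
    sex: np.ndarray  # "male"/"female"
    traits: pd.DataFrame  # raw (pre-normalization) trait values
    outcomes: pd.DataFrame
    factors: np.ndarray  # individuals x factors latent scores
    factor_snp_effects: np.ndarray  # variants x factors, on standardized dosages
    config: SimConfig

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def mask(self, sex_group: str) -> np.ndarray:
        if sex_group == "combined":
            return np.ones(self.n, dtype=bool)
        if sex_group in ("male", "female"):
            return self.sex == sex_group
        raise ValueError(f"unknown sex group {sex_group!r}")


def _assign_coordinates(cfg: SimConfig) -> pd.DataFrame:
    per_chrom = max(1, cfg.chrom_length_bp // cfg.variant_spacing_bp)
    idx = np.arange(cfg.n_snps)
    chrom = (idx // per_chrom) % cfg.n_chromosomes + 1
    pos = (idx % per_chrom) * cfg.variant_spacing_bp + 1
    return pd.DataFrame(
        {
            "variant": [f"rs{i + 1}" for i in idx],
            "chrom": chrom.astype(str),
            "pos": pos.astype(np.int64),
        }
    )


def _draw_genotypes(cfg: SimConfig, mafs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n, m = cfg.n_individuals, cfg.n_snps
    if cfg.ld_block_size <= 1 or cfg.ld_block_rho == 0.0:
        return rng.binomial(2, mafs[None, :], size=(n, m)).astype(np.int8)
    # block LD: within a block, each haplotype's allele indicators are
    # correlated Gaussians thresholded at the allele frequency
    rho = cfg.ld_block_rho
    geno = np.zeros((n, m), dtype=np.int8)
    for start in range(0, m, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, m)
        k = stop - start
        cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        chol = np.linalg.cholesky(cov)
        thr = stats.norm.ppf(mafs[start:stop])
        for _hap in range(2):
            z = rng.standard_normal((n, k)) @ chol.T
            geno[:, start:stop] += (z < thr[None, :]).astype(np.int8)
    return geno


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Draw a cohort under the latent-factor generative model.

    Latent factor f of individual i is ``amp * (G_std @ u_f) + e`` with
    ``||u_f||^2`` equal to the factor heritability, the environmental
    term bringing the (unamplified) variance to 1, and ``amp`` the
    female amplification multiplier. Traits are ``Z @ L' + confounder +
    correlated noise``; binary outcomes threshold a liability at the
    empirical quantile matching the requested prevalence.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m, F, T = cfg.n_individuals, cfg.n_snps, cfg.n_latent_factors, cfg.n_traits

    variants = _assign_coordinates(cfg)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    variants["maf"] = mafs
    geno = _draw_genotypes(cfg, mafs, rng)

    sex = np.where(rng.random(n) < 0.5, "male", "female")

    # per-factor SNP effects on disjoint causal sets
    k = cfg.causal_snps_per_factor or max(1, m // (2 * F))
    if k * F > m:
        raise ValueError("causal_snps_per_factor too large for n_snps")
    causal = rng.choice(m, size=k * F, replace=False)
    U = np.zeros((m, F))
    for f in range(F):
        idx = causal[f * k : (f + 1) * k]
        if cfg.snp_effect_dist == "fixed":
            # equal per-variant contribution, random sign: the number of
            # discoverable instruments per factor is the design parameter
            u = rng.choice([-1.0, 1.0], size=k)
        else:
            u = rng.standard_normal(k)
        h2 = cfg.factor_heritabilities[f]
        if h2 > 0:
            U[idx, f] = u * np.sqrt(h2) / np.linalg.norm(u)

    sd = np.sqrt(2 * mafs * (1 - mafs))
    g_std = (geno - 2 * mafs[None, :]) / sd[None, :]
    genetic = g_std @ U  # n x F
    amp = np.where(
        (sex == "female")[:, None], cfg.sex_amplification[None, :], np.ones((1, F))
    )
    env_sd = np.sqrt(1.0 - cfg.factor_heritabilities)
    Z = amp * genetic + rng.standard_normal((n, F)) * env_sd[None, :]

    confounder = rng.standard_normal(n)

    L = cfg.trait_loading_matrix
    noise_sd = np.sqrt(1.0 - (L**2).sum(axis=1) - cfg.confounder_strength**2)
    chol = np.linalg.cholesky(cfg.trait_noise_corr + 1e-12 * np.eye(T))
    noise = rng.standard_normal((n, T)) @ chol.T * noise_sd[None, :]
    traits = Z @ L.T + cfg.confounder_strength * confounder[:, None] + noise

    out_cols = {}
    for spec in cfg.outcome_specs:
        liab = (
            Z @ np.asarray(spec.factor_effects)
            + cfg.confounder_strength * confounder
            + rng.standard_normal(n)
        )
        if spec.kind == "binary":
            thr = np.quantile(liab, 1.0 - spec.prevalence)
            out_cols[spec.name] = (liab > thr).astype(np.int8)
        else:
            out_cols[spec.name] = liab

    return Cohort(
        genotypes=geno,
        variants=variants,
        sex=sex,
        traits=pd.DataFrame(traits, columns=list(cfg.trait_names)),
        outcomes=pd.DataFrame(out_cols),
        factors=Z,
        factor_snp_effects=U,
        config=cfg,
    )


def inverse_rank_normalize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Blom inverse-rank normal transform, ties broken in random order."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    jitter = rng.permutation(n)  # random tie order, deterministic per rng
    order = np.lexsort((jitter, x))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def _phenotype(cohort: Cohort, name: str) -> tuple[np.ndarray, bool]:
    """Return (values, is_binary) for a trait or outcome name."""
    if name in cohort.traits.columns:
        return cohort.traits[name].to_numpy(float), False
    if name in cohort.outcomes.columns:
        spec = {s.name: s for s in cohort.config.outcome_specs}[name]
        return cohort.outcomes[name].to_numpy(float), spec.kind == "binary"
    raise KeyError(f"no trait or outcome named {name!r}")


def normalized_traits(cohort: Cohort, sex_group: str = "combined") -> pd.DataFrame:
    """Trait matrix exactly as :func:`run_gwas` normalizes it within a sex group.

    Useful as the individual-level counterpart of composite summary
    statistics: a GWAS on a weighted sum of these columns is the direct
    oracle for the summary-level combination.
    """
    mask = cohort.mask(sex_group)
    n = int(mask.sum())
    cols = {}
    for t in cohort.traits.columns:
        rng = np.random.default_rng(np.random.SeedSequence([cohort.config.seed, 7, n]))
        cols[t] = inverse_rank_normalize(cohort.traits.loc[mask, t].to_numpy(float), rng)
    return pd.DataFrame(cols)


def run_gwas(
    cohort: Cohort,
    sex_group: Literal["male", "female", "combined"],
    trait_or_outcome: str,
    covariates: np.ndarray | None = None,
    normalize: bool | None = None,
) -> SumStats:
    """Per-variant simple linear regression within one sex group.

    Continuous phenotypes are inverse-rank-normalized within the
    analyzed subsample (so effects are in SD units); binary outcomes are
    regressed raw on dosage and tagged ``raw-binary``. Monomorphic
    variants get missing (NaN) effects. An optional covariate matrix is
    residualized out of both phenotype and dosages.
    """
    mask = cohort.mask(sex_group)
    n = int(mask.sum())
    if n < 50:
        raise ValueError(f"sex group {sex_group!r} has {n} < 50 individuals")

    y, is_binary = _phenotype(cohort, trait_or_outcome)
    y = y[mask]
    if normalize is None:
        normalize = not is_binary
    if normalize:
        rng = np.random.default_rng(np.random.SeedSequence([cohort.config.seed, 7, n]))
        y = inverse_rank_normalize(y, rng)

    G = cohort.genotypes[mask].astype(float)
    df_adjust = 0
    if covariates is not None:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)[mask]])
        proj = np.linalg.lstsq(C, np.column_stack([y, G]), rcond=None)[0]
        resid = np.column_stack([y, G]) - C @ proj
        y, G = resid[:, 0], resid[:, 1:]
        df_adjust = C.shape[1] - 1

    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ssg = (gc**2).sum(axis=0)
    ssy = float(yc @ yc)
    mono = ssg <= 0
    ssg_safe = np.where(mono, 1.0, ssg)
    beta = (gc.T @ yc) / ssg_safe
    dof = n - 2 - df_adjust
    resid_ss = np.maximum(ssy - beta**2 * ssg_safe, 0.0)
    # floor guards the degenerate noiseless-phenotype case (se would be 0)
    se = np.maximum(np.sqrt(resid_ss / dof / ssg_safe), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = beta / se
    # two-sided normal reference, matching the large-sample convention of
    # biobank phenome-wide statistics (keeps p consistent with beta/se)
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(zstat)), 1e-300)
    beta[mono] = np.nan
    se[mono] = np.nan
    pval[mono] = np.nan

    freq = G.mean(axis=0) / 2.0 if covariates is None else cohort.genotypes[mask].mean(axis=0) / 2.0
    table = pd.DataFrame(
        {
            "variant": cohort.variants["variant"],
            "chrom": cohort.variants["chrom"],
            "pos": cohort.variants["pos"],
            "ref": "A",
            "alt": "G",
            "minor_AF": np.minimum(freq, 1 - freq),
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )[COLUMNS]
    return SumStats(
        table,
        trait=trait_or_outcome,
        sex_group=sex_group,
        scale="raw-binary" if (is_binary and not normalize) else "standardized",
    )


def export_ld_panel(cohort: Cohort) -> LDPanel:
    """LD reference from the cohort's own dosages (pairwise r² lookup)."""
    return LDPanel.from_dosages(cohort.genotypes.astype(float), cohort.variants)


def simulate_iv_set(
    n_instruments: int,
    causal_effect: float,
    rng: np.random.Generator,
    exp_effect_sd: float = 0.1,
    exp_se: float = 0.005,
    out_se: float = 0.02,
    n_outliers: int = 0,
    outlier_sds: float = 10.0,
    exposure: str = "exposure",
    outcome: str = "outcome",
):
    """Draw instrument-level summary statistics for a two-sample MR.

    True instrument-exposure effects are N(0, exp_effect_sd²); observed
    exposure and outcome effects add independent Gaussian noise at the
    stated standard errors (valid two-sample setting, no overlap).
    ``n_outliers`` instruments get their outcome effect displaced by
    ``outlier_sds`` combined standard deviations, emulating pleiotropy.

    Returns an :class:`~compmr.mr.IVSet`.
    """
    from .mr import IVSet

    b_true = rng.normal(0.0, exp_effect_sd, size=n_instruments)
    # keep instruments relevantly strong (|beta_exp| well above its SE)
    b_true += np.sign(b_true) * 2 * exp_effect_sd
    be = b_true + rng.normal(0.0, exp_se, size=n_instruments)
    bo = causal_effect * b_true + rng.normal(0.0, out_se, size=n_instruments)
    if n_outliers:
        idx = rng.choice(n_instruments, size=n_outliers, replace=False)
        comb_sd = np.sqrt(out_se**2 + (causal_effect * exp_se) ** 2)
        bo[idx] += rng.choice([-1.0, 1.0], size=n_outliers) * outlier_sds * comb_sd
    table = pd.DataFrame(
        {
            "id": [f"iv{i + 1}" for i in range(n_instruments)],
            "beta_exp": be,
            "se_exp": exp_se,
            "beta_out": bo,
            "se_out": out_se,
        }
    )
    return IVSet(table, exposure=exposure, outcome=outcome)
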