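"""Composite traits from PCA of a multi-trait genetic-effect matrix.

The central trick: principal components of the SNP x trait matrix of
standardized effect estimates define linear trait combinations, and the
summary statistics of such a combination can be computed directly from
the per-trait statistics — no individual-level data needed. Because a
weighted sum of unit-variance traits does not itself have unit
variance, the raw loadings w are rescaled to v = w / sqrt(w' K w) with
K the phenotypic correlation matrix, so the composite behaves like a
GWAS of a standardized trait:

    beta_C,j = sum_t v_t * beta_t,j
    se_C,j   = sqrt( v' S_j K S_j v ),   S_j = diag(se_t,j)

The K sandwich in the SE accounts for the correlation between the
per-trait effect estimates, which (single-cohort statistics) equals the
phenotypic correlation of the traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simcohort import Cohort, inverse_rank_normalize
from .sumstats import COLUMNS, GWS, LDPanel, SumStats, multi_trait_priority, prune

logger = logging.getLogger(__name__)


@dataclass
class PhenoCorr:
    """Phenotypic correlation matrix K of the component traits."""

    matrix: np.ndarray
    trait_names: tuple[str, ...]

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("K must be symmetric")
        if not np.allclose(np.diag(K), 1.0, atol=1e-8):
            raise ValueError("K must have unit diagonal")
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-8:
            raise ValueError(f"K is not positive semi-definite (min eigenvalue {w.min():.3g})")
        if w.min() < 0:
            # marginally negative from rounding: clip to the PSD cone
            warnings.warn("K marginally non-PSD; clipping negative eigenvalues")
            vals, vecs = np.linalg.eigh(K)
            K = vecs @ np.diag(np.maximum(vals, 0.0)) @ vecs.T
            d = np.sqrt(np.diag(K))
            K = K / np.outer(d, d)
        self.matrix = K
        self.trait_names = tuple(self.trait_names)
        if len(self.trait_names) != K.shape[0]:
            raise ValueError("trait_names length must match K dimension")


@dataclass
class EffectMatrix:
    """Pruned SNP x trait matrix of standardized effects feeding the PCA."""

    effects: np.ndarray  # M x T, missing entries set to 0
    ses: np.ndarray  # M x T, NaN where missing
    missing: np.ndarray  # M x T boolean mask, True = was missing
    snp_ids: tuple[str, ...]
    trait_names: tuple[str, ...]

    def __post_init__(self) -> None:
        M, T = self.effects.shape
        if self.ses.shape != (M, T) or self.missing.shape != (M, T):
            raise ValueError("effects / ses / missing dimensions inconsistent")
        if len(self.snp_ids) != M or len(self.trait_names) != T:
            raise ValueError("label lengths inconsistent with matrix shape")
        if np.any(self.effects[self.missing] != 0):
            raise ValueError("masked entries must be exactly 0 in the effect matrix")


@dataclass
class Loadings:
    """Raw (w) and variance-rescaled (v) PCA weights per component."""

    w: np.ndarray  # T x C, orthonormal columns
    explained_variance: np.ndarray  # length C fractions
    trait_names: tuple[str, ...]
    component_labels: tuple[str, ...]
    v: np.ndarray | None = None  # T x C once rescaled

    def as_frame(self) -> pd.DataFrame:
        """Trait x component table of both weight sets (tab-friendly)."""
        cols = {}
        for i, lab in enumerate(self.component_labels):
            cols[f"{lab}_w"] = self.w[:, i]
            if self.v is not None:
                cols[f"{lab}_v"] = self.v[:, i]
        return pd.DataFrame(cols, index=list(self.trait_names))


def build_effect_matrix(
    ss_list: Sequence[SumStats],
    ld: LDPanel,
    gws: float = GWS,
    dist_bp: int = 10_000_000,
    r2_max: float = 0.01,
) -> EffectMatrix:
    """Select, prioritize and prune the SNPs entering the PCA.

    Takes the union of per-trait genome-wide-significant SNPs, orders it
    by the best-within-trait-rank priority rule, LD-prunes it, and
    assembles effects with missing estimates set to 0 (and masked).
    """
    if len(ss_list) < 2:
        raise ValueError("need at least 2 traits")
    for ss in ss_list:
        if ss.scale != "standardized":
            raise ValueError(f"trait {ss.trait!r} is not on the standardized scale")
    trait_names = tuple(ss.trait for ss in ss_list)
    tables = [ss.indexed() for ss in ss_list]

    all_ids = sorted(set().union(*(t.index for t in tables)))
    pmat = pd.DataFrame(
        {ss.trait: t["pval"].reindex(all_ids) for ss, t in zip(ss_list, tables)},
        index=all_ids,
    )
    priority = multi_trait_priority(pmat.fillna(1.0), gws=gws)
    if priority.empty:
        raise ValueError("no genome-wide significant SNP in any trait")
    kept = prune(list(priority.index), ld, dist_bp=dist_bp, r2_max=r2_max)

    M, T = len(kept), len(trait_names)
    eff = np.zeros((M, T))
    ses = np.full((M, T), np.nan)
    missing = np.ones((M, T), dtype=bool)
    for t_i, tab in enumerate(tables):
        sub = tab.reindex(kept)
        have = sub["beta"].notna().to_numpy()
        eff[have, t_i] = sub["beta"].to_numpy(float)[have]
        ses[have, t_i] = sub["se"].to_numpy(float)[have]
        missing[have, t_i] = False
    n_miss = int(missing.sum())
    if n_miss:
        logger.info("effect matrix: %d of %d entries missing, set to 0", n_miss, M * T)
    return EffectMatrix(eff, ses, missing, tuple(kept), trait_names)


def fit_pca(E: EffectMatrix, n_components: int | None = None) -> Loadings:
    """Uncentered PCA of the effect matrix.

    The matrix is neither centered nor scaled: standardized effects have
    (approximately) zero mean already, and a trait's effect variance is
    informative. Components are right singular vectors; the explained-
    variance fraction of component i is sigma_i² over the total sum of
    squares. Signs are fixed so each component's largest-magnitude trait
    loading is positive.
    """
    M, T = E.effects.shape
    if M < T:
        warnings.warn(f"effect matrix has fewer SNPs ({M}) than traits ({T})")
    if n_components is None:
        n_components = min(4, T)
    _, sing, vt = np.linalg.svd(E.effects, full_matrices=False)
    total = float((sing**2).sum())
    frac = sing**2 / total if total > 0 else np.zeros_like(sing)
    w = vt[:n_components].T.copy()  # T x C
    signs = np.sign(w[np.argmax(np.abs(w), axis=0), np.arange(w.shape[1])])
    signs[signs == 0] = 1.0
    w *= signs[None, :]
    labels = tuple(f"PC{i + 1}" for i in range(n_components))
    return Loadings(w, frac[:n_components], E.trait_names, labels)


def composite_variance(weights: np.ndarray, K: PhenoCorr) -> float:
    """Variance w' K w of the weighted trait combination."""
    w = np.asarray(weights, dtype=float)
    if w.shape[-1] != K.matrix.shape[0]:
        raise ValueError("weight length does not match K dimension")
    return float(w @ K.matrix @ w)


def rescale_loadings(loadings: Loadings, K: PhenoCorr) -> Loadings:
    """Populate v_i = w_i / sqrt(w_i' K w_i) so each composite has unit variance."""
    if K.matrix.shape[0] != loadings.w.shape[0]:
        raise ValueError("K dimension does not match trait count")
    v = np.empty_like(loadings.w)
    for i in range(loadings.w.shape[1]):
        q = composite_variance(loadings.w[:, i], K)
        if q <= 0:
            raise ValueError(f"degenerate composite variance {q:.3g} for component {i + 1}")
        v[:, i] = loadings.w[:, i] / np.sqrt(q)
    return Loadings(
        loadings.w,
        loadings.explained_variance,
        loadings.trait_names,
        loadings.component_labels,
        v=v,
    )


def composite_sumstats(
    ss_list: Sequence[SumStats],
    loadings: Loadings,
    K: PhenoCorr,
    component: int | str = 0,
    ld: LDPanel | None = None,
    gws: float = GWS,
    reprune: bool = False,
) -> SumStats:
    """Genome-wide summary statistics of one composite component.

    Per SNP j: beta = sum_t v_t beta_tj, se = sqrt(v' S_j K S_j v) with
    S_j the diagonal matrix of per-trait SEs, and a two-sided normal
    p-value. SNPs missing any trait's estimate are dropped (logged).
    With ``reprune=True`` the significant SNPs are LD-pruned again, as a
    component's instrument set should be.
    """
    if loadings.v is None:
        raise ValueError("loadings must be rescaled first (rescale_loadings)")
    if isinstance(component, str):
        component = loadings.component_labels.index(component)
    v = loadings.v[:, component]
    label = loadings.component_labels[component]

    tables = [ss.indexed() for ss in ss_list]
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    B = np.column_stack([t.loc[common, "beta"].to_numpy(float) for t in tables])
    S = np.column_stack([t.loc[common, "se"].to_numpy(float) for t in tables])
    ok = np.isfinite(B).all(axis=1) & np.isfinite(S).all(axis=1) & (S > 0).all(axis=1)
    n_drop = int((~ok).sum()) + sum(len(t) for t in tables) - len(common) * len(tables)
    if n_drop:
        logger.info("composite_sumstats: dropped %d rows missing some trait", n_drop)
    common = common[ok]
    B, S = B[ok], S[ok]

    beta = B @ v
    A = S * v[None, :]  # rows are S_j v elementwise
    var = np.einsum("jt,ts,js->j", A, K.matrix, A)
    se = np.sqrt(var)
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))

    ref = tables[0].loc[common]
    out = pd.DataFrame(
        {
            "variant": common,
            "chrom": ref["chrom"].to_numpy(),
            "pos": ref["pos"].to_numpy(np.int64),
            "ref": ref["ref"].to_numpy(),
            "alt": ref["alt"].to_numpy(),
            "minor_AF": ref["minor_AF"].to_numpy(float),
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": ref["n"].to_numpy(np.int64),
        }
    )[COLUMNS].reset_index(drop=True)

    if reprune:
        if ld is None:
            raise ValueError("reprune=True requires an LD panel")
        sig = out[out["pval"] < gws].sort_values("pval")
        kept = prune(list(sig["variant"]), ld)
        out = out[out["variant"].isin(kept)].reset_index(drop=True)

    sex = ss_list[0].sex_group
    return SumStats(out, trait=label, sex_group=sex, scale="standardized")


def estimate_pheno_corr(
    cohort: Cohort, covariates: np.ndarray | None = None, normalize: bool = True
) -> PhenoCorr:
    """Pearson correlation matrix of the cohort's (normalized) traits."""
    X = cohort.traits.to_numpy(float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    if covariates is not None:
        C = np.column_stack([np.ones(X.shape[0]), np.asarray(covariates, dtype=float)])
        X = X - C @ np.linalg.lstsq(C, X, rcond=None)[0]
    if normalize:
        rng = np.random.default_rng(np.random.SeedSequence([cohort.config.seed, 11]))
        X = np.column_stack([inverse_rank_normalize(X[:, j], rng) for j in range(X.shape[1])])
    K = np.corrcoef(X, rowvar=False)
    return PhenoCorr(K, tuple(cohort.traits.columns))


def fit_linear_combination(
    cohort: Cohort, target: str, basis: Sequence[str]
) -> tuple[np.ndarray, float]:
    """Least-squares approximation of one trait by a combination of others.

    A hypothesis-driven alternative to the PCA composites: regress the
    target trait on a basis of available traits and reuse the weights
    (after unit-variance rescaling) with :func:`composite_sumstats`.
    Returns (weights, in-sample r²). A collinear basis falls back to the
    minimum-norm solution with a warning.
    """
    names = set(cohort.traits.columns) | set(cohort.outcomes.columns)
    for name in [target, *basis]:
        if name not in names:
            raise KeyError(f"no trait named {name!r} in cohort")
    y = (
        cohort.traits[target] if target in cohort.traits.columns else cohort.outcomes[target]
    ).to_numpy(float)
    X = np.column_stack([cohort.traits[b].to_numpy(float) for b in basis])
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        warnings.warn("collinear basis; returning minimum-norm weights")
    w, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ w
    ssy = float(yc @ yc)
    r2 = 1.0 - float(resid @ resid) / ssy if ssy > 0 else 0.0
    return w, r2
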