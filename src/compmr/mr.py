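"""Inverse-variance-weighted Mendelian randomization with cross-sex arms.

Instruments are genome-wide-significant, LD-independent variants for
the exposure. Estimation is fixed-effect IVW — the zero-intercept
regression of outcome effects on exposure effects weighted by inverse
outcome variance — with a weighted-median fallback for pleiotropy
robustness, a reverse-causality magnitude filter, and iterative
Cochran's-Q outlier removal.

The cross-sex design removes one-sample overlap bias: each sex's
summary statistics serve as exposure against the other sex's outcome
statistics (disjoint samples, independent errors), and the two arm
estimates are meta-analyzed by inverse variance. When instrument
effects on the exposure differ between sexes by a factor r, each arm's
estimate is off by 1/r or r; :func:`theoretical_bias` gives the
resulting multiplicative bias of the meta-analyzed estimate, including
the down-weighting of the noisier (weaker-sex-exposure) arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import GWS, LDPanel, SumStats

logger = logging.getLogger(__name__)

#: Minimum instruments to attempt MR at all.
MIN_IV = 10
#: Minimum instruments that must survive Q-outlier removal.
MIN_IV_Q = 5
#: Per-instrument heterogeneity p-value triggering removal.
Q_PTHRESH = 1e-3


class EstimationError(ValueError):
    """The estimator is degenerate for this instrument set."""


@dataclass
class IVSet:
    """Instrument-level exposure/outcome effects for one MR analysis.

    ``table`` columns: id, beta_exp, se_exp, beta_out, se_out.
    """

    table: pd.DataFrame
    exposure: str = ""
    outcome: str = ""
    exposure_sex: str = "combined"
    outcome_sex: str = "combined"

    def __post_init__(self) -> None:
        need = ["id", "beta_exp", "se_exp", "beta_out", "se_out"]
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise ValueError(f"IVSet table missing columns {missing}")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate instrument ids")
        if len(self.table) and (
            (self.table["se_exp"] <= 0).any() or (self.table["se_out"] <= 0).any()
        ):
            raise ValueError("instrument standard errors must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def arm(self) -> str:
        return f"{self.exposure_sex}->{self.outcome_sex}"


@dataclass
class MREstimate:
    """A causal-effect estimate (or an explicit skip)."""

    beta: float
    se: float
    pval: float
    method: Literal["ivw", "weighted-median", "cross-sex-meta"]
    n_instruments: int
    removed: tuple[str, ...] = ()
    status: str = "ok"  # ok | insufficient_instruments | single_arm | outlier_stop
    exposure: str = ""
    outcome: str = ""
    arm: str = ""

    @classmethod
    def skipped(cls, method: str, exposure: str = "", outcome: str = "", arm: str = "") -> "MREstimate":
        return cls(
            beta=np.nan,
            se=np.nan,
            pval=np.nan,
            method=method,
            n_instruments=0,
            status="insufficient_instruments",
            exposure=exposure,
            outcome=outcome,
            arm=arm,
        )

    @property
    def ok(self) -> bool:
        return np.isfinite(self.beta)


def select_ivs(
    exposure: SumStats,
    outcome: SumStats,
    ld: LDPanel | None = None,
    gws: float = GWS,
    dist_bp: int = 10_000_000,
    r2_max: float = 0.01,
) -> IVSet:
    """Exposure-significant, LD-pruned instruments intersected with the outcome.

    The exposure's genome-wide-significant variants, ordered by ascending
    p, are pruned (if a panel is given) and matched to the outcome table;
    instruments absent there are dropped with a log line. The resulting
    set may be too small for MR — callers enforce the >=10 rule.
    """
    et = exposure.indexed()
    sig = et[et["pval"] < gws].sort_values("pval")
    cand = list(sig.index)
    if ld is not None:
        from .sumstats import prune

        cand = prune(cand, ld, dist_bp=dist_bp, r2_max=r2_max)
    ot = outcome.indexed()
    present = [v for v in cand if v in ot.index and np.isfinite(ot.loc[v, "beta"])]
    n_absent = len(cand) - len(present)
    if n_absent:
        logger.info("select_ivs: %d instrument(s) absent from outcome table", n_absent)
    table = pd.DataFrame(
        {
            "id": present,
            "beta_exp": et.loc[present, "beta"].to_numpy(float),
            "se_exp": et.loc[present, "se"].to_numpy(float),
            "beta_out": ot.loc[present, "beta"].to_numpy(float),
            "se_out": ot.loc[present, "se"].to_numpy(float),
        }
    )
    return IVSet(
        table,
        exposure=exposure.trait,
        outcome=outcome.trait,
        exposure_sex=exposure.sex_group,
        outcome_sex=outcome.sex_group,
    )


def reverse_causality_filter(ivs: IVSet, alpha: float = 0.05) -> IVSet:
    """Drop instruments whose outcome effect significantly exceeds the exposure effect.

    On the shared SD scale a valid instrument acts on the outcome only
    through the exposure, so |beta_out| > |beta_exp| signals reverse
    causation or confounding. One-sided normal test of
    (|beta_out| - |beta_exp|) / sqrt(se_out² + se_exp²); removal at p < alpha.
    """
    t = ivs.table
    z = (t["beta_out"].abs() - t["beta_exp"].abs()) / np.sqrt(t["se_out"] ** 2 + t["se_exp"] ** 2)
    p = stats.norm.sf(z)
    keep = p >= alpha
    n_rm = int((~keep).sum())
    if n_rm:
        logger.info("reverse_causality_filter: removed %d instrument(s)", n_rm)
    return replace(ivs, table=t.loc[keep].reset_index(drop=True))


def ivw(ivs: IVSet) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    beta_MR = sum(b_exp b_out / se_out²) / sum(b_exp² / se_out²);
    se_MR = 1 / sqrt(sum(b_exp² / se_out²)); two-sided normal p. This is
    the zero-intercept WLS slope of outcome on exposure effects.
    """
    t = ivs.table
    if len(t) == 0:
        raise EstimationError("empty instrument set")
    w = t["beta_exp"] ** 2 / t["se_out"] ** 2
    denom = float(w.sum())
    if denom <= 0:
        raise EstimationError("all exposure effects are zero")
    beta = float((t["beta_exp"] * t["beta_out"] / t["se_out"] ** 2).sum()) / denom
    se = 1.0 / np.sqrt(denom)
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate(
        beta,
        se,
        pval,
        "ivw",
        len(t),
        exposure=ivs.exposure,
        outcome=ivs.outcome,
        arm=ivs.arm,
    )


def cochran_q(ivs: IVSet, est: MREstimate) -> pd.DataFrame:
    """Per-instrument heterogeneity against the fitted causal model.

    Q_i = (b_out - beta_MR b_exp)² /
          (se_out² + b_exp² se_MR² + beta_MR² se_exp² + se_MR² se_exp²),
    chi²(1)-distributed under homogeneity; returns columns id, Q, p.
    """
    t = ivs.table
    num = (t["beta_out"] - est.beta * t["beta_exp"]) ** 2
    den = (
        t["se_out"] ** 2
        + t["beta_exp"] ** 2 * est.se**2
        + est.beta**2 * t["se_exp"] ** 2
        + est.se**2 * t["se_exp"] ** 2
    )
    q = num / den
    return pd.DataFrame({"id": t["id"], "Q": q, "p": stats.chi2.sf(q, df=1)})


def remove_outliers(
    ivs: IVSet,
    p_thresh: float = Q_PTHRESH,
    min_iv: int = MIN_IV_Q,
) -> tuple[IVSet, tuple[str, ...], MREstimate]:
    """Iterative Cochran's-Q pruning of heterogeneous instruments.

    Fit IVW, compute per-instrument Q; while the smallest heterogeneity
    p-value is below ``p_thresh``, remove that single most heterogeneous
    instrument and refit — but never shrink the set below ``min_iv``
    (the attempt is flagged instead, keeping the last valid estimate).
    Returns (final instruments, removed ids, final estimate).
    """
    current = ivs
    removed: list[str] = []
    est = ivw(current)
    while True:
        qtab = cochran_q(current, est)
        imin = int(qtab["p"].idxmin())
        if qtab.loc[imin, "p"] >= p_thresh:
            break
        if len(current) - 1 < min_iv:
            est = replace(est, status="outlier_stop")
            logger.info(
                "remove_outliers: outlier present but removal would leave <%d instruments",
                min_iv,
            )
            break
        worst = qtab.loc[imin, "id"]
        removed.append(worst)
        current = replace(
            current, table=current.table[current.table["id"] != worst].reset_index(drop=True)
        )
        est = ivw(current)
    est = replace(est, removed=tuple(removed))
    return current, tuple(removed), est


def weighted_median(
    ivs: IVSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of per-instrument ratio estimates.

    Ratios b_out/b_exp are weighted by b_exp²/se_out² (the IVW weights)
    and the median is interpolated at cumulative weight 0.5, making the
    estimate consistent while under half the total weight comes from
    invalid instruments. The SE comes from a seeded parametric
    bootstrap: instrument effects are redrawn from their sampling
    distributions and the weighted median recomputed.
    """
    t = ivs.table
    if len(t) == 0:
        raise EstimationError("empty instrument set")
    be = t["beta_exp"].to_numpy(float)
    bo = t["beta_out"].to_numpy(float)
    if np.all(be == 0):
        raise EstimationError("all exposure effects are zero")
    w = be**2 / t["se_out"].to_numpy(float) ** 2

    def wmed(bex: np.ndarray, bout: np.ndarray) -> float:
        ratios = bout / bex
        order = np.argsort(ratios)
        r, ww = ratios[order], w[order]
        s = (np.cumsum(ww) - 0.5 * ww) / ww.sum()
        return float(np.interp(0.5, s, r))

    beta = wmed(be, bo)
    rng = np.random.default_rng(seed)
    se_exp = t["se_exp"].to_numpy(float)
    se_out = t["se_out"].to_numpy(float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = wmed(
            be + rng.standard_normal(len(be)) * se_exp,
            bo + rng.standard_normal(len(bo)) * se_out,
        )
    se = float(boots.std(ddof=1))
    pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(
        beta,
        se,
        pval,
        "weighted-median",
        len(t),
        exposure=ivs.exposure,
        outcome=ivs.outcome,
        arm=ivs.arm,
    )


def cross_sex_meta(est_mf: MREstimate, est_fm: MREstimate) -> MREstimate:
    """Inverse-variance meta-analysis of the two cross-sex arms.

    If one arm was skipped for lack of instruments the other is returned
    with a ``single_arm`` flag; if both were skipped the meta-estimate
    is itself a skip.
    """
    arms = [e for e in (est_mf, est_fm) if e.ok]
    exposure = est_mf.exposure or est_fm.exposure
    outcome = est_mf.outcome or est_fm.outcome
    if not arms:
        return MREstimate.skipped("cross-sex-meta", exposure, outcome, "meta")
    if len(arms) == 1:
        e = arms[0]
        return replace(e, method="cross-sex-meta", status="single_arm", arm="meta")
    w = np.array([1.0 / e.se**2 for e in arms])
    beta = float(np.sum(w * [e.beta for e in arms]) / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate(
        beta,
        se,
        pval,
        "cross-sex-meta",
        est_mf.n_instruments + est_fm.n_instruments,
        removed=est_mf.removed + est_fm.removed,
        exposure=exposure,
        outcome=outcome,
        arm="meta",
    )


def mr_pipeline(
    ivs: IVSet,
    min_iv: int = MIN_IV,
    reverse_alpha: float = 0.05,
    q_thresh: float = Q_PTHRESH,
    min_iv_q: int = MIN_IV_Q,
    method: Literal["ivw", "weighted-median"] = "ivw",
    seed: int = 0,
) -> MREstimate:
    """Full single-arm analysis: reverse filter, >=10-IV gate, Q outlier removal."""
    filtered = reverse_causality_filter(ivs, alpha=reverse_alpha)
    if len(filtered) < min_iv:
        logger.info(
            "mr_pipeline: %s on %s (%s): %d < %d instruments, skipped",
            ivs.exposure,
            ivs.outcome,
            ivs.arm,
            len(filtered),
            min_iv,
        )
        return MREstimate.skipped(method, ivs.exposure, ivs.outcome, ivs.arm)
    if method == "weighted-median":
        return weighted_median(filtered, seed=seed)
    _, _, est = remove_outliers(filtered, p_thresh=q_thresh, min_iv=min_iv_q)
    return est


def cross_sex_mr(
    exposure_m: SumStats,
    exposure_f: SumStats,
    outcome_m: SumStats,
    outcome_f: SumStats,
    ld: LDPanel | None = None,
    gws: float = GWS,
    **pipeline_kwargs,
) -> dict[str, MREstimate]:
    """Both cross-sex arms plus their meta-analysis.

    Male summary statistics are the exposure against the female outcome
    and vice versa, so exposure and outcome errors come from disjoint
    samples. Returns ``{"male_exposure": ..., "female_exposure": ...,
    "meta": ...}``.
    """
    est_mf = mr_pipeline(select_ivs(exposure_m, outcome_f, ld=ld, gws=gws), **pipeline_kwargs)
    est_fm = mr_pipeline(select_ivs(exposure_f, outcome_m, ld=ld, gws=gws), **pipeline_kwargs)
    return {
        "male_exposure": est_mf,
        "female_exposure": est_fm,
        "meta": cross_sex_meta(est_mf, est_fm),
    }


def theoretical_bias(effect_ratio: float, variance_ratio: float = 1.0) -> float:
    """Relative bias of the cross-sex meta-analyzed estimate.

    ``effect_ratio`` r is how much stronger the instrument-exposure
    effects are in the stronger sex; ``variance_ratio`` rho is the
    variance inflation of the weaker-sex-exposure arm (fewer, weaker
    instruments). The stronger-sex-exposure arm estimates alpha/r, the
    other alpha*r; meta-weights are proportional to (1, 1/rho).
    Returns (expected estimate / alpha) - 1, signed: positive = away
    from the null, negative = toward it. With equal weights the bias is
    (r + 1/r)/2 - 1 >= 0.
    """
    r, rho = float(effect_ratio), float(variance_ratio)
    if r <= 0 or rho <= 0:
        raise ValueError("effect_ratio and variance_ratio must be positive")
    w_strong = 1.0 / (1.0 + 1.0 / rho)
    w_weak = (1.0 / rho) / (1.0 + 1.0 / rho)
    expected_ratio = w_strong * (1.0 / r) + w_weak * r
    return expected_ratio - 1.0


def bonferroni_threshold(n_exposures: int, n_outcomes: int, alpha: float = 0.05) -> float:
    """Category-pair multiple-testing threshold alpha / (n_exposures * n_outcomes)."""
    if n_exposures < 1 or n_outcomes < 1:
        raise ValueError("counts must be positive")
    return alpha / (n_exposures * n_outcomes)
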