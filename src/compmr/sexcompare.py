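"""Sex-homogeneity testing and comparison of causal-effect profiles.

The cross-sex MR design is only unbiased for sex-specific effects if
the instruments act on the exposure with the same strength in both
sexes. Two complementary screens check this on the paired instrument
effects: a Wilcoxon signed-rank test on absolute effects (systematic
magnitude difference) and a zero-intercept total-least-squares fit
(proportional difference, tested on the angle scale against 45°). Only
exposures passing both screens are used for sex-specific estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mr import MREstimate, mr_pipeline, select_ivs
from .sumstats import GWS, LDPanel, SumStats


@dataclass
class TLSFit:
    """Zero-intercept orthogonal-regression fit of y on x."""

    slope: float
    angle_deg: float
    angle_se: float
    pval: float  # vs the 45-degree (slope 1) null
    n: int


@dataclass
class SexHomogeneityReport:
    """Joint verdict of the Wilcoxon and TLS screens."""

    wilcoxon_p: float
    tls: TLSFit
    verdict: str  # "homogeneous" | "heterogeneous"
    alpha: float = 0.05
    underpowered: bool = False


def _tls_angle(x: np.ndarray, y: np.ndarray) -> float:
    """Angle (degrees) of the principal axis through the origin.

    The orthogonal-distance-minimizing line through the origin is the
    top eigenvector of the uncentered second-moment matrix
    [[sum x², sum xy], [sum xy, sum y²]].
    """
    sxx, syy, sxy = float(x @ x), float(y @ y), float(x @ y)
    # eigenvector of the larger eigenvalue of [[sxx, sxy], [sxy, syy]]
    lam = 0.5 * (sxx + syy + np.sqrt((sxx - syy) ** 2 + 4 * sxy**2))
    if abs(sxy) < 1e-300 and syy >= sxx:
        return 90.0
    # (lam - syy, sxy) is orthogonal-complement form; use (sxy, lam - sxx)
    vx, vy = lam - syy, sxy
    if vx == 0 and vy == 0:
        vx, vy = sxy, lam - sxx
    return float(np.degrees(np.arctan2(vy, vx)))


def tls_origin(x: np.ndarray, y: np.ndarray) -> TLSFit:
    """Total-least-squares slope through the origin with jackknife angle SE.

    Minimizes summed squared orthogonal distances to a line through the
    origin; equal error variance is assumed on both axes. The SE is
    computed on the angle rather than the slope — the angle is symmetric
    in the two variables (swapping x and y maps theta to 90° - theta)
    while the slope is not — by leave-one-out jackknife, and the p-value
    is a two-sided normal test of the angle against 45°.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.all(x == 0) and np.all(y == 0):
        raise ValueError("all points at the origin")

    angle = _tls_angle(x, y)
    loo = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        loo[i] = _tls_angle(x[keep], y[keep])
    se = float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))
    if se > 0:
        pval = float(2.0 * stats.norm.sf(abs(angle - 45.0) / se))
    else:
        pval = 1.0 if np.isclose(angle, 45.0) else 0.0
    slope = float(np.tan(np.radians(angle))) if not np.isclose(abs(angle), 90.0) else np.inf
    return TLSFit(slope=slope, angle_deg=angle, angle_se=se, pval=pval, n=n)


def z_difference(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Two-sided Z-test for a difference of two independent estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def sex_homogeneity(
    iv_effects_m: np.ndarray,
    iv_ses_m: np.ndarray,
    iv_effects_f: np.ndarray,
    iv_ses_f: np.ndarray,
    alpha: float = 0.05,
) -> SexHomogeneityReport:
    """Screen paired instrument effects for sex differences.

    Paired two-sided Wilcoxon signed-rank on |effects| (exact for <= 25
    pairs, normal approximation with continuity correction beyond) plus
    a TLS fit of female on male effects tested against slope 1. The
    exposure is judged homogeneous only if both are non-significant at
    ``alpha``. The sign-flip blind spot of the magnitude test (equal
    |effects| with opposite signs) is covered by the TLS screen.
    """
    m = np.asarray(iv_effects_m, dtype=float)
    f = np.asarray(iv_effects_f, dtype=float)
    if m.shape != f.shape:
        raise ValueError("paired effect vectors must have equal length")
    n = len(m)
    underpowered = n < 6
    diff = np.abs(f) - np.abs(m)
    if np.allclose(diff, 0):
        wp = 1.0
    else:
        method = "exact" if n <= 25 else "approx"
        wp = float(
            stats.wilcoxon(
                np.abs(f), np.abs(m), zero_method="wilcox", correction=True, method=method
            ).pvalue
        )
    tls = tls_origin(m, f)
    verdict = "homogeneous" if (wp >= alpha and tls.pval >= alpha) else "heterogeneous"
    return SexHomogeneityReport(
        wilcoxon_p=wp, tls=tls, verdict=verdict, alpha=alpha, underpowered=underpowered
    )


@dataclass
class SexSpecificResult:
    """Per-sex causal estimates with their difference test."""

    status: str  # "ok" | "unsuitable" | "insufficient_instruments"
    male: MREstimate | None = None
    female: MREstimate | None = None
    z: float = np.nan
    pval: float = np.nan
    significant: bool | None = None


def sex_specific_causal_effects(
    exposure_m: SumStats,
    exposure_f: SumStats,
    outcome_m: SumStats,
    outcome_f: SumStats,
    homogeneity: SexHomogeneityReport,
    ld: LDPanel | None = None,
    gws: float = GWS,
    bonferroni: float = 0.05,
    **pipeline_kwargs,
) -> SexSpecificResult:
    """Sex-specific causal effects via opposite-sex exposures.

    Requires a homogeneous exposure (otherwise the opposite-sex exposure
    statistics misestimate the instrument strength and the analysis is
    refused with status ``unsuitable``). The male-specific effect uses
    the female exposure statistics against the male outcome, and vice
    versa; the two estimates are compared with a two-sided Z-test
    labeled at the supplied Bonferroni threshold.
    """
    if homogeneity.verdict != "homogeneous":
        return SexSpecificResult(status="unsuitable")
    est_m = mr_pipeline(select_ivs(exposure_f, outcome_m, ld=ld, gws=gws), **pipeline_kwargs)
    est_f = mr_pipeline(select_ivs(exposure_m, outcome_f, ld=ld, gws=gws), **pipeline_kwargs)
    if not (est_m.ok and est_f.ok):
        return SexSpecificResult(status="insufficient_instruments", male=est_m, female=est_f)
    z, p = z_difference(est_m.beta, est_m.se, est_f.beta, est_f.se)
    return SexSpecificResult(
        status="ok", male=est_m, female=est_f, z=z, pval=p, significant=bool(p < bonferroni)
    )
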