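"""Multi-component disease-risk prediction and ROC evaluation.

An individual's component scores are projections of their standardized
traits onto the PCA loadings. A disease-specific risk score combines
the components with inverse-variance weights built from the MR causal
effects:

    d = sum_i  gamma_i * p_i / sigma_i**2

where gamma_i and sigma_i are the causal effect of component i on the
disease and its standard error, and p_i the individual's component
score. Components with non-significant effects are kept — their small
gamma / large sigma already down-weights them. Discrimination is
measured by AUC and compared between predictors with DeLong's test for
paired ROC curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simcohort import Cohort

logger = logging.getLogger(__name__)


class UndefinedAUCError(ValueError):
    """AUC needs both a case and a control class."""


@dataclass
class Predictor:
    """A trained risk predictor: loadings, effect weights, and training scaling.

    Scaling parameters (trait means/SDs) always come from the training
    sample, so the predictor can be applied to a holdout without
    touching its distribution.
    """

    loadings: np.ndarray  # traits x components (raw orthonormal w)
    gamma: np.ndarray  # causal effect of each component on the outcome
    sigma: np.ndarray  # SE of each causal effect
    train_means: np.ndarray
    train_sds: np.ndarray
    trait_names: tuple[str, ...]
    outcome: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("component effects must be finite")
        if np.any(self.sigma <= 0):
            raise ValueError("component-effect SEs must be positive")
        if self.loadings.shape != (len(self.trait_names), len(self.gamma)):
            raise ValueError("loadings shape inconsistent with traits/components")

    def score(self, traits: pd.DataFrame) -> np.ndarray:
        """Risk score d for each individual in a trait table."""
        scores = pc_scores(traits, self.loadings, self.train_means, self.train_sds, self.trait_names)
        return combine_predictor(scores, self.gamma, self.sigma)


def single_trait_predictor(
    trait: str,
    gamma: float,
    sigma: float,
    train_means: np.ndarray,
    train_sds: np.ndarray,
    trait_names: Sequence[str],
    outcome: str = "",
) -> Predictor:
    """Predictor using one trait alone (indicator loading)."""
    names = tuple(trait_names)
    w = np.zeros((len(names), 1))
    w[names.index(trait), 0] = 1.0
    return Predictor(
        w,
        np.array([gamma]),
        np.array([sigma]),
        np.asarray(train_means, float),
        np.asarray(train_sds, float),
        names,
        outcome=outcome,
        name=trait,
    )


def pc_scores(
    traits: pd.DataFrame | np.ndarray,
    loadings: np.ndarray,
    train_means: np.ndarray,
    train_sds: np.ndarray,
    trait_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Project standardized traits onto the component loadings.

    p = ((traits - train_means) / train_sds) @ loadings. Individuals
    with any missing trait value are dropped (count logged).
    """
    if isinstance(traits, pd.DataFrame):
        if trait_names is not None:
            traits = traits[list(trait_names)]
        X = traits.to_numpy(float)
    else:
        X = np.asarray(traits, dtype=float)
    if X.shape[1] != loadings.shape[0]:
        raise ValueError("trait columns do not match loading rows")
    ok = np.isfinite(X).all(axis=1)
    if not ok.all():
        logger.info("pc_scores: dropped %d individual(s) with missing traits", int((~ok).sum()))
        X = X[ok]
    return (X - np.asarray(train_means, float)) / np.asarray(train_sds, float) @ loadings


def combine_predictor(scores: np.ndarray, gamma: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Inverse-variance-weighted risk score d = sum_i gamma_i p_i / sigma_i²."""
    gamma = np.asarray(gamma, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma == 0):
        raise ValueError("zero standard error in predictor weights")
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] != len(gamma) or len(gamma) != len(sigma):
        raise ValueError("scores, gamma and sigma must align on components")
    return scores @ (gamma / sigma**2)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals the probability that a random case outscores a random
    control, ties counted one half; higher score = higher predicted risk.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(scores: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values via midranks (ties at one half)."""
    s = np.asarray(scores, dtype=float)
    m, n = int(pos.sum()), int((~pos).sum())
    all_r = stats.rankdata(s)
    pos_r = stats.rankdata(s[pos])
    neg_r = stats.rankdata(s[~pos])
    v10 = (all_r[pos] - pos_r) / n  # per-case placement
    v01 = 1.0 - (all_r[~pos] - neg_r) / m  # per-control placement
    return v10, v01


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """DeLong's test for two correlated AUCs on the same individuals.

    Returns (AUC_a, AUC_b, two-sided p) using the placement-value
    covariance estimator for the variance of the paired AUC difference.
    """
    labels = np.asarray(labels)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise UndefinedAUCError("both classes must be present")
    v10a, v01a = _placements(scores_a, pos)
    v10b, v01b = _placements(scores_b, pos)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        p = 1.0 if np.isclose(auc_a, auc_b) else 0.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, p


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of a single AUC (used for bootstrap cross-checks)."""
    labels = np.asarray(labels)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    v10, v01 = _placements(scores, pos)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def evaluate_out_of_sample(
    predictor: Predictor,
    holdout: Cohort,
    outcome: str | None = None,
    single_trait_effects: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Holdout AUCs of the component predictor and single-trait comparators.

    Applies the predictor's training-sample scaling to the holdout
    traits, scores the requested outcome, and — when
    ``single_trait_effects`` maps trait names to (gamma, sigma) — also
    evaluates each single-trait predictor and their inverse-variance
    combination, reporting every AUC with the DeLong p-value against the
    component predictor.
    """
    outcome = outcome or predictor.outcome
    if outcome not in holdout.outcomes.columns:
        return pd.DataFrame(
            [{"predictor": predictor.name or "components", "auc": np.nan, "status": "no_outcome"}]
        )
    labels = holdout.outcomes[outcome].to_numpy()
    d_main = predictor.score(holdout.traits)
    rows = [
        {
            "predictor": predictor.name or "components",
            "auc": auc(d_main, labels),
            "delong_p_vs_components": np.nan,
            "status": "ok",
        }
    ]
    if single_trait_effects:
        traits = list(single_trait_effects)
        combo = np.zeros((len(predictor.trait_names), len(traits)))
        gammas, sigmas = [], []
        for j, tr in enumerate(traits):
            g, s = single_trait_effects[tr]
            combo[list(predictor.trait_names).index(tr), j] = 1.0
            gammas.append(g)
            sigmas.append(s)
            single = single_trait_predictor(
                tr, g, s, predictor.train_means, predictor.train_sds, predictor.trait_names
            )
            d = single.score(holdout.traits)
            _, a, p = delong_test(d_main, d, labels)
            rows.append(
                {"predictor": tr, "auc": a, "delong_p_vs_components": p, "status": "ok"}
            )
        multi = Predictor(
            combo,
            np.array(gammas),
            np.array(sigmas),
            predictor.train_means,
            predictor.train_sds,
            predictor.trait_names,
            outcome=outcome,
            name="+".join(traits),
        )
        d = multi.score(holdout.traits)
        _, a, p = delong_test(d_main, d, labels)
        rows.append(
            {"predictor": multi.name, "auc": a, "delong_p_vs_components": p, "status": "ok"}
        )
    return pd.DataFrame(rows)
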