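"""Domain construction: indicators → domain scores and deprivation ranks.

Three combination recipes cover the seven default domains:

``sum_rate``
    Indicators sharing one denominator are summed (equivalently, their
    numerators are totalled and divided once). Used for the benefit-receipt,
    income-support and victimisation domains.
``minmax_weighted``
    Each indicator is min-max normalized to [0, 1] and combined with fixed
    weights (housing: 60% overcrowding, 40% renting).
``fa_weighted``
    Each indicator is ranked (mean ties), rank-transformed to normal scores
    (Blom constants), and combined with weights that are either fixed or
    estimated as normalized regression scoring coefficients of a
    single-factor maximum-likelihood factor model. The normal-scores step
    stops outliers dominating the composite.

Every domain score is finally ranked 1..n ascending in deprivation with tied
scores receiving the mean of their positional ranks, so rank sums are always
n(n+1)/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FactorAnalysis

from .errors import (
    ConfigurationError,
    DegenerateScaleError,
    EstimationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

METHODS = ("sum_rate", "minmax_weighted", "fa_weighted")


@dataclass(frozen=True)
class DomainRecipe:
    """How one domain is built from its indicator columns.

    ``fixed_weights`` must sum to 1; it is required for ``minmax_weighted``
    and optional for ``fa_weighted`` (when absent, weights are estimated from
    the data). Factor analysis on two items is statistically unsound, so
    ``fa_weighted`` requires at least three indicators.
    """

    domain: str
    method: str
    indicators: tuple[str, ...]
    fixed_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown domain method {self.method!r}")
        if self.method == "minmax_weighted" and self.fixed_weights is None:
            raise ConfigurationError(f"{self.domain}: minmax_weighted requires fixed_weights")
        if self.method == "fa_weighted" and len(self.indicators) < 3:
            raise ConfigurationError(
                f"{self.domain}: factor-analysis weighting needs >= 3 indicators"
            )
        if self.fixed_weights is not None:
            if len(self.fixed_weights) != len(self.indicators):
                raise ConfigurationError(f"{self.domain}: weights/indicators length mismatch")
            # published weight tables are rounded to 2 dp and can sum to
            # 0.99-1.01; they are renormalized exactly when applied
            if abs(sum(self.fixed_weights) - 1.0) > 0.02:
                raise ConfigurationError(f"{self.domain}: fixed weights must sum to 1")


@dataclass
class DomainResult:
    """Per-area score and deprivation rank for one domain (rank n = most deprived)."""

    domain: str
    score: pd.Series
    rank: pd.Series
    n: int
    weights: pd.Series | None = field(default=None)

    def __post_init__(self):
        total = self.rank.sum()
        expected = self.n * (self.n + 1) / 2
        if abs(total - expected) > 1e-6 * max(expected, 1.0):
            raise ValidationError(
                f"{self.domain}: rank sum {total} != n(n+1)/2 = {expected}"
            )


def rank_with_mean_ties(scores: pd.Series | np.ndarray) -> pd.Series:
    """Ascending ranks 1..n; tied scores share the mean of their positional ranks."""
    s = pd.Series(scores, dtype=float)
    if s.isna().any():
        raise ValidationError("cannot rank scores containing missing values")
    return pd.Series(stats.rankdata(s.to_numpy(), method="average"), index=s.index)


def blom_normal_scores(ranks: pd.Series | np.ndarray, n: int) -> pd.Series:
    """Normal scores via the Blom plotting position Φ⁻¹((r − 3/8)/(n + 1/4))."""
    r = pd.Series(ranks, dtype=float)
    if ((r < 1) | (r > n)).any():
        raise ValidationError(f"ranks must lie in [1, {n}]")
    return pd.Series(stats.norm.ppf((r.to_numpy() - 0.375) / (n + 0.25)), index=r.index)


def minmax_normalize(values: pd.Series | np.ndarray) -> pd.Series:
    """(x − min)/(max − min); invariant to positive affine transforms of x."""
    v = pd.Series(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateScaleError("constant input: min-max scale is degenerate (all areas tied)")
    return (v - lo) / (hi - lo)


def fa_indicator_weights(
    indicator_matrix: pd.DataFrame,
    max_iter: int = 2000,
) -> pd.Series:
    """Indicator weights from a single-factor maximum-likelihood factor model.

    The model is fit on standardized columns (equivalently, the correlation
    matrix). With loadings λ and uniquenesses ψ, the regression-method
    scoring coefficients for one factor are proportional to λᵢ/ψᵢ
    (Sherman–Morrison applied to Σ = λλ' + ψI gives Σ⁻¹λ ∝ ψ⁻¹λ). The factor
    is oriented so summed loadings are positive and the coefficients are
    normalized to sum to 1.

    A negative normalized coefficient is reported as a warning rather than
    clipped: on deprivation indicators all published weights are positive,
    so a sign flip usually signals mis-oriented input data.
    """
    X = indicator_matrix.to_numpy(dtype=float)
    n, p = X.shape
    if p < 3:
        raise ConfigurationError("factor-analysis weighting needs >= 3 indicators")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = list(indicator_matrix.columns[sd == 0])
        raise ValidationError(f"constant indicator columns: {const}")
    if n < 10 * p:
        raise ValidationError(f"need >= {10 * p} areas to weight {p} indicators, got {n}")
    Z = (X - X.mean(axis=0)) / sd
    fa = FactorAnalysis(n_components=1, max_iter=max_iter, tol=1e-8)
    fa.fit(Z)
    if fa.n_iter_ >= max_iter:
        raise EstimationError(f"factor model did not converge in {max_iter} EM iterations")
    loadings = fa.components_.ravel()
    if loadings.sum() < 0:
        loadings = -loadings
    psi = fa.noise_variance_
    coeff = loadings / psi
    weights = coeff / coeff.sum()
    if np.any(weights < 0):
        report = dict(zip(indicator_matrix.columns, np.round(weights, 4)))
        warnings.warn(
            f"negative scoring coefficients (check indicator orientation): {report}",
            stacklevel=2,
        )
    return pd.Series(weights, index=indicator_matrix.columns)


def build_domain_score(
    recipe: DomainRecipe,
    table: pd.DataFrame,
    normalization: str = "minmax",
) -> DomainResult:
    """Apply one recipe to the oriented indicator table and rank the result.

    ``normalization`` only affects ``minmax_weighted`` recipes and exists for
    sensitivity analysis: ``minmax`` (default), ``blom`` (normal scores of
    indicator ranks) or ``raw_rank`` (the ranks themselves).
    """
    missing = [c for c in recipe.indicators if c not in table.columns]
    if missing:
        raise ConfigurationError(f"{recipe.domain}: indicators not in table: {missing}")
    sub = table[list(recipe.indicators)]
    n = len(sub)
    weights_used: pd.Series | None = None

    if recipe.method == "sum_rate":
        # indicators in a sum_rate domain share one denominator, so summing
        # the per-indicator rates equals summing numerators then dividing once
        score = sub.sum(axis=1)
    elif recipe.method == "minmax_weighted":
        w = np.asarray(recipe.fixed_weights, dtype=float)
        if normalization == "minmax":
            norm = sub.apply(minmax_normalize)
        elif normalization == "blom":
            norm = sub.apply(lambda c: blom_normal_scores(rank_with_mean_ties(c), n))
        elif normalization == "raw_rank":
            norm = sub.apply(rank_with_mean_ties)
        else:
            raise ConfigurationError(f"unknown normalization {normalization!r}")
        score = norm @ w
        weights_used = pd.Series(w, index=recipe.indicators)
    else:  # fa_weighted
        normal_scores = sub.apply(lambda c: blom_normal_scores(rank_with_mean_ties(c), n))
        if recipe.fixed_weights is not None:
            w = np.asarray(recipe.fixed_weights, dtype=float)
            weights_used = pd.Series(w / w.sum(), index=recipe.indicators)
        else:
            weights_used = fa_indicator_weights(normal_scores)
        score = normal_scores @ weights_used.to_numpy()

    rank = rank_with_mean_ties(score)
    return DomainResult(domain=recipe.domain, score=score, rank=rank, n=n, weights=weights_used)
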