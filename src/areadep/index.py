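"""Index builder: domain ranks → exponential scores → weighted composite.

Domain ranks are mapped through a calibrated exponential transform before
weighting. The transform of the scaled rank R = rank/n is

    score(R) = −k · ln(1 − R·(1 − e^(−top/k)))

which is strictly increasing with score(1) = top exactly. The constant k is
calibrated so the score at the upper-tail boundary R = 1 − p equals the
mid-scale value (defaults: top 100, mid 50, p 10%, giving k = 50/ln 9). The
right-skew this induces means severe deprivation on one domain is not
cancelled by mild advantage on another when domains are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, ConfigurationError
from .domains import DomainResult, rank_with_mean_ties


@dataclass(frozen=True)
class ExponentialTransformSpec:
    """Anchors of the rank-to-exponential-score transform."""

    top_score: float = 100.0
    mid_score: float = 50.0
    upper_tail: float = 0.10

    def __post_init__(self):
        if not (0 < self.mid_score < self.top_score):
            raise CalibrationError("need 0 < mid_score < top_score")
        if not (0 < self.upper_tail < 1):
            raise CalibrationError("upper_tail must lie in (0, 1)")


def calibrate_exponential_constant(spec: ExponentialTransformSpec) -> float:
    """Solve for the transform constant k from the two anchors.

    score(R=1) = top holds for every k by construction, so k is pinned by
    score(1 − upper_tail) = mid. When top = 2·mid the substitution
    u = e^(−mid/k) reduces this to the quadratic (1−p)u² − u + p = 0 whose
    non-trivial root is u = p/(1−p), i.e. k = mid / ln((1−p)/p); the general
    case is solved numerically. p ≥ 0.5 (u ≥ 1) and a mid anchor at or above
    top·(1−p) (the transform's linear limit as k → ∞) admit no constant.
    """
    top, mid, p = spec.top_score, spec.mid_score, spec.upper_tail
    if top * (1 - p) <= mid:
        raise CalibrationError(
            f"mid anchor {mid} unreachable: the transform is bounded by "
            f"{top * (1 - p):.4g} at the tail boundary as k grows"
        )
    if top == 2 * mid:
        u = p / (1 - p)
        if u >= 1:
            raise CalibrationError("upper_tail >= 0.5 is degenerate")
        return mid / math.log(1 / u)

    def gap(k: float) -> float:
        return -k * math.log1p(-(1 - p) * (1 - math.exp(-top / k))) - mid

    lo, hi = 1e-6 * top, top
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e9 * top:  # pragma: no cover - guarded by the bound check above
            raise CalibrationError("no admissible constant found")
    return float(brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14))


def exponential_transform(
    ranks: pd.Series | np.ndarray,
    n: int,
    k: float,
    top_score: float = 100.0,
) -> pd.Series:
    """Map ranks 1..n to skewed scores in (0, top]; strictly increasing in rank."""
    if k <= 0:
        raise ConfigurationError("transform constant k must be positive")
    r = pd.Series(ranks, dtype=float)
    R = r.to_numpy() / n
    score = -k * np.log1p(-R * (1 - np.exp(-top_score / k)))
    return pd.Series(score, index=r.index)


@dataclass(frozen=True)
class DomainWeightSet:
    """Domain → weight map with optional leave-out exclusions.

    ``active()`` drops excluded domains and renormalizes the remaining
    weights proportionally so they again sum to 1.
    """

    weights: dict[str, float]
    exclusions: tuple[str, ...] = ()

    def __post_init__(self):
        bad = [d for d in self.exclusions if d not in self.weights]
        if bad:
            raise ConfigurationError(f"cannot exclude unknown domains: {bad}")
        if any(w < 0 for w in self.weights.values()):
            raise ConfigurationError("domain weights must be nonnegative")
        if len(self.exclusions) >= len(self.weights):
            raise ConfigurationError("cannot exclude every domain")

    def active(self) -> pd.Series:
        kept = {d: w for d, w in self.weights.items() if d not in self.exclusions}
        total = sum(kept.values())
        if total <= 0:
            raise ConfigurationError("active domain weights sum to zero")
        return pd.Series({d: w / total for d, w in kept.items()})


@dataclass
class IMDResult:
    """The combined index: per-area table plus the run's effective parameters.

    ``table`` columns: ``imd_score``, ``imd_rank``, ``quintile``, ``decile``,
    plus ``score_<domain>``, ``rank_<domain>`` and ``exp_<domain>`` for every
    active domain. Rank n is the most deprived area; quintile/decile 1 the
    least deprived fifth/tenth.
    """

    table: pd.DataFrame
    n: int
    k: float
    weights: pd.Series
    transform: ExponentialTransformSpec
    domain_weights_used: dict[str, pd.Series | None] = field(default_factory=dict)

    @property
    def imd_rank(self) -> pd.Series:
        return self.table["imd_rank"]

    def domain_rank(self, domain: str) -> pd.Series:
        return self.table[f"rank_{domain}"]


def quantile_classify(
    ranks: pd.Series | np.ndarray,
    n: int,
    k_groups: int,
    allow_any: bool = False,
) -> pd.Series:
    """Equal-count classification of ranks: group g covers (n(g−1)/k, ng/k].

    Group 1 is the least deprived. Only quintiles and deciles are accepted
    unless ``allow_any`` is set.
    """
    if k_groups not in (5, 10) and not allow_any:
        raise ConfigurationError("k_groups must be 5 or 10 (pass allow_any=True to override)")
    if k_groups < 1:
        raise ConfigurationError("k_groups must be positive")
    r = pd.Series(ranks, dtype=float)
    groups = np.ceil(r.to_numpy() * k_groups / n).astype(int)
    return pd.Series(np.clip(groups, 1, k_groups), index=r.index)


def combine_domains(
    domain_results: list[DomainResult],
    weights: DomainWeightSet,
    transform: ExponentialTransformSpec | None = None,
) -> IMDResult:
    """Weight exponentially transformed domain ranks into the composite index."""
    transform = transform or ExponentialTransformSpec()
    active = weights.active()
    by_name = {d.domain: d for d in domain_results}
    missing = [d for d in active.index if d not in by_name]
    if missing:
        raise ConfigurationError(f"weights given for absent domains: {missing}")

    k = calibrate_exponential_constant(transform)
    first = by_name[active.index[0]]
    n = first.n
    imd_score = pd.Series(0.0, index=first.rank.index)
    cols: dict[str, pd.Series] = {}
    for name, w in active.items():
        res = by_name[name]
        if res.n != n:
            raise ConfigurationError(f"domain {name} has n={res.n}, expected {n}")
        exp_score = exponential_transform(res.rank, n, k, transform.top_score)
        imd_score = imd_score + w * exp_score
        cols[f"score_{name}"] = res.score
        cols[f"rank_{name}"] = res.rank
        cols[f"exp_{name}"] = exp_score

    imd_rank = rank_with_mean_ties(imd_score)
    table = pd.DataFrame(
        {
            "imd_score": imd_score,
            "imd_rank": imd_rank,
            "quintile": quantile_classify(imd_rank, n, 5),
            "decile": quantile_classify(imd_rank, n, 10),
            **cols,
        }
    )
    return IMDResult(
        table=table,
        n=n,
        k=k,
        weights=active,
        transform=transform,
        domain_weights_used={d.domain: d.weights for d in domain_results},
    )


def build_imd(
    areas: pd.DataFrame,
    sources: pd.DataFrame,
    facilities=None,
    reference_rates=None,
    specs=None,
    recipes=None,
    weights: DomainWeightSet | None = None,
    transform: ExponentialTransformSpec | None = None,
    exclusions: tuple[str, ...] = (),
    profile: str = "nz2013",
):
    """End-to-end pipeline: raw tables → indicator table → domains → index.

    Returns ``(IMDResult, intermediates)`` where the intermediates dict holds
    the assembled indicator table and the per-domain results for audit.
    """
    from .indicators import assemble_indicator_table, default_indicator_specs
    from .domains import build_domain_score
    from .profiles import DOMAIN_WEIGHTS, default_recipes

    specs = specs if specs is not None else default_indicator_specs()
    recipes = recipes if recipes is not None else default_recipes(profile)
    weights = weights or DomainWeightSet(dict(DOMAIN_WEIGHTS), exclusions=tuple(exclusions))

    table = assemble_indicator_table(
        specs, areas, sources, facilities=facilities, reference_rates=reference_rates
    )
    active_names = set(weights.active().index)
    domain_results = [
        build_domain_score(r, table) for r in recipes if r.domain in active_names
    ]
    result = combine_domains(domain_results, weights, transform)
    intermediates = {
        "indicator_table": table,
        "domains": {d.domain: d for d in domain_results},
    }
    return result, intermediates
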