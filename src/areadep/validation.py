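"""Validation machinery: rank correlations, decile composition, sensitivity.

The index is validated the way composite deprivation measures usually are:
Spearman rank correlations of the index and each domain against external
outcome rates (smoking, household poverty), the urban/rural mix across
deciles, per-parent-region rank distributions, and the sensitivity of the
housing domain to the choice of normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .domains import DomainRecipe, build_domain_score, rank_with_mean_ties
from .errors import ConfigurationError, UndefinedCorrelationError, ValidationError
from .geography import aggregate_by_parent
from .index import IMDResult

logger = logging.getLogger(__name__)

_EXACT_P_BELOW = 20


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman's ρ (Pearson on mean-tie ranks) with a two-sided p-value.

    The p-value uses the t approximation at n ≥ 20 and an exact/permutation
    pairing test below that, where the approximation is poor.
    """
    xs = pd.Series(x, dtype=float).to_numpy()
    ys = pd.Series(y, dtype=float).to_numpy()
    if len(xs) != len(ys) or len(xs) < 3:
        raise ValidationError("inputs must have equal length >= 3")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise UndefinedCorrelationError("correlation of a constant input is undefined")
    rho, p = stats.spearmanr(xs, ys)
    if len(xs) < _EXACT_P_BELOW:
        rx, ry = stats.rankdata(xs), stats.rankdata(ys)
        res = stats.permutation_test(
            (rx, ry),
            lambda a, b: stats.pearsonr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            rng=np.random.default_rng(0),
        )
        p = float(res.pvalue)
    return float(rho), float(p)


@dataclass
class CorrelationTable:
    """Symmetric Spearman matrix over the index, its domains and outcomes."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: int

    def __post_init__(self):
        if not np.allclose(self.rho.to_numpy(), self.rho.to_numpy().T):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.rho.to_numpy()), 1.0):
            raise ValidationError("correlation matrix must be unit-diagonal")


def correlation_table(imd: IMDResult, outcomes: pd.DataFrame | None = None) -> CorrelationTable:
    """Spearman matrix over the index rank, all domain ranks, and ranked outcomes."""
    cols = {"IMD": imd.table["imd_rank"]}
    for c in imd.table.columns:
        if c.startswith("rank_"):
            cols[c.removeprefix("rank_")] = imd.table[c]
    if outcomes is not None:
        missing = outcomes.index.difference(imd.table.index)
        if len(missing) or len(outcomes) != len(imd.table):
            raise ValidationError(
                "outcome areas do not align with the index "
                f"({len(missing)} unmatched identifiers)"
            )
        for c in outcomes.columns:
            cols[c] = rank_with_mean_ties(outcomes.loc[imd.table.index, c])
    frame = pd.DataFrame(cols)
    names = list(frame.columns)
    k = len(names)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = spearman_rho(frame.iloc[:, i], frame.iloc[:, j])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    return CorrelationTable(
        rho=pd.DataFrame(rho, index=names, columns=names),
        p=pd.DataFrame(pmat, index=names, columns=names),
        n=len(frame),
    )


def decile_composition(
    imd: IMDResult,
    areas: pd.DataFrame,
    attribute: str = "rural",
    ranking: str = "IMD",
) -> pd.DataFrame:
    """Percentage of flagged areas in each decile of the chosen ranking.

    ``attribute`` names a boolean/0-1 column of ``areas`` (``"rural"`` is
    derived from ``urban_rural`` if absent). ``ranking`` is ``"IMD"`` or a
    domain name, so e.g. the rural share of the most access-deprived decile
    can be tabulated.
    """
    a = areas.set_index("area_id") if "area_id" in areas.columns else areas.copy()
    if attribute == "rural" and "rural" not in a.columns and "urban_rural" in a.columns:
        a["rural"] = a["urban_rural"] == "R"
    if attribute not in a.columns:
        raise ConfigurationError(f"unknown attribute column {attribute!r}")
    flag = a[attribute].reindex(imd.table.index).astype(bool)

    if ranking == "IMD":
        deciles = imd.table["decile"]
    else:
        col = f"rank_{ranking}"
        if col not in imd.table.columns:
            raise ConfigurationError(f"unknown ranking {ranking!r}")
        from .index import quantile_classify

        deciles = quantile_classify(imd.table[col], imd.n, 10)

    out = pd.DataFrame(
        {
            "n_areas": deciles.groupby(deciles).size(),
            "pct_flagged": flag.groupby(deciles).mean() * 100.0,
        }
    )
    out["pct_unflagged"] = 100.0 - out["pct_flagged"]
    out.index.name = "decile"
    return out


def normalization_sensitivity(
    housing_indicators: pd.DataFrame,
    methods: tuple[str, ...] = ("minmax", "blom", "raw_rank"),
    fixed_weights: tuple[float, ...] = (0.6, 0.4),
    domain: str = "Housing",
) -> pd.DataFrame:
    """Pairwise Spearman ρ between domain rankings built under each normalization.

    The published construction chose min-max after confirming that Blom
    normal scores and raw ranks give near-identical rankings; this reproduces
    that check on any data.
    """
    if len(methods) < 2:
        raise ConfigurationError("need at least two normalization methods to compare")
    recipe = DomainRecipe(
        domain=domain,
        method="minmax_weighted",
        indicators=tuple(housing_indicators.columns),
        fixed_weights=fixed_weights,
    )
    ranks = {
        m: build_domain_score(recipe, housing_indicators, normalization=m).rank
        for m in methods
    }
    out = pd.DataFrame(np.eye(len(methods)), index=list(methods), columns=list(methods))
    for i, mi in enumerate(methods):
        for mj in methods[i + 1:]:
            if len(housing_indicators) < 3:
                # below the correlation minimum, monotone agreement is all
                # that can be compared: identical ranks or reversed
                rho = 1.0 if ranks[mi].equals(ranks[mj]) else -1.0
            else:
                rho, _ = spearman_rho(ranks[mi], ranks[mj])
            out.loc[mi, mj] = out.loc[mj, mi] = rho
    return out


def distribution_by_parent(
    imd: IMDResult,
    areas: pd.DataFrame,
    domains: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Five-number summaries of index ranks per parent region, ordered by median.

    Optionally appends the same summaries for named domains (columns prefixed
    with the domain name). Parents with no areas are skipped with a warning.
    """
    a = areas[areas["area_id"].isin(imd.table.index)]
    empty = set(areas["parent_id"].unique()) - set(a["parent_id"].unique())
    if empty:
        logger.warning("parents with no areas skipped: %s", sorted(empty))
    summary = aggregate_by_parent(imd.table["imd_rank"], a, "five_number_summary")
    summary = summary.sort_values("median")
    for d in domains:
        dom = aggregate_by_parent(imd.table[f"rank_{d}"], a, "five_number_summary")
        summary = summary.join(dom.add_prefix(f"{d}_"))
    return summary
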