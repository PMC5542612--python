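"""Geography utilities: crosswalk apportionment and parent-region aggregation.

Administrative counts are often geocoded to an older geography vintage than
the analysis units. A *crosswalk* assigns each legacy unit to one or more
target areas with population-proportional shares summing to one, so that a
legacy count is split across the areas it overlaps. Apportioned values stay
fractional — rates are computed after summation, never from rounded pieces.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnmappedUnitError, ValidationError

CROSSWALK_COLUMNS = ("legacy_id", "area_id", "share")

_SHARE_TOL = 1e-9


def validate_crosswalk(crosswalk: pd.DataFrame) -> pd.DataFrame:
    """Check a crosswalk table and return it unchanged.

    Requirements: columns ``legacy_id, area_id, share``; shares in [0, 1];
    per-legacy shares summing to 1 within 1e-9; unique (legacy, area) pairs.
    """
    missing = [c for c in CROSSWALK_COLUMNS if c not in crosswalk.columns]
    if missing:
        raise ValidationError(f"crosswalk missing columns: {missing}")
    share = crosswalk["share"].to_numpy(dtype=float)
    if np.any(share < 0) or np.any(share > 1):
        raise ValidationError("crosswalk shares must lie in [0, 1]")
    if crosswalk.duplicated(subset=["legacy_id", "area_id"]).any():
        dupes = crosswalk.loc[
            crosswalk.duplicated(subset=["legacy_id", "area_id"]), "legacy_id"
        ].unique()
        raise ValidationError(f"duplicate (legacy_id, area_id) pairs for: {list(dupes)[:10]}")
    sums = crosswalk.groupby("legacy_id")["share"].sum()
    bad = sums[(sums - 1.0).abs() > _SHARE_TOL]
    if not bad.empty:
        raise ValidationError(
            f"crosswalk shares do not sum to 1 for {len(bad)} legacy units, "
            f"e.g. {dict(bad.head(5))}"
        )
    return crosswalk


def apportion_counts(
    legacy_values: Mapping[str, float] | pd.Series,
    crosswalk: pd.DataFrame,
) -> pd.Series:
    """Apportion legacy-unit values onto target areas via population shares.

    Each area receives ``sum(legacy value × share)`` over the legacy units
    mapped to it. Totals are conserved exactly (up to float addition) and the
    operation is linear in the input values.

    Parameters
    ----------
    legacy_values
        Value per legacy unit (counts or amounts — the operation is generic).
    crosswalk
        Validated crosswalk table.

    Returns
    -------
    pandas.Series
        Fractional value per ``area_id``, covering every area present in the
        crosswalk rows touched by ``legacy_values``.
    """
    values = pd.Series(legacy_values, dtype=float)
    mapped = set(crosswalk["legacy_id"])
    unmapped = set(values.index) - mapped
    if unmapped:
        raise UnmappedUnitError(unmapped)
    rows = crosswalk[crosswalk["legacy_id"].isin(values.index)]
    contrib = rows["share"].to_numpy() * values.loc[rows["legacy_id"]].to_numpy()
    out = pd.Series(contrib).groupby(rows["area_id"].to_numpy()).sum()
    out.index.name = "area_id"
    return out


_FIVE_NUMBER_LABELS = ("min", "q1", "median", "q3", "max")


def _five_number(values: np.ndarray) -> pd.Series:
    # linear-interpolation quartiles; fixed convention for reproducibility
    qs = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
    return pd.Series(qs, index=list(_FIVE_NUMBER_LABELS))


def aggregate_by_parent(
    values: Mapping[str, float] | pd.Series,
    areas: pd.DataFrame,
    statistic: str = "median",
) -> pd.Series | pd.DataFrame:
    """Summarise an area-level value within each parent region.

    ``statistic`` is ``"median"`` (returns a Series, parents orderable by
    median) or ``"five_number_summary"`` (returns a DataFrame with columns
    min, q1, median, q3, max — boxplot statistics).
    """
    if statistic not in ("median", "five_number_summary"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    vals = pd.Series(values, dtype=float)
    parents = areas.set_index("area_id")["parent_id"].reindex(vals.index)
    if parents.isna().any():
        orphans = list(vals.index[parents.isna()])[:10]
        raise ValidationError(f"areas without a parent region: {orphans}")
    grouped = vals.groupby(parents.to_numpy())
    if statistic == "median":
        out = grouped.median()
    else:
        out = grouped.apply(lambda s: _five_number(s.to_numpy())).unstack()
    out.index.name = "parent_id"
    return out
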