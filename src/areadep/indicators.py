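"""Indicator engine: raw numerators → oriented per-area indicator values.

Four indicator kinds cover the whole default set:

``count_rate``
    scale × numerator / denominator (benefit receipt, victimisations,
    overcrowding, hospitalisations, school-leaver outcomes...).
``per_capita_amount``
    dollars / population (income-support payments).
``standardized_ratio``
    observed / expected events under reference age-band rates (SMR,
    indirect standardization).
``distance``
    mean straight-line distance from the area centroid to the nearest k
    facilities of a category (geographic access).

All outputs are oriented so that larger = more deprived; distances pass
through unchanged because remoteness itself is the disadvantage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, UndefinedRatioError, ValidationError

logger = logging.getLogger(__name__)

DOMAINS = ("Employment", "Income", "Crime", "Housing", "Health", "Education", "Access")

DENOMINATORS = ("pop_total", "pop_working_age", "pop_youth", "school_leavers", "none")

KINDS = ("count_rate", "per_capita_amount", "standardized_ratio", "distance")


@dataclass(frozen=True)
class IndicatorSpec:
    """Recipe for one oriented indicator column.

    ``numerator_source`` is a source-table column, a list of columns to be
    summed before the rate is taken (offence types into one victimisation
    count), or a facility category for ``distance`` indicators.
    """

    name: str
    domain: str
    kind: str
    numerator_source: str | list[str] = ""
    denominator: str = "none"
    scale: float = 1.0

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ConfigurationError(f"unknown domain {self.domain!r} for {self.name}")
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown indicator kind {self.kind!r} for {self.name}")
        if self.denominator not in DENOMINATORS:
            raise ConfigurationError(f"unknown denominator {self.denominator!r} for {self.name}")
        if self.kind == "distance" and self.denominator != "none":
            raise ConfigurationError(f"distance indicator {self.name} must have denominator 'none'")
        if self.scale <= 0:
            raise ConfigurationError(f"scale must be positive for {self.name}")


@dataclass
class FacilitySet:
    """Planar facility point locations, grouped by category (coordinates in metres)."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def category(self, name: str) -> np.ndarray:
        if name not in self.points:
            raise ConfigurationError(f"unknown facility category {name!r}")
        return self.points[name]

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"category": cat, "x": pts[:, 0], "y": pts[:, 1]})
            for cat, pts in self.points.items()
        ]
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FacilitySet":
        pts = {
            str(cat): grp[["x", "y"]].to_numpy(dtype=float)
            for cat, grp in df.groupby("category")
        }
        return cls(points=pts)


# Default indicator set: 28 inputs across seven themed domains. The seven
# recorded offence types feed a single victimisation rate per 1,000 residents.
OFFENCE_TYPES = (
    "off_homicide",
    "off_assault",
    "off_sexual_assault",
    "off_abduction",
    "off_robbery",
    "off_burglary",
    "off_theft",
)

ACCESS_CATEGORIES = (
    "early_childhood_centre",
    "primary_school",
    "supermarket",
    "petrol_station",
    "gp_clinic",
)


def default_indicator_specs() -> list[IndicatorSpec]:
    """The shipped indicator configuration (two benefit-receipt rates, two
    per-capita payment amounts, one victimisation rate built from seven
    offence types, two housing rates, five health indicators, five education
    rates, five access distances)."""
    specs = [
        IndicatorSpec("unemployment_benefit_rate", "Employment", "count_rate",
                      "unemployment_benefit", "pop_working_age"),
        IndicatorSpec("sickness_benefit_rate", "Employment", "count_rate",
                      "sickness_benefit", "pop_working_age"),
        IndicatorSpec("msd_payments_per_capita", "Income", "per_capita_amount",
                      "msd_payments", "pop_total"),
        IndicatorSpec("ir_payments_per_capita", "Income", "per_capita_amount",
                      "ir_payments", "pop_total"),
        IndicatorSpec("victimisation_rate", "Crime", "count_rate",
                      list(OFFENCE_TYPES), "pop_total", scale=1000.0),
        IndicatorSpec("overcrowding_rate", "Housing", "count_rate",
                      "overcrowded", "pop_total"),
        IndicatorSpec("renting_rate", "Housing", "count_rate",
                      "rented", "pop_total"),
        IndicatorSpec("cancer_registration_rate", "Health", "count_rate",
                      "cancer_registrations", "pop_total"),
        IndicatorSpec("smr", "Health", "standardized_ratio", "deaths"),
        IndicatorSpec("infectious_hosp_rate", "Health", "count_rate",
                      "infectious_hosp", "pop_total"),
        IndicatorSpec("respiratory_hosp_rate", "Health", "count_rate",
                      "respiratory_hosp", "pop_total"),
        IndicatorSpec("emergency_admission_rate", "Health", "count_rate",
                      "emergency_admissions", "pop_total"),
        IndicatorSpec("no_tertiary_rate", "Education", "count_rate",
                      "edu_no_tertiary", "school_leavers"),
        IndicatorSpec("neet_rate", "Education", "count_rate",
                      "neet", "pop_youth"),
        IndicatorSpec("left_school_young_rate", "Education", "count_rate",
                      "edu_left_young", "school_leavers"),
        IndicatorSpec("no_qualifications_rate", "Education", "count_rate",
                      "no_qualifications", "pop_working_age"),
        IndicatorSpec("below_ncea2_rate", "Education", "count_rate",
                      "edu_below_ncea2", "school_leavers"),
    ]
    specs += [
        IndicatorSpec(f"dist_{cat}", "Access", "distance", cat)
        for cat in ACCESS_CATEGORIES
    ]
    return specs


def compute_rate(
    numerator: pd.Series | np.ndarray,
    denominator: pd.Series | np.ndarray,
    scale: float = 1.0,
    zero_denominator: str = "zero",
) -> pd.Series:
    """Rate = scale × numerator / denominator.

    Areas with a zero denominator get rate 0 (no eligible population means no
    measurable deprivation on the indicator) with a logged warning;
    ``zero_denominator="exclude"`` drops them instead.
    """
    num = pd.Series(numerator, dtype=float)
    den = pd.Series(denominator, dtype=float)
    if (num < 0).any():
        raise ValidationError("negative numerator counts")
    if (den < 0).any():
        raise ValidationError("negative denominator counts")
    zero = den == 0
    if zero.any():
        logger.warning("%d areas have a zero denominator; policy=%s", int(zero.sum()), zero_denominator)
        if zero_denominator == "exclude":
            num, den = num[~zero.to_numpy()], den[~zero.to_numpy()]
            zero = den == 0
        elif zero_denominator != "zero":
            raise ConfigurationError(f"unknown zero-denominator policy {zero_denominator!r}")
    rate = scale * num / den.where(~zero, other=np.nan)
    return rate.fillna(0.0)


def compute_per_capita_amount(
    dollars: pd.Series | np.ndarray,
    population: pd.Series | np.ndarray,
    zero_denominator: str = "zero",
) -> pd.Series:
    """Dollars paid per resident (a rate with scale 1)."""
    if (pd.Series(dollars, dtype=float) < 0).any():
        raise ValidationError("negative dollar totals")
    return compute_rate(dollars, population, 1.0, zero_denominator)


def compute_smr(
    observed: pd.Series | np.ndarray,
    pop_by_age_band: pd.DataFrame,
    reference_rates: pd.Series | np.ndarray,
) -> pd.Series:
    """Indirectly standardized event ratio: observed / expected.

    Expected events per area = Σ over age bands of (reference rate × band
    population). The banding is generic — any bands may be supplied as long
    as ``reference_rates`` aligns with the columns of ``pop_by_age_band``.
    """
    obs = pd.Series(observed, dtype=float)
    rates = np.asarray(reference_rates, dtype=float)
    if rates.ndim != 1 or rates.size != pop_by_age_band.shape[1]:
        raise ValidationError("reference rates must align with the age-band columns")
    if (rates < 0).any():
        raise ValidationError("negative reference rates")
    if (obs < 0).any():
        raise ValidationError("negative observed counts")
    expected = pop_by_age_band.to_numpy(dtype=float) @ rates
    bad = (expected == 0) & (obs.to_numpy() > 0)
    if bad.any():
        raise UndefinedRatioError(
            f"{int(bad.sum())} areas have observed events but zero expected events"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        smr = np.where(expected > 0, obs.to_numpy() / expected, 0.0)
    return pd.Series(smr, index=obs.index)


def nearest_k_mean_distance(
    centroids: np.ndarray,
    facilities: np.ndarray,
    k: int = 3,
) -> np.ndarray:
    """Mean planar Euclidean distance from each centroid to its k nearest facilities."""
    facilities = np.asarray(facilities, dtype=float)
    if len(facilities) < k:
        raise ConfigurationError(f"need at least k={k} facilities, got {len(facilities)}")
    tree = cKDTree(facilities)
    dists, _ = tree.query(np.asarray(centroids, dtype=float), k=k)
    if k == 1:
        return np.asarray(dists, dtype=float)
    return dists.mean(axis=1)


def assemble_indicator_table(
    specs: list[IndicatorSpec],
    areas: pd.DataFrame,
    sources: pd.DataFrame,
    facilities: FacilitySet | None = None,
    reference_rates: pd.Series | None = None,
    k_nearest: int = 3,
    zero_denominator: str = "zero",
) -> pd.DataFrame:
    """Build the full area × indicator table, indexed by ``area_id``.

    ``sources`` holds one row per area with raw numerator columns;
    age-band population columns (``pop_band_*``) live in ``areas``.
    Every output column is oriented larger = more deprived.
    """
    areas = areas.set_index("area_id") if "area_id" in areas.columns else areas
    src = sources.set_index("area_id") if "area_id" in sources.columns else sources
    src = src.reindex(areas.index)
    band_cols = [c for c in areas.columns if c.startswith("pop_band_")]
    out = {}
    for spec in specs:
        if spec.kind == "distance":
            if facilities is None:
                raise ConfigurationError(f"no facilities supplied for {spec.name}")
            pts = facilities.category(str(spec.numerator_source))
            out[spec.name] = nearest_k_mean_distance(
                areas[["x", "y"]].to_numpy(dtype=float), pts, k=k_nearest
            )
            continue
        cols = (
            list(spec.numerator_source)
            if isinstance(spec.numerator_source, list)
            else [spec.numerator_source]
        )
        missing = [c for c in cols if c not in src.columns]
        if missing:
            raise ValidationError(f"indicator {spec.name}: missing source columns {missing}")
        numer = src[cols].sum(axis=1)
        if spec.kind == "standardized_ratio":
            if not band_cols:
                raise ValidationError(f"indicator {spec.name}: no pop_band_* columns in areas")
            if reference_rates is None:
                raise ConfigurationError(f"indicator {spec.name}: reference rates required")
            out[spec.name] = compute_smr(numer, areas[band_cols], reference_rates)
        elif spec.kind == "per_capita_amount":
            out[spec.name] = compute_per_capita_amount(
                numer, areas[spec.denominator], zero_denominator
            )
        else:
            out[spec.name] = compute_rate(
                numer, areas[spec.denominator], spec.scale, zero_denominator
            )
    table = pd.DataFrame(out, index=areas.index)
    if table.isna().any().any():
        raise ValidationError("indicator table contains missing values after assembly")
    return table
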