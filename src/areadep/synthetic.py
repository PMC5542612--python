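"""Synthetic small-area data with a known latent deprivation factor.

The generator emulates the statistical structure the index pipeline assumes:
~6,000 small areas of 500–1,000 residents whose indicator numerators are all
driven by a single latent deprivation factor plus domain-shared and
indicator-specific noise; two outcome rates (smoking, household poverty)
whose rank correlation with the latent factor hits a stated target; access
to facilities driven by rurality rather than deprivation (rural areas are,
if anything, slightly *less* deprived, so access correlates negatively with
the index); a parent-region structure with region-level deprivation shifts;
and a legacy geography in which a small fraction of units straddle two or
three areas and must be apportioned by population share.

Because the latent factor is known, every downstream stage is testable:
domain and index ranks can be checked for latent recovery, factor-analysis
weights against the generating loadings, and validation reports against the
structure planted here.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError
from .indicators import ACCESS_CATEGORIES, FacilitySet, OFFENCE_TYPES

# Latent-factor loadings for each raw numerator column. Within each domain
# the ordering mirrors the published weight ordering (weakest-loading health
# indicator = cancer registrations, strongest = emergency admissions, etc.);
# the levels themselves are calibration choices for a realistic, strongly
# one-dimensional deprivation structure.
DEFAULT_LOADINGS: dict[str, float] = {
    "unemployment_benefit": 0.85,
    "sickness_benefit": 0.80,
    "msd_payments": 0.85,
    "ir_payments": 0.75,
    **{t: 0.50 for t in OFFENCE_TYPES},
    "overcrowded": 0.65,
    "rented": 0.55,
    "cancer_registrations": 0.35,
    "deaths": 0.45,
    "infectious_hosp": 0.60,
    "respiratory_hosp": 0.65,
    "emergency_admissions": 0.70,
    "edu_no_tertiary": 0.45,
    "neet": 0.55,
    "edu_left_young": 0.60,
    "no_qualifications": 0.62,
    "edu_below_ncea2": 0.65,
}

# Baseline prevalences / levels (multi-year pooling folded in where counts
# would otherwise be tiny, mirroring how routine health data are pooled).
_BASE_RATES: dict[str, float] = {
    "unemployment_benefit": 0.040,
    "sickness_benefit": 0.030,
    "overcrowded": 0.10,
    "rented": 0.33,
    "cancer_registrations": 0.020,
    "infectious_hosp": 0.030,
    "respiratory_hosp": 0.045,
    "emergency_admissions": 0.15,
    "edu_no_tertiary": 0.30,
    "neet": 0.12,
    "edu_left_young": 0.18,
    "no_qualifications": 0.20,
    "edu_below_ncea2": 0.25,
}

# Offence-type mix of the victimisation total (theft dominates, then
# burglary and assault) applied to an overall ~56-per-1000 victimisation rate.
_OFFENCE_MIX: dict[str, float] = {
    "off_theft": 0.546,
    "off_burglary": 0.244,
    "off_assault": 0.175,
    "off_robbery": 0.020,
    "off_sexual_assault": 0.012,
    "off_abduction": 0.002,
    "off_homicide": 0.001,
}
_VICTIMISATION_RATE = 0.0557

_DOMAIN_OF: dict[str, str] = {
    "unemployment_benefit": "Employment",
    "sickness_benefit": "Employment",
    "msd_payments": "Income",
    "ir_payments": "Income",
    **{t: "Crime" for t in OFFENCE_TYPES},
    "overcrowded": "Housing",
    "rented": "Housing",
    "cancer_registrations": "Health",
    "deaths": "Health",
    "infectious_hosp": "Health",
    "respiratory_hosp": "Health",
    "emergency_admissions": "Health",
    "edu_no_tertiary": "Education",
    "neet": "Education",
    "edu_left_young": "Education",
    "no_qualifications": "Education",
    "edu_below_ncea2": "Education",
}

# Age-band reference event rates (per person per pooled period), rising
# steeply with age as mortality does.
AGE_BANDS = ("pop_band_0_14", "pop_band_15_44", "pop_band_45_64", "pop_band_65p")
REFERENCE_RATES = pd.Series([0.0012, 0.0048, 0.024, 0.14], index=list(AGE_BANDS))

_BAND_SHARE_BASE = np.array([0.20, 0.40, 0.25, 0.15])

_PARENT_SPACING = 120_000.0  # metres between parent-region centres


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    ``indicator_loadings`` maps raw numerator columns to latent loadings in
    (0, 1]; ``noise_sd`` sets the indicator-specific noise level (scalar or
    per-indicator map). ``outcome_correlation`` is the target Spearman
    correlation between the latent factor and each outcome rate.
    """

    n_areas: int = 5958
    mean_pop: float = 712.0
    pop_bounds: tuple[int, int] = (501, 999)
    rural_fraction: float = 0.15
    indicator_loadings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    noise_sd: float | dict[str, float] = 0.5
    outcome_correlation: float = 0.8
    n_legacy_units: int | None = None
    n_parents: int = 20
    seed: int = 0
    # secondary structure
    domain_shared_sd: float = 0.35
    parent_effect_sd: float = 0.25
    rural_latent_shift: float = 0.30
    split_fraction: float = 0.0221
    facility_density: int | None = None
    include_small_area: bool = False

    def __post_init__(self):
        lo, hi = self.pop_bounds
        if self.n_areas < 1:
            raise ConfigurationError("n_areas must be positive")
        if not (lo <= self.mean_pop <= hi) or lo > hi or lo < 1:
            raise ConfigurationError(
                f"need pop_bounds[0] <= mean_pop <= pop_bounds[1], got {lo}, {self.mean_pop}, {hi}"
            )
        if not (0 <= self.rural_fraction <= 1):
            raise ConfigurationError("rural_fraction must lie in [0, 1]")
        if not (0 < self.outcome_correlation < 1):
            raise ConfigurationError("outcome_correlation must lie in (0, 1)")
        if self.n_parents < 1:
            raise ConfigurationError("n_parents must be positive")
        unknown = set(self.indicator_loadings) - set(DEFAULT_LOADINGS)
        if unknown:
            raise ConfigurationError(f"unknown indicator names in loadings: {sorted(unknown)}")
        bad = {k: v for k, v in self.indicator_loadings.items() if not (0 <= v <= 1)}
        if bad:
            raise ConfigurationError(f"loadings must lie in (0, 1]: {bad}")
        if isinstance(self.noise_sd, dict):
            if any(v <= 0 for v in self.noise_sd.values()):
                raise ConfigurationError("all noise_sd must be positive")
        elif self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")

    def loading(self, name: str) -> float:
        return self.indicator_loadings.get(name, DEFAULT_LOADINGS[name])

    def noise(self, name: str) -> float:
        if isinstance(self.noise_sd, dict):
            return self.noise_sd.get(name, 0.5)
        return self.noise_sd

    def legacy_units(self) -> int:
        # ratio of legacy building blocks to areas in administrative data
        return self.n_legacy_units or max(1, round(6.33 * self.n_areas))

    def facilities_per_category(self) -> int:
        # facility networks must cover every parent region, so density scales
        # with region count as well as area count
        return self.facility_density or max(5 * self.n_parents, round(0.025 * self.n_areas))


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the generating latent factor."""

    areas: pd.DataFrame
    latent: pd.Series
    indicator_numerators: pd.DataFrame
    outcomes: pd.DataFrame
    facilities: FacilitySet
    crosswalk: pd.DataFrame
    reference_rates: pd.Series


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named sub-stream: stable against adding or reordering other streams."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _parent_centres(n_parents: int) -> np.ndarray:
    ncol = int(np.ceil(np.sqrt(n_parents)))
    idx = np.arange(n_parents)
    return np.column_stack([(idx % ncol), (idx // ncol)]) * _PARENT_SPACING


def generate_area_units(config: SyntheticConfig) -> pd.DataFrame:
    """Areas with populations, age bands, denominators, rural flags, centroids.

    Populations are integer draws from a beta distribution scaled to
    ``pop_bounds`` with mean targeted at ``mean_pop``. Age-band shares come
    from a Dirichlet around a realistic national profile; the working-age
    denominator is the 15–64 band total (a stochastic 60–70% share of the
    population). Rural areas are placed on a peripheral ring around their
    parent-region centre, urban areas in a Gaussian core.
    """
    rng = _rng(config.seed, "areas")
    n = config.n_areas
    lo, hi = config.pop_bounds
    m = (config.mean_pop - lo) / (hi - lo)
    conc = 8.0
    pop = np.round(lo + (hi - lo) * rng.beta(m * conc, (1 - m) * conc, size=n)).astype(int)
    if config.include_small_area and n >= 1:
        pop[0] = 384  # isolated-island edge case, outside the usual bounds

    shares = rng.dirichlet(_BAND_SHARE_BASE * 150.0, size=n)
    bands = np.floor(shares * pop[:, None]).astype(int)
    bands[:, -1] += pop - bands.sum(axis=1)  # rounding remainder to the oldest band
    working_age = bands[:, 1] + bands[:, 2]
    youth = np.maximum(1, np.round(rng.uniform(0.28, 0.42, size=n) * bands[:, 1])).astype(int)
    leavers = np.maximum(3, np.round(rng.uniform(0.03, 0.05, size=n) * pop)).astype(int)

    rural = rng.random(n) < config.rural_fraction
    parent = rng.integers(0, config.n_parents, size=n)
    centres = _parent_centres(config.n_parents)[parent]
    theta = rng.uniform(0, 2 * np.pi, size=n)
    radius = np.where(
        rural,
        rng.uniform(8_000, 35_000, size=n),
        np.abs(rng.normal(0, 7_000, size=n)),
    )
    xy = centres + np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])

    width = len(str(n))
    return pd.DataFrame(
        {
            "area_id": [f"A{i + 1:0{width}d}" for i in range(n)],
            "pop_total": pop,
            "pop_working_age": working_age,
            "pop_youth": youth,
            "school_leavers": leavers,
            **{band: bands[:, j] for j, band in enumerate(AGE_BANDS)},
            "urban_rural": np.where(rural, "R", "U"),
            "parent_id": [f"P{p + 1:02d}" for p in parent],
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )


def _latent_factor(areas: pd.DataFrame, config: SyntheticConfig) -> pd.Series:
    rng = _rng(config.seed, "latent")
    n = len(areas)
    parents = sorted(areas["parent_id"].unique())
    shift = pd.Series(
        rng.normal(0, config.parent_effect_sd, size=len(parents)), index=parents
    )
    rural = (areas["urban_rural"] == "R").to_numpy()
    core_sd = np.sqrt(max(1e-6, 1 - config.parent_effect_sd**2))
    latent = (
        shift.loc[areas["parent_id"]].to_numpy()
        - config.rural_latent_shift * (rural - config.rural_fraction)
        + core_sd * rng.normal(size=n)
    )
    return pd.Series(latent, index=areas["area_id"].to_numpy(), name="latent")


def generate_indicator_data(
    areas: pd.DataFrame, config: SyntheticConfig
) -> SyntheticBundle:
    """Draw the latent factor, all raw numerators, outcomes, facilities and crosswalk.

    Count numerators are binomial draws against their own denominator with a
    per-area success probability that is logistic in (loading × latent +
    domain-shared noise + indicator noise); dollar amounts are log-normal
    with location increasing in the latent factor; deaths are Poisson around
    age-band reference expectations scaled by exp of the latent signal.
    """
    if len(areas) == 0:
        raise ConfigurationError("areas must be nonempty")
    latent = _latent_factor(areas, config)
    L = latent.to_numpy()
    n = len(areas)
    rng = _rng(config.seed, "indicators")

    domains = sorted(set(_DOMAIN_OF.values()))
    shared = {d: rng.normal(size=n) for d in domains}

    def signal(name: str) -> np.ndarray:
        lam = config.loading(name)
        return (
            lam * L
            + config.domain_shared_sd * shared[_DOMAIN_OF[name]]
            + config.noise(name) * rng.normal(size=n)
        )

    den = {
        "pop_total": areas["pop_total"].to_numpy(),
        "pop_working_age": areas["pop_working_age"].to_numpy(),
        "pop_youth": areas["pop_youth"].to_numpy(),
        "school_leavers": areas["school_leavers"].to_numpy(),
    }
    count_denoms = {
        "unemployment_benefit": "pop_working_age",
        "sickness_benefit": "pop_working_age",
        "overcrowded": "pop_total",
        "rented": "pop_total",
        "cancer_registrations": "pop_total",
        "infectious_hosp": "pop_total",
        "respiratory_hosp": "pop_total",
        "emergency_admissions": "pop_total",
        "edu_no_tertiary": "school_leavers",
        "neet": "pop_youth",
        "edu_left_young": "school_leavers",
        "no_qualifications": "pop_working_age",
        "edu_below_ncea2": "school_leavers",
    }

    cols: dict[str, np.ndarray] = {}
    for name, dkey in count_denoms.items():
        p = expit(logit(_BASE_RATES[name]) + signal(name))
        cols[name] = rng.binomial(den[dkey], p)
    for name, share in _OFFENCE_MIX.items():
        p = expit(logit(share * _VICTIMISATION_RATE) + signal(name))
        cols[name] = rng.binomial(den["pop_total"], p)
    # income support: per-capita dollars log-linear in the latent signal
    for name, mu in (("msd_payments", 6.0), ("ir_payments", 5.6)):
        cols[name] = den["pop_total"] * np.exp(mu + 0.6 * signal(name))
    # deaths: indirect-standardization target, Poisson around scaled expectation
    expected = areas[list(AGE_BANDS)].to_numpy() @ REFERENCE_RATES.to_numpy()
    cols["deaths"] = rng.poisson(expected * np.exp(0.45 * signal("deaths")))

    numerators = pd.DataFrame(cols, index=areas["area_id"].to_numpy())
    numerators.index.name = "area_id"

    outcomes = _generate_outcomes(L, areas, config)
    facilities = generate_facilities(
        list(ACCESS_CATEGORIES),
        config.facilities_per_category(),
        config.seed,
        areas=areas,
    )
    crosswalk = generate_crosswalk(
        areas, config.legacy_units(), config.seed, split_fraction=config.split_fraction
    )
    return SyntheticBundle(
        areas=areas,
        latent=latent,
        indicator_numerators=numerators,
        outcomes=outcomes,
        facilities=facilities,
        crosswalk=crosswalk,
        reference_rates=REFERENCE_RATES.copy(),
    )


def _generate_outcomes(
    L: np.ndarray, areas: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Smoking and household-poverty rates with Spearman(latent, outcome) on target.

    For bivariate normals Spearman's ρ_s relates to Pearson's r by
    ρ_s = (6/π)·arcsin(r/2); the generator inverts this so the *rank*
    correlation hits ``outcome_correlation``, then maps the Gaussian signal
    through a logistic curve (monotone, so ranks are preserved).
    """
    rng = _rng(config.seed, "outcomes")
    r = 2 * np.sin(np.pi * config.outcome_correlation / 6)
    out = {}
    for name, intercept, slope in (("smoking_rate", -1.9, 0.55), ("poverty_rate", -1.4, 0.55)):
        z = r * L + np.sqrt(1 - r**2) * rng.normal(size=len(L))
        out[name] = expit(intercept + slope * z)
    df = pd.DataFrame(out, index=areas["area_id"].to_numpy())
    df.index.name = "area_id"
    return df


def generate_facilities(
    categories: list[str],
    density: int,
    seed: int,
    areas: pd.DataFrame | None = None,
) -> FacilitySet:
    """Facility point locations, denser in urban cores than in rural zones.

    80% of each category's points sit near a randomly chosen urban area
    centroid; the rest scatter near any area centroid, so remote areas still
    have a (distant) nearest-three set.
    """
    if density < 3:
        raise ConfigurationError("need at least 3 facilities per category for nearest-3")
    rng = _rng(seed, "facilities")
    if areas is None:
        anchors = _parent_centres(20)
        urban_anchors = anchors
    else:
        anchors = areas[["x", "y"]].to_numpy()
        urban_mask = (areas["urban_rural"] == "U").to_numpy()
        urban_anchors = anchors[urban_mask] if urban_mask.any() else anchors
    points = {}
    for cat in categories:
        n_urban = int(round(0.8 * density))
        picks_u = urban_anchors[rng.integers(0, len(urban_anchors), size=n_urban)]
        picks_a = anchors[rng.integers(0, len(anchors), size=density - n_urban)]
        jitter_u = rng.normal(0, 2_000, size=(n_urban, 2))
        jitter_a = rng.normal(0, 5_000, size=(density - n_urban, 2))
        points[cat] = np.vstack([picks_u + jitter_u, picks_a + jitter_a])
    return FacilitySet(points=points)


def generate_crosswalk(
    areas: pd.DataFrame,
    n_legacy: int,
    seed: int,
    split_fraction: float = 0.0221,
) -> pd.DataFrame:
    """Legacy-unit → area crosswalk with population-proportional shares.

    Most legacy units sit wholly inside one area (share 1.0); a small
    fraction straddle two or three areas and are split in proportion to the
    target areas' populations.
    """
    if n_legacy < 1:
        raise ConfigurationError("n_legacy must be at least 1")
    rng = _rng(seed, "crosswalk")
    area_ids = areas["area_id"].to_numpy()
    pops = areas["pop_total"].to_numpy(dtype=float)
    n_areas = len(area_ids)
    weights = pops / pops.sum()

    width = len(str(n_legacy))
    legacy_rows, area_rows, share_rows = [], [], []
    split = rng.random(n_legacy) < split_fraction
    primary = rng.choice(n_areas, size=n_legacy, p=weights)
    for i in range(n_legacy):
        lid = f"M{i + 1:0{width}d}"
        if not split[i] or n_areas < 2:
            legacy_rows.append(lid)
            area_rows.append(area_ids[primary[i]])
            share_rows.append(1.0)
            continue
        n_targets = min(int(rng.integers(2, 4)), n_areas)
        others = rng.choice(n_areas, size=n_targets, replace=False)
        if primary[i] not in others:
            others[0] = primary[i]
        shares = pops[others] / pops[others].sum()
        for j, s in zip(others, shares):
            legacy_rows.append(lid)
            area_rows.append(area_ids[j])
            share_rows.append(float(s))
    return pd.DataFrame({"legacy_id": legacy_rows, "area_id": area_rows, "share": share_rows})


def generate_bundle(config: SyntheticConfig | None = None, **overrides) -> SyntheticBundle:
    """Convenience end-to-end generation under one config (or field overrides)."""
    config = replace(config, **overrides) if config else SyntheticConfig(**overrides)
    areas = generate_area_units(config)
    return generate_indicator_data(areas, config)
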