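"""Shipped configuration profiles.

``nz2013``
    The published 2013 configuration: fixed factor-analysis weights for the
    Health, Education and Access domains, 60/40 min-max housing weights, and
    domain weights 28/28/14/14/9/5/2.
``estimate``
    Identical structure, but factor-analysis weights are re-estimated from
    the data at hand instead of using the frozen published values.
"""

from __future__ import annotations

from .domains import DomainRecipe
from .indicators import ACCESS_CATEGORIES, IndicatorSpec, default_indicator_specs

DOMAIN_WEIGHTS = {
    "Income": 0.28,
    "Employment": 0.28,
    "Health": 0.14,
    "Education": 0.14,
    "Housing": 0.09,
    "Crime": 0.05,
    "Access": 0.02,
}

HOUSING_WEIGHTS = (0.6, 0.4)  # overcrowding, renting

HEALTH_WEIGHTS_2013 = {
    "cancer_registration_rate": 0.04,
    "smr": 0.08,
    "infectious_hosp_rate": 0.19,
    "respiratory_hosp_rate": 0.28,
    "emergency_admission_rate": 0.42,
}

EDUCATION_WEIGHTS_2013 = {
    "no_tertiary_rate": 0.06,
    "neet_rate": 0.13,
    "left_school_young_rate": 0.25,
    "no_qualifications_rate": 0.26,
    "below_ncea2_rate": 0.30,
}

ACCESS_WEIGHTS_2013 = {
    "dist_early_childhood_centre": 0.15,
    "dist_primary_school": 0.15,
    "dist_supermarket": 0.20,
    "dist_petrol_station": 0.23,
    "dist_gp_clinic": 0.26,
}

TRANSFORM_ANCHORS = {"top_score": 100.0, "mid_score": 50.0, "upper_tail": 0.10}

PROFILES = ("nz2013", "estimate")


def default_recipes(profile: str = "nz2013") -> list[DomainRecipe]:
    """The seven domain recipes under the requested weighting profile."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    fixed = profile == "nz2013"

    def fa(domain: str, weight_map: dict[str, float]) -> DomainRecipe:
        return DomainRecipe(
            domain=domain,
            method="fa_weighted",
            indicators=tuple(weight_map),
            fixed_weights=tuple(weight_map.values()) if fixed else None,
        )

    return [
        DomainRecipe("Employment", "sum_rate",
                     ("unemployment_benefit_rate", "sickness_benefit_rate")),
        DomainRecipe("Income", "sum_rate",
                     ("msd_payments_per_capita", "ir_payments_per_capita")),
        DomainRecipe("Crime", "sum_rate", ("victimisation_rate",)),
        DomainRecipe("Housing", "minmax_weighted",
                     ("overcrowding_rate", "renting_rate"), HOUSING_WEIGHTS),
        fa("Health", HEALTH_WEIGHTS_2013),
        fa("Education", EDUCATION_WEIGHTS_2013),
        fa("Access", ACCESS_WEIGHTS_2013),
    ]


__all__ = [
    "ACCESS_CATEGORIES",
    "ACCESS_WEIGHTS_2013",
    "DOMAIN_WEIGHTS",
    "EDUCATION_WEIGHTS_2013",
    "HEALTH_WEIGHTS_2013",
    "HOUSING_WEIGHTS",
    "IndicatorSpec",
    "PROFILES",
    "TRANSFORM_ANCHORS",
    "default_indicator_specs",
    "default_recipes",
]
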