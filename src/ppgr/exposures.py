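"""Canonical exposure and covariate vocabularies shared across the pipeline.

Every module that touches the meal-level analysis table refers to these
lists, so exposure names are validated in one place.
"""

from __future__ import annotations

#: Food-group flags collected at every logged meal (check-all-that-apply).
FOOD_GROUPS: list[str] = [
    "refined_grains",
    "whole_grains",
    "seafood",
    "chicken",
    "red_meat",
    "eggs",
    "dairy",
    "soy_food",
    "beans_or_nuts",
    "vegetables",
    "fruits",
    "deep_fried_food",
    "sweet_desserts",
    "sugary_beverages",
    "non_sugary_beverages",
]

#: Meal-anchored movement and sleep exposures, all in hours.
ACTIVITY_EXPOSURES: list[str] = [
    "pp_lpa_h",      # light-intensity activity in the 2-h postprandial window
    "pp_mvpa_h",     # moderate-to-vigorous activity in the 2-h postprandial window
    "daily_lpa_h",   # light-intensity activity in the 24 h before the meal
    "daily_mvpa_h",  # moderate-to-vigorous activity in the 24 h before the meal
    "sleep_h",       # sleep duration the night before the meal
]

#: Longitudinal exposures entering the association models (within/between pairs).
EXPOSURES: list[str] = FOOD_GROUPS + ["satiety"] + ACTIVITY_EXPOSURES

#: Meal time-of-day categories; morning is the modelling reference.
TIME_CATEGORIES: list[str] = [
    "morning_0600_1200",
    "afternoon_1200_1800",
    "evening_1800_2400",
]

#: Person-level covariates of the basic and full models (raw column names in
#: the analysis table; categorical ones are dummy-expanded by build_design).
BASELINE_COVARIATES: list[str] = [
    "age",
    "sex",
    "ethnicity",
    "education",
    "smoker",
    "heavy_alcohol",
    "bmi",
]

ETHNICITIES: list[str] = ["Chinese", "Malay", "Indian"]
EDUCATION_LEVELS: list[str] = ["secondary_or_below", "a_level", "university_or_above"]


def validate_exposure_names(names) -> None:
    """Raise ValueError if any name is not a canonical exposure."""
    bad = [n for n in names if n not in EXPOSURES]
    if bad:
        raise ValueError(
            f"unknown exposure name(s): {bad!r}; canonical names are {EXPOSURES!r}"
        )
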