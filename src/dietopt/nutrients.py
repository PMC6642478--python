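"""Canonical nutrient registry, units, energy-conversion factors and food taxonomy.

Every table that flows through the package (compositions, recommendations,
constraint rows) refers to nutrients by the canonical names defined here.
Amounts are always *per day* for diets and *per 100 g edible portion* for
food compositions.  Units are fixed per nutrient: kcal for energy, grams for
macronutrients and fiber, milligrams for minerals and most vitamins,
micrograms for vitamin A (RAE), vitamin B12, vitamin D, and folate (DFE).
"""

from __future__ import annotations

ENERGY = "energy"

#: Canonical nutrient -> unit.  This is the unit registry used by the CSV
#: readers to validate column sets and by reporting code to label outputs.
NUTRIENT_UNITS: dict[str, str] = {
    "energy": "kcal",
    "carbohydrate": "g",
    "protein": "g",
    "total_fat": "g",
    "saturated_fat": "g",
    "trans_fat": "g",
    "free_sugar": "g",
    "fiber": "g",
    "sodium": "mg",
    "calcium": "mg",
    "copper": "mg",
    "iron": "mg",
    "phosphorus": "mg",
    "magnesium": "mg",
    "zinc": "mg",
    "niacin": "mg",
    "vitamin_a": "mcg",
    "thiamin": "mg",
    "riboflavin": "mg",
    "vitamin_b6": "mg",
    "vitamin_b12": "mcg",
    "vitamin_c": "mg",
    "vitamin_d": "mcg",
    "vitamin_e": "mg",
    "folate": "mcg",
}

NUTRIENTS = tuple(NUTRIENT_UNITS)

#: Energy-conversion (Atwater) factors, kcal per gram.  Fiber contributes no
#: energy.  Free sugar is part of carbohydrate; saturated and trans fat are
#: part of total fat.
ATWATER_KCAL_PER_G: dict[str, float] = {
    "carbohydrate": 4.0,
    "protein": 4.0,
    "free_sugar": 4.0,
    "total_fat": 9.0,
    "saturated_fat": 9.0,
    "trans_fat": 9.0,
}

#: The seven food groups used to categorize items.
FOOD_GROUPS = (
    "fruits_vegetables",
    "seeds_legumes",
    "cereals",
    "dairy",
    "meats_eggs",
    "oils",
    "other",
)

#: The 26 food subgroups and the group each belongs to.
SUBGROUP_TO_GROUP: dict[str, str] = {
    "leafy_vegetables": "fruits_vegetables",
    "other_vegetables": "fruits_vegetables",
    "tuber": "fruits_vegetables",
    "fruits": "fruits_vegetables",
    "beans": "seeds_legumes",
    "nuts": "seeds_legumes",
    "rice": "cereals",
    "whole_cereals": "cereals",
    "pasta": "cereals",
    "cake_cookies": "cereals",
    "breads": "cereals",
    "cheese": "dairy",
    "yogurt": "dairy",
    "nonfat_milk": "dairy",
    "milk": "dairy",
    "red_meat": "meats_eggs",
    "chicken": "meats_eggs",
    "processed_meat": "meats_eggs",
    "eggs": "meats_eggs",
    "fish_seafood": "meats_eggs",
    "margarine_butter": "oils",
    "olive_oil": "oils",
    "ssb": "other",
    "snacks": "other",
    "sweets": "other",
    "manioc_flour": "other",
}

SUBGROUPS = tuple(SUBGROUP_TO_GROUP)

#: Subgroups counted against the red + processed meat cap.
RED_PROCESSED_MEAT_SUBGROUPS = frozenset({"red_meat", "processed_meat"})

#: Cap on red + processed meat, grams per week.
WEEKLY_RED_PROCESSED_MEAT_CAP_G = 500.0


def percent_energy(nutrient: str, grams_per_day: float, energy_kcal: float) -> float:
    """Share of total energy (in %) contributed by ``grams_per_day`` of a
    macronutrient, using the fixed energy-conversion factors."""
    if nutrient not in ATWATER_KCAL_PER_G:
        raise KeyError(f"no energy-conversion factor for nutrient {nutrient!r}")
    if energy_kcal <= 0:
        raise ValueError("energy must be positive to express a %kcal share")
    return 100.0 * ATWATER_KCAL_PER_G[nutrient] * grams_per_day / energy_kcal


def grams_for_percent_energy(nutrient: str, percent: float, energy_kcal: float) -> float:
    """Grams per day corresponding to a given share (%) of total energy."""
    if nutrient not in ATWATER_KCAL_PER_G:
        raise KeyError(f"no energy-conversion factor for nutrient {nutrient!r}")
    return percent / 100.0 * energy_kcal / ATWATER_KCAL_PER_G[nutrient]


def validate_nutrient(name: str) -> str:
    if name not in NUTRIENT_UNITS:
        raise KeyError(f"unknown nutrient {name!r}; known: {sorted(NUTRIENT_UNITS)}")
    return name
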