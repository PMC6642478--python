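"""Nutrient targets and constraint-set assembly.

The default recommendation table holds the nutritional constraint rows
imposed on every model: macronutrient shares of energy, a fiber floor,
caps on free sugar, saturated and trans fat, an energy equality, a sodium
cap at the observed content, and RDA-derived absolute floors for sixteen
micronutrients.  :func:`build_constraint_set` instantiates those rows for
one stratum, adds the observed-linked rows (beneficial-nutrient floors,
harmful-component caps), the red + processed meat cap, the per-food
acceptability bounds and, for cost-constrained models, the cost row.

%kcal rows are converted to linear gram-space rows using the stratum's
(fixed) observed energy and the Atwater factors, so the whole model stays
linear in the food quantities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InvalidInputError
from .food_data import FoodItem, StratumProfile
from .nutrients import (
    ATWATER_KCAL_PER_G,
    ENERGY,
    RED_PROCESSED_MEAT_SUBGROUPS,
    WEEKLY_RED_PROCESSED_MEAT_CAP_G,
    grams_for_percent_energy,
    validate_nutrient,
)

__all__ = [
    "RdaEntry",
    "NutrientConstraint",
    "LinearRow",
    "ConstraintSet",
    "weighted_rda_bound",
    "default_table1",
    "build_constraint_set",
    "nutritional_rows",
    "read_rda",
    "read_population",
    "apply_rda",
    "load_constraint_overrides",
]

#: Nutrients whose optimized content may not fall below the observed mean
#: (the RDA-floored micronutrients plus fiber).
BENEFICIAL_NUTRIENTS = (
    "fiber",
    "calcium",
    "copper",
    "iron",
    "phosphorus",
    "magnesium",
    "zinc",
    "niacin",
    "vitamin_a",
    "thiamin",
    "riboflavin",
    "vitamin_b6",
    "vitamin_b12",
    "vitamin_c",
    "vitamin_d",
    "vitamin_e",
    "folate",
)

#: Components whose optimized content may not exceed the observed mean.
HARMFUL_COMPONENTS = ("sodium", "saturated_fat", "trans_fat", "free_sugar")

#: RDA-derived absolute daily floors (registry units per nutrient).
RDA_FLOORS: dict[str, float] = {
    "calcium": 1021.0,
    "copper": 1.1,
    "iron": 10.7,
    "phosphorus": 888.0,
    "magnesium": 377.0,
    "zinc": 11.7,
    "niacin": 16.4,
    "vitamin_a": 803.0,
    "thiamin": 1.3,
    "riboflavin": 1.5,
    "vitamin_b6": 1.6,
    "vitamin_b12": 4.2,
    "vitamin_c": 84.0,
    "vitamin_d": 10.0,
    "vitamin_e": 12.0,
    "folate": 426.0,
}


@dataclass(frozen=True)
class RdaEntry:
    nutrient: str
    age_sex_group: str
    rda_value: float

    def __post_init__(self) -> None:
        validate_nutrient(self.nutrient)
        if self.rda_value <= 0:
            raise InvalidInputError("rda_value must be > 0")


@dataclass(frozen=True)
class NutrientConstraint:
    """One recommendation row before instantiation for a stratum.

    ``basis`` is ``"absolute"`` (amount/day), ``"percent_energy"`` (%kcal,
    converted at build time) or ``"observed"`` (bound taken from the
    stratum's observed content).  ``direction`` is ``ge``, ``le``, ``range``
    or ``eq``; strict inequalities of the source recommendations are carried
    as non-strict bounds, the LP convention.
    """

    nutrient: str
    basis: str
    direction: str
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        validate_nutrient(self.nutrient)
        if self.basis not in ("absolute", "percent_energy", "observed"):
            raise InvalidInputError(f"unknown basis {self.basis!r}")
        if self.direction not in ("ge", "le", "range", "eq"):
            raise InvalidInputError(f"unknown direction {self.direction!r}")
        if self.direction == "range":
            if self.lower is None or self.upper is None or self.lower > self.upper:
                raise InvalidInputError("range bounds must be ordered")
        if self.basis == "percent_energy":
            for bound in (self.lower, self.upper):
                if bound is not None and not (0.0 <= bound <= 100.0):
                    raise InvalidInputError("%kcal bounds must lie in [0, 100]")


@dataclass(frozen=True)
class LinearRow:
    """One single-sided linear constraint over the food-quantity vector.

    Either ``nutrient`` is set (coefficients are the foods' densities / 100)
    or ``foods`` is set (unit coefficient on the listed foods, e.g. the meat
    cap).  ``relaxable`` marks nutritional rows eligible for goal-programming
    relaxation; acceptability, energy and cost are never relaxed.
    """

    name: str
    sense: str  # "ge" | "le"
    rhs: float
    nutrient: str | None = None
    foods: tuple[str, ...] | None = None
    relaxable: bool = False

    def __post_init__(self) -> None:
        if self.sense not in ("ge", "le"):
            raise InvalidInputError(f"sense must be 'ge' or 'le', got {self.sense!r}")
        if (self.nutrient is None) == (self.foods is None):
            raise InvalidInputError("exactly one of nutrient/foods must be set")
        if self.nutrient is not None:
            validate_nutrient(self.nutrient)

    def coefficients(self, food_items: Sequence[FoodItem]) -> np.ndarray:
        if self.nutrient is not None:
            return np.array(
                [f.composition.get(self.nutrient, 0.0) / 100.0 for f in food_items]
            )
        members = set(self.foods or ())
        return np.array([1.0 if f.id in members else 0.0 for f in food_items])

    def satisfied_by(self, value: float, rel_tol: float = 1e-6) -> bool:
        slack = rel_tol * max(1.0, abs(self.rhs))
        if self.sense == "ge":
            return value >= self.rhs - slack
        return value <= self.rhs + slack


@dataclass(frozen=True)
class ConstraintSet:
    """Everything imposed on one model besides the objective.

    ``rows`` are the nutritional and food-group rows (single-sided); the
    energy equality is the scalar ``energy_kcal`` with tolerance
    ``energy_tol``; ``cost_limit`` is ``None`` for cost-free models;
    ``acceptability`` maps each stratum food to its (lower, upper) g/day
    bounds; ``reference_intake`` holds the positive denominators used for
    relative food deviations (observed intake, or the region mean for
    introduced foods).
    """

    rows: tuple[LinearRow, ...]
    energy_kcal: float
    acceptability: Mapping[str, tuple[float, float]]
    reference_intake: Mapping[str, float]
    energy_tol: float = 0.5
    cost_limit: float | None = None
    cost_equality: bool = False
    level: str | None = None
    cost_regime: str | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def weighted_rda_bound(
    entries: Iterable[RdaEntry], group_frequencies: Mapping[str, float]
) -> float:
    """Population-weighted mean RDA over age-sex groups for one nutrient."""
    entries = list(entries)
    if not entries:
        raise InvalidInputError("at least one RDA entry is required")
    total = math.fsum(group_frequencies.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidInputError(f"group frequencies must sum to 1, got {total}")
    by_group = {e.age_sex_group: e.rda_value for e in entries}
    missing = set(group_frequencies) - set(by_group)
    if missing:
        raise InvalidInputError(f"missing RDA entries for groups: {sorted(missing)}")
    return math.fsum(freq * by_group[g] for g, freq in group_frequencies.items())


def default_table1() -> list[NutrientConstraint]:
    """The default nutritional recommendation table (25 rows): energy
    equality, macronutrient %kcal rows, fiber floor, sodium cap at observed,
    and the sixteen RDA-derived absolute micronutrient floors."""
    rows = [
        NutrientConstraint("energy", "observed", "eq"),
        NutrientConstraint("carbohydrate", "percent_energy", "range", 45.0, 55.0),
        NutrientConstraint("free_sugar", "percent_energy", "le", upper=10.0),
        NutrientConstraint("fiber", "absolute", "ge", lower=31.0),
        NutrientConstraint("protein", "percent_energy", "ge", lower=10.0),
        NutrientConstraint("total_fat", "percent_energy", "range", 25.0, 35.0),
        NutrientConstraint("saturated_fat", "percent_energy", "le", upper=10.0),
        NutrientConstraint("trans_fat", "percent_energy", "le", upper=1.0),
        NutrientConstraint("sodium", "observed", "le"),
    ]
    rows.extend(
        NutrientConstraint(n, "absolute", "ge", lower=floor)
        for n, floor in RDA_FLOORS.items()
    )
    return rows


def nutritional_rows(
    table1: Sequence[NutrientConstraint],
    energy_kcal: float,
    observed_nutrients: Mapping[str, float],
) -> list[LinearRow]:
    """Instantiate recommendation rows as single-sided gram-space rows for a
    stratum with the given observed energy and nutrient vector.  The energy
    equality is excluded (it is held separately)."""
    rows: list[LinearRow] = []
    for nc in table1:
        n = nc.nutrient
        if n == ENERGY:
            continue
        if nc.basis == "percent_energy":
            lo = (
                grams_for_percent_energy(n, nc.lower, energy_kcal)
                if nc.lower is not None
                else None
            )
            hi = (
                grams_for_percent_energy(n, nc.upper, energy_kcal)
                if nc.upper is not None
                else None
            )
        elif nc.basis == "absolute":
            lo, hi = nc.lower, nc.upper
        else:  # observed
            obs = observed_nutrients.get(n, 0.0)
            lo = obs if nc.direction in ("ge", "eq") else None
            hi = obs if nc.direction in ("le", "eq") else None
        suffix = "_obs" if nc.basis == "observed" else ""
        if nc.direction in ("ge", "range", "eq") and lo is not None:
            rows.append(LinearRow(f"{n}_min{suffix}", "ge", lo, nutrient=n, relaxable=True))
        if nc.direction in ("le", "range", "eq") and hi is not None:
            rows.append(LinearRow(f"{n}_max{suffix}", "le", hi, nutrient=n, relaxable=True))
    return rows


def build_constraint_set(
    stratum: StratumProfile,
    food_items: Sequence[FoodItem],
    level: str,
    cost_regime: str,
    table1: Sequence[NutrientConstraint] | None = None,
    bounds=None,
    *,
    cost_equality: bool = False,
    energy_tol: float = 0.5,
    extra_rows: Sequence[LinearRow] = (),
) -> ConstraintSet:
    """Complete constraint set for one (stratum, scenario) model.

    ``bounds`` is an :class:`~dietopt.acceptability.AcceptabilityBounds` for
    the stratum's region (or a plain mapping food -> (lower, upper)).  Foods
    with ``Q_obs = 0`` (introduced from elsewhere in the state) get a lower
    bound of 0 so introduction stays optional, and their relative-deviation
    denominator is the region mean intake.
    """
    if cost_regime not in ("free", "constrained"):
        raise InvalidInputError(f"unknown cost regime {cost_regime!r}")
    table1 = list(table1) if table1 is not None else default_table1()

    rows = nutritional_rows(table1, stratum.observed_energy, stratum.observed_nutrients)
    present = {r.name for r in rows}

    # Observed-linked floors for beneficial nutrients and caps for harmful
    # components (sodium's observed cap comes from the recommendation table).
    for n in BENEFICIAL_NUTRIENTS:
        obs = stratum.observed_nutrients.get(n, 0.0)
        if obs > 0 and f"{n}_min_obs" not in present:
            rows.append(LinearRow(f"{n}_min_obs", "ge", obs, nutrient=n, relaxable=True))
    for n in HARMFUL_COMPONENTS:
        if f"{n}_max_obs" in present:
            continue
        obs = stratum.observed_nutrients.get(n, 0.0)
        rows.append(LinearRow(f"{n}_max_obs", "le", obs, nutrient=n, relaxable=True))

    # Red + processed meat cap, expressed per day.
    subgroup_of = {f.id: f.subgroup for f in food_items}
    meat_ids = tuple(
        sorted(
            fid
            for fid in stratum.foods
            if subgroup_of.get(fid) in RED_PROCESSED_MEAT_SUBGROUPS
        )
    )
    if meat_ids:
        rows.append(
            LinearRow(
                "red_processed_meat_max",
                "le",
                WEEKLY_RED_PROCESSED_MEAT_CAP_G / 7.0,
                foods=meat_ids,
                relaxable=False,
            )
        )
    rows.extend(extra_rows)

    # Referenced nutrients must exist in every composition (possibly 0).
    referenced = {r.nutrient for r in rows if r.nutrient is not None} | {ENERGY}
    for item in food_items:
        missing = referenced - set(item.composition)
        if missing:
            raise ConfigurationError(
                f"food {item.id!r} lacks composition entries for {sorted(missing)}"
            )

    # Acceptability bounds and deviation references per stratum food.
    lower_of, upper_of, ref_of = _bounds_lookup(bounds)
    acceptability: dict[str, tuple[float, float]] = {}
    reference: dict[str, float] = {}
    for fid in stratum.foods:
        if fid not in lower_of:
            warnings.warn(
                f"food {fid!r} absent from acceptability table; bounds set to (0, 0)",
                stacklevel=2,
            )
        lo = lower_of.get(fid, 0.0)
        hi = upper_of.get(fid, 0.0)
        if lo > hi:
            raise ConfigurationError(f"food {fid!r}: lower bound {lo} > upper bound {hi}")
        q = stratum.q_obs.get(fid, 0.0)
        if q == 0.0:
            lo = 0.0
        acceptability[fid] = (lo, hi)
        reference[fid] = q if q > 0 else ref_of.get(fid, 0.0)

    return ConstraintSet(
        rows=tuple(rows),
        energy_kcal=stratum.observed_energy,
        acceptability=acceptability,
        reference_intake=reference,
        energy_tol=energy_tol,
        cost_limit=stratum.observed_cost if cost_regime == "constrained" else None,
        cost_equality=cost_equality,
        level=level,
        cost_regime=cost_regime,
    )


def _bounds_lookup(bounds):
    """Accept an AcceptabilityBounds or a plain mapping food -> (lo, hi)."""
    if bounds is None:
        raise ConfigurationError("acceptability bounds are required")
    if hasattr(bounds, "lower") and hasattr(bounds, "upper"):
        return bounds.lower, bounds.upper, getattr(bounds, "ref_mean", {})
    lower = {f: b[0] for f, b in bounds.items()}
    upper = {f: b[1] for f, b in bounds.items()}
    return lower, upper, {}


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------


def read_rda(path: str | Path) -> list[RdaEntry]:
    """Read ``rda.csv``: nutrient, age_sex_group, value."""
    df = pd.read_csv(path, dtype={"nutrient": str, "age_sex_group": str})
    return [
        RdaEntry(str(r.nutrient), str(r.age_sex_group), float(r.value))
        for r in df.itertuples()
    ]


def read_population(path: str | Path) -> dict[str, float]:
    """Read ``population.csv``: group, fraction."""
    df = pd.read_csv(path, dtype={"group": str})
    return {str(r.group): float(r.fraction) for r in df.itertuples()}


def apply_rda(
    table1: Sequence[NutrientConstraint],
    rda_entries: Sequence[RdaEntry],
    group_frequencies: Mapping[str, float],
) -> list[NutrientConstraint]:
    """Replace absolute floors with population-weighted RDA bounds for every
    nutrient present in the RDA table."""
    by_nutrient: dict[str, list[RdaEntry]] = {}
    for e in rda_entries:
        by_nutrient.setdefault(e.nutrient, []).append(e)
    out = []
    for nc in table1:
        if nc.basis == "absolute" and nc.direction == "ge" and nc.nutrient in by_nutrient:
            bound = weighted_rda_bound(by_nutrient[nc.nutrient], group_frequencies)
            out.append(replace(nc, lower=bound))
        else:
            out.append(nc)
    return out


def load_constraint_overrides(
    path: str | Path, base: Sequence[NutrientConstraint] | None = None
) -> list[NutrientConstraint]:
    """Apply a ``constraints.yaml`` override file on top of the defaults.

    The file maps nutrient names to mappings with any of ``basis``,
    ``direction``, ``lower``, ``upper``; nutrients not mentioned keep their
    default row, and a nutrient mapped to ``null`` is dropped.
    """
    base = list(base) if base is not None else default_table1()
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, dict):
        raise InvalidInputError("constraints.yaml must map nutrient -> settings")
    out: list[NutrientConstraint] = []
    seen = set()
    for nc in base:
        if nc.nutrient in overrides:
            seen.add(nc.nutrient)
            override = overrides[nc.nutrient]
            if override is None:
                continue
            out.append(replace(nc, **override))
        else:
            out.append(nc)
    for nutrient, override in overrides.items():
        if nutrient in seen or override is None:
            continue
        out.append(NutrientConstraint(nutrient=nutrient, **override))
    return out
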