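"""Synthetic survey-like inputs with controlled statistical structure.

The generator emulates the *derived* structure of a household budget /
dietary survey: a universe of ~105 food items in 26 subgroups with
group-typical nutrient densities and log-normal positive prices; geographic
strata whose observed mean diets carry ~1,800 kcal/day; and a full
("all-income") collection of strata from which acceptability percentiles
are taken, with the optimization sample a nested subset (as when bounds are
derived from the whole population but models run on low-income strata).

Densities start from a packaged template table (``data/group_densities.csv``)
and are calibrated so that a reference diet — subgroup-typical amounts
rescaled to the energy target — reproduces a chosen nutrient profile:

* ``natural`` mode targets a profile typical of a low-income middle-income
  country population (most floors met; calcium, magnesium, vitamins D and
  E, and fiber short), so step-1 models are generally infeasible and the
  goal-programming step is exercised;
* ``feasible`` mode targets every floor with a 25% margin;
* ``infeasible:<nutrient>`` additionally makes one floor unattainable.

A single integer seed drives named RNG streams (one per generator stage),
so adding a stage never perturbs earlier streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acceptability import LEVELS, AcceptabilityBounds
from .errors import GeneratorError, InvalidInputError
from .food_data import (
    FoodItem,
    IntakeRecord,
    PriceRecord,
    StratumProfile,
    build_stratum_profile,
)
from .nutrients import ATWATER_KCAL_PER_G, NUTRIENT_UNITS, SUBGROUP_TO_GROUP
from .optimizer import solve_step1, build_step1_model
from .recommendations import (
    ConstraintSet,
    LinearRow,
    NutrientConstraint,
    RDA_FLOORS,
    build_constraint_set,
    default_table1,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticSurvey",
    "SyntheticInstance",
    "InfeasibleInstance",
    "WorkedExample",
    "generate_food_universe",
    "generate_strata",
    "generate_feasible_instance",
    "generate_infeasible_instance",
    "worked_example_floor",
    "worked_example_cap",
    "generate_intake_records",
    "generate_price_records",
]

_STREAMS = {
    "universe": 0,
    "strata": 1,
    "feasible": 2,
    "infeasible": 3,
    "intakes": 4,
    "prices": 5,
}

_MACROS = ("carbohydrate", "protein", "total_fat")
_MICROS = tuple(RDA_FLOORS) + ("fiber", "sodium")

#: Reference nutrient profile for the ``natural`` mode: energy shares for
#: the macronutrients (%kcal) and daily amounts for fiber, sodium and the
#: RDA-floored micronutrients, chosen to mimic a low-income population in
#: which calcium, magnesium, vitamins D and E and fiber run short of their
#: recommendations while most other floors are met.
NATURAL_SHARES = {"carbohydrate": 51.7, "protein": 18.3, "total_fat": 30.0}
NATURAL_COMPONENT_SHARES = {"free_sugar": 8.4, "saturated_fat": 10.4, "trans_fat": 1.15}
NATURAL_MICRO_TARGETS = {
    "fiber": 19.9,
    "sodium": 2995.0,
    "calcium": 456.0,
    "copper": 1.32,
    "iron": 11.57,
    "phosphorus": 975.0,
    "magnesium": 228.9,
    "zinc": 10.9,
    "niacin": 25.1,
    "vitamin_a": 632.0,
    "thiamin": 1.14,
    "riboflavin": 1.37,
    "vitamin_b6": 1.43,
    "vitamin_b12": 6.12,
    "vitamin_c": 44.5,
    "vitamin_d": 3.32,
    "vitamin_e": 5.47,
    "folate": 416.0,
}

FEASIBLE_SHARES = {"carbohydrate": 51.0, "protein": 17.5, "total_fat": 31.5}
FEASIBLE_COMPONENT_SHARES = {"free_sugar": 6.0, "saturated_fat": 8.5, "trans_fat": 0.5}
_FEASIBLE_MARGIN = 1.25


def _feasible_micro_targets() -> dict[str, float]:
    targets = {n: _FEASIBLE_MARGIN * floor for n, floor in RDA_FLOORS.items()}
    targets["fiber"] = _FEASIBLE_MARGIN * 31.0
    targets["sodium"] = 2995.0
    return targets


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stage],))
    )


def _template() -> pd.DataFrame:
    with resources.files("dietopt.data").joinpath("group_densities.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("subgroup")


@dataclass(frozen=True)
class SyntheticConfig:
    n_regions: int = 5
    n_strata: int = 89
    low_income_fraction: float = 0.5
    n_foods: int = 105
    foods_per_stratum: tuple[int, int] = (37, 92)
    energy_target_kcal: float = 1792.0
    energy_jitter: float = 0.005
    price_sigma: float = 0.35
    density_sigma: float = 0.25
    intake_sigma: float = 0.4
    feasibility: str = "natural"

    def __post_init__(self) -> None:
        if not (1 <= self.n_regions <= self.n_strata):
            raise InvalidInputError("need n_strata >= n_regions >= 1")
        lo, hi = self.foods_per_stratum
        if not (1 <= lo <= hi):
            raise InvalidInputError("foods_per_stratum range invalid")
        if not (0.0 < self.low_income_fraction <= 1.0):
            raise InvalidInputError("low_income_fraction must be in (0, 1]")
        if self.energy_target_kcal <= 0:
            raise InvalidInputError("energy target must be positive")
        mode = self.feasibility
        if mode not in ("natural", "feasible") and not mode.startswith("infeasible:"):
            raise InvalidInputError(f"unknown feasibility mode {mode!r}")


@dataclass
class SyntheticSurvey:
    """Universe + optimization strata + the full collection of strata means
    (for acceptability percentiles); the optimization sample is a subset."""

    foods: list[FoodItem]
    profiles: list[StratumProfile]
    all_means: dict[str, dict[str, float]]
    region_of: dict[str, str]
    state_of: dict[str, str]
    config: SyntheticConfig


@dataclass
class SyntheticInstance:
    """One stratum with foods, per-level acceptability bounds and the
    recommendation table; enough to build any scenario's constraint set."""

    stratum: StratumProfile
    foods: list[FoodItem]
    bounds_by_level: dict[str, AcceptabilityBounds]
    table1: list[NutrientConstraint] = field(default_factory=default_table1)

    def constraint_set(
        self, level: str = "moderate", cost_regime: str = "free", **kwargs
    ) -> ConstraintSet:
        return build_constraint_set(
            self.stratum,
            self.foods,
            level,
            cost_regime,
            table1=self.table1,
            bounds=self.bounds_by_level[level],
            **kwargs,
        )


@dataclass
class InfeasibleInstance:
    instance: SyntheticInstance
    nutrient: str
    target: float
    max_attainable: float
    carrier: str

    @property
    def expected_deviation(self) -> float:
        return self.target - self.max_attainable


@dataclass
class WorkedExample:
    """Tiny two-food instance whose step-2 deviation is known exactly."""

    stratum: StratumProfile
    foods: list[FoodItem]
    constraint_set: ConstraintSet
    row_name: str
    target: float
    expected_deviation: float


# ---------------------------------------------------------------------------
# Universe generation and calibration
# ---------------------------------------------------------------------------


def _allocate_counts(n_foods: int, subgroups: Sequence[str]) -> dict[str, int]:
    base, extra = divmod(n_foods, len(subgroups))
    return {s: base + (1 if i < extra else 0) for i, s in enumerate(subgroups)}


def generate_food_universe(config: SyntheticConfig, seed: int) -> list[FoodItem]:
    """Food items with group-typical densities and log-normal prices,
    calibrated to the configured feasibility mode; reproducible per seed."""
    rng = _rng(seed, "universe")
    tpl = _template()
    counts = _allocate_counts(config.n_foods, list(tpl.index))
    micros_no_na = [m for m in _MICROS]

    foods: list[FoodItem] = []
    for subgroup, count in counts.items():
        row = tpl.loc[subgroup]
        for k in range(count):
            jitter = lambda sigma: float(rng.lognormal(-0.5 * sigma**2, sigma))
            comp = dict.fromkeys(NUTRIENT_UNITS, 0.0)
            for macro in _MACROS:
                comp[macro] = float(row[macro]) * jitter(config.density_sigma)
            comp["free_sugar"] = min(
                float(row["free_sugar_frac"]) * jitter(0.1), 0.95
            ) * comp["carbohydrate"]
            comp["saturated_fat"] = min(
                float(row["sat_frac"]) * jitter(0.1), 0.95
            ) * comp["total_fat"]
            comp["trans_fat"] = min(float(row["trans_frac"]) * jitter(0.1), 0.2) * comp[
                "total_fat"
            ]
            for micro in micros_no_na:
                comp[micro] = float(row[micro]) * jitter(config.density_sigma)
            comp["energy"] = (
                4.0 * comp["carbohydrate"] + 4.0 * comp["protein"] + 9.0 * comp["total_fat"]
            )
            price = float(row["price_per_100g"]) * jitter(config.price_sigma)
            foods.append(
                FoodItem(
                    id=f"{subgroup}_{k:02d}",
                    name=f"{subgroup.replace('_', ' ')} {k + 1}",
                    group=SUBGROUP_TO_GROUP[subgroup],
                    subgroup=subgroup,
                    composition=comp,
                    price=max(price, 0.01),
                )
            )

    mode = config.feasibility
    if mode == "natural":
        foods = _calibrate_universe(
            foods, config, NATURAL_SHARES, NATURAL_COMPONENT_SHARES, NATURAL_MICRO_TARGETS
        )
    else:
        foods = _calibrate_universe(
            foods,
            config,
            FEASIBLE_SHARES,
            FEASIBLE_COMPONENT_SHARES,
            _feasible_micro_targets(),
        )
        if mode.startswith("infeasible:"):
            nutrient = mode.split(":", 1)[1]
            if nutrient not in NUTRIENT_UNITS:
                raise InvalidInputError(f"unknown nutrient {nutrient!r}")
            foods = [
                replace(
                    f,
                    composition={
                        **f.composition,
                        nutrient: 0.05 * f.composition.get(nutrient, 0.0),
                    },
                )
                for f in foods
            ]
    return foods


def _reference_diet(foods: Sequence[FoodItem], energy_target: float) -> dict[str, float]:
    """Subgroup-typical amounts spread evenly over each subgroup's foods and
    rescaled to the energy target."""
    tpl = _template()
    by_subgroup: dict[str, list[FoodItem]] = {}
    for f in foods:
        by_subgroup.setdefault(f.subgroup, []).append(f)
    diet = {}
    for subgroup, members in by_subgroup.items():
        amount = float(tpl.loc[subgroup, "typical_g_day"]) / len(members)
        for f in members:
            diet[f.id] = amount
    energy = sum(
        diet[f.id] * f.composition.get("energy", 0.0) / 100.0 for f in foods
    )
    scale = energy_target / energy
    return {fid: g * scale for fid, g in diet.items()}


def _calibrate_universe(
    foods: list[FoodItem],
    config: SyntheticConfig,
    macro_shares: Mapping[str, float],
    component_shares: Mapping[str, float],
    micro_targets: Mapping[str, float],
) -> list[FoodItem]:
    """Globally rescale densities so the reference diet hits the target
    macronutrient shares, component shares and micronutrient amounts."""
    ref = _reference_diet(foods, config.energy_target_kcal)
    return _calibrate_with_diet(foods, ref, macro_shares, component_shares, micro_targets)


# ---------------------------------------------------------------------------
# Strata generation
# ---------------------------------------------------------------------------


def generate_strata(
    config: SyntheticConfig, seed: int, universe: Sequence[FoodItem] | None = None
) -> SyntheticSurvey:
    """Strata with observed mean diets near the energy target.

    Returns the optimization profiles (the "low-income" subset, nested in
    the full collection) together with the full collection of strata means
    used for acceptability percentiles.
    """
    rng = _rng(seed, "strata")
    foods = list(universe) if universe is not None else generate_food_universe(config, seed)
    index = {f.id: f for f in foods}
    tpl = _template()

    n_total = max(config.n_strata, math.ceil(config.n_strata / config.low_income_fraction))
    regions = [f"R{i + 1}" for i in range(config.n_regions)]
    all_means: dict[str, dict[str, float]] = {}
    region_of: dict[str, str] = {}
    state_of: dict[str, str] = {}

    food_ids = np.array([f.id for f in foods])
    lo, hi = config.foods_per_stratum
    for i in range(n_total):
        sid = f"GS{i + 1:03d}"
        region = regions[i % len(regions)]
        region_of[sid] = region
        state_of[sid] = f"{region}_state{(i // len(regions)) % 2 + 1}"

        n_i = int(rng.integers(lo, min(hi, len(foods)) + 1))
        chosen = rng.choice(food_ids, size=n_i, replace=False)
        by_subgroup: dict[str, list[str]] = {}
        for fid in chosen:
            by_subgroup.setdefault(index[fid].subgroup, []).append(fid)

        q: dict[str, float] = {}
        for subgroup, members in by_subgroup.items():
            amount = float(tpl.loc[subgroup, "typical_g_day"]) * float(
                rng.lognormal(-0.5 * config.intake_sigma**2, config.intake_sigma)
            )
            weights = rng.dirichlet(np.ones(len(members)) * 4.0)
            for fid, w in zip(sorted(members), weights):
                q[fid] = amount * float(w)

        energy = sum(g * index[f].composition["energy"] / 100.0 for f, g in q.items())
        target = config.energy_target_kcal * (
            1.0 + float(rng.uniform(-1.0, 1.0)) * config.energy_jitter
        )
        scale = target / energy
        all_means[sid] = {f: g * scale for f, g in q.items()}

    low_income = sorted(
        rng.choice(sorted(all_means), size=config.n_strata, replace=False).tolist()
    )
    reported_by_state: dict[str, set[str]] = {}
    for sid, means in all_means.items():
        if sid in low_income:
            reported_by_state.setdefault(state_of[sid], set()).update(
                f for f, g in means.items() if g > 0
            )

    profiles = []
    for sid in low_income:
        q_obs = dict(all_means[sid])
        for food in reported_by_state.get(state_of[sid], set()):
            q_obs.setdefault(food, 0.0)
        profiles.append(build_stratum_profile(sid, region_of[sid], q_obs, index))

    return SyntheticSurvey(
        foods=foods,
        profiles=profiles,
        all_means=all_means,
        region_of=region_of,
        state_of=state_of,
        config=config,
    )


# ---------------------------------------------------------------------------
# Guaranteed fixtures
# ---------------------------------------------------------------------------

_LEVEL_UPPER_MULT = {"rigorous": 1.5, "moderate": 1.75, "flexible": 2.1}
_LOWER_MULT = 0.5
_DEFICIT_SUBGROUPS = ("milk", "yogurt", "nonfat_milk", "cheese", "fruits")
_FIXTURE_MARGIN = 1.15


def _fixture_bounds(q_obs: Mapping[str, float]) -> dict[str, AcceptabilityBounds]:
    out = {}
    for level in LEVELS:
        mult = _LEVEL_UPPER_MULT[level]
        out[level] = AcceptabilityBounds(
            region="R1",
            level=level,
            lower={f: _LOWER_MULT * g for f, g in q_obs.items()},
            upper={f: mult * g for f, g in q_obs.items()},
            ref_mean=dict(q_obs),
        )
    return out


def generate_feasible_instance(
    seed: int,
    config: SyntheticConfig | None = None,
    deficit: float = 0.7,
    max_retries: int = 5,
) -> SyntheticInstance:
    """A stratum guaranteed step-1 feasible under every scenario.

    A hidden diet ``H`` (one food per subgroup, subgroup-typical amounts) is
    constructed to satisfy every nutritional row with margin: macronutrient
    shares are placed inside their bands, component shares below their caps,
    micronutrient and fiber densities scaled so contents sit 15% above their
    floors, and red + processed meat held at 80% of the weekly cap.  The
    observed diet is ``H`` with dairy and fruit scaled by ``deficit`` (so
    step 1 has real work to do); each candidate is verified by solving all
    six scenarios, and the deficit moves back toward 1 (where the observed
    diet itself is feasible) on the rare verification failure.
    """
    config = config or SyntheticConfig()
    rng = _rng(seed, "feasible")
    tpl = _template()

    foods: list[FoodItem] = []
    for subgroup in tpl.index:
        row = tpl.loc[subgroup]
        jitter = lambda sigma=0.15: float(rng.lognormal(-0.5 * sigma**2, sigma))
        comp = dict.fromkeys(NUTRIENT_UNITS, 0.0)
        for macro in _MACROS:
            comp[macro] = float(row[macro]) * jitter()
        comp["free_sugar"] = min(float(row["free_sugar_frac"]), 0.95) * comp["carbohydrate"]
        comp["saturated_fat"] = min(float(row["sat_frac"]), 0.95) * comp["total_fat"]
        comp["trans_fat"] = min(float(row["trans_frac"]), 0.2) * comp["total_fat"]
        for micro in _MICROS:
            comp[micro] = float(row[micro]) * jitter()
        comp["energy"] = (
            4.0 * comp["carbohydrate"] + 4.0 * comp["protein"] + 9.0 * comp["total_fat"]
        )
        foods.append(
            FoodItem(
                id=subgroup,
                name=subgroup.replace("_", " "),
                group=SUBGROUP_TO_GROUP[subgroup],
                subgroup=subgroup,
                composition=comp,
                price=float(row["price_per_100g"]) * jitter(0.1),
            )
        )

    # Hidden diet H: typical amounts, jittered, meat held below the cap,
    # energy pinned to the target.
    index = {f.id: f for f in foods}
    h = {
        f.id: float(tpl.loc[f.subgroup, "typical_g_day"]) * float(rng.lognormal(0.0, 0.1))
        for f in foods
    }
    meat = h["red_meat"] + h["processed_meat"]
    meat_cap_daily = 500.0 / 7.0
    if meat > 0.8 * meat_cap_daily:
        shrink = 0.8 * meat_cap_daily / meat
        h["red_meat"] *= shrink
        h["processed_meat"] *= shrink

    def rescale_energy(q: dict[str, float], target: float) -> dict[str, float]:
        energy = sum(g * index[f].composition["energy"] / 100.0 for f, g in q.items())
        return {f: g * target / energy for f, g in q.items()}

    h = rescale_energy(h, config.energy_target_kcal)

    micro_targets = {n: _FIXTURE_MARGIN * floor for n, floor in RDA_FLOORS.items()}
    micro_targets["fiber"] = _FIXTURE_MARGIN * 31.0
    micro_targets["sodium"] = 2995.0
    foods = _calibrate_with_diet(
        foods, h, FEASIBLE_SHARES, {"free_sugar": 5.5, "saturated_fat": 8.2, "trans_fat": 0.45}, micro_targets
    )
    index = {f.id: f for f in foods}
    h = rescale_energy(h, config.energy_target_kcal)

    table1 = default_table1()
    factors = np.linspace(deficit, 1.0, max_retries)
    for factor in factors:
        q_obs = dict(h)
        for f in _DEFICIT_SUBGROUPS:
            q_obs[f] *= float(factor)
        target = config.energy_target_kcal * (1.0 + float(rng.uniform(-1.0, 1.0)) * 0.004)
        q_obs = rescale_energy(q_obs, target)
        stratum = build_stratum_profile(f"FIX{seed}", "R1", q_obs, index)
        instance = SyntheticInstance(stratum, foods, _fixture_bounds(q_obs), table1)
        if _all_scenarios_feasible(instance):
            return instance
    raise GeneratorError(
        f"could not construct a feasible stratum for seed {seed} after {max_retries} tries"
    )


def _calibrate_with_diet(foods, diet, macro_shares, component_shares, micro_targets):
    """Like :func:`_calibrate_universe` but against an explicit diet."""

    amounts = np.array([diet[f.id] for f in foods])

    def total(nutrient: str, items) -> float:
        return float(
            sum(a * f.composition.get(nutrient, 0.0) / 100.0 for a, f in zip(amounts, items))
        )

    energy = 4.0 * total("carbohydrate", foods) + 4.0 * total("protein", foods) + 9.0 * total(
        "total_fat", foods
    )
    alpha = {
        m: (macro_shares[m] / 100.0 * energy / ATWATER_KCAL_PER_G[m]) / total(m, foods)
        for m in _MACROS
    }
    scaled = []
    for f in foods:
        comp = dict(f.composition)
        for m in _MACROS:
            comp[m] *= alpha[m]
        comp["free_sugar"] *= alpha["carbohydrate"]
        comp["saturated_fat"] *= alpha["total_fat"]
        comp["trans_fat"] *= alpha["total_fat"]
        comp["energy"] = (
            4.0 * comp["carbohydrate"] + 4.0 * comp["protein"] + 9.0 * comp["total_fat"]
        )
        scaled.append(replace(f, composition=comp))

    ceilings = {
        "free_sugar": ("carbohydrate", 0.95),
        "saturated_fat": ("total_fat", 0.95),
        "trans_fat": ("total_fat", 0.2),
    }
    for component, share in component_shares.items():
        current = total(component, scaled)
        desired = share / 100.0 * energy / ATWATER_KCAL_PER_G[component]
        gamma = desired / current if current > 0 else 0.0
        parent, cap = ceilings[component]
        scaled = [
            replace(
                f,
                composition={
                    **f.composition,
                    component: min(f.composition[component] * gamma, cap * f.composition[parent]),
                },
            )
            for f in scaled
        ]
    for micro, target in micro_targets.items():
        current = total(micro, scaled)
        if current <= 0:
            continue
        gamma = target / current
        scaled = [
            replace(f, composition={**f.composition, micro: f.composition[micro] * gamma})
            for f in scaled
        ]
    return scaled


def _all_scenarios_feasible(instance: SyntheticInstance) -> bool:
    for level in LEVELS:
        for regime in ("free", "constrained"):
            cset = instance.constraint_set(level, regime)
            model = build_step1_model(instance.stratum, instance.foods, cset)
            if solve_step1(model).status != "optimal":
                return False
    return True


def generate_infeasible_instance(
    nutrient: str,
    seed: int,
    attainable_fraction: float = 0.4,
) -> InfeasibleInstance:
    """A stratum where exactly one nutrient floor is unattainable.

    Starting from a fully feasible stratum (no deficit, so the observed diet
    satisfies every row), the nutrient is stripped from every food except a
    single carrier whose upper acceptability bound is pinned at its observed
    amount; the maximum attainable content is then exactly
    ``attainable_fraction x target``, so the step-2 undesirable deviation is
    known in closed form and checkable against an LP max-attainable oracle.
    """
    floors = dict(RDA_FLOORS, fiber=31.0)
    if nutrient not in floors:
        raise InvalidInputError(f"nutrient {nutrient!r} has no floor row")
    target = floors[nutrient]
    base = generate_feasible_instance(seed, deficit=1.0, max_retries=3)

    q_obs = base.stratum.q_obs
    carrier = max(q_obs, key=lambda f: (q_obs[f], f))
    density = attainable_fraction * target * 100.0 / q_obs[carrier]
    foods = [
        replace(
            f,
            composition={
                **f.composition,
                nutrient: density if f.id == carrier else 0.0,
            },
        )
        for f in base.foods
    ]
    index = {f.id: f for f in foods}
    stratum = build_stratum_profile(
        base.stratum.stratum_id, base.stratum.region, q_obs, index
    )
    bounds = {
        level: AcceptabilityBounds(
            region=b.region,
            level=level,
            lower=dict(b.lower),
            upper={**b.upper, carrier: q_obs[carrier]},
            ref_mean=dict(b.ref_mean),
        )
        for level, b in base.bounds_by_level.items()
    }
    instance = SyntheticInstance(stratum, foods, bounds, base.table1)
    return InfeasibleInstance(
        instance=instance,
        nutrient=nutrient,
        target=target,
        max_attainable=attainable_fraction * target,
        carrier=carrier,
    )


# ---------------------------------------------------------------------------
# Worked examples with exact deviations
# ---------------------------------------------------------------------------


def worked_example_floor() -> WorkedExample:
    """Floor nutrient with target 100 mg and maximum attainable content
    90 mg: the step-2 undesirable deviation is exactly 10 mg.

    The nutrient rides on a single carrier food whose observed amount sits
    on its upper acceptability bound, so the deviation is decoupled from the
    energy-equality tolerance.
    """
    staple = FoodItem(
        id="staple",
        name="staple",
        group="cereals",
        subgroup="rice",
        composition={"energy": 200.0, "calcium": 0.0},
        price=0.5,
    )
    greens = FoodItem(
        id="greens",
        name="greens",
        group="fruits_vegetables",
        subgroup="leafy_vegetables",
        composition={"energy": 50.0, "calcium": 30.0},
        price=1.0,
    )
    q_obs = {"staple": 425.0, "greens": 300.0}  # 850 + 150 = 1000 kcal; 90 mg
    stratum = build_stratum_profile("WE_floor", "R1", q_obs, [staple, greens])
    cset = ConstraintSet(
        rows=(LinearRow("calcium_min", "ge", 100.0, nutrient="calcium", relaxable=True),),
        energy_kcal=1000.0,
        acceptability={"staple": (350.0, 600.0), "greens": (0.0, 300.0)},
        reference_intake=dict(q_obs),
    )
    return WorkedExample(stratum, [staple, greens], cset, "calcium_min", 100.0, 10.0)


def worked_example_cap() -> WorkedExample:
    """Capped harmful component with target 2 g and minimum attainable
    content 2.5 g: the step-2 undesirable deviation is exactly 0.5 g."""
    staple = FoodItem(
        id="staple",
        name="staple",
        group="cereals",
        subgroup="rice",
        composition={"energy": 200.0, "trans_fat": 0.0},
        price=0.5,
    )
    spread = FoodItem(
        id="spread",
        name="spread",
        group="oils",
        subgroup="margarine_butter",
        composition={"energy": 50.0, "trans_fat": 1.0},
        price=1.0,
    )
    q_obs = {"staple": 425.0, "spread": 250.0}  # 850 + 125 = 975 kcal; 2.5 g
    stratum = build_stratum_profile("WE_cap", "R1", q_obs, [staple, spread])
    cset = ConstraintSet(
        rows=(LinearRow("trans_fat_max", "le", 2.0, nutrient="trans_fat", relaxable=True),),
        energy_kcal=stratum.observed_energy,
        acceptability={"staple": (350.0, 600.0), "spread": (250.0, 400.0)},
        reference_intake=dict(q_obs),
    )
    return WorkedExample(stratum, [staple, spread], cset, "trans_fat_max", 2.0, 0.5)


# ---------------------------------------------------------------------------
# Survey-record emulation (for the CSV pipeline / CLI)
# ---------------------------------------------------------------------------


def generate_intake_records(
    survey: SyntheticSurvey, seed: int, individuals_per_stratum: int = 4
) -> list[IntakeRecord]:
    """Individual two-record intakes whose stratum means jitter around the
    profiles' observed diets (3% of individuals have one record only)."""
    rng = _rng(seed, "intakes")
    records = []
    for sid in sorted(survey.all_means):
        means = survey.all_means[sid]
        positive = {f: g for f, g in means.items() if g > 0}
        for j in range(individuals_per_stratum):
            weight = float(rng.lognormal(0.0, 0.3))
            jitter = lambda: float(rng.lognormal(-0.01125, 0.15))
            rec1 = {f: g * jitter() for f, g in positive.items()}
            rec2 = None
            if rng.uniform() > 0.03:
                rec2 = {f: g * jitter() for f, g in positive.items()}
            records.append(
                IntakeRecord(
                    individual_id=f"{sid}_ind{j + 1}",
                    stratum_id=sid,
                    sampling_weight=weight,
                    record1=rec1,
                    record2=rec2,
                )
            )
    return records


_MONTH_INDEX = {
    "2008-03": 96.0,
    "2008-06": 97.2,
    "2008-09": 98.5,
    "2008-12": 99.4,
    "2009-01": 100.0,
}


def generate_price_records(
    foods: Sequence[FoodItem], seed: int, records_per_food: int = 3
) -> list[PriceRecord]:
    """Purchase records whose deflated edible-portion prices reproduce the
    items' prices up to small noise."""
    rng = _rng(seed, "prices")
    months = sorted(_MONTH_INDEX)
    records = []
    for f in foods:
        for _ in range(records_per_food):
            month = months[int(rng.integers(len(months)))]
            index = _MONTH_INDEX[month]
            grams = float(rng.choice([250.0, 500.0, 1000.0]))
            edible = float(rng.uniform(0.7, 1.0))
            cooking = float(rng.uniform(0.8, 1.2))
            target_price = f.price * float(rng.lognormal(0.0, 0.05))
            price_at_purchase = target_price * index / 100.0
            records.append(
                PriceRecord(
                    food_id=f.id,
                    purchase_price=price_at_purchase * grams * edible * cooking / 100.0,
                    purchase_grams=grams,
                    edible_fraction=edible,
                    cooking_yield=cooking,
                    price_index_at_purchase=index,
                    month=month,
                )
            )
    return records
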