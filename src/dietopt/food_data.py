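"""Per-stratum model inputs: prices per 100 g edible portion, aggregated item
compositions, observed mean diets, and nutrient/cost evaluation of any diet.

The unit of analysis throughout is the geographic stratum (GS).  A
:class:`StratumProfile` holds everything the optimizer needs about one GS:
the list of modeled foods, the observed mean intake vector ``Q_obs`` (g/day),
and the nutrient vector, energy and cost of that observed diet.

Conventions
-----------
* Food compositions are per 100 g edible portion; prices are currency per
  100 g edible portion.
* ``edible_fraction`` converts purchased grams down to edible raw grams;
  ``cooking_yield`` converts edible raw grams to as-consumed grams.  Both
  default to 1.
* An individual's intake is the mean of the two food records when both are
  present; a missing second record is simply skipped (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UnknownFoodError
from .nutrients import ENERGY, FOOD_GROUPS, NUTRIENT_UNITS, SUBGROUP_TO_GROUP

__all__ = [
    "FoodItem",
    "PriceRecord",
    "IntakeRecord",
    "StratumProfile",
    "compute_edible_price",
    "deflate_price",
    "aggregate_item",
    "compute_stratum_mean_intake",
    "compute_nutrient_content",
    "compute_diet_cost",
    "build_stratum_profile",
    "read_foods",
    "write_foods",
    "read_prices",
    "read_intakes",
    "write_intakes",
    "read_strata",
    "build_profiles_from_tables",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoodItem:
    """One modeled food item.

    ``composition`` maps nutrient name -> amount per 100 g edible portion in
    the registry unit for that nutrient; ``price`` is currency per 100 g
    edible portion and must be strictly positive.
    """

    id: str
    name: str
    group: str
    subgroup: str
    composition: Mapping[str, float]
    price: float

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise InvalidInputError(f"food {self.id!r}: price must be > 0, got {self.price}")
        if self.group not in FOOD_GROUPS:
            raise InvalidInputError(
                f"food {self.id!r}: unknown group {self.group!r}; known: {FOOD_GROUPS}"
            )
        for nutrient, amount in self.composition.items():
            if nutrient not in NUTRIENT_UNITS:
                raise InvalidInputError(f"food {self.id!r}: unknown nutrient {nutrient!r}")
            if amount < 0:
                raise InvalidInputError(
                    f"food {self.id!r}: {nutrient} amount must be >= 0, got {amount}"
                )
        if self.composition.get(ENERGY, 0.0) < 0:
            raise InvalidInputError(f"food {self.id!r}: energy must be >= 0")


@dataclass(frozen=True)
class PriceRecord:
    """One purchase observation, as recorded in a budget survey."""

    food_id: str
    purchase_price: float
    purchase_grams: float
    edible_fraction: float = 1.0
    cooking_yield: float = 1.0
    price_index_at_purchase: float = 100.0
    month: str = ""

    def __post_init__(self) -> None:
        if self.purchase_grams <= 0:
            raise InvalidInputError("purchase_grams must be > 0")
        if not (0.0 < self.edible_fraction <= 1.0):
            raise InvalidInputError("edible_fraction must be in (0, 1]")
        if self.cooking_yield <= 0:
            raise InvalidInputError("cooking_yield must be > 0")
        if self.price_index_at_purchase <= 0:
            raise InvalidInputError("price index must be > 0")


@dataclass(frozen=True)
class IntakeRecord:
    """Two (possibly one) food records for one individual in one stratum.

    ``record1``/``record2`` map food id -> grams consumed on that record day;
    foods absent from a record count as 0 g.  ``record2`` is ``None`` when
    the individual filled in a single record.
    """

    individual_id: str
    stratum_id: str
    sampling_weight: float
    record1: Mapping[str, float]
    record2: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sampling_weight <= 0:
            raise InvalidInputError("sampling_weight must be > 0")
        for rec in (self.record1, self.record2):
            if rec is None:
                continue
            for food, grams in rec.items():
                if grams < 0:
                    raise InvalidInputError(
                        f"negative intake {grams} for food {food!r} "
                        f"(individual {self.individual_id!r})"
                    )


@dataclass(frozen=True)
class StratumProfile:
    """Observed state of one geographic stratum.

    ``foods`` is the model food list: the union of foods reported in the
    stratum and foods reported elsewhere in the same state (the latter have
    ``Q_obs = 0`` and may be introduced by the optimizer).
    """

    stratum_id: str
    region: str
    q_obs: Mapping[str, float]
    observed_energy: float
    observed_nutrients: Mapping[str, float]
    observed_cost: float

    def __post_init__(self) -> None:
        for food, grams in self.q_obs.items():
            if grams < 0:
                raise InvalidInputError(
                    f"stratum {self.stratum_id!r}: Q_obs[{food!r}] must be >= 0"
                )

    @property
    def foods(self) -> list[str]:
        return list(self.q_obs)

    @property
    def g(self) -> int:
        """Number of foods in the stratum model."""
        return len(self.q_obs)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_edible_price(record: PriceRecord) -> float:
    """Price per 100 g of edible, as-consumed portion.

    The purchased mass is reduced by the edible fraction (waste removal) and
    converted to as-consumed mass by the cooking yield; the purchase price is
    then spread over that mass in 100 g units.
    """
    edible_100g = record.purchase_grams * record.edible_fraction * record.cooking_yield / 100.0
    return record.purchase_price / edible_100g


def deflate_price(price: float, index_at_purchase: float, index_at_reference: float) -> float:
    """Deflate (or inflate) a price to the reference date of a price index."""
    if index_at_purchase <= 0 or index_at_reference <= 0:
        raise InvalidInputError("price indices must be > 0")
    return price * index_at_reference / index_at_purchase


def aggregate_item(
    member_values: Sequence[float], report_frequencies: Sequence[float]
) -> float:
    """Frequency-weighted mean over the members of an aggregated food item.

    The same operator serves prices and compositions: member foods are folded
    into one item weighting each member by how often it was reported.
    """
    values = np.asarray(member_values, dtype=float)
    freqs = np.asarray(report_frequencies, dtype=float)
    if values.shape != freqs.shape:
        raise InvalidInputError("member_values and report_frequencies must align")
    if np.any(freqs < 0):
        raise InvalidInputError("frequencies must be >= 0")
    total = freqs.sum()
    if total <= 0:
        raise InvalidInputError("total report frequency must be positive")
    return float(values @ freqs / total)


def compute_stratum_mean_intake(records: Iterable[IntakeRecord]) -> dict[str, float]:
    """Sampling-weight-weighted mean intake (g/day per food) for one stratum.

    Per individual, the intake of each food is the mean of the available food
    records (two when both present, otherwise the single record).  The
    stratum mean then weights individuals by their sampling weights.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("at least one intake record is required")
    foods: set[str] = set()
    for rec in records:
        foods.update(rec.record1)
        if rec.record2 is not None:
            foods.update(rec.record2)
    totals = dict.fromkeys(foods, 0.0)
    weight_sum = 0.0
    for rec in records:
        weight_sum += rec.sampling_weight
        for food in foods:
            if rec.record2 is None:
                intake = rec.record1.get(food, 0.0)
            else:
                intake = (rec.record1.get(food, 0.0) + rec.record2.get(food, 0.0)) / 2.0
            totals[food] += rec.sampling_weight * intake
    return {food: totals[food] / weight_sum for food in sorted(foods)}


def _food_index(foods: Iterable[FoodItem]) -> dict[str, FoodItem]:
    return {item.id: item for item in foods}


def compute_nutrient_content(
    q: Mapping[str, float], foods: Iterable[FoodItem] | Mapping[str, FoodItem]
) -> dict[str, float]:
    """Nutrient vector (amount/day) of a diet ``q`` (food id -> g/day)."""
    index = foods if isinstance(foods, Mapping) else _food_index(foods)
    content: dict[str, float] = {}
    for food_id, grams in q.items():
        try:
            item = index[food_id]
        except KeyError:
            raise UnknownFoodError(f"no composition for food {food_id!r}") from None
        for nutrient, per100 in item.composition.items():
            content[nutrient] = content.get(nutrient, 0.0) + grams * per100 / 100.0
    return content


def compute_diet_cost(
    q: Mapping[str, float], foods: Iterable[FoodItem] | Mapping[str, FoodItem]
) -> float:
    """Cost (currency/day) of a diet ``q`` at the items' edible-portion prices."""
    index = foods if isinstance(foods, Mapping) else _food_index(foods)
    cost = 0.0
    for food_id, grams in q.items():
        try:
            item = index[food_id]
        except KeyError:
            raise UnknownFoodError(f"no price for food {food_id!r}") from None
        cost += grams * item.price / 100.0
    return cost


def build_stratum_profile(
    stratum_id: str,
    region: str,
    q_obs: Mapping[str, float],
    foods: Iterable[FoodItem] | Mapping[str, FoodItem],
) -> StratumProfile:
    """Assemble a :class:`StratumProfile`, deriving the observed nutrient
    vector, energy and cost from ``q_obs`` (so the invariants hold by
    construction)."""
    index = foods if isinstance(foods, Mapping) else _food_index(foods)
    nutrients = compute_nutrient_content(q_obs, index)
    return StratumProfile(
        stratum_id=stratum_id,
        region=region,
        q_obs=dict(sorted(q_obs.items())),
        observed_energy=nutrients.get(ENERGY, 0.0),
        observed_nutrients=nutrients,
        observed_cost=compute_diet_cost(q_obs, index),
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

_FOOD_FIXED_COLS = ["id", "name", "group", "subgroup", "price_per_100g"]


def read_foods(path: str | Path) -> list[FoodItem]:
    """Read ``foods.csv``: id, name, group, subgroup, price_per_100g and one
    column per nutrient (canonical names, registry units)."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _FOOD_FIXED_COLS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"foods table missing columns: {missing}")
    nutrient_cols = [c for c in df.columns if c in NUTRIENT_UNITS]
    unknown = [
        c for c in df.columns if c not in _FOOD_FIXED_COLS and c not in NUTRIENT_UNITS
    ]
    if unknown:
        raise InvalidInputError(f"foods table has unrecognized columns: {unknown}")
    items = []
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        comp = {n: float(rowd[n]) for n in nutrient_cols}
        items.append(
            FoodItem(
                id=str(rowd["id"]),
                name=str(rowd["name"]),
                group=str(rowd["group"]),
                subgroup=str(rowd["subgroup"]),
                composition=comp,
                price=float(rowd["price_per_100g"]),
            )
        )
    return items


def write_foods(foods: Sequence[FoodItem], path: str | Path) -> None:
    nutrient_cols = sorted({n for f in foods for n in f.composition}, key=list(NUTRIENT_UNITS).index)
    rows = []
    for f in foods:
        row = {
            "id": f.id,
            "name": f.name,
            "group": f.group,
            "subgroup": f.subgroup,
            "price_per_100g": f.price,
        }
        row.update({n: f.composition.get(n, 0.0) for n in nutrient_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_prices(path: str | Path) -> list[PriceRecord]:
    """Read ``prices.csv`` with :class:`PriceRecord` columns."""
    df = pd.read_csv(path, dtype={"food_id": str, "month": str})
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            PriceRecord(
                food_id=str(d["food_id"]),
                purchase_price=float(d["purchase_price"]),
                purchase_grams=float(d["purchase_grams"]),
                edible_fraction=float(d.get("edible_fraction", 1.0)),
                cooking_yield=float(d.get("cooking_yield", 1.0)),
                price_index_at_purchase=float(d.get("price_index_at_purchase", 100.0)),
                month=str(d.get("month", "")),
            )
        )
    return records


def read_intakes(path: str | Path) -> list[IntakeRecord]:
    """Read ``intakes.csv`` in long format: individual, stratum, weight,
    record_no (1 or 2), food, grams."""
    df = pd.read_csv(path, dtype={"individual": str, "stratum": str, "food": str})
    required = {"individual", "stratum", "weight", "record_no", "food", "grams"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"intakes table missing columns: {sorted(missing)}")
    records = []
    for (individual, stratum), sub in df.groupby(["individual", "stratum"], sort=True):
        weight = float(sub["weight"].iloc[0])
        rec1 = {
            str(r.food): float(r.grams) for r in sub[sub["record_no"] == 1].itertuples()
        }
        sub2 = sub[sub["record_no"] == 2]
        rec2 = (
            {str(r.food): float(r.grams) for r in sub2.itertuples()} if len(sub2) else None
        )
        records.append(
            IntakeRecord(
                individual_id=str(individual),
                stratum_id=str(stratum),
                sampling_weight=weight,
                record1=rec1,
                record2=rec2,
            )
        )
    return records


def write_intakes(records: Sequence[IntakeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for record_no, record in ((1, rec.record1), (2, rec.record2)):
            if record is None:
                continue
            for food, grams in sorted(record.items()):
                rows.append(
                    {
                        "individual": rec.individual_id,
                        "stratum": rec.stratum_id,
                        "weight": rec.sampling_weight,
                        "record_no": record_no,
                        "food": food,
                        "grams": grams,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_strata(path: str | Path) -> pd.DataFrame:
    """Read ``strata.csv``: stratum_id, region, state and (optionally) a
    0/1 ``low_income`` marker."""
    df = pd.read_csv(path, dtype={"stratum_id": str, "region": str, "state": str})
    required = {"stratum_id", "region", "state"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"strata table missing columns: {sorted(missing)}")
    return df


def build_profiles_from_tables(
    intakes: Sequence[IntakeRecord],
    strata: pd.DataFrame,
    foods: Sequence[FoodItem],
) -> list[StratumProfile]:
    """Build one profile per stratum listed in ``strata``.

    The model food list of a stratum is the union of foods reported in the
    stratum and foods reported in any other stratum of the same state
    (entered with ``Q_obs = 0`` and available for introduction).
    """
    index = _food_index(foods)
    by_stratum: dict[str, list[IntakeRecord]] = {}
    for rec in intakes:
        by_stratum.setdefault(rec.stratum_id, []).append(rec)

    means = {sid: compute_stratum_mean_intake(recs) for sid, recs in by_stratum.items()}
    state_of = dict(zip(strata["stratum_id"], strata["state"]))
    region_of = dict(zip(strata["stratum_id"], strata["region"]))
    state_foods: dict[str, set[str]] = {}
    for sid, mean in means.items():
        state = state_of.get(sid)
        if state is None:
            continue
        reported = {f for f, g in mean.items() if g > 0}
        state_foods.setdefault(state, set()).update(reported)

    profiles = []
    for sid in strata["stratum_id"]:
        if sid not in means:
            continue
        mean = means[sid]
        q_obs = {f: g for f, g in mean.items() if g > 0}
        for food in state_foods.get(state_of[sid], set()):
            q_obs.setdefault(food, 0.0)
        profiles.append(build_stratum_profile(sid, region_of[sid], q_obs, index))
    return profiles
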