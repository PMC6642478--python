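"""Scenario sweep and summary surfaces.

Runs the six scenarios (cost-free / cost-constrained x rigorous / moderate /
flexible acceptability) over all strata and condenses the per-model results
into the standard reporting tables: mean (SD) nutrient contents across
strata, mean (SD) food-subgroup contents with a cost row, the percentage of
strata meeting each recommendation row (observed vs optimized), and the
distribution of per-stratum % changes in nutrient contents.

Summaries weight strata equally and use the sample standard deviation
(ddof = 1; reported as 0 for a single stratum).  Every summary is a pure
function of the result map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .acceptability import LEVELS, AcceptabilityBounds, derive_bounds
from .errors import ConfigurationError
from .food_data import FoodItem, StratumProfile
from .nutrients import NUTRIENT_UNITS
from .optimizer import OptimizationResult, optimize_stratum
from .recommendations import (
    NutrientConstraint,
    build_constraint_set,
    default_table1,
    nutritional_rows,
)

__all__ = [
    "Scenario",
    "SCENARIOS",
    "derive_bounds_by_level",
    "run_scenarios",
    "summarize_nutrients",
    "summarize_foods",
    "adequacy_percentages",
    "change_distributions",
    "write_outputs",
]

logger = logging.getLogger("dietopt")

COST_REGIMES = ("constrained", "free")


@dataclass(frozen=True)
class Scenario:
    cost_regime: str
    level: str

    def __post_init__(self) -> None:
        if self.cost_regime not in COST_REGIMES:
            raise ConfigurationError(f"unknown cost regime {self.cost_regime!r}")
        if self.level not in LEVELS:
            raise ConfigurationError(f"unknown level {self.level!r}")

    @property
    def label(self) -> str:
        return f"{self.cost_regime}_{self.level}"


#: The six scenarios: cost regime x acceptability level.
SCENARIOS: tuple[Scenario, ...] = tuple(
    Scenario(regime, level) for regime in COST_REGIMES for level in LEVELS
)


def derive_bounds_by_level(
    strata_means: Mapping[str, Mapping[str, float]],
    region_of: Mapping[str, str],
    levels: Sequence[str] = LEVELS,
) -> dict[str, dict[str, AcceptabilityBounds]]:
    """Acceptability bounds per level per region from the full collection of
    strata means."""
    return {level: derive_bounds(strata_means, region_of, level) for level in levels}


def run_scenarios(
    strata: Sequence[StratumProfile],
    food_items: Sequence[FoodItem],
    bounds_by_level: Mapping[str, Mapping[str, AcceptabilityBounds] | AcceptabilityBounds],
    table1: Sequence[NutrientConstraint] | None = None,
    scenarios: Sequence[Scenario] = SCENARIOS,
    on_result: Callable[[OptimizationResult], None] | None = None,
) -> dict[tuple[str, str], OptimizationResult]:
    """One two-step optimization per (scenario, stratum); failures are
    recorded as error results, never dropped."""
    table1 = list(table1) if table1 is not None else default_table1()
    results: dict[tuple[str, str], OptimizationResult] = {}
    for scenario in scenarios:
        by_region = bounds_by_level[scenario.level]
        for stratum in strata:
            if isinstance(by_region, AcceptabilityBounds):
                bounds = by_region
            else:
                bounds = by_region[stratum.region]
            try:
                cset = build_constraint_set(
                    stratum,
                    food_items,
                    scenario.level,
                    scenario.cost_regime,
                    table1=table1,
                    bounds=bounds,
                )
                result = optimize_stratum(
                    stratum, food_items, cset, scenario=scenario.label
                )
            except Exception as exc:  # per-model failures are data, not fatal
                logger.warning("model failed: %s %s: %s", scenario.label, stratum.stratum_id, exc)
                result = OptimizationResult(
                    status="error",
                    step_used=0,
                    stratum_id=stratum.stratum_id,
                    scenario=scenario.label,
                    diagnostics={"exception": repr(exc)},
                )
            logger.info(
                "model stratum=%s scenario=%s status=%s step=%s objective=%s limiting=%s",
                stratum.stratum_id,
                scenario.label,
                result.status,
                result.step_used,
                None if result.objective is None else round(result.objective, 6),
                sorted(result.limiting_nutrients),
            )
            results[(scenario.label, stratum.stratum_id)] = result
            if on_result is not None:
                on_result(result)
    return results


def _optimal(results: Mapping[tuple[str, str], OptimizationResult]):
    return [r for r in results.values() if r.status == "optimal"]


def summarize_nutrients(
    results: Mapping[tuple[str, str], OptimizationResult],
    strata: Sequence[StratumProfile],
) -> pd.DataFrame:
    """Mean (SD) nutrient contents across strata, per scenario, with the
    observed diet as the first column pair."""
    rows = []
    for s in strata:
        for nutrient, value in s.observed_nutrients.items():
            rows.append({"scenario": "observed", "nutrient": nutrient, "value": value})
    for r in _optimal(results):
        for nutrient, value in (r.nutrients or {}).items():
            rows.append({"scenario": r.scenario, "nutrient": nutrient, "value": value})
    if not rows:
        raise ConfigurationError("no optimal results to summarize")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["nutrient", "scenario"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .unstack("scenario")
    )
    out.columns = [f"{scenario}_{stat}" for stat, scenario in out.columns]
    order = [n for n in NUTRIENT_UNITS if n in out.index]
    return out.loc[order]


def summarize_foods(
    results: Mapping[tuple[str, str], OptimizationResult],
    strata: Sequence[StratumProfile],
    food_items: Sequence[FoodItem],
) -> pd.DataFrame:
    """Mean (SD) food contents by subgroup across strata, per scenario,
    plus a diet-cost row."""
    subgroup_of = {f.id: f.subgroup for f in food_items}
    unmapped = {
        fid for s in strata for fid in s.foods if fid not in subgroup_of
    }
    if unmapped:
        raise ConfigurationError(f"foods without a subgroup mapping: {sorted(unmapped)}")

    rows = []

    all_subgroups = sorted({f.subgroup for f in food_items})

    def add(scenario: str, q: Mapping[str, float], cost: float) -> None:
        # a stratum without any food of a subgroup contributes 0 g to it
        totals: dict[str, float] = dict.fromkeys(all_subgroups, 0.0)
        for fid, grams in q.items():
            sub = subgroup_of[fid]
            totals[sub] = totals.get(sub, 0.0) + grams
        for sub, grams in totals.items():
            rows.append({"scenario": scenario, "item": sub, "value": grams})
        rows.append({"scenario": scenario, "item": "diet_cost", "value": cost})

    for s in strata:
        add("observed", s.q_obs, s.observed_cost)
    for r in _optimal(results):
        add(r.scenario, r.q_opt or {}, r.cost or 0.0)

    df = pd.DataFrame(rows)
    out = (
        df.groupby(["item", "scenario"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .unstack("scenario")
    )
    out.columns = [f"{scenario}_{stat}" for stat, scenario in out.columns]
    return out


def adequacy_percentages(
    results: Mapping[tuple[str, str], OptimizationResult],
    strata: Sequence[StratumProfile],
    table1: Sequence[NutrientConstraint] | None = None,
) -> pd.DataFrame:
    """Percentage of strata meeting each recommendation row, for the
    observed diets and per scenario."""
    table1 = list(table1) if table1 is not None else default_table1()
    strata_by_id = {s.stratum_id: s for s in strata}

    counts: dict[str, dict[str, list[bool]]] = {}

    def tally(column: str, stratum: StratumProfile, nutrients: Mapping[str, float]) -> None:
        rows = nutritional_rows(
            table1, stratum.observed_energy, stratum.observed_nutrients
        )
        for row in rows:
            value = nutrients.get(row.nutrient, 0.0)
            counts.setdefault(row.name, {}).setdefault(column, []).append(
                row.satisfied_by(value)
            )

    for s in strata:
        tally("observed", s, s.observed_nutrients)
    for r in _optimal(results):
        stratum = strata_by_id.get(r.stratum_id)
        if stratum is None or r.nutrients is None:
            continue
        tally(r.scenario, stratum, r.nutrients)

    data = {
        name: {col: 100.0 * np.mean(flags) for col, flags in cols.items()}
        for name, cols in counts.items()
    }
    return pd.DataFrame(data).T.sort_index()


def change_distributions(
    results: Mapping[tuple[str, str], OptimizationResult],
    strata: Sequence[StratumProfile],
    scenarios: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum % change of each nutrient versus the observed content.

    Returns the full long-format table (scenario, stratum, nutrient,
    pct_change) and a quartile summary per scenario and nutrient.  Strata
    with zero observed content for a nutrient are excluded from that
    nutrient's distribution.
    """
    strata_by_id = {s.stratum_id: s for s in strata}
    rows = []
    for r in _optimal(results):
        if scenarios is not None and r.scenario not in scenarios:
            continue
        stratum = strata_by_id.get(r.stratum_id)
        if stratum is None:
            continue
        for nutrient, opt in (r.nutrients or {}).items():
            obs = stratum.observed_nutrients.get(nutrient, 0.0)
            if obs <= 0:
                continue
            rows.append(
                {
                    "scenario": r.scenario,
                    "stratum": r.stratum_id,
                    "nutrient": nutrient,
                    "pct_change": 100.0 * (opt - obs) / obs,
                }
            )
    changes = pd.DataFrame(rows, columns=["scenario", "stratum", "nutrient", "pct_change"])
    if changes.empty:
        return changes, pd.DataFrame()
    summary = (
        changes.groupby(["scenario", "nutrient"])["pct_change"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q25", 0.5: "median", 0.75: "q75"})
        .reset_index()
    )
    return changes, summary


def write_outputs(
    out_dir: str | Path,
    results: Mapping[tuple[str, str], OptimizationResult],
    strata: Sequence[StratumProfile],
    food_items: Sequence[FoodItem],
    table1: Sequence[NutrientConstraint] | None = None,
) -> dict[str, Path]:
    """Write the summary CSVs and the full per-model JSONL record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nutrients": out_dir / "nutrients.csv",
        "foods": out_dir / "foods.csv",
        "adequacy": out_dir / "adequacy.csv",
        "changes": out_dir / "changes.csv",
        "models": out_dir / "models.jsonl",
    }
    summarize_nutrients(results, strata).to_csv(paths["nutrients"])
    summarize_foods(results, strata, food_items).to_csv(paths["foods"])
    adequacy_percentages(results, strata, table1).to_csv(paths["adequacy"])
    changes, summary = change_distributions(results, strata)
    changes.to_csv(paths["changes"], index=False)
    if not summary.empty:
        summary.to_csv(out_dir / "changes_summary.csv", index=False)
    with open(paths["models"], "w") as fh:
        for (scenario, stratum_id), r in results.items():
            record = asdict(r)
            record["limiting_nutrients"] = sorted(r.limiting_nutrients)
            fh.write(json.dumps(record) + "\n")
    return paths
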