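"""Shared fixtures: tiny hand-built instances and session-scoped synthetic
surveys, plus an LP-independent deletion-filter oracle for limiting-set
checks."""

from __future__ import annotations

from dataclasses import replace

import pytest

from dietopt.food_data import FoodItem, build_stratum_profile
from dietopt.nutrients import NUTRIENT_UNITS
from dietopt.optimizer import LpInstance, solve_step1
from dietopt.pipeline import derive_bounds_by_level
from dietopt.recommendations import ConstraintSet, LinearRow
from dietopt.synthetic_data import (
    SyntheticConfig,
    generate_feasible_instance,
    generate_strata,
)


def make_food(fid, energy=100.0, price=1.0, group="cereals", subgroup="rice", **nutrients):
    """Food with a complete (zero-filled) composition."""
    comp = dict.fromkeys(NUTRIENT_UNITS, 0.0)
    comp["energy"] = energy
    comp.update(nutrients)
    return FoodItem(
        id=fid, name=fid, group=group, subgroup=subgroup, composition=comp, price=price
    )


def make_toy_instance(foods, q_obs, rows, bounds, energy=None):
    """StratumProfile + ConstraintSet for a hand-built LP instance."""
    profile = build_stratum_profile("toy", "R1", q_obs, foods)
    cset = ConstraintSet(
        rows=tuple(rows),
        energy_kcal=energy if energy is not None else profile.observed_energy,
        acceptability=dict(bounds),
        reference_intake=dict(q_obs),
    )
    return profile, cset


def deletion_filter(instance: LpInstance) -> set[str]:
    """Minimal set of relaxable rows whose removal restores feasibility,
    found by greedy reinsertion — an oracle independent of the elastic
    diagnosis.  Starts from all relaxable rows removed (must be feasible)
    and adds back every row the model can still afford."""
    relaxable = [r.name for r in instance.hard_rows if r.relaxable]

    def feasible(removed: set[str]) -> bool:
        kept = tuple(r for r in instance.hard_rows if r.name not in removed)
        return solve_step1(replace(instance, hard_rows=kept)).status == "optimal"

    removed = set(relaxable)
    assert feasible(removed), "even the fully relaxed model is infeasible"
    for name in sorted(relaxable):
        if feasible(removed - {name}):
            removed.remove(name)
    return removed


@pytest.fixture(scope="session")
def feasible_instance():
    """A stratum guaranteed step-1 feasible under every scenario."""
    return generate_feasible_instance(11)


@pytest.fixture(scope="session")
def small_survey():
    """A compact synthetic survey for pipeline tests."""
    cfg = SyntheticConfig(
        n_strata=6,
        n_regions=2,
        low_income_fraction=0.5,
        n_foods=60,
        foods_per_stratum=(30, 45),
    )
    return generate_strata(cfg, 5)


@pytest.fixture(scope="session")
def small_bounds(small_survey):
    return derive_bounds_by_level(small_survey.all_means, small_survey.region_of)
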