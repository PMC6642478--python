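"""Tests for the recommendation table, RDA weighting and constraint-set
assembly."""

import math

import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from dietopt.errors import ConfigurationError, InvalidInputError
from dietopt.food_data import build_stratum_profile
from dietopt.recommendations import (
    NutrientConstraint,
    RdaEntry,
    build_constraint_set,
    default_table1,
    load_constraint_overrides,
    weighted_rda_bound,
)

from conftest import make_food


class TestWeightedRda:
    def test_symmetric_mean(self):
        entries = [RdaEntry("calcium", "a", 800.0), RdaEntry("calcium", "b", 1200.0)]
        assert weighted_rda_bound(entries, {"a": 0.5, "b": 0.5}) == pytest.approx(1000.0)

    def test_single_group_identity(self):
        assert weighted_rda_bound(
            [RdaEntry("folate", "adults", 426.0)], {"adults": 1.0}
        ) == pytest.approx(426.0)

    def test_three_group_population_weighting(self):
        # age-distribution-like frequencies: 10-19 y 29.5%, 20-59 y 62.7%, 60+ 7.8%
        entries = [
            RdaEntry("calcium", "10-19", 700.0),
            RdaEntry("calcium", "20-59", 900.0),
            RdaEntry("calcium", "60+", 1300.0),
        ]
        freqs = {"10-19": 0.295, "20-59": 0.627, "60+": 0.078}
        assert weighted_rda_bound(entries, freqs) == pytest.approx(872.2)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            weighted_rda_bound([RdaEntry("iron", "a", 10.0)], {"a": 0.9})

    def test_missing_group_rejected(self):
        with pytest.raises(InvalidInputError):
            weighted_rda_bound(
                [RdaEntry("iron", "a", 10.0)], {"a": 0.5, "b": 0.5}
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1, 2000, allow_nan=False), min_size=2, max_size=6))
    def test_bounded_by_group_extremes(self, rdas):
        entries = [RdaEntry("zinc", f"g{k}", v) for k, v in enumerate(rdas)]
        freqs = {f"g{k}": 1.0 / len(rdas) for k in range(len(rdas))}
        bound = weighted_rda_bound(entries, freqs)
        assert min(rdas) - 1e-9 <= bound <= max(rdas) + 1e-9


class TestDefaultTable:
    def test_row_count(self):
        assert len(default_table1()) == 25

    def test_key_bounds(self):
        by_nutrient = {nc.nutrient: nc for nc in default_table1()}
        assert (by_nutrient["calcium"].direction, by_nutrient["calcium"].lower) == ("ge", 1021.0)
        assert (by_nutrient["fiber"].direction, by_nutrient["fiber"].lower) == ("ge", 31.0)
        assert by_nutrient["carbohydrate"].lower == 45.0
        assert by_nutrient["carbohydrate"].upper == 55.0
        assert by_nutrient["trans_fat"].upper == 1.0
        assert by_nutrient["vitamin_d"].lower == 10.0
        floors = [
            nc for nc in default_table1() if nc.basis == "absolute" and nc.direction == "ge"
            and nc.nutrient != "fiber"
        ]
        assert len(floors) == 16


def _toy_stratum(observed_energy=2000.0):
    food = make_food("staple", energy=100.0, sodium=150.0, free_sugar=2.0, fiber=1.0)
    q = {"staple": 100.0 * observed_energy / food.composition["energy"]}
    return build_stratum_profile("s", "R1", q, [food]), [food]


class TestBuildConstraintSet:
    def _bounds(self, stratum):
        return {f: (0.0, 5000.0) for f in stratum.foods}

    def test_cost_free_has_no_cost_row(self):
        stratum, foods = _toy_stratum()
        cset = build_constraint_set(stratum, foods, "moderate", "free", bounds=self._bounds(stratum))
        assert cset.cost_limit is None

    def test_regime_switch_changes_only_the_cost_row(self):
        stratum, foods = _toy_stratum()
        free = build_constraint_set(stratum, foods, "moderate", "free", bounds=self._bounds(stratum))
        constrained = build_constraint_set(
            stratum, foods, "moderate", "constrained", bounds=self._bounds(stratum)
        )
        assert free.rows == constrained.rows
        assert free.acceptability == constrained.acceptability
        assert constrained.cost_limit == pytest.approx(stratum.observed_cost)

    def test_sodium_cap_is_observed_content(self):
        stratum, foods = _toy_stratum()
        cset = build_constraint_set(stratum, foods, "moderate", "free", bounds=self._bounds(stratum))
        row = next(r for r in cset.rows if r.name == "sodium_max_obs")
        assert (row.sense, row.rhs) == ("le", pytest.approx(stratum.observed_nutrients["sodium"]))

    def test_percent_energy_rows_convert_to_grams(self):
        stratum, foods = _toy_stratum(observed_energy=2000.0)
        cset = build_constraint_set(stratum, foods, "moderate", "free", bounds=self._bounds(stratum))
        fs = next(r for r in cset.rows if r.name == "free_sugar_max")
        assert fs.rhs == pytest.approx(50.0)  # 10% of 2000 kcal at 4 kcal/g

    def test_observed_diet_satisfies_observed_linked_rows(self, feasible_instance):
        stratum = feasible_instance.stratum
        cset = feasible_instance.constraint_set("moderate", "constrained")
        for row in cset.rows:
            if not row.name.endswith("_obs"):
                continue
            value = stratum.observed_nutrients.get(row.nutrient, 0.0)
            assert row.satisfied_by(value), row.name

    def test_acceptability_covers_each_stratum_food(self, feasible_instance):
        cset = feasible_instance.constraint_set()
        assert set(cset.acceptability) == set(feasible_instance.stratum.foods)
        for lo, hi in cset.acceptability.values():
            assert 0.0 <= lo <= hi

    def test_introduced_food_lower_bound_is_zero(self):
        food_a = make_food("a", energy=100.0)
        food_b = make_food("b", energy=100.0)
        stratum = build_stratum_profile("s", "R1", {"a": 2000.0, "b": 0.0}, [food_a, food_b])
        cset = build_constraint_set(
            stratum,
            [food_a, food_b],
            "moderate",
            "free",
            bounds={"a": (10.0, 4000.0), "b": (15.0, 80.0)},
        )
        assert cset.acceptability["b"] == (0.0, 80.0)
        assert cset.acceptability["a"] == (10.0, 4000.0)

    def test_missing_bounds_rejected(self):
        stratum, foods = _toy_stratum()
        with pytest.raises(ConfigurationError):
            build_constraint_set(stratum, foods, "moderate", "free", bounds=None)

    def test_yaml_override(self, tmp_path):
        path = tmp_path / "constraints.yaml"
        path.write_text(yaml.safe_dump({"fiber": {"lower": 25.0}, "vitamin_d": None}))
        table = load_constraint_overrides(path)
        by_nutrient = {nc.nutrient: nc for nc in table}
        assert by_nutrient["fiber"].lower == 25.0
        assert "vitamin_d" not in by_nutrient
        assert len(table) == 24
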