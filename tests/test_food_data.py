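"""Unit and property tests for price conversion, aggregation, mean-diet
computation and diet evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietopt.errors import InvalidInputError, UnknownFoodError
from dietopt.food_data import (
    FoodItem,
    IntakeRecord,
    PriceRecord,
    aggregate_item,
    build_stratum_profile,
    compute_diet_cost,
    compute_edible_price,
    compute_nutrient_content,
    compute_stratum_mean_intake,
    deflate_price,
    read_foods,
    read_intakes,
    write_foods,
    write_intakes,
)

from conftest import make_food


class TestEdiblePrice:
    @pytest.mark.parametrize(
        "price,grams,edible,cooking,expected",
        [
            (5.00, 1000.0, 0.8, 1.0, 0.625),
            (2.00, 100.0, 1.0, 1.0, 2.00),
            (3.00, 500.0, 0.75, 1.2, 3.00 / (500 * 0.75 * 1.2 / 100)),
        ],
    )
    def test_conversion(self, price, grams, edible, cooking, expected):
        rec = PriceRecord("f", price, grams, edible, cooking)
        assert compute_edible_price(rec) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"purchase_grams": 0.0},
            {"edible_fraction": 0.0},
            {"edible_fraction": 1.2},
            {"cooking_yield": -1.0},
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        base = dict(food_id="f", purchase_price=1.0, purchase_grams=100.0)
        with pytest.raises(InvalidInputError):
            PriceRecord(**{**base, **kwargs})


class TestDeflation:
    @pytest.mark.parametrize(
        "price,at,ref,expected",
        [
            (10.00, 110.0, 110.0, 10.00),
            (10.00, 110.0, 100.0, 10.00 * 100 / 110),
            (8.50, 100.0, 104.0, 8.84),
        ],
    )
    def test_deflation(self, price, at, ref, expected):
        assert deflate_price(price, at, ref) == pytest.approx(expected, abs=5e-3)

    def test_nonpositive_index_rejected(self):
        with pytest.raises(InvalidInputError):
            deflate_price(10.0, 0.0, 100.0)


class TestAggregation:
    @pytest.mark.parametrize(
        "values,freqs,expected",
        [((2, 4), (1, 1), 3.0), ((2, 4), (3, 1), 2.5), ((7.3,), (5,), 7.3)],
    )
    def test_weighted_mean(self, values, freqs, expected):
        assert aggregate_item(values, freqs) == pytest.approx(expected)

    def test_zero_total_frequency_rejected(self):
        with pytest.raises(InvalidInputError):
            aggregate_item([1.0, 2.0], [0.0, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e4, allow_nan=False),
                st.floats(0.01, 100, allow_nan=False),
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_bounded_by_member_range(self, pairs):
        values = [v for v, _ in pairs]
        freqs = [f for _, f in pairs]
        agg = aggregate_item(values, freqs)
        assert min(values) - 1e-9 <= agg <= max(values) + 1e-9


class TestStratumMeanIntake:
    def test_two_records_averaged(self):
        rec = IntakeRecord("i1", "s", 1.0, {"rice": 100.0}, {"rice": 200.0})
        assert compute_stratum_mean_intake([rec])["rice"] == pytest.approx(150.0)

    def test_weights_applied_across_individuals(self):
        recs = [
            IntakeRecord("i1", "s", 1.0, {"rice": 100.0}, {"rice": 100.0}),
            IntakeRecord("i2", "s", 3.0, {"rice": 200.0}, {"rice": 200.0}),
        ]
        assert compute_stratum_mean_intake(recs)["rice"] == pytest.approx(175.0)

    def test_single_record_used_as_is(self):
        rec = IntakeRecord("i1", "s", 2.0, {"rice": 80.0}, None)
        assert compute_stratum_mean_intake([rec])["rice"] == pytest.approx(80.0)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_stratum_mean_intake([])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 500, allow_nan=False), min_size=1, max_size=8))
    def test_equal_weights_reduce_to_arithmetic_mean(self, intakes):
        recs = [
            IntakeRecord(f"i{k}", "s", 1.0, {"rice": v}, None)
            for k, v in enumerate(intakes)
        ]
        mean = compute_stratum_mean_intake(recs)["rice"]
        assert mean == pytest.approx(np.mean(intakes), rel=1e-9, abs=1e-9)


class TestDietEvaluation:
    foods = [
        make_food("a", energy=100.0, price=0.50, fiber=2.0, calcium=50.0),
        make_food("b", energy=200.0, price=0.25, fiber=6.0),
    ]

    def test_zero_diet_has_zero_content(self):
        content = compute_nutrient_content({"a": 0.0, "b": 0.0}, self.foods)
        assert all(v == 0.0 for v in content.values())

    def test_identity_per_100g(self):
        assert compute_nutrient_content({"a": 100.0}, self.foods)["calcium"] == 50.0

    def test_linear_combination(self):
        content = compute_nutrient_content({"a": 150.0, "b": 50.0}, self.foods)
        assert content["fiber"] == pytest.approx(150 * 0.02 + 50 * 0.06)  # 6 g

    def test_unknown_food_rejected(self):
        with pytest.raises(UnknownFoodError):
            compute_nutrient_content({"nope": 10.0}, self.foods)

    @pytest.mark.parametrize(
        "diet,expected",
        [({"a": 100.0, "b": 200.0}, 1.00), ({}, 0.0), ({"a": 37.0}, 37 * 0.5 / 100)],
    )
    def test_cost(self, diet, expected):
        assert compute_diet_cost(diet, self.foods) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0, 1000, allow_nan=False),
        st.floats(0, 1000, allow_nan=False),
        st.floats(0, 8, allow_nan=False),
    )
    def test_homogeneity(self, qa, qb, lam):
        q = {"a": qa, "b": qb}
        scaled = {f: lam * g for f, g in q.items()}
        base = compute_nutrient_content(q, self.foods)
        for nutrient, value in compute_nutrient_content(scaled, self.foods).items():
            assert value == pytest.approx(lam * base[nutrient], rel=1e-9, abs=1e-9)
        assert compute_diet_cost(scaled, self.foods) == pytest.approx(
            lam * compute_diet_cost(q, self.foods), rel=1e-9, abs=1e-9
        )


class TestProfileAndIO:
    def test_profile_internally_consistent(self):
        foods = TestDietEvaluation.foods
        q = {"a": 120.0, "b": 30.0}
        p = build_stratum_profile("s1", "R1", q, foods)
        assert p.observed_nutrients == compute_nutrient_content(q, foods)
        assert p.observed_cost == pytest.approx(compute_diet_cost(q, foods))
        assert p.g == 2

    def test_negative_price_rejected(self):
        with pytest.raises(InvalidInputError):
            make_food("bad", price=-1.0)

    def test_foods_roundtrip(self, tmp_path):
        foods = TestDietEvaluation.foods
        write_foods(foods, tmp_path / "foods.csv")
        back = read_foods(tmp_path / "foods.csv")
        assert [f.id for f in back] == ["a", "b"]
        assert back[0].composition["calcium"] == 50.0
        assert back[0].price == 0.5

    def test_intakes_roundtrip(self, tmp_path):
        recs = [
            IntakeRecord("i1", "s1", 1.5, {"a": 10.0}, {"a": 20.0, "b": 5.0}),
            IntakeRecord("i2", "s1", 1.0, {"b": 7.0}, None),
        ]
        write_intakes(recs, tmp_path / "intakes.csv")
        back = read_intakes(tmp_path / "intakes.csv")
        assert compute_stratum_mean_intake(back) == pytest.approx(
            compute_stratum_mean_intake(recs)
        )
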