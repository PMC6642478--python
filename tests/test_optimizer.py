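"""Tests for LP assembly, the two-step solve, infeasibility diagnosis and
deviation reporting — including brute-force grid and deletion-filter
oracles."""

from dataclasses import replace

import numpy as np
import pytest

from dietopt.errors import DiagnosisError, InvalidInputError
from dietopt.optimizer import (
    attainable_range,
    build_step1_model,
    build_step2_model,
    diagnose_limiting_nutrients,
    evaluate_objective,
    optimize_stratum,
    run_two_step,
    solve_step1,
    solve_step2,
)
from dietopt.recommendations import LinearRow
from dietopt.synthetic_data import (
    generate_infeasible_instance,
    worked_example_cap,
    worked_example_floor,
)

from conftest import deletion_filter, make_food, make_toy_instance


def _instance(foods, q_obs, rows, bounds, energy=None):
    stratum, cset = make_toy_instance(foods, q_obs, rows, bounds, energy)
    return build_step1_model(stratum, foods, cset)


class TestStep1Model:
    foods = [make_food("a", energy=100.0), make_food("b", energy=100.0, fiber=5.0)]

    def test_objective_zero_at_observed(self):
        inst = _instance(
            self.foods, {"a": 100.0, "b": 50.0}, [], {"a": (0, 500), "b": (0, 500)}
        )
        assert evaluate_objective(inst, {"a": 100.0, "b": 50.0}) == 0.0

    def test_objective_sums_relative_deviations(self):
        inst = _instance(
            self.foods, {"a": 100.0, "b": 50.0}, [], {"a": (0, 500), "b": (0, 500)}
        )
        assert evaluate_objective(inst, {"a": 110.0, "b": 40.0}) == pytest.approx(0.3)

    def test_variable_count_is_three_per_food(self):
        inst = _instance(
            self.foods, {"a": 100.0, "b": 50.0}, [], {"a": (0, 500), "b": (0, 500)}
        )
        assert inst.num_variables == 3 * inst.n_foods == 6

    def test_identity_when_observed_diet_feasible(self):
        rows = [LinearRow("fiber_min", "ge", 2.0, nutrient="fiber", relaxable=True)]
        inst = _instance(
            self.foods, {"a": 100.0, "b": 50.0}, rows, {"a": (0, 500), "b": (0, 500)}
        )
        res = solve_step1(inst)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(0.0, abs=1e-9)
        assert res.q_opt == pytest.approx({"a": 100.0, "b": 50.0}, abs=1e-6)

    def test_unattainable_floor_reports_infeasible(self):
        rows = [LinearRow("fiber_min", "ge", 100.0, nutrient="fiber", relaxable=True)]
        inst = _instance(
            self.foods, {"a": 100.0, "b": 50.0}, rows, {"a": (0, 500), "b": (0, 500)}
        )
        assert solve_step1(inst).status == "infeasible"


def _grid_minimum_2food(inst, row, step=0.1):
    """Brute-force minimum of the step-1 objective on a 0.1 g grid."""
    (alo, ahi), (blo, bhi) = (
        (inst.lower[k], inst.upper[k]) for k in range(2)
    )
    a = np.arange(alo, ahi + step / 2, step)
    b = np.arange(blo, bhi + step / 2, step)
    A, B = np.meshgrid(a, b, indexing="ij")
    e = inst.energy_coefficients()
    energy = e[0] * A + e[1] * B
    coeff = row.coefficients(inst.food_items)
    value = coeff[0] * A + coeff[1] * B
    feasible = (np.abs(energy - inst.energy_kcal) <= inst.energy_tol) & (
        value >= row.rhs - 1e-9
    )
    obj = np.abs(A - inst.q_obs[0]) / inst.ref[0] + np.abs(B - inst.q_obs[1]) / inst.ref[1]
    return obj[feasible].min()


class TestGridOracle:
    def test_two_food_lp_matches_grid(self):
        foods = [
            make_food("a", energy=100.0, fiber=1.0),
            make_food("b", energy=100.0, fiber=5.0),
        ]
        row = LinearRow("fiber_min", "ge", 25.0, nutrient="fiber", relaxable=True)
        inst = _instance(
            foods,
            {"a": 1200.0, "b": 100.0},
            [row],
            {"a": (900.0, 1100.0), "b": (250.0, 400.0)},
            energy=1300.0,
        )
        res = solve_step1(inst)
        assert res.status == "optimal"
        grid = _grid_minimum_2food(inst, row)
        resolution = 0.1 * float(np.sum(1.0 / inst.ref)) + 1e-9
        assert res.objective <= grid + 1e-9
        assert abs(res.objective - grid) <= resolution

    def test_three_food_lp_matches_grid(self):
        foods = [
            make_food("p", energy=100.0),
            make_food("q", energy=100.0, calcium=50.0),
            make_food("r", energy=100.0, calcium=100.0),
        ]
        row = LinearRow("calcium_min", "ge", 12.0, nutrient="calcium", relaxable=True)
        inst = _instance(
            foods,
            {"p": 10.0, "q": 6.0, "r": 4.0},
            [row],
            {"p": (0.0, 20.0), "q": (0.0, 20.0), "r": (0.0, 20.0)},
            energy=20.0,
        )
        res = solve_step1(inst)
        assert res.status == "optimal"

        step = 0.1
        axis = np.arange(0.0, 20.0 + step / 2, step)
        e = inst.energy_coefficients()
        coeff = row.coefficients(inst.food_items)
        best = np.inf
        Q, R = np.meshgrid(axis, axis, indexing="ij")
        for p in axis:
            energy = e[0] * p + e[1] * Q + e[2] * R
            value = coeff[0] * p + coeff[1] * Q + coeff[2] * R
            feasible = (np.abs(energy - inst.energy_kcal) <= inst.energy_tol) & (
                value >= row.rhs - 1e-9
            )
            if not feasible.any():
                continue
            obj = (
                abs(p - inst.q_obs[0]) / inst.ref[0]
                + np.abs(Q - inst.q_obs[1]) / inst.ref[1]
                + np.abs(R - inst.q_obs[2]) / inst.ref[2]
            )
            best = min(best, obj[feasible].min())
        resolution = step * float(np.sum(1.0 / inst.ref)) + 1e-9
        assert res.objective <= best + 1e-9
        assert abs(res.objective - best) <= resolution


class TestDiagnosis:
    def test_unreachable_floor_is_the_limiting_row(self):
        foods = [make_food("a", energy=100.0), make_food("b", energy=100.0)]
        rows = [
            LinearRow("vitamin_d_min", "ge", 10.0, nutrient="vitamin_d", relaxable=True),
            LinearRow("fiber_min", "ge", 0.0, nutrient="fiber", relaxable=True),
        ]
        inst = _instance(
            foods, {"a": 100.0, "b": 50.0}, rows, {"a": (0, 500), "b": (0, 500)}
        )
        assert diagnose_limiting_nutrients(inst) == {"vitamin_d_min"}

    def test_feasible_two_step_returns_empty_limiting_set(self):
        foods = [make_food("a", energy=100.0, fiber=5.0)]
        rows = [LinearRow("fiber_min", "ge", 2.0, nutrient="fiber", relaxable=True)]
        inst = _instance(foods, {"a": 100.0}, rows, {"a": (0, 500)})
        res = run_two_step(inst)
        assert res.step_used == 1
        assert res.limiting_nutrients == frozenset()

    def test_jointly_infeasible_rows_match_deletion_filter(self):
        # the zinc floor is only reachable through a high-sodium food that
        # the sodium cap forbids; relaxing either row restores feasibility
        foods = [
            make_food("plain", energy=100.0),
            make_food("salty", energy=100.0, zinc=10.0, sodium=2000.0),
        ]
        rows = [
            LinearRow("zinc_min", "ge", 12.0, nutrient="zinc", relaxable=True),
            LinearRow("sodium_max_obs", "le", 500.0, nutrient="sodium", relaxable=True),
        ]
        inst = _instance(
            foods, {"plain": 140.0, "salty": 10.0}, rows, {"plain": (0, 500), "salty": (0, 500)}
        )
        assert solve_step1(inst).status == "infeasible"
        elastic = diagnose_limiting_nutrients(inst)
        oracle = deletion_filter(inst)
        assert len(oracle) == 1
        assert elastic <= {"zinc_min", "sodium_max_obs"}
        kept = tuple(r for r in inst.hard_rows if r.name not in elastic)
        assert solve_step1(replace(inst, hard_rows=kept)).status == "optimal"

    def test_diagnosis_without_relaxable_rows_raises(self):
        foods = [make_food("a", energy=100.0)]
        rows = [LinearRow("meat", "le", 1.0, foods=("a",), relaxable=False)]
        inst = _instance(foods, {"a": 100.0}, rows, {"a": (50, 500)})
        with pytest.raises(DiagnosisError):
            diagnose_limiting_nutrients(inst)


class TestStep2:
    def test_empty_limiting_set_is_identity(self):
        foods = [make_food("a", energy=100.0)]
        inst = _instance(foods, {"a": 100.0}, [], {"a": (0, 500)})
        assert build_step2_model(inst, set()) is inst

    def test_non_relaxable_row_cannot_be_relaxed(self):
        foods = [make_food("a", energy=100.0)]
        rows = [LinearRow("meat", "le", 50.0, foods=("a",), relaxable=False)]
        inst = _instance(foods, {"a": 100.0}, rows, {"a": (0, 500)})
        with pytest.raises(InvalidInputError):
            build_step2_model(inst, {"meat"})

    @pytest.mark.parametrize(
        "example,expected", [(worked_example_floor, 10.0), (worked_example_cap, 0.5)]
    )
    def test_worked_example_deviations_exact(self, example, expected):
        we = example()
        inst = build_step1_model(we.stratum, we.foods, we.constraint_set)
        res = run_two_step(inst)
        assert res.status == "optimal"
        assert res.step_used == 2
        assert res.limiting_nutrients == {we.row_name}
        assert res.deviations[we.row_name] == pytest.approx(we.expected_deviation, abs=1e-9)

    def test_deviation_equals_target_minus_attainable_max(self):
        fx = generate_infeasible_instance("vitamin_d", 7)
        cset = fx.instance.constraint_set("moderate", "free")
        inst = build_step1_model(fx.instance.stratum, fx.instance.foods, cset)
        res = run_two_step(inst)
        assert res.step_used == 2
        assert res.limiting_nutrients == {f"{fx.nutrient}_min"}
        inst2 = build_step2_model(inst, {f"{fx.nutrient}_min"})
        lo, hi = attainable_range(inst2, fx.nutrient)
        assert hi == pytest.approx(fx.max_attainable, rel=1e-6)
        assert res.deviations[f"{fx.nutrient}_min"] == pytest.approx(
            fx.target - hi, rel=1e-6
        )
        # deviation + optimized content reconstructs the target
        assert res.nutrients[fx.nutrient] + res.deviations[f"{fx.nutrient}_min"] == pytest.approx(
            fx.target, rel=1e-6
        )


class TestTwoStepOnStrata:
    def test_feasible_stratum_uses_step_one(self, feasible_instance):
        cset = feasible_instance.constraint_set("moderate", "constrained")
        res = optimize_stratum(feasible_instance.stratum, feasible_instance.foods, cset)
        assert (res.status, res.step_used) == ("optimal", 1)
        assert res.limiting_nutrients == frozenset()
        assert res.diagnostics["certified"]
        assert res.scenario == "constrained_moderate"

    def test_cost_relaxation_never_hurts(self, feasible_instance):
        free = optimize_stratum(
            feasible_instance.stratum,
            feasible_instance.foods,
            feasible_instance.constraint_set("moderate", "free"),
        )
        constrained = optimize_stratum(
            feasible_instance.stratum,
            feasible_instance.foods,
            feasible_instance.constraint_set("moderate", "constrained"),
        )
        assert free.objective <= constrained.objective + 1e-9

    def test_wider_acceptability_never_hurts(self, feasible_instance):
        objs = {}
        for level in ("rigorous", "moderate", "flexible"):
            res = optimize_stratum(
                feasible_instance.stratum,
                feasible_instance.foods,
                feasible_instance.constraint_set(level, "constrained"),
            )
            objs[level] = res.objective
        assert objs["flexible"] <= objs["moderate"] + 1e-9
        assert objs["moderate"] <= objs["rigorous"] + 1e-9
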