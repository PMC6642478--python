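"""Two-step LP/goal-programming optimizer.

Step 1 minimizes the summed relative departure of the optimized diet from
the observed diet,

    Y = sum_i |Q_i_opt - Q_i_obs| / ref_i ,

subject to every nutritional, acceptability, food-group and (optionally)
cost row.  The absolute values are linearized with a positive/negative
deviation split per food: Q_i - Q_i_obs = u_i - v_i with u_i, v_i >= 0 and
objective coefficients 1/ref_i on both; minimization drives min(u_i, v_i)
to 0.  ``ref_i`` is the observed intake, or the region mean for foods being
introduced (whose observed intake is 0).

If step 1 is infeasible, an elastic diagnosis adds a nonnegative normalized
slack to every *relaxable* (nutritional) row and minimizes the total slack;
rows that still need slack at the optimum are the limiting nutrients.  Step
2 removes those rows as hard constraints and instead penalizes, per
limiting nutrient n, the normalized undesirable deviation

    d_n / target_n ,   d_n >= target_n - nut_n(Q)   (floors)
                       d_n >= nut_n(Q) - target_n   (caps),  d_n >= 0,

added to the food-departure objective.  Energy, acceptability, food-group
and cost rows are never relaxed.

All solves use HiGHS dual simplex (single-threaded, deterministic) with
foods in sorted-id order; reported solutions are re-checked against every
retained row at 1e-6 relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import (
    ConfigurationError,
    DiagnosisError,
    InvalidInputError,
    SolverError,
)
from .food_data import FoodItem, StratumProfile, compute_diet_cost, compute_nutrient_content
from .recommendations import ConstraintSet, LinearRow

__all__ = [
    "LpInstance",
    "OptimizationResult",
    "build_step1_model",
    "solve_step1",
    "diagnose_limiting_nutrients",
    "build_step2_model",
    "solve_step2",
    "optimize_stratum",
    "run_two_step",
    "evaluate_objective",
    "attainable_range",
]

_SLACK_TOL = 1e-6
_VERIFY_TOL = 1e-6


@dataclass(frozen=True)
class LpInstance:
    """One assembled model: decision variables are the food quantities
    ``Q`` (g/day, bounded by the acceptability interval), the per-food
    deviation split ``u, v >= 0`` and, in step 2, one deviation variable
    ``d_n >= 0`` per limiting row."""

    food_ids: tuple[str, ...]
    food_items: tuple[FoodItem, ...]
    q_obs: np.ndarray
    ref: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    energy_kcal: float
    energy_tol: float
    hard_rows: tuple[LinearRow, ...]
    cost_limit: float | None = None
    cost_equality: bool = False
    limiting_rows: tuple[LinearRow, ...] = ()
    nutrient_weight: float = 1.0
    constraint_set: ConstraintSet | None = None

    @property
    def n_foods(self) -> int:
        return len(self.food_ids)

    @property
    def num_variables(self) -> int:
        return 3 * self.n_foods + len(self.limiting_rows)

    def energy_coefficients(self) -> np.ndarray:
        return np.array([f.composition.get("energy", 0.0) / 100.0 for f in self.food_items])

    def price_coefficients(self) -> np.ndarray:
        return np.array([f.price / 100.0 for f in self.food_items])


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of a (two-step) optimization for one stratum and scenario."""

    status: str  # "optimal" | "infeasible" | "error"
    step_used: int
    q_opt: dict[str, float] | None = None
    objective: float | None = None
    objective_food: float | None = None
    objective_nutrient: float | None = None
    limiting_nutrients: frozenset[str] = frozenset()
    deviations: dict[str, float] = field(default_factory=dict)
    nutrients: dict[str, float] | None = None
    cost: float | None = None
    stratum_id: str | None = None
    scenario: str | None = None
    diagnostics: dict = field(default_factory=dict)


def _target_scale(rhs: float) -> float:
    return abs(rhs) if abs(rhs) > 1e-9 else 1.0


def build_step1_model(
    stratum: StratumProfile,
    food_items: Sequence[FoodItem],
    constraints: ConstraintSet,
) -> LpInstance:
    """Assemble the step-1 model for one stratum.

    Foods are ordered by sorted id for deterministic solves.  Every stratum
    food needs acceptability bounds and a positive deviation reference.
    """
    index = {f.id: f for f in food_items}
    food_ids = tuple(sorted(stratum.foods))
    missing = [fid for fid in food_ids if fid not in index]
    if missing:
        raise ConfigurationError(f"no FoodItem for foods {missing}")
    items = tuple(index[fid] for fid in food_ids)

    lower = np.empty(len(food_ids))
    upper = np.empty(len(food_ids))
    ref = np.empty(len(food_ids))
    q_obs = np.array([stratum.q_obs[fid] for fid in food_ids])
    for k, fid in enumerate(food_ids):
        try:
            lower[k], upper[k] = constraints.acceptability[fid]
        except KeyError:
            raise ConfigurationError(f"no acceptability bounds for food {fid!r}") from None
        r = constraints.reference_intake.get(fid, q_obs[k])
        if r <= 0:
            if upper[k] == 0.0:
                r = 1.0  # food pinned to 0; denominator is irrelevant
            else:
                raise ConfigurationError(
                    f"food {fid!r} has no positive reference quantity for the "
                    "relative-deviation objective and no introduction rule"
                )
        ref[k] = r

    return LpInstance(
        food_ids=food_ids,
        food_items=items,
        q_obs=q_obs,
        ref=ref,
        lower=lower,
        upper=upper,
        energy_kcal=constraints.energy_kcal,
        energy_tol=constraints.energy_tol,
        hard_rows=tuple(constraints.rows),
        cost_limit=constraints.cost_limit,
        cost_equality=constraints.cost_equality,
        constraint_set=constraints,
    )


def _assemble(instance: LpInstance):
    """Matrices for the deviation-split LP over x = [Q, u, v, d]."""
    n = instance.n_foods
    m = len(instance.limiting_rows)
    nvar = 3 * n + m
    e = instance.energy_coefficients()

    A_ub_rows, b_ub = [], []

    def ub_row(coeffs_q: np.ndarray, coeffs_d: np.ndarray | None, rhs: float) -> None:
        row = np.zeros(nvar)
        row[:n] = coeffs_q
        if coeffs_d is not None:
            row[3 * n :] = coeffs_d
        A_ub_rows.append(row)
        b_ub.append(rhs)

    # Energy equality with solver tolerance.
    ub_row(e, None, instance.energy_kcal + instance.energy_tol)
    ub_row(-e, None, -(instance.energy_kcal - instance.energy_tol))

    for row in instance.hard_rows:
        a = row.coefficients(instance.food_items)
        if row.sense == "le":
            ub_row(a, None, row.rhs)
        else:
            ub_row(-a, None, -row.rhs)

    if instance.cost_limit is not None and not instance.cost_equality:
        ub_row(instance.price_coefficients(), None, instance.cost_limit)

    for j, row in enumerate(instance.limiting_rows):
        a = row.coefficients(instance.food_items)
        d = np.zeros(m)
        d[j] = -1.0
        if row.sense == "ge":
            ub_row(-a, d, -row.rhs)  # target - a.Q <= d
        else:
            ub_row(a, d, row.rhs)  # a.Q - target <= d

    # Deviation-split equalities Q - u + v = Q_obs.
    A_eq = np.zeros((n + (1 if instance.cost_limit is not None and instance.cost_equality else 0), nvar))
    b_eq = np.zeros(A_eq.shape[0])
    for k in range(n):
        A_eq[k, k] = 1.0
        A_eq[k, n + k] = -1.0
        A_eq[k, 2 * n + k] = 1.0
        b_eq[k] = instance.q_obs[k]
    if instance.cost_limit is not None and instance.cost_equality:
        A_eq[n, :n] = instance.price_coefficients()
        b_eq[n] = instance.cost_limit

    c = np.zeros(nvar)
    c[n : 2 * n] = 1.0 / instance.ref
    c[2 * n : 3 * n] = 1.0 / instance.ref
    for j, row in enumerate(instance.limiting_rows):
        c[3 * n + j] = instance.nutrient_weight / _target_scale(row.rhs)

    bounds = (
        [(lo, hi) for lo, hi in zip(instance.lower, instance.upper)]
        + [(0.0, None)] * (2 * n)
        + [(0.0, None)] * m
    )
    return c, np.array(A_ub_rows), np.array(b_ub), A_eq, b_eq, bounds


def _linprog(c, A_ub, b_ub, A_eq, b_eq, bounds):
    return linprog(
        c,
        A_ub=A_ub if len(A_ub) else None,
        b_ub=b_ub if len(b_ub) else None,
        A_eq=A_eq if A_eq is not None and len(A_eq) else None,
        b_eq=b_eq if b_eq is not None and len(b_eq) else None,
        bounds=bounds,
        method="highs-ds",
    )


def verify_solution(
    instance: LpInstance, q: np.ndarray, rel_tol: float = _VERIFY_TOL
) -> tuple[bool, float, dict[str, float]]:
    """Feasibility certificate: relative violation of every retained row,
    the energy band, the cost row and the acceptability box."""
    violations: dict[str, float] = {}

    def record(name: str, violation: float, scale: float) -> None:
        rel = violation / max(1.0, abs(scale))
        if rel > 0:
            violations[name] = rel

    e = float(instance.energy_coefficients() @ q)
    record("energy", abs(e - instance.energy_kcal) - instance.energy_tol, instance.energy_kcal)
    for row in instance.hard_rows:
        val = float(row.coefficients(instance.food_items) @ q)
        gap = row.rhs - val if row.sense == "ge" else val - row.rhs
        record(row.name, gap, row.rhs)
    if instance.cost_limit is not None:
        cost = float(instance.price_coefficients() @ q)
        if instance.cost_equality:
            record("cost", abs(cost - instance.cost_limit), instance.cost_limit)
        else:
            record("cost", cost - instance.cost_limit, instance.cost_limit)
    box = np.maximum(instance.lower - q, q - instance.upper)
    k = int(np.argmax(box))
    record(f"bounds[{instance.food_ids[k]}]", float(box[k]), float(instance.upper[k]))

    worst = max(violations.values(), default=0.0)
    return worst <= rel_tol, worst, {k: v for k, v in violations.items() if v > rel_tol}


def _solve(instance: LpInstance, step: int) -> OptimizationResult:
    c, A_ub, b_ub, A_eq, b_eq, bounds = _assemble(instance)
    res = _linprog(c, A_ub, b_ub, A_eq, b_eq, bounds)
    if res.status == 2:
        return OptimizationResult(status="infeasible", step_used=step)
    if res.status != 0:
        return OptimizationResult(
            status="error",
            step_used=step,
            diagnostics={"solver_status": res.status, "message": res.message},
        )

    n = instance.n_foods
    q = np.clip(res.x[:n], instance.lower, instance.upper)
    q_map = dict(zip(instance.food_ids, q.tolist()))
    food_term = float(np.sum(np.abs(q - instance.q_obs) / instance.ref))
    deviations = {}
    nutrient_term = 0.0
    limiting = frozenset(r.name for r in instance.limiting_rows)
    for row in instance.limiting_rows:
        val = float(row.coefficients(instance.food_items) @ q)
        dev = max(0.0, row.rhs - val if row.sense == "ge" else val - row.rhs)
        deviations[row.name] = dev
        nutrient_term += instance.nutrient_weight * dev / _target_scale(row.rhs)

    ok, worst, details = verify_solution(instance, q)
    return OptimizationResult(
        status="optimal",
        step_used=step,
        q_opt=q_map,
        objective=food_term + nutrient_term,
        objective_food=food_term,
        objective_nutrient=nutrient_term,
        limiting_nutrients=limiting,
        deviations=deviations,
        nutrients=compute_nutrient_content(q_map, instance.food_items),
        cost=compute_diet_cost(q_map, {f.id: f for f in instance.food_items}),
        diagnostics={
            "certified": ok,
            "max_relative_violation": worst,
            "violations": details,
            "solver_objective": float(res.fun),
        },
    )


def solve_step1(instance: LpInstance) -> OptimizationResult:
    """Solve the step-1 model (all nutritional rows hard)."""
    if instance.limiting_rows:
        raise InvalidInputError("step-1 instance must not carry limiting rows")
    return _solve(instance, step=1)


def solve_step2(instance: LpInstance) -> OptimizationResult:
    """Solve a step-2 goal program (limiting rows penalized, not imposed)."""
    return _solve(instance, step=2)


def diagnose_limiting_nutrients(instance: LpInstance, tol: float = _SLACK_TOL) -> set[str]:
    """Elastic diagnosis of an infeasible step-1 instance.

    Every relaxable row gets a nonnegative slack normalized by its target so
    that slacks on different nutrient scales are comparable; the LP
    minimizes the total slack subject to all non-relaxable rows.  Rows with
    slack above ``tol`` form the limiting set.
    """
    relaxable = [r for r in instance.hard_rows if r.relaxable]
    if not relaxable:
        raise DiagnosisError("infeasible model has no relaxable rows to diagnose")
    n = instance.n_foods
    m = len(relaxable)
    nvar = n + m
    e = instance.energy_coefficients()

    A_ub_rows, b_ub = [], []

    def ub_row(coeffs_q, slack_col, slack_coeff, rhs):
        row = np.zeros(nvar)
        row[:n] = coeffs_q
        if slack_col is not None:
            row[n + slack_col] = slack_coeff
        A_ub_rows.append(row)
        b_ub.append(rhs)

    ub_row(e, None, 0.0, instance.energy_kcal + instance.energy_tol)
    ub_row(-e, None, 0.0, -(instance.energy_kcal - instance.energy_tol))
    j = 0
    for row in instance.hard_rows:
        a = row.coefficients(instance.food_items)
        if row.relaxable:
            scale = _target_scale(row.rhs)
            if row.sense == "le":
                ub_row(a, j, -scale, row.rhs)
            else:
                ub_row(-a, j, -scale, -row.rhs)
            j += 1
        else:
            if row.sense == "le":
                ub_row(a, None, 0.0, row.rhs)
            else:
                ub_row(-a, None, 0.0, -row.rhs)
    if instance.cost_limit is not None:
        p = instance.price_coefficients()
        if instance.cost_equality:
            ub_row(p, None, 0.0, instance.cost_limit)
            ub_row(-p, None, 0.0, -instance.cost_limit)
        else:
            ub_row(p, None, 0.0, instance.cost_limit)

    c = np.concatenate([np.zeros(n), np.ones(m)])
    bounds = [(lo, hi) for lo, hi in zip(instance.lower, instance.upper)] + [(0.0, None)] * m
    res = _linprog(c, np.array(A_ub_rows), np.array(b_ub), None, None, bounds)
    if res.status == 2:
        raise DiagnosisError(
            "elastic model infeasible: the non-relaxable rows (energy, "
            "acceptability, cost, food-group) conflict on their own"
        )
    if res.status != 0:
        raise SolverError(f"elastic diagnosis failed: {res.message}")
    slacks = res.x[n:]
    limiting = {row.name for row, s in zip(relaxable, slacks) if s > tol}
    if not limiting:
        raise DiagnosisError(
            "step-1 reported infeasible but the elastic relaxation needs no slack"
        )
    return limiting


def build_step2_model(instance: LpInstance, limiting: set[str]) -> LpInstance:
    """Move the named rows from hard constraints to penalized deviations."""
    if not limiting:
        return instance
    names = {r.name: r for r in instance.hard_rows}
    unknown = set(limiting) - set(names)
    if unknown:
        raise InvalidInputError(f"unknown constraint rows: {sorted(unknown)}")
    non_relaxable = [name for name in limiting if not names[name].relaxable]
    if non_relaxable:
        raise InvalidInputError(
            f"rows {sorted(non_relaxable)} are not nutritional rows and cannot be relaxed"
        )
    moved = tuple(r for r in instance.hard_rows if r.name in limiting)
    kept = tuple(r for r in instance.hard_rows if r.name not in limiting)
    return replace(
        instance,
        hard_rows=kept,
        limiting_rows=instance.limiting_rows + moved,
    )


def run_two_step(instance: LpInstance) -> OptimizationResult:
    """Run step 1; on infeasibility, diagnose limiting nutrients and run the
    step-2 goal program."""
    res1 = solve_step1(instance)
    if res1.status != "infeasible":
        return res1
    limiting = diagnose_limiting_nutrients(instance)
    res2 = solve_step2(build_step2_model(instance, limiting))
    if res2.status == "infeasible":
        raise DiagnosisError(
            f"model remains infeasible after relaxing {sorted(limiting)}"
        )
    return res2


def optimize_stratum(
    stratum: StratumProfile,
    food_items: Sequence[FoodItem],
    constraints: ConstraintSet,
    *,
    scenario: str | None = None,
) -> OptimizationResult:
    """Two-step optimization of one stratum under an assembled constraint
    set; the result records which step produced it and the limiting set."""
    instance = build_step1_model(stratum, food_items, constraints)
    result = run_two_step(instance)
    return replace(
        result,
        stratum_id=stratum.stratum_id,
        scenario=scenario
        or (
            f"{constraints.cost_regime}_{constraints.level}"
            if constraints.cost_regime and constraints.level
            else None
        ),
    )


def evaluate_objective(instance: LpInstance, q: Mapping[str, float] | np.ndarray) -> float:
    """Step-1 objective (summed relative food deviation) at a candidate diet."""
    if isinstance(q, Mapping):
        q = np.array([q[fid] for fid in instance.food_ids])
    return float(np.sum(np.abs(np.asarray(q) - instance.q_obs) / instance.ref))


def attainable_range(instance: LpInstance, nutrient: str) -> tuple[float, float]:
    """Minimum and maximum content of ``nutrient`` attainable under the
    instance's *hard* rows, energy band, cost row and acceptability box
    (limiting rows, if any, are ignored).  Independent check for deviation
    magnitudes."""
    base = replace(instance, limiting_rows=())
    n = base.n_foods
    density = np.array(
        [f.composition.get(nutrient, 0.0) / 100.0 for f in base.food_items]
    )
    _, A_ub, b_ub, _, _, _ = _assemble(base)
    A_q = A_ub[:, :n]
    bounds = [(lo, hi) for lo, hi in zip(base.lower, base.upper)]
    out = []
    for sign in (1.0, -1.0):
        res = _linprog(sign * density, A_q, b_ub, None, None, bounds)
        if res.status != 0:
            raise SolverError(f"attainable-range solve failed: {res.message}")
        out.append(float(density @ res.x))
    return out[0], out[1]
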