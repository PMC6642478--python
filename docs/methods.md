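# Methods

## Problem and unit of analysis

The package models diet optimization at the level of a *geographic stratum*
(GS): an aggregated survey stratum with its own mean observed diet
(grams/day per food item), food prices (currency per 100 g edible portion)
and food list.  For each GS and each of six scenarios — cost regime
(cost-free vs cost-constrained) × acceptability level (rigorous, moderate,
flexible) — one linear program is solved whose decision variables are the
daily grams of each food.

## Observed diets, prices, aggregation

* An individual's intake of a food is the mean of the two food records when
  both exist; a missing second record is skipped, never imputed.  The GS
  mean weights individuals by sampling weights.
* Purchase prices are converted to currency per 100 g of edible,
  as-consumed portion: the purchased mass is multiplied by the edible
  fraction (waste removal) and by the cooking yield (raw → as consumed);
  both factors default to 1.  The multiplicative convention is this
  package's choice; sources that publish correction and cooking factors
  rarely state the composition rule.
* Prices observed in different months are deflated to a common reference
  date with a consumer-price index (price × index_ref / index_at_purchase).
* Aggregated items (several survey foods folded into one model item) use
  the report-frequency-weighted mean, the same operator for prices and for
  compositions.

## Constraint set

Nutritional rows (defaults, per model):

| Row | Bound |
| --- | --- |
| energy | = observed energy (±0.5 kcal solver tolerance) |
| carbohydrate | 45–55 %kcal |
| free sugar | ≤ 10 %kcal and ≤ observed grams |
| fiber | ≥ 31 g and ≥ observed |
| protein | ≥ 10 %kcal |
| total fat | 25–35 %kcal |
| saturated fat | ≤ 10 %kcal and ≤ observed grams |
| trans fat | ≤ 1 %kcal and ≤ observed grams |
| sodium | ≤ observed mg |
| 16 micronutrients | ≥ RDA-derived floors (calcium 1021 mg … folate 426 µg DFE), each also ≥ observed |
| red + processed meat | ≤ 500 g/week (expressed as ≤ 500/7 g/day) |

Notes on the choices that were genuinely open:

* **%kcal conversion.** %kcal rows are converted to linear gram-space rows
  at the stratum's *fixed* observed energy using Atwater factors 4 kcal/g
  (carbohydrate, protein, free sugar) and 9 kcal/g (fats); fiber carries no
  energy.  Because optimized energy is constrained equal to observed
  energy, this linearization is exact up to the ±0.5 kcal tolerance.
* **Strict inequalities** ("< 10 %kcal") are carried as ≤, the LP
  convention.
* **Cost row direction.** The cost-constrained regime bounds optimized cost
  *at or below* the observed cost (an equality option exists).  A ≤ bound
  dominates an equality: every equality-feasible diet remains feasible and
  the optimum can only improve.
* **Nutrients without an RDA** (e.g. potassium) carry no row.  An optional
  extra-row hook exists for auditing undocumented constraints (for
  instance, pinning MUFA), but none is installed by default.
* **RDA weighting.** When an RDA table and population age-sex frequencies
  are supplied, each micronutrient floor is the frequency-weighted mean of
  the group RDAs; the bound always lies between the smallest and largest
  group RDA.

## Acceptability bounds

For each region and food, stratum-level mean intakes are pooled across the
*full* collection of strata, excluding strata where the food's mean is
zero.  The lower bound is the 10th percentile (same exclusion as the upper
bounds); the upper bound is the 70th/80th/90th percentile for
rigorous/moderate/flexible.  Percentiles use linear interpolation between
order statistics ("type 7") — fixed and documented because the bounds feed
the LP.  Foods never reported in a region get (0, 0).

Foods with zero observed intake in a GS (reported elsewhere in the same
state) may be *introduced*: their lower bound is forced to 0 — a positive
regional 10th percentile would otherwise make introduction mandatory — and
their relative-deviation denominator is the region mean over non-zero
strata, so introduction is penalized in proportion to typical consumption.

## Optimizer

* **Linearization.** Per food, `Q_i − Q_obs_i = u_i − v_i` with
  `u_i, v_i ≥ 0` and objective coefficients `1/ref_i` on both; at any
  optimum `min(u_i, v_i) = 0`, so `u_i + v_i = |Q_i − Q_obs_i|` exactly.
* **Elastic diagnosis.** On step-1 infeasibility, every *relaxable* row
  (all nutritional rows, including the observed-linked floors and caps)
  receives a slack normalized by its target; the LP minimizes total slack
  subject to the never-relaxed rows (energy, acceptability, cost, the meat
  cap).  Rows with slack > 1e-6 form the limiting set.  This is an elastic
  filter, not a vendor IIS routine; on jointly-infeasible row pairs it
  returns a minimal-total-slack explanation, which the tests cross-check
  against a deletion-filter oracle.  If even the elastic model is
  infeasible, the never-relaxed rows conflict on their own and the model is
  reported as an error (this occurs only in aggressively down-scaled
  synthetic surveys whose region bounds cannot carry the energy target).
* **Step 2.** Limiting rows become penalized deviations: for a floor,
  `d_n ≥ target_n − nut_n(Q)`; for a cap, `d_n ≥ nut_n(Q) − target_n`;
  `d_n ≥ 0`; the objective gains `d_n / target_n` (equal weight with the
  food term by default; a weight knob exists).
* **Determinism and tolerances.** Foods enter in sorted-id order; HiGHS
  dual simplex, single-threaded.  Energy equality uses a ±0.5 kcal band to
  absorb solver arithmetic.  Every reported optimum is re-checked against
  all retained rows at 1e-6 relative tolerance and carries a certificate
  flag.  Alternate optima are solver-determined; analyses should rely on
  the objective value and deviations, which are unique, rather than on
  individual food coordinates.

## Synthetic data generator

The generator emulates the derived structure of a national budget/dietary
survey, not its raw microdata:

* **Universe.** ~105 foods across 26 subgroups (7 groups), densities drawn
  log-normally around a packaged template and *calibrated* so a reference
  diet — subgroup-typical amounts at the 1,792 kcal/day energy target —
  reproduces a target nutrient profile.  The `natural` mode targets a
  low-income population profile in which calcium, magnesium, vitamins D and
  E and fiber fall short of their floors while most other nutrients do
  not; under it, essentially every stratum is step-1 infeasible and the
  goal-programming path is exercised, with the familiar nutrients
  dominating the limiting sets.  Prices are log-normal and strictly
  positive.
* **Strata.** Default 89 optimization strata nested in a twice-larger
  all-income collection (lower bounds and percentiles are taken from the
  full collection); 37–92 reported foods per stratum plus same-state
  introductions; observed energy within 1% of the target (default ±0.5%).
* **Guaranteed fixtures.** `generate_feasible_instance` builds a 26-food
  stratum around a hidden diet that satisfies every row with margin
  (micronutrients 15% above floors, meat at 80% of the weekly cap,
  macronutrient shares mid-band), then injects a dairy/fruit deficit so
  step 1 has real work; every candidate is verified by solving all six
  scenarios before being returned.  `generate_infeasible_instance` pins one
  nutrient to a single carrier food whose upper bound equals its observed
  amount, making the maximum attainable content — and hence the step-2
  deviation — exact and checkable against an LP max-attainable oracle.
* **What it does not emulate.** Real food names and price levels, survey
  design effects (clustering, weighting beyond stratum means), seasonal and
  regional composition differences, and correlated nutrient densities
  within foods.  Passing tests therefore demonstrate correctness of the
  machinery and the qualitative behavior of the method, not numerical
  agreement with any real population.

## Problem sizes used in the test and acceptance runs

The default sweep (89 strata × 6 scenarios = 534 models, ~105 foods per
model) solves in well under a minute.  The acceptance quantities use the
two 2-food worked examples and one 26-food feasible stratum; oracle
comparisons use 2–3-food grids at 0.1 g resolution and 20 single-cause
infeasible fixtures.

## Known limitations

* Limiting sets on jointly-infeasible constraint systems are one minimal
  explanation among possibly several; a different diagnosis algorithm (for
  example a vendor IIS) may name a different but equally valid set.
* The ±0.5 kcal energy band means "equality" is a narrow interval; reported
  energies can differ from the observed energy by up to that amount.
* Cost-constrained feasibility of step 2 is guaranteed only when the
  observed diet lies within its acceptability bounds; otherwise a model can
  legitimately fail, and the pipeline records it rather than dropping it.
* Intake-inadequacy prevalence estimation, survey-variance machinery and
  raw microdata parsing are out of scope.
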