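# Methods

This note documents the models implemented in `wardstock`, the choices made
where the design was genuinely open, and what the synthetic study does and
does not show.

## Setting

An intensive-care ward with `B` beds stocks a set `F` of critical drugs
(antibiotics) with low, intermittent, therapy-driven demand.  Drugs are
consumed in doses, ordered in boxes of `U^f` doses at `c^f` EUR per dose,
and stored on a dedicated per-drug shelf (capacity `C^f` boxes) with
overflow to a shared per-group shelf (capacity in volume units, `V̄_g`),
used only when the dedicated shelf is full.  Regular orders have a one-day
lead time; nothing is received on Sundays and no regular order is placed on
Saturdays (a Saturday order would arrive on Monday).  A stock-out triggers a
rush order served within hours from a regional warehouse at a high fixed
cost per drug involved (300 EUR by default).

The package's hybrid policy combines *push* orders — pre-scheduled for each
planning period by a lot-sizing MILP fed with a demand forecast — and
*pull* orders issued by the simulated ward: rush orders on stock-outs and
*extra* (restocking) orders when an administered drug ends the day strictly
below its safety floor `s̲^f`.

## Demand generation

The ward is advanced day by day.  Five empirical distributions drive the
process, each estimated from event logs as favourable over possible cases:

* `pd1(i | v)` — number of admissions on a day with `v` empty beds
  (vacancy is computed after the day's discharges, and admissions are
  additionally truncated at the vacancy: a hard physical constraint);
* `pd2(class)` — class of a new patient;
* `pd3(los | class)` — length of stay;
* `pd4(day | class, los)` — day after admission at which an infection is
  first suspected, with an explicit `never` outcome so masses sum to one;
* `pd5(lag | class, los)` — days until the microbiology lab responds.

Each class carries a therapy tree.  The default tree has three stages:
a baseline supportive treatment until the (stochastic, `pd4`-distributed)
infection onset; a broad-spectrum *empirical therapy* of two drugs until
the lab responds (`pd5`); then a branch — de-escalation back to the
baseline drug on success, or a *targeted therapy* drug on failure
(success probability 0.6 by default, consistent with typical culture
positivity).  Node treatments prescribe drugs at their daily posology.
Trees are configuration data, not code: deeper trees, other treatments or
different branch probabilities can be supplied.  Unseen `(class, los)`
conditioning keys fall back to pooling over the class.

Death is sampled at admission with the class death probability and recorded
in the event logs (it feeds the descriptive statistics); the stay still
spans the sampled length of stay, interpreted as admission-to-outcome time.
Timing death inside the tree is possible via an explicit branch but is not
part of the default tree.

A first-order Markov therapy model (probability that a drug is needed
today given the drugs administered yesterday) is provided as an alternative
generator with the same interface.

The same machinery serves as the one-shot *forecaster* over a planning
period (run on a private copy of the ward, with its own random stream) and
as the day-by-day demand revealer inside the simulator.  A drug-driven
competitor forecaster draws independent Poisson(λ_f) doses per drug-day,
with λ_f the mean daily demand estimated from a long training run.

## The lot-sizing MILP

For a planning period of Ω days (28 by default, starting on a Sunday) the
model decides, per drug, on which days it is ordered and with which fixed
lot size ρ^f (every order of a drug within a period has the same size).
Decision variables cover daily stock, order quantities and indicators, the
dedicated/shared storage split (integer box counts; the shared shelf is
usable only when the dedicated shelf is full, which also fixes the split
uniquely), a single soft-budget violation ε, and per-drug first-day urgent
indicators.  Constraints: daily flow conservation with one-day lead time
and no Sunday receipt; no Saturday order events; storage capacities (boxes
dedicated, boxes and volume shared); a soft cap `B_dw` on the end-of-day
stock value above the safety floor, violated by at most ε; lot-size
regularity; a floor `s^f_dw ≥ s̲^f`; and order homogeneity — the spread
between the largest and smallest number of distinct drugs per order event
is capped by ῡ, calibrated as the mean spread of unconstrained training
solutions minus a tolerance `t_l` (default 1).

The first-day urgent option covers the case where the carried-over stock
cannot meet the first day's forecast demand plus the floor; the box count
ȳ^f = max(0, ⌈(q^f_1 + s̲^f − l^f)/U^f⌉) is precomputed.  Urgent orders
are a *planning feasibility device*: they are not deployed to the
simulator, where rush orders arise only from realized stock-outs.  (When
planned urgents were deployed as day-one rush orders, policies with higher
safety floors were charged more rush orders for merely topping up their
floors — inverting the expected ranking between the knapsack and basic
safety-stock policies.)

Criteria are ordered: (i) budget violation, (ii) urgent orders, (iii)
order-event days, (iv) stock value.  Two solving modes are provided:

* **lexicographic** (default): the four criteria are minimized
  sequentially, each fixed (with a small tolerance; integer criteria are
  rounded) before the next.  Per-stage gaps/time limits are configurable;
  a stage that hits its limit returns its incumbent.
* **weighted**: the single objective
  `ε + M·Σ υ_dw + Ō·Σ ν̄^f + Σ (c^f/B_dw)·s^f_dw` with
  `M = 10·(Ō·|F| + Ω)` by default.  No finite weights can enforce a strict
  hierarchy over a continuous ε, so with a binding budget this mode can
  trade ε for fewer order events; with the default loose budget (below)
  ε = 0 and the weighted solution matches the hierarchy in practice, at a
  fraction of the solve time.  The experiment matrix therefore uses the
  weighted mode.

The solver is the HiGHS branch-and-bound behind `scipy.optimize.milp`,
single-threaded and deterministic for a fixed model.  On small instances
(≤ 2 drugs, ≤ 14 days, ≤ 3 boxes of storage) the solver is tested for
exact objective equality against a brute-force enumeration over all
(lot size, order-day subset, urgent flag) combinations.

## Safety stock

*Basic*: one posology of every drug, charged to the safety budget `B_ss`.
*Knapsack*: the residual budget is spent on additional floor stock by an
exact 0/1 knapsack whose items are the positive daily-consumption values
observed for each drug in a long generator run (1000 days by default),
with their empirical frequencies as profits and their monetary cost as
weights; several values of the same drug may be selected.  The knapsack is
solved by dynamic programming over integer cents; ties are broken toward
lower total weight, then lexicographic item order, so the selection is
deterministic.  Days with zero consumption carry the implicit remaining
probability mass.

## The (s,S) benchmark

Weekly Monday review: every drug below its reorder point
`s^f = d_f + z·δ^f` (mean and SD of daily demand from the training run,
z = 1.96 for a 97.5% service level; the one-day lead time adds no term) is
ordered up to `S^f = s^f + EOQ^f`, with
`EOQ^f = sqrt(2·D_f·K/(h·c^f))`, `D_f = 365·d_f`, order-handling cost
`K = 2` EUR (a 20 EUR/h nurse spending 6 minutes per drug) and holding
fraction `h = 0.8`.  Doses are rounded up to whole boxes so delivered
stock never lands below `S^f`.  Between reviews, stock-outs trigger the
same rush mechanism as the hybrid policy; there are no extra orders.

## Rolling horizon

Every ω days (ω ∈ {7, 21}) the controller forecasts Ω = 28 days of demand
from the current ward state, solves the MILP with the current inventory as
initial stock, deploys only the first ω days of the plan, and simulates
them day by day.  Patients and stock carry over between periods.  A
horizon that is not a multiple of ω is floored to whole scheduling periods
(364 days become 357 for ω = 21).  All variants of a replication share the
realized ward trajectory (common random numbers); forecasts use separate
per-period streams, so forecast error is genuine under shared seeds.

Within each simulated day the order of events is: deliveries (regular
orders placed the previous non-Saturday day), ward evolution
(discharges, admissions, therapy steps), administration with same-day rush
coverage of shortfalls, then extra orders for administered drugs strictly
below their floor.  The aware restocking rule projects the drug's
consumption forward as `⌈r·max(0, 1 − k/τ)⌉` for k = 1..τ — today's
requirement `r` decaying linearly to zero by the drug's next push order
(τ days ahead, or the period end if none is scheduled) — and orders enough
boxes to cover the projection plus the floor; the not-aware rule restores
the floor only.  The linear decay is one simple monotone choice; the rule
is confined to `restock_quantity` and can be swapped.

## Synthetic study conditions

The default configuration emulates the study ward: 18 drugs with dose
costs log-uniform on [0.30, 113] EUR (both extremes pinned), boxes of
1–25 doses, posologies 1–8, box volumes spanning a 100-fold range, three
storage groups, 8 beds, 6 patient classes whose shares, death
probabilities and stay ranges follow the observed 3-feature
stratification (shares ≈ 0.7–35%, death ≈ 0.5–43%, stays 1–27 days),
truncated-Poisson admissions (rate 1.3/day), and lab lags uniform on 3–7
days.  Quantities the source setting does not specify were fixed once:

* shelf capacities size the dedicated shelf to ≈ 2.5 days and the shared
  overflow to ≈ 1.5 days of worst-case (every-bed) demand, so a weekend
  without receipts is always physically coverable — storage then binds
  only in stress cases, which crafted tests cover;
* the daily budget is a loose guard-rail against over-stocking, ten times
  the cost of the basic reserve; the safety budget is 20% of the daily
  budget, so the basic reserve is affordable and the knapsack has a
  meaningful residual;
* the first period starts with the basic reserve plus one extra posology
  per drug in stock, and an empty ward.

Event-log fixtures are sampled exactly from these distributions with the
ground truth retained, which is what makes the estimator-recovery tests
(total variation < 0.05 at 10⁵ days for pd1/pd2) meaningful.

## Problem sizes in the shipped experiments

The shipped acceptance study runs the full variant matrix (ω ∈ {7, 21} ×
{basic, knapsack} × {aware, not} with the therapy-driven forecaster, plus
the (s,S) benchmark) over 12 weeks with 5 common-random-number seeds, and
a single full-year (52-week) run for the invariant audit — sizes chosen so
the whole study completes in minutes on one CPU.  Directional findings
(hybrids rush far less than (s,S); knapsack-aware rushes no more than
basic-not-aware; hybrids hold more stock value) already separate cleanly
at this scale; year-long, 30-seed runs of the same matrix are available
through the CLI for tighter estimates.

## What passing tests do and do not show

The generator reproduces the *structure* of therapy-driven demand
(admission/vacancy coupling, class-dependent stays, infection-triggered
drug switches) but not any real hospital's estimated distributions; KPI
magnitudes are therefore not comparable to published magnitudes, only
directions and mechanisms are.  Pull-order budgets are not constrained at
simulation time (reactive necessities); perishability, intra-day timing
beyond the delivery→administration→restock order, and ward-to-ward
transshipment are out of scope.

## Numerical choices

* Sample standard deviations use the n−1 denominator; single-observation
  cells contribute zero to the weighted classification-quality metric.
* Integer quantities (boxes, capacities, volumes) reject fractional
  inputs rather than rounding.
* Solver tolerances: gap 10⁻⁶ and 300 s default; the quick preset used in
  the shipped experiments is gap 5·10⁻³ with a 6 s cap per solve
  (incumbents are used on cap).  Lexicographic stage values are fixed with
  a 10⁻⁶ tolerance, integer criteria rounded first.
* Deliveries exceeding storage capacity are rejected box-by-box and
  logged — reachable only through hand-built agendas, since the MILP
  respects capacities.
* An empty admission log yields an empty pd1 table; sampling an unseen
  vacancy key falls back to the nearest smaller observed vacancy and is
  logged in the ward notes.
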