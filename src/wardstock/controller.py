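"""Rolling-horizon control loop tying predictor, optimizer and simulator.

At the start of each scheduling period the demand for the next planning
period (28 days by default) is forecast from the current ward population —
either by the therapy-driven generator or by the Poisson drug-driven
competitor — the lot-sizing MILP is solved against the current stock, and
only the first ``omega`` days of the resulting push agenda are deployed.
The simulator then reveals the realized demand day by day, issuing rush
and extra orders as needed, and the loop carries patients and stock
forward into the next period.  The (s,S) benchmark variant replaces
forecast + MILP with a weekly Monday review.

Common random numbers: for a given replication seed, the realized ward
trajectory (admissions, therapy evolutions) is identical across variants,
so policy differences are not confounded by demand differences.  Forecasts
draw from their own per-period streams, so forecast error is genuine even
under shared seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from wardstock import benchmark as bm
from wardstock.demand import (
    TreeTherapyModel,
    WardState,
    forecast_demand,
    forecast_demand_poisson,
)
from wardstock.distributions import (
    EmpiricalDistribution,
    build_consumption_distribution,
    estimate_poisson_rates,
)
from wardstock.domain import Calendar, Catalog, InventoryState, WardConfig
from wardstock.optimizer import (
    MILPInstance,
    build_milp,
    compute_upsilon_bar,
    extract_push_agenda,
    solve_milp,
)
from wardstock.safety_stock import SafetyStockLevels, basic_levels, knapsack_levels
from wardstock.simulator import KPIReport, SimulationLog, WardSimulator, compute_kpis

BENCHMARK_TAG = "sS"


@dataclass(frozen=True)
class VariantSpec:
    """One policy variant of the experiment matrix.

    Hybrid variants combine a scheduling-period length, a safety-stock
    policy, a forecaster and a restocking rule; the ``sS`` benchmark tag
    excludes the other fields.
    """

    omega: int | None = None
    safety: str | None = None        # "basic" | "knapsack"
    forecaster: str | None = None    # "generator" | "poisson"
    aware: bool | None = None
    benchmark: bool = False

    def __post_init__(self):
        if self.benchmark:
            if any(v is not None for v in (self.omega, self.safety, self.forecaster, self.aware)):
                raise ValueError("benchmark variant takes no other fields")
        else:
            if self.safety not in ("basic", "knapsack"):
                raise ValueError("safety must be 'basic' or 'knapsack'")
            if self.forecaster not in ("generator", "poisson"):
                raise ValueError("forecaster must be 'generator' or 'poisson'")
            if self.omega is None or self.aware is None:
                raise ValueError("omega and aware are required")

    @property
    def name(self) -> str:
        if self.benchmark:
            return BENCHMARK_TAG
        tag = "KP" if self.safety == "knapsack" else "B"
        fc = "Generator" if self.forecaster == "generator" else "Poisson"
        return f"{self.omega}-{tag}-{fc}-{'A' if self.aware else 'N'}"


def hybrid_variants(
    omegas: Sequence[int] = (7, 21),
    forecasters: Sequence[str] = ("generator",),
) -> list[VariantSpec]:
    """The hybrid part of the experiment matrix."""
    out = []
    for omega in omegas:
        for safety in ("basic", "knapsack"):
            for fc in forecasters:
                for aware in (False, True):
                    out.append(VariantSpec(omega=omega, safety=safety,
                                           forecaster=fc, aware=aware))
    return out


@dataclass
class ExperimentConfig:
    """Everything a rolling-horizon run needs besides the variant and seed."""

    catalog: Catalog
    ward: WardConfig
    calendar: Calendar
    dists: Mapping[str, EmpiricalDistribution]   # pd1..pd5
    therapy_model: TreeTherapyModel
    upsilon_bar: int | None = None       # None: calibrate on training forecasts
    t_l: int = 1
    training_days: int = 1000            # generator run for lambda / Val-Prob / (s,S)
    training_seed: int = 12345
    n_upsilon_instances: int = 2
    solver_mode: str = "lexicographic"
    solver_time_limit: float = 300.0
    solver_gap: float = 1e-6
    solver_stage_options: Mapping | None = None
    initial_extra_posologies: int = 1    # initial stock above the basic floor

    def with_omega(self, omega: int) -> Calendar:
        """The calendar for a variant's scheduling length.

        The horizon is floored to a whole number of scheduling periods
        (e.g. 364 -> 357 days when omega = 21).
        """
        horizon = (self.calendar.horizon // omega) * omega
        return replace(self.calendar, scheduling_length=omega, horizon=horizon)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _training_demand_log(config: ExperimentConfig) -> pd.DataFrame:
    """A long therapy-driven demand table used to estimate drug-driven
    quantities: Poisson rates, consumption values, (s,S) parameters."""
    rng = _rng(config.training_seed, 101)
    state = WardState(day=0, beds=config.ward.beds)
    matrix = forecast_demand(
        state,
        _round_up_week(config.training_days),
        config.dists,
        config.therapy_model,
        config.catalog.drug_ids,
        rng,
    )
    return matrix.to_frame().T  # days x drugs


def _round_up_week(days: int) -> int:
    return ((days + 6) // 7) * 7


def make_safety_levels(config: ExperimentConfig, policy: str,
                       training_log: pd.DataFrame | None = None) -> SafetyStockLevels:
    basic = basic_levels(config.catalog, config.ward.safety_budget)
    if policy == "basic":
        return basic
    log = training_log if training_log is not None else _training_demand_log(config)
    consumption = build_consumption_distribution(
        log, {f: d.daily_posology for f, d in config.catalog.drugs.items()}
    )
    costs = {f: d.cost_per_dose for f, d in config.catalog.drugs.items()}
    return knapsack_levels(basic, consumption, costs)


def calibrate_upsilon_bar(config: ExperimentConfig, safety: SafetyStockLevels | None = None) -> int:
    """Homogeneity reference from a few training forecasts, as the mean
    order-size spread of unconstrained solutions minus the tolerance."""
    if safety is None:
        safety = basic_levels(config.catalog, config.ward.safety_budget)
    spreads = []
    for i in range(config.n_upsilon_instances):
        rng = _rng(config.training_seed, 202, i)
        state = WardState(day=0, beds=config.ward.beds)
        q = forecast_demand(state, config.calendar.planning_length, config.dists,
                            config.therapy_model, config.catalog.drug_ids, rng)
        inst = MILPInstance(
            catalog=config.catalog,
            demand=q,
            initial_stock=dict(safety.levels),
            safety_stock=dict(safety.levels),
            daily_budget=config.ward.daily_budget,
            rush_cost=config.ward.rush_cost,
            upsilon_bar=len(config.catalog),  # unconstrained spread
            hierarchy_weight=config.ward.hierarchy_weight,
        )
        sol = solve_milp(build_milp(inst), mode="weighted",
                         time_limit=config.solver_time_limit, gap=config.solver_gap)
        spreads.append((sol.ups_max, sol.ups_min))
    return compute_upsilon_bar(spreads, t_l=config.t_l)


@dataclass
class RunResult:
    variant: VariantSpec
    seed: int
    kpis: KPIReport
    log: SimulationLog
    notes: list = field(default_factory=list)
    solutions: list = field(default_factory=list)  # (period_start, MILPModel, MILPSolution)


def run_rolling_horizon(
    config: ExperimentConfig,
    variant: VariantSpec,
    seed: int,
    collect_solutions: bool = False,
) -> RunResult:
    """One policy variant over the full horizon for one replication seed."""
    cal = config.calendar if variant.benchmark else config.with_omega(variant.omega)
    H, Omega, omega = cal.horizon, cal.planning_length, cal.scheduling_length

    training_log = _training_demand_log(config)
    if variant.benchmark:
        safety = SafetyStockLevels({f: 0 for f in config.catalog.drug_ids}, "none", 0.0)
        ss_params = bm.estimate_ss_parameters(
            training_log, {f: d.cost_per_dose for f, d in config.catalog.drugs.items()}
        )
        aware = False
    else:
        safety = make_safety_levels(config, variant.safety, training_log)
        ss_params = None
        aware = variant.aware

    upsilon_bar = config.upsilon_bar
    if upsilon_bar is None and not variant.benchmark:
        upsilon_bar = calibrate_upsilon_bar(config, safety)

    if not variant.benchmark and variant.forecaster == "poisson":
        rates = estimate_poisson_rates(training_log)
    else:
        rates = None

    basic = basic_levels(config.catalog, config.ward.safety_budget)
    initial = {
        f: basic.levels[f]
        + config.initial_extra_posologies * config.catalog.drugs[f].daily_posology
        for f in config.catalog.drug_ids
    }
    inventory = InventoryState.canonical(config.catalog, initial)
    state = WardState(day=0, beds=config.ward.beds)
    sim = WardSimulator(
        config.catalog, inventory, safety, aware=aware,
        start_weekday=cal.start_weekday,
    )
    ward_rng = _rng(seed, 1)
    solutions: list = []

    if variant.benchmark:
        # weekly Monday review; orders placed on review day, arrive next day
        for day in range(H):
            push_today = []
            if cal.day_index(day) == config.ward.review_weekday:
                order = bm.periodic_review_order(sim.inventory, ss_params, config.catalog, day)
                if order is not None:
                    push_today.append(order)
            sim.step_day(day, state, config.dists, config.therapy_model, ward_rng,
                         push_orders_today=push_today)
    else:
        for it in range(1, H // omega + 1):
            start = omega * (it - 1)
            if variant.forecaster == "generator":
                fc_rng = _rng(seed, 2, it)
                q = forecast_demand(state, Omega, config.dists, config.therapy_model,
                                    config.catalog.drug_ids, fc_rng)
            else:
                fc_rng = _rng(seed, 3, it)
                q = forecast_demand_poisson(rates, Omega, config.catalog.drug_ids, fc_rng)
            inst = MILPInstance(
                catalog=config.catalog,
                demand=q,
                initial_stock=dict(sim.inventory.doses),
                safety_stock=dict(safety.levels),
                daily_budget=config.ward.daily_budget,
                rush_cost=config.ward.rush_cost,
                upsilon_bar=upsilon_bar,
                hierarchy_weight=config.ward.hierarchy_weight,
                start_weekday=cal.day_index(start),
            )
            model = build_milp(inst)
            sol = solve_milp(model, mode=config.solver_mode,
                             time_limit=config.solver_time_limit, gap=config.solver_gap,
                             stage_options=config.solver_stage_options)
            if sol.status in ("infeasible", "unbounded", "error"):
                raise RuntimeError(
                    f"period {it}: solver returned {sol.status} "
                    f"(stock={dict(sim.inventory.doses)})"
                )
            if collect_solutions:
                solutions.append((start, model, sol))
            agenda = extract_push_agenda(sol, model, omega, period_start=start)
            by_day: dict[int, list] = {}
            for o in agenda:
                by_day.setdefault(o.day, []).append(o)
            for day in range(start, start + omega):
                tau = _days_to_next_push(agenda, day, start + omega, config.catalog.drug_ids)
                sim.step_day(day, state, config.dists, config.therapy_model, ward_rng,
                             push_orders_today=by_day.get(day, []),
                             days_to_next_push=tau)

    kpis = compute_kpis(sim.log, config.catalog, rush_cost=config.ward.rush_cost)
    return RunResult(variant=variant, seed=seed, kpis=kpis, log=sim.log,
                     notes=state.notes, solutions=solutions)


def _days_to_next_push(agenda, day: int, period_end: int, drug_ids) -> dict[str, int]:
    """Lag from ``day`` to each drug's next push order (or the period end)."""
    tau = {}
    for f in drug_ids:
        nxt = period_end
        for o in agenda:
            if o.kind == "push" and o.day > day and f in o.lines:
                nxt = min(nxt, o.day)
        tau[f] = max(1, nxt - day)
    return tau


def run_experiment_matrix(
    config: ExperimentConfig,
    variants: Sequence[VariantSpec],
    seeds: Sequence[int],
) -> pd.DataFrame:
    """All variants x replications as a tidy KPI table.

    Variants share the replication seed, hence the realized demand
    trajectory (common random numbers).
    """
    if config.upsilon_bar is None and any(not v.benchmark for v in variants):
        config = replace(config, upsilon_bar=calibrate_upsilon_bar(config))
    rows = []
    for seed in seeds:
        for variant in variants:
            result = run_rolling_horizon(config, variant, seed)
            rows.append({"variant": variant.name, "seed": seed} | result.kpis.to_dict())
    return pd.DataFrame(rows)
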