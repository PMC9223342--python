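"""Lot-sizing MILP scheduling push orders for a planning period.

Given the forecast demand of each drug on each day of the period, the
initial stock, per-drug safety-stock floors and a daily soft budget, the
model decides on which days each drug is ordered and with which fixed lot
size (the same number of boxes every time a drug is ordered within the
period).  It encodes:

* daily stock flow with one-day lead time — boxes ordered on day t arrive
  on day t+1, nothing arrives on Sundays, and no regular order event may
  happen on Saturday;
* a first-day urgent order option (binary per drug, with the pre-computed
  box count that covers a first-day shortfall at a high cost);
* the dedicated/shared storage split: each drug overflows to its group's
  shared shelf only once its dedicated shelf is full, with a volume cap on
  each shared shelf;
* a soft daily budget on the monetary value of stock above the safety
  floor, violated by at most ``eps`` (minimized first);
* order-homogeneity: the spread between the largest and smallest number of
  distinct drugs per order event is capped by a reference value.

The objective hierarchy — budget violation, urgent orders, order events,
stock value — is honored either by a weighted single objective
(``eps + M * sum(order_events) + rush_cost * sum(urgent) + stock_value``)
or, by default, by sequential lexicographic solving of the four criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from wardstock.domain import SATURDAY, SUNDAY, Catalog, DemandMatrix, Order

_VAR_GROUPS = ("s", "y", "nu", "x", "alpha", "beta", "gamma")  # per (f, t)


def compute_first_day_rush(q01: int, ss01: int, stock0: int, doses_per_box: int) -> int:
    """Boxes to order urgently so that day-1 demand plus the safety floor
    is covered: ``max(0, ceil((q + ss - l) / U))``."""
    if doses_per_box < 1:
        raise ValueError("doses_per_box must be >= 1")
    if min(q01, ss01, stock0) < 0:
        raise ValueError("inputs must be non-negative")
    return max(0, math.ceil((q01 + ss01 - stock0) / doses_per_box))


def compute_upsilon_bar(training_spreads: Sequence[tuple[float, float]], t_l: int = 1) -> int:
    """Homogeneity reference from training solutions.

    ``ceil(mean of (ups_max - ups_min) over the training instances) - t_l``,
    floored at 0.  ``t_l`` encodes how little flexibility nurses tolerate.
    """
    if not training_spreads:
        raise ValueError("training set must be non-empty")
    mean_spread = sum(mx - mn for mx, mn in training_spreads) / len(training_spreads)
    return max(0, math.ceil(mean_spread - 1e-12) - t_l)


def default_hierarchy_weight(n_drugs: int, n_days: int, rush_cost: float) -> float:
    """Default M for the weighted objective: 10 * (rush_cost * |F| + n_days)."""
    return 10.0 * (rush_cost * n_drugs + n_days)


@dataclass
class MILPInstance:
    """Everything the lot-sizing model needs for one planning period."""

    catalog: Catalog
    demand: DemandMatrix
    initial_stock: Mapping[str, int]
    safety_stock: Mapping[str, int]
    daily_budget: float
    rush_cost: float
    upsilon_bar: int = 0
    hierarchy_weight: float | None = None
    start_weekday: int = SUNDAY

    def __post_init__(self):
        if self.demand.drug_ids != self.catalog.drug_ids:
            raise ValueError("demand drug ids must match the catalog order")
        if self.demand.n_days % 7:
            raise ValueError("planning period must be a multiple of 7 days")
        for f in self.catalog.drug_ids:
            if self.initial_stock.get(f, 0) < 0 or self.safety_stock.get(f, 0) < 0:
                raise ValueError(f"negative stock parameter for drug {f}")
        if self.daily_budget <= 0 or self.rush_cost <= 0:
            raise ValueError("budget and rush cost must be > 0")
        if self.upsilon_bar < 0:
            raise ValueError("upsilon_bar must be >= 0")

    @property
    def n_days(self) -> int:
        return self.demand.n_days

    def weekday(self, t: int) -> int:
        return (self.start_weekday + t) % 7

    def to_dict(self) -> dict:
        return {
            "catalog": self.catalog.to_dict(),
            "demand": self.demand.values.tolist(),
            "initial_stock": dict(self.initial_stock),
            "safety_stock": dict(self.safety_stock),
            "daily_budget": self.daily_budget,
            "rush_cost": self.rush_cost,
            "upsilon_bar": self.upsilon_bar,
            "hierarchy_weight": self.hierarchy_weight,
            "start_weekday": self.start_weekday,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MILPInstance":
        catalog = Catalog.from_dict(data["catalog"])
        demand = DemandMatrix(catalog.drug_ids, np.asarray(data["demand"]))
        return cls(
            catalog=catalog,
            demand=demand,
            initial_stock=data["initial_stock"],
            safety_stock=data["safety_stock"],
            daily_budget=data["daily_budget"],
            rush_cost=data["rush_cost"],
            upsilon_bar=data["upsilon_bar"],
            hierarchy_weight=data.get("hierarchy_weight"),
            start_weekday=data.get("start_weekday", SUNDAY),
        )

    def first_day_rush(self) -> dict[str, int]:
        return {
            f: compute_first_day_rush(
                self.demand.demand(f, 0),
                int(self.safety_stock.get(f, 0)),
                int(self.initial_stock.get(f, 0)),
                self.catalog.drugs[f].doses_per_box,
            )
            for f in self.catalog.drug_ids
        }


class MILPModel:
    """The assembled model: variable index, constraint blocks, objectives."""

    def __init__(self, instance: MILPInstance):
        self.instance = instance
        F, T = len(instance.catalog), instance.n_days
        self.nF, self.T = F, T
        self.offsets: dict[str, int] = {}
        off = 0
        for name in _VAR_GROUPS:
            self.offsets[name] = off
            off += F * T
        for name, size in (("ups", T), ("nub", F), ("rho", F),
                           ("upsmax", 1), ("upsmin", 1), ("eps", 1)):
            self.offsets[name] = off
            off += size
        self.n_vars = off
        self.blocks: dict[str, LinearConstraint] = {}
        self.lb = np.zeros(self.n_vars)
        self.ub = np.full(self.n_vars, np.inf)
        self.integrality = np.zeros(self.n_vars)
        self._build()

    # -- indexing ----------------------------------------------------------
    def var(self, name: str, f: int | None = None, t: int | None = None) -> int:
        base = self.offsets[name]
        if name in _VAR_GROUPS:
            return base + f * self.T + t
        if name in ("nub", "rho", "ups"):
            idx = f if f is not None else t
            return base + idx
        return base

    # -- assembly ----------------------------------------------------------
    def _build(self) -> None:
        inst = self.instance
        cat = inst.catalog
        drugs = [cat.drugs[f] for f in cat.drug_ids]
        F, T = self.nF, self.T
        q = inst.demand.values
        l0 = np.array([inst.initial_stock.get(f, 0) for f in cat.drug_ids])
        ss = np.array([inst.safety_stock.get(f, 0) for f in cat.drug_ids])
        ybar = np.array([inst.first_day_rush()[f] for f in cat.drug_ids])
        U = np.array([d.doses_per_box for d in drugs])
        C = np.array([d.dedicated_capacity for d in drugs])
        Cbar = np.array([d.shared_capacity for d in drugs])
        Gam = np.array([d.max_boxes for d in drugs])
        cost = np.array([d.cost_per_dose for d in drugs])

        # bounds and integrality
        for fi in range(F):
            for t in range(T):
                self.lb[self.var("s", fi, t)] = ss[fi]            # (25)
                self.ub[self.var("y", fi, t)] = Gam[fi]
                self.ub[self.var("x", fi, t)] = Cbar[fi]
                self.ub[self.var("alpha", fi, t)] = C[fi]         # (10)
                self.ub[self.var("beta", fi, t)] = Gam[fi]
                self.ub[self.var("nu", fi, t)] = 1
                self.ub[self.var("gamma", fi, t)] = 1
                if C[fi] == 0:
                    # dedicated shelf of size zero is vacuously full
                    self.lb[self.var("gamma", fi, t)] = 1
                for name in ("y", "nu", "x", "alpha", "beta", "gamma"):
                    self.integrality[self.var(name, fi, t)] = 1
            self.ub[self.var("nub", fi)] = 1
            self.ub[self.var("rho", fi)] = Gam[fi]                # (16)
            self.integrality[self.var("nub", fi)] = 1
            self.integrality[self.var("rho", fi)] = 1
        for t in range(T):
            self.ub[self.var("ups", t)] = 1
            self.integrality[self.var("ups", t)] = 1
            if inst.weekday(t) == SATURDAY:
                self.ub[self.var("ups", t)] = 0                   # (15)
        self.ub[self.var("upsmax")] = F
        self.ub[self.var("upsmin")] = F

        rows: dict[str, list] = {}

        def add(block, coeffs, lo, hi):
            rows.setdefault(block, []).append((coeffs, lo, hi))

        # (2)-(4) stock flow
        for fi in range(F):
            add("flow", [(self.var("s", fi, 0), 1.0),
                         (self.var("nub", fi), -float(U[fi] * ybar[fi]))],
                float(l0[fi] - q[fi, 0]), float(l0[fi] - q[fi, 0]))
            for t in range(1, T):
                coeffs = [(self.var("s", fi, t), 1.0), (self.var("s", fi, t - 1), -1.0)]
                if inst.weekday(t) != SUNDAY:  # receipt of yesterday's order
                    coeffs.append((self.var("y", fi, t - 1), -float(U[fi])))
                add("flow", coeffs, float(-q[fi, t]), float(-q[fi, t]))

        # (5)-(12) storage
        for fi in range(F):
            for t in range(T):
                add("storage", [(self.var("s", fi, t), 1.0),
                                (self.var("x", fi, t), -float(U[fi]))],
                    -np.inf, float(U[fi] * C[fi]))                          # (5)
                add("storage", [(self.var("beta", fi, t), float(U[fi])),
                                (self.var("s", fi, t), -1.0)],
                    -np.inf, float(U[fi] - 1))                              # (7)
                add("storage", [(self.var("s", fi, t), 1.0),
                                (self.var("beta", fi, t), -float(U[fi]))],
                    -np.inf, 0.0)                                           # (8)
                add("storage", [(self.var("beta", fi, t), 1.0),
                                (self.var("alpha", fi, t), -1.0),
                                (self.var("x", fi, t), -1.0)], 0.0, 0.0)    # (9)
                if C[fi] > 0:
                    add("storage", [(self.var("gamma", fi, t), float(C[fi])),
                                    (self.var("alpha", fi, t), -1.0)],
                        -np.inf, 0.0)                                       # (11)
                add("storage", [(self.var("x", fi, t), 1.0),
                                (self.var("gamma", fi, t), -float(Cbar[fi]))],
                    -np.inf, 0.0)                                           # (12)
        for g in cat.groups.values():
            for t in range(T):
                coeffs = [
                    (self.var("x", cat.drug_ids.index(f), t),
                     float(cat.drugs[f].box_volume))
                    for f in g.members
                ]
                add("storage", coeffs, -np.inf, float(g.shared_volume))     # (6)

        # (13)-(14) soft budget
        eps = self.var("eps")
        base = float(np.dot(cost, ss))
        for t in range(T):
            coeffs = [(self.var("s", fi, t), float(cost[fi])) for fi in range(F)]
            coeffs.append((eps, -1.0))
            add("budget", coeffs, -np.inf, inst.daily_budget + base)        # (14)
            if t == 0:
                coeffs0 = [(self.var("s", fi, 0), float(cost[fi])) for fi in range(F)]
                coeffs0 += [(self.var("nub", fi), -float(cost[fi] * U[fi] * ybar[fi]))
                            for fi in range(F)]
                coeffs0.append((eps, -1.0))
                add("budget", coeffs0, -np.inf, inst.daily_budget + base)   # (13)

        # (17)-(19) lot-size regularity
        for fi in range(F):
            for t in range(T):
                add("lot", [(self.var("y", fi, t), 1.0),
                            (self.var("nu", fi, t), -float(Gam[fi]))],
                    -np.inf, 0.0)                                           # (17)
                add("lot", [(self.var("y", fi, t), 1.0),
                            (self.var("rho", fi), -1.0)], -np.inf, 0.0)     # (18)
                add("lot", [(self.var("y", fi, t), 1.0),
                            (self.var("rho", fi), -1.0),
                            (self.var("nu", fi, t), -float(Gam[fi]))],
                    -float(Gam[fi]), np.inf)                                # (19)

        # (20)-(23) order events and homogeneity
        for fi in range(F):
            for t in range(T):
                add("events", [(self.var("nu", fi, t), 1.0),
                               (self.var("ups", t), -1.0)], -np.inf, 0.0)   # (20)
        for t in range(T):
            coeffs = [(self.var("nu", fi, t), 1.0) for fi in range(F)]
            add("events", coeffs + [(self.var("upsmax"), -1.0)], -np.inf, 0.0)  # (21)
            add("events",
                [(self.var("upsmin"), 1.0), (self.var("ups", t), float(F))]
                + [(self.var("nu", fi, t), -1.0) for fi in range(F)],
                -np.inf, float(F))                                          # (22)
        add("events", [(self.var("upsmax"), 1.0), (self.var("upsmin"), -1.0)],
            -np.inf, float(inst.upsilon_bar))                               # (23)

        for name, entries in rows.items():
            data, ri, ci, lo, hi = [], [], [], [], []
            for r, (coeffs, l, h) in enumerate(entries):
                for col, val in coeffs:
                    ri.append(r)
                    ci.append(col)
                    data.append(val)
                lo.append(l)
                hi.append(h)
            A = sparse.csr_matrix((data, (ri, ci)), shape=(len(entries), self.n_vars))
            self.blocks[name] = LinearConstraint(A, lo, hi)

    # -- objectives --------------------------------------------------------
    def objective_terms(self) -> dict[str, np.ndarray]:
        """The four criterion vectors: budget violation, urgent orders,
        order events, stock value (each as a cost vector over variables)."""
        inst = self.instance
        cat = inst.catalog
        eps_v = np.zeros(self.n_vars)
        eps_v[self.var("eps")] = 1.0
        urgent = np.zeros(self.n_vars)
        for fi in range(self.nF):
            urgent[self.var("nub", fi)] = 1.0
        events = np.zeros(self.n_vars)
        for t in range(self.T):
            events[self.var("ups", t)] = 1.0
        stock = np.zeros(self.n_vars)
        for fi, f in enumerate(cat.drug_ids):
            c_over_b = cat.drugs[f].cost_per_dose / inst.daily_budget
            for t in range(self.T):
                stock[self.var("s", fi, t)] = c_over_b
        return {"eps": eps_v, "urgent": urgent, "events": events, "stock": stock}

    def weighted_objective(self) -> np.ndarray:
        inst = self.instance
        M = inst.hierarchy_weight
        if M is None:
            M = default_hierarchy_weight(self.nF, self.T, inst.rush_cost)
        terms = self.objective_terms()
        return terms["eps"] + M * terms["events"] + inst.rush_cost * terms["urgent"] + terms["stock"]

    def constraints(self, extra: list[LinearConstraint] | None = None) -> list:
        cons = list(self.blocks.values())
        if extra:
            cons += extra
        return cons


def build_milp(instance: MILPInstance) -> MILPModel:
    """Assemble the lot-sizing model for one planning period."""
    return MILPModel(instance)


@dataclass
class MILPSolution:
    """A solved planning period: order schedule, stock path, indicators."""

    status: str
    objective: float
    stock: np.ndarray          # (F, T) doses
    orders: np.ndarray         # (F, T) boxes ordered on day t
    order_flags: np.ndarray    # (F, T) nu
    event_flags: np.ndarray    # (T,) ups
    urgent_flags: np.ndarray   # (F,) nub
    urgent_boxes: np.ndarray   # (F,) ybar * nub
    lot_sizes: np.ndarray      # (F,)
    shared_boxes: np.ndarray   # (F, T) x
    dedicated_boxes: np.ndarray  # (F, T) alpha
    ups_max: float
    ups_min: float
    eps: float
    criteria: dict = field(default_factory=dict)


_STATUS = {0: "optimal", 1: "feasible", 2: "infeasible", 3: "unbounded", 4: "error"}


def _extract(model: MILPModel, x: np.ndarray, status: str, objective: float) -> MILPSolution:
    F, T = model.nF, model.T
    inst = model.instance

    def grid(name):
        return np.array(
            [[x[model.var(name, fi, t)] for t in range(T)] for fi in range(F)]
        )

    ybar = np.array([inst.first_day_rush()[f] for f in inst.catalog.drug_ids])
    nub = np.round([x[model.var("nub", fi)] for fi in range(F)]).astype(int)
    terms = model.objective_terms()
    sol = MILPSolution(
        status=status,
        objective=objective,
        stock=grid("s").round(6),
        orders=np.round(grid("y")).astype(int),
        order_flags=np.round(grid("nu")).astype(int),
        event_flags=np.round([x[model.var("ups", t)] for t in range(T)]).astype(int),
        urgent_flags=nub,
        urgent_boxes=nub * ybar,
        lot_sizes=np.round([x[model.var("rho", fi)] for fi in range(F)]).astype(int),
        shared_boxes=np.round(grid("x")).astype(int),
        dedicated_boxes=np.round(grid("alpha")).astype(int),
        ups_max=float(x[model.var("upsmax")]),
        ups_min=float(x[model.var("upsmin")]),
        eps=float(x[model.var("eps")]),
        criteria={name: float(vec @ x) for name, vec in terms.items()},
    )
    return sol


def solve_milp(
    model: MILPModel,
    mode: str = "lexicographic",
    time_limit: float = 300.0,
    gap: float = 1e-6,
    stage_options: Mapping[str, tuple[float, float]] | None = None,
) -> MILPSolution:
    """Solve the assembled model.

    ``mode`` is ``"lexicographic"`` (default: budget violation, then urgent
    orders, then order events, then stock value, each fixed before the
    next) or ``"weighted"`` (the single weighted objective).
    ``stage_options`` may override ``(gap, time_limit)`` per lexicographic
    stage (keys ``eps``, ``urgent``, ``events``, ``stock``); a capped stage
    returns its incumbent.  Deterministic for a fixed model: the backend
    runs single-threaded.
    """
    bounds = Bounds(model.lb, model.ub)
    options = {"time_limit": time_limit, "mip_rel_gap": gap, "presolve": True}
    if mode == "weighted":
        c = model.weighted_objective()
        res = milp(c=c, constraints=model.constraints(), integrality=model.integrality,
                   bounds=bounds, options=options)
        if res.x is None:
            return MILPSolution("infeasible" if res.status == 2 else "error", np.nan,
                                *(np.zeros(0),) * 9, 0.0, 0.0, 0.0)
        return _extract(model, res.x, _STATUS.get(res.status, "error"), float(res.fun))
    if mode != "lexicographic":
        raise ValueError("mode must be 'lexicographic' or 'weighted'")

    terms = model.objective_terms()
    order = ["eps", "urgent", "events", "stock"]
    extra: list[LinearConstraint] = []
    res = None
    for i, name in enumerate(order):
        c = terms[name]
        stage_opts = dict(options)
        if stage_options and name in stage_options:
            g, tl = stage_options[name]
            stage_opts.update({"mip_rel_gap": g, "time_limit": tl})
        res = milp(c=c, constraints=model.constraints(extra), integrality=model.integrality,
                   bounds=bounds, options=stage_opts)
        if res.x is None and res.status == 1:
            # capped without incumbent: accept any feasible point for this stage
            retry = dict(stage_opts)
            retry["mip_rel_gap"] = 0.9
            retry["time_limit"] = max(30.0, 5 * stage_opts["time_limit"])
            res = milp(c=c, constraints=model.constraints(extra),
                       integrality=model.integrality, bounds=bounds, options=retry)
        if res.x is None:
            return MILPSolution("infeasible" if res.status == 2 else "error", np.nan,
                                *(np.zeros(0),) * 9, 0.0, 0.0, 0.0)
        value = float(res.fun)
        if i < len(order) - 1:
            # fix this criterion before optimizing the next one
            tol = 1e-6 + 1e-9 * abs(value)
            if name in ("urgent", "events"):
                value = round(value)
                tol = 1e-6
            extra.append(LinearConstraint(sparse.csr_matrix(c), -np.inf, value + tol))
    sol = _extract(model, res.x, _STATUS.get(res.status, "error"), float(res.fun))
    sol.objective = float(model.weighted_objective() @ res.x)
    return sol


def extract_push_agenda(
    solution: MILPSolution,
    model: MILPModel,
    scheduling_length: int,
    period_start: int = 0,
    include_urgent: bool = False,
) -> list[Order]:
    """Keep only the orders placed in the first ``scheduling_length`` days.

    Returns absolute-day orders: one push order per day with positive
    lines; lot-size regularity is preserved because lines copy the solved
    order quantities.  The model's first-day urgent option is a planning
    feasibility device — realized stockouts trigger rush orders inside the
    simulator — so urgent orders are only deployed when
    ``include_urgent`` is set.
    """
    cat = model.instance.catalog
    agenda: list[Order] = []
    urgent_lines = {
        f: int(solution.urgent_boxes[fi])
        for fi, f in enumerate(cat.drug_ids)
        if solution.urgent_flags[fi] and solution.urgent_boxes[fi] > 0
    }
    if urgent_lines and include_urgent:
        agenda.append(Order(kind="rush", day=period_start, lines=urgent_lines))
    for t in range(min(scheduling_length, model.T)):
        lines = {
            f: int(solution.orders[fi, t])
            for fi, f in enumerate(cat.drug_ids)
            if solution.orders[fi, t] > 0
        }
        if lines:
            agenda.append(Order(kind="push", day=period_start + t, lines=lines))
    return agenda


def agenda_to_frame(agenda: Sequence[Order]):
    """An agenda as a tidy (day, drug, boxes, kind) table."""
    import pandas as pd

    rows = [
        {"day": o.day, "drug": f, "boxes": b, "kind": o.kind}
        for o in agenda
        for f, b in sorted(o.lines.items())
    ]
    return pd.DataFrame(rows, columns=["day", "drug", "boxes", "kind"])
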