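"""Day-by-day ward replay: deliveries, administration, pull orders, KPIs.

Each simulated day proceeds in a fixed sequence: (1) regular orders placed
earlier and due today are delivered (never on a Sunday; a Saturday order
arrives on Monday) and placed dedicated-shelf-first; (2) the ward evolves —
discharges, admissions, therapy steps — revealing the day's realized
demand; (3) the nurse administers from stock, and any shortfall triggers a
same-day rush order (one rush order may cover several drugs; each drug in
it counts once toward the rush KPI); (4) for every drug administered today
whose end-of-day stock fell strictly below its safety floor, an extra
(restocking) order is issued with a quantity set by the active rule:
*not-aware* restores the floor exactly, *aware* additionally covers a
short-term projection of the drug's consumption, decaying linearly to zero
by the next push order of that drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from wardstock.demand import WardState, step_ward_day
from wardstock.domain import (
    SUNDAY,
    Catalog,
    InventoryState,
    Order,
    validate_inventory,
)
from wardstock.safety_stock import SafetyStockLevels


def restock_quantity(
    stock_doses: int,
    safety_level: int,
    doses_per_box: int,
    aware: bool = False,
    today_requirement: int = 0,
    days_to_next_push: int = 1,
) -> int:
    """Boxes for an extra (safety-restock) order.

    Not-aware: the minimal restore ``ceil((ss - stock) / U)``.  Aware: also
    cover the projected consumption ``ceil(r * max(0, 1 - k/tau))`` for
    days k = 1..tau, where r is today's ward requirement for the drug and
    tau the lag to the drug's next push order.
    """
    tau = max(1, days_to_next_push)
    projection = 0
    if aware and today_requirement > 0:
        projection = sum(
            math.ceil(today_requirement * max(0.0, 1.0 - k / tau)) for k in range(1, tau + 1)
        )
    deficit = projection + safety_level - stock_doses
    return max(0, math.ceil(deficit / doses_per_box))


@dataclass
class DayRecord:
    """What happened on one simulated day."""

    day: int
    demand: dict
    administered: dict
    delivered: dict
    rejected_boxes: dict
    orders: list
    end_stock: dict
    stock_value: float


@dataclass
class SimulationLog:
    """Append-only record of a simulation run."""

    records: list = field(default_factory=list)

    def append(self, record: DayRecord) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def orders(self, kind: str | None = None) -> list:
        out = []
        for r in self.records:
            for o in r.orders:
                if kind is None or o.kind == kind:
                    out.append(o)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "day": r.day,
                    "total_demand": sum(r.demand.values()),
                    "total_administered": sum(r.administered.values()),
                    "n_rush_orders": sum(1 for o in r.orders if o.kind == "rush"),
                    "n_extra_orders": sum(1 for o in r.orders if o.kind == "extra"),
                    "n_push_orders": sum(1 for o in r.orders if o.kind == "push"),
                    "stock_value": r.stock_value,
                }
            )
        return pd.DataFrame(rows)


class WardSimulator:
    """Replays the ward day by day against a push-order agenda."""

    def __init__(
        self,
        catalog: Catalog,
        inventory: InventoryState,
        safety_levels: SafetyStockLevels,
        aware: bool = False,
        start_weekday: int = SUNDAY,
        validate: bool = True,
    ):
        self.catalog = catalog
        self.inventory = inventory
        self.safety = safety_levels
        self.aware = aware
        self.start_weekday = start_weekday
        self.validate = validate
        self.pending: dict[int, list[Order]] = {}
        self.log = SimulationLog()

    # -- deliveries --------------------------------------------------------
    def _weekday(self, day: int) -> int:
        return (self.start_weekday + day) % 7

    def _arrival_day(self, order_day: int) -> int:
        arrival = order_day + 1
        if self._weekday(arrival) == SUNDAY:
            arrival += 1
        return arrival

    def schedule_order(self, order: Order) -> None:
        arrival = order.day if order.kind == "rush" else self._arrival_day(order.day)
        self.pending.setdefault(arrival, []).append(order)

    def _accept_boxes(self, drug_id: str, n_boxes: int) -> int:
        """Boxes of a delivery that fit the drug's storage; rest rejected."""
        drug = self.catalog.drugs[drug_id]
        inv = self.inventory
        current = inv.boxes_total(drug_id)
        room_total = drug.max_boxes - current
        accept = min(n_boxes, max(0, room_total))
        # shared-shelf volume check for the overflow part
        group = self.catalog.groups[drug.group_id]
        used_volume = sum(
            inv.boxes_shared[f] * self.catalog.drugs[f].box_volume for f in group.members
        )
        while accept > 0:
            new_total = current + accept
            overflow = max(0, new_total - drug.dedicated_capacity)
            extra_volume = (overflow - inv.boxes_shared[drug_id]) * drug.box_volume
            if overflow <= drug.shared_capacity and used_volume + extra_volume <= group.shared_volume:
                break
            accept -= 1
        return accept

    def _add_boxes(self, drug_id: str, n_boxes: int) -> None:
        drug = self.catalog.drugs[drug_id]
        inv = self.inventory
        inv.doses[drug_id] += n_boxes * drug.doses_per_box
        self._replace(drug_id)

    def _replace(self, drug_id: str) -> None:
        """Re-derive the canonical dedicated-first placement for a drug."""
        drug = self.catalog.drugs[drug_id]
        inv = self.inventory
        boxes = math.ceil(inv.doses[drug_id] / drug.doses_per_box)
        inv.boxes_dedicated[drug_id] = min(boxes, drug.dedicated_capacity)
        inv.boxes_shared[drug_id] = boxes - inv.boxes_dedicated[drug_id]

    # -- one day -----------------------------------------------------------
    def step_day(
        self,
        day: int,
        state: WardState,
        dists: Mapping,
        therapy_model,
        rng: np.random.Generator,
        push_orders_today: list[Order] | None = None,
        days_to_next_push: Mapping[str, int] | None = None,
    ) -> DayRecord:
        """Advance the simulation one day; returns the day's record."""
        if state.day != day:
            raise ValueError(f"ward state is on day {state.day}, not {day}")
        inv = self.inventory
        for order in push_orders_today or []:
            self.schedule_order(order)

        # 1. deliveries due today
        delivered: dict[str, int] = {}
        rejected: dict[str, int] = {}
        for order in self.pending.pop(day, []):
            for f, boxes in order.lines.items():
                accepted = self._accept_boxes(f, boxes)
                if accepted < boxes:
                    rejected[f] = rejected.get(f, 0) + (boxes - accepted)
                    state.notes.append(
                        f"day {day}: rejected {boxes - accepted} boxes of {f} (storage full)"
                    )
                if accepted:
                    self._add_boxes(f, accepted)
                    delivered[f] = delivered.get(f, 0) + accepted

        # 2. ward evolution reveals today's demand
        demand = step_ward_day(state, dists, therapy_model, rng)

        # 3. administration; shortfall -> same-day rush order
        orders_today: list[Order] = list(push_orders_today or [])
        rush_lines: dict[str, int] = {}
        for f, needed in demand.items():
            stock = inv.doses[f]
            if needed > stock:
                drug = self.catalog.drugs[f]
                rush_lines[f] = math.ceil((needed - stock) / drug.doses_per_box)
        if rush_lines:
            rush = Order(kind="rush", day=day, lines=rush_lines)
            orders_today.append(rush)
            for f, boxes in rush_lines.items():
                inv.doses[f] += boxes * self.catalog.drugs[f].doses_per_box
                self._replace(f)
        administered = dict(demand)  # pending administrations complete after restock
        for f, doses in administered.items():
            inv.doses[f] -= doses
            self._replace(f)

        # 4. extra orders for administered drugs strictly below the floor
        tau = days_to_next_push or {}
        extra_lines: dict[str, int] = {}
        for f, doses in administered.items():
            if doses <= 0:
                continue
            if inv.doses[f] < self.safety[f]:
                boxes = restock_quantity(
                    inv.doses[f],
                    self.safety[f],
                    self.catalog.drugs[f].doses_per_box,
                    aware=self.aware,
                    today_requirement=demand.get(f, 0),
                    days_to_next_push=tau.get(f, 1),
                )
                if boxes:
                    extra_lines[f] = boxes
        if extra_lines:
            extra = Order(kind="extra", day=day, lines=extra_lines)
            orders_today.append(extra)
            self.schedule_order(extra)

        if self.validate:
            violations = validate_inventory(inv, self.catalog)
            if violations:
                raise RuntimeError(f"day {day}: inventory invariants violated: {violations}")

        record = DayRecord(
            day=day,
            demand=demand,
            administered=administered,
            delivered=delivered,
            rejected_boxes=rejected,
            orders=orders_today,
            end_stock=dict(inv.doses),
            stock_value=inv.stock_value(self.catalog),
        )
        self.log.append(record)
        return record


# ---------------------------------------------------------------------------
# KPIs


@dataclass
class KPIReport:
    """Year-level performance indicators of a policy run."""

    rush_order_count: int          # a rush order covering k drugs counts k
    push_order_days: int
    extra_order_days: int
    any_order_days: int
    avg_drugs_per_push_order: float
    avg_drugs_per_extra_order: float
    avg_drugs_per_order: float
    avg_daily_stock_value: float
    rush_cost_total: float
    horizon_days: int

    def to_dict(self) -> dict:
        return vars(self) | {}


def compute_kpis(log: SimulationLog, catalog: Catalog, rush_cost: float = 300.0) -> KPIReport:
    """Aggregate a simulation log into the policy KPIs."""
    rush_count = 0
    push_days, extra_days, any_days = set(), set(), set()
    drugs_push, drugs_extra, drugs_all = [], [], []
    values = []
    for r in log.records:
        values.append(r.stock_value)
        for o in r.orders:
            drugs_all.append(o.n_drugs)
            any_days.add(r.day)
            if o.kind == "rush":
                rush_count += o.n_drugs
            elif o.kind == "push":
                push_days.add(r.day)
                drugs_push.append(o.n_drugs)
            elif o.kind == "extra":
                extra_days.add(r.day)
                drugs_extra.append(o.n_drugs)
    return KPIReport(
        rush_order_count=rush_count,
        push_order_days=len(push_days),
        extra_order_days=len(extra_days),
        any_order_days=len(any_days),
        avg_drugs_per_push_order=float(np.mean(drugs_push)) if drugs_push else 0.0,
        avg_drugs_per_extra_order=float(np.mean(drugs_extra)) if drugs_extra else 0.0,
        avg_drugs_per_order=float(np.mean(drugs_all)) if drugs_all else 0.0,
        avg_daily_stock_value=float(np.mean(values)) if values else 0.0,
        rush_cost_total=rush_count * rush_cost,
        horizon_days=len(log.records),
    )
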