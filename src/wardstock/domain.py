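"""Shared data model: drugs, storage, calendar, inventory, orders, demand.

Conventions used throughout the package:

* Weekday index 0 is Sunday and 6 is Saturday.  The global horizon starts on
  a Sunday, so ``absolute day % 7`` is the weekday unless a different start
  weekday is configured.
* Quantities are integers: doses for consumption and stock, boxes for orders
  and storage.  Fractional capacities or volumes are rejected, not rounded.
* Each drug has a dedicated shelf (capacity in boxes) and may overflow into
  the shared shelf of its group (capacity in volume units), but only once the
  dedicated shelf is full.
* No regular order is placed on Saturday and nothing regular is received on
  Sunday; drugs ordered on Saturday would arrive on Monday.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

SUNDAY = 0
SATURDAY = 6


def _require_int(value, name: str) -> int:
    """Accept ints and integer-valued floats; reject everything else."""
    if isinstance(value, bool):
        raise TypeError(f"{name} must be an integer, got bool")
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, float) and value.is_integer():
        return int(value)
    raise TypeError(f"{name} must be an integer, got {value!r}")


@dataclass(frozen=True)
class Drug:
    """A drug and its packaging, cost, storage and posology attributes.

    Parameters
    ----------
    id : str
        Drug identifier.
    doses_per_box : int
        Doses contained in one box (U).
    cost_per_dose : float
        Cost of a single dose in EUR (c).
    box_volume : int
        Volume of one box in shared-shelf volume units (V).
    dedicated_capacity : int
        Boxes that fit on the drug's dedicated shelf (C).
    shared_capacity : int
        Maximum boxes of this drug allowed on the group's shared shelf.
    group_id : str
        Identifier of the storage group the drug belongs to.
    daily_posology : int
        Doses needed to treat one patient for one day (1-8).
    """

    id: str
    doses_per_box: int
    cost_per_dose: float
    box_volume: int
    dedicated_capacity: int
    shared_capacity: int
    group_id: str
    daily_posology: int

    def __post_init__(self):
        object.__setattr__(self, "doses_per_box", _require_int(self.doses_per_box, "doses_per_box"))
        object.__setattr__(self, "box_volume", _require_int(self.box_volume, "box_volume"))
        object.__setattr__(
            self, "dedicated_capacity", _require_int(self.dedicated_capacity, "dedicated_capacity")
        )
        object.__setattr__(
            self, "shared_capacity", _require_int(self.shared_capacity, "shared_capacity")
        )
        object.__setattr__(self, "daily_posology", _require_int(self.daily_posology, "daily_posology"))
        if self.doses_per_box < 1:
            raise ValueError(f"drug {self.id}: doses_per_box must be >= 1")
        if self.cost_per_dose <= 0:
            raise ValueError(f"drug {self.id}: cost_per_dose must be > 0")
        if self.box_volume < 1:
            raise ValueError(f"drug {self.id}: box_volume must be >= 1")
        if self.dedicated_capacity < 0 or self.shared_capacity < 0:
            raise ValueError(f"drug {self.id}: capacities must be non-negative")
        if self.max_boxes < 1:
            raise ValueError(f"drug {self.id}: total box capacity must be >= 1")
        if self.daily_posology < 1:
            raise ValueError(f"drug {self.id}: daily_posology must be >= 1")

    @property
    def max_boxes(self) -> int:
        """Upper bound on boxes in stock (dedicated + shared)."""
        return self.dedicated_capacity + self.shared_capacity


@dataclass(frozen=True)
class DrugGroup:
    """Drugs sharing one shared storage shelf of a given volume capacity."""

    id: str
    members: tuple
    shared_volume: int

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        object.__setattr__(self, "shared_volume", _require_int(self.shared_volume, "shared_volume"))
        if self.shared_volume < 0:
            raise ValueError(f"group {self.id}: shared_volume must be >= 0")


class Catalog:
    """The drug catalog: drugs plus their storage groups.

    Every drug belongs to exactly one group; this is validated on
    construction.
    """

    def __init__(self, drugs: Iterable[Drug], groups: Iterable[DrugGroup]):
        self.drugs: dict[str, Drug] = {d.id: d for d in drugs}
        self.groups: dict[str, DrugGroup] = {g.id: g for g in groups}
        seen: dict[str, str] = {}
        for g in self.groups.values():
            for f in g.members:
                if f not in self.drugs:
                    raise ValueError(f"group {g.id} lists unknown drug {f}")
                if f in seen:
                    raise ValueError(f"drug {f} appears in groups {seen[f]} and {g.id}")
                seen[f] = g.id
        for d in self.drugs.values():
            if seen.get(d.id) != d.group_id:
                raise ValueError(f"drug {d.id}: group_id {d.group_id} inconsistent with groups")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.drugs)

    def __len__(self) -> int:
        return len(self.drugs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Catalog)
            and self.drugs == other.drugs
            and self.groups == other.groups
        )

    def to_dict(self) -> dict:
        return {
            "drugs": [vars(d) | {} for d in self.drugs.values()],
            "groups": [
                {"id": g.id, "members": list(g.members), "shared_volume": g.shared_volume}
                for g in self.groups.values()
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Catalog":
        drugs = [Drug(**d) for d in data["drugs"]]
        groups = [DrugGroup(**g) for g in data["groups"]]
        return cls(drugs, groups)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Catalog":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class Calendar:
    """Horizon / planning / scheduling lengths, all multiples of a week.

    ``horizon`` (H) is the simulated span, ``planning_length`` (Omega) the
    span the MILP optimizes over, and ``scheduling_length`` (omega) the
    leading part of each plan that is actually deployed.
    """

    horizon: int
    planning_length: int
    scheduling_length: int
    start_weekday: int = SUNDAY

    def __post_init__(self):
        for name in ("horizon", "planning_length", "scheduling_length"):
            v = _require_int(getattr(self, name), name)
            object.__setattr__(self, name, v)
            if v <= 0 or v % 7:
                raise ValueError(f"{name} must be a positive multiple of 7, got {v}")
        if not (self.scheduling_length < self.planning_length < self.horizon):
            raise ValueError("need scheduling_length < planning_length < horizon")
        if self.horizon % self.scheduling_length:
            raise ValueError("horizon must be an integer multiple of scheduling_length")
        if not 0 <= self.start_weekday <= 6:
            raise ValueError("start_weekday must be in 0..6")

    def day_index(self, absolute_day: int) -> int:
        """Weekday index (0=Sunday .. 6=Saturday) of an absolute day."""
        absolute_day = _require_int(absolute_day, "absolute_day")
        if absolute_day < 0:
            raise ValueError("absolute_day must be >= 0")
        return (self.start_weekday + absolute_day) % 7

    def is_sunday(self, absolute_day: int) -> bool:
        return self.day_index(absolute_day) == SUNDAY

    def is_saturday(self, absolute_day: int) -> bool:
        return self.day_index(absolute_day) == SATURDAY

    @property
    def n_periods(self) -> int:
        return self.horizon // self.scheduling_length

    def to_dict(self) -> dict:
        return vars(self) | {}

    @classmethod
    def from_dict(cls, data: Mapping) -> "Calendar":
        return cls(**data)


def day_index(absolute_day: int, start_weekday: int = SUNDAY) -> int:
    """Weekday index of an absolute day under a given start weekday."""
    absolute_day = _require_int(absolute_day, "absolute_day")
    if absolute_day < 0:
        raise ValueError("absolute_day must be >= 0")
    return (start_weekday + absolute_day) % 7


@dataclass(frozen=True)
class WardConfig:
    """Ward-level parameters: beds, rush-order cost, budgets, lead times."""

    beds: int
    rush_cost: float = 300.0
    daily_budget: float = 2000.0
    safety_budget: float = 400.0
    hierarchy_weight: float | None = None
    regular_lead_days: int = 1
    review_weekday: int = 1  # Monday, for the periodic-review benchmark

    def __post_init__(self):
        object.__setattr__(self, "beds", _require_int(self.beds, "beds"))
        if self.beds < 1:
            raise ValueError("beds must be >= 1")
        if self.rush_cost <= 0:
            raise ValueError("rush_cost must be > 0")
        if self.daily_budget <= 0 or self.safety_budget < 0:
            raise ValueError("budgets must be positive")

    def to_dict(self) -> dict:
        return vars(self) | {}

    @classmethod
    def from_dict(cls, data: Mapping) -> "WardConfig":
        return cls(**data)


def save_config(path, catalog: Catalog, ward: WardConfig, calendar: Calendar) -> None:
    """Write ward, calendar and catalog parameters to one YAML file.

    Schema: top-level keys ``ward`` (beds, rush_cost, daily_budget,
    safety_budget, hierarchy_weight, regular_lead_days, review_weekday),
    ``calendar`` (horizon, planning_length, scheduling_length,
    start_weekday) and ``catalog`` (drugs, groups as in
    :meth:`Catalog.to_dict`).
    """
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"ward": ward.to_dict(), "calendar": calendar.to_dict(),
             "catalog": catalog.to_dict()},
            fh, sort_keys=False,
        )


def load_config(path) -> tuple[Catalog, WardConfig, Calendar]:
    """Read a configuration file written by :func:`save_config`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return (
        Catalog.from_dict(data["catalog"]),
        WardConfig.from_dict(data["ward"]),
        Calendar.from_dict(data["calendar"]),
    )


# ---------------------------------------------------------------------------
# Inventory


class InventoryState:
    """Per-drug stock in doses with the dedicated/shared box placement.

    The canonical placement fills the dedicated shelf first and overflows to
    the shared shelf, mirroring ward practice; ``validate_inventory`` checks
    any explicitly constructed state against the storage rules.
    """

    def __init__(self, doses: Mapping[str, int], boxes_dedicated: Mapping[str, int],
                 boxes_shared: Mapping[str, int]):
        self.doses = {f: int(v) for f, v in doses.items()}
        self.boxes_dedicated = {f: int(v) for f, v in boxes_dedicated.items()}
        self.boxes_shared = {f: int(v) for f, v in boxes_shared.items()}

    @classmethod
    def canonical(cls, catalog: Catalog, doses: Mapping[str, int]) -> "InventoryState":
        """Build a state from dose counts with dedicated-first placement."""
        ded, sha = {}, {}
        full = {f: int(doses.get(f, 0)) for f in catalog.drug_ids}
        for f, s in full.items():
            if s < 0:
                raise ValueError(f"drug {f}: negative stock")
            drug = catalog.drugs[f]
            boxes = math.ceil(s / drug.doses_per_box)
            ded[f] = min(boxes, drug.dedicated_capacity)
            sha[f] = boxes - ded[f]
        return cls(full, ded, sha)

    def boxes_total(self, drug_id: str) -> int:
        return self.boxes_dedicated[drug_id] + self.boxes_shared[drug_id]

    def stock_value(self, catalog: Catalog) -> float:
        return sum(self.doses[f] * catalog.drugs[f].cost_per_dose for f in self.doses)

    def copy(self) -> "InventoryState":
        return InventoryState(self.doses, self.boxes_dedicated, self.boxes_shared)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, InventoryState)
            and self.doses == other.doses
            and self.boxes_dedicated == other.boxes_dedicated
            and self.boxes_shared == other.boxes_shared
        )

    def to_dict(self) -> dict:
        return {
            "doses": dict(self.doses),
            "boxes_dedicated": dict(self.boxes_dedicated),
            "boxes_shared": dict(self.boxes_shared),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "InventoryState":
        return cls(data["doses"], data["boxes_dedicated"], data["boxes_shared"])


def validate_inventory(state: InventoryState, catalog: Catalog) -> list[str]:
    """Check an inventory state against the storage invariants.

    Returns the list of violated invariants (empty iff the state is
    feasible).  Raises on drugs unknown to the catalog.
    """
    violations: list[str] = []
    for f in state.doses:
        if f not in catalog.drugs:
            raise KeyError(f"unknown drug id {f!r}")
    for f in catalog.drug_ids:
        if f not in state.doses:
            raise KeyError(f"state missing drug {f!r}")
        drug = catalog.drugs[f]
        s = state.doses[f]
        alpha = state.boxes_dedicated[f]
        x = state.boxes_shared[f]
        beta = alpha + x
        if s < 0:
            violations.append(f"{f}: negative stock")
        if beta != math.ceil(s / drug.doses_per_box):
            violations.append(f"{f}: box-count mismatch (beta={beta}, doses={s})")
        if alpha > drug.dedicated_capacity:
            violations.append(f"{f}: dedicated capacity exceeded")
        if x > drug.shared_capacity:
            violations.append(f"{f}: shared capacity exceeded")
        if x > 0 and alpha < drug.dedicated_capacity:
            violations.append(f"{f}: shared-before-dedicated")
    for g in catalog.groups.values():
        used = sum(state.boxes_shared[f] * catalog.drugs[f].box_volume for f in g.members)
        if used > g.shared_volume:
            violations.append(f"group {g.id}: shared volume exceeded ({used} > {g.shared_volume})")
    return violations


# ---------------------------------------------------------------------------
# Orders and demand


ORDER_KINDS = ("push", "rush", "extra")


@dataclass(frozen=True)
class Order:
    """An order event: kind, absolute day it is placed, and drug -> boxes."""

    kind: str
    day: int
    lines: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ORDER_KINDS:
            raise ValueError(f"order kind must be one of {ORDER_KINDS}")
        lines = {f: _require_int(b, f"boxes of {f}") for f, b in self.lines.items()}
        if any(b < 1 for b in lines.values()):
            raise ValueError("order lines must be >= 1 box")
        object.__setattr__(self, "lines", lines)

    @property
    def n_drugs(self) -> int:
        return len(self.lines)


class DemandMatrix:
    """Doses per drug per day over a period (forecast or realized).

    Stored as a dense integer array of shape (n_drugs, n_days); rows follow
    ``drug_ids`` order.
    """

    def __init__(self, drug_ids: Iterable[str], values):
        self.drug_ids = list(drug_ids)
        arr = np.asarray(values)
        if arr.ndim != 2 or arr.shape[0] != len(self.drug_ids):
            raise ValueError("values must be (n_drugs, n_days)")
        if np.any(arr < 0):
            raise ValueError("demand must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("demand must be integer doses")
            arr = np.round(arr).astype(np.int64)
        self.values = arr.astype(np.int64)

    @classmethod
    def zeros(cls, drug_ids: Iterable[str], n_days: int) -> "DemandMatrix":
        ids = list(drug_ids)
        return cls(ids, np.zeros((len(ids), n_days), dtype=np.int64))

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    def demand(self, drug_id: str, day: int) -> int:
        return int(self.values[self.drug_ids.index(drug_id), day])

    def day_totals(self, day: int) -> dict[str, int]:
        return {f: int(self.values[i, day]) for i, f in enumerate(self.drug_ids)}

    def window(self, start: int, length: int) -> "DemandMatrix":
        return DemandMatrix(self.drug_ids, self.values[:, start : start + length])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DemandMatrix)
            and self.drug_ids == other.drug_ids
            and np.array_equal(self.values, other.values)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.drug_ids, name="drug"),
            columns=pd.RangeIndex(self.n_days, name="day"),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DemandMatrix":
        return cls(list(frame.index), frame.to_numpy())

    @classmethod
    def from_csv(cls, path) -> "DemandMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))
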