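"""Safety-stock sizing: the basic one-patient-day reserve and its
knapsack augmentation.

The basic policy reserves, for every drug, the doses needed to treat one
patient for one day (the posology) and charges the reserve to the safety
budget.  The knapsack policy spends the residual budget on additional
stock: candidate items are the positive daily-consumption values observed
for each drug in a long demand-generator run, with their empirical
frequencies as profits and their monetary cost as weights; the 0/1 knapsack
is solved exactly and more than one value per drug may be selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from wardstock.distributions import ConsumptionDistribution
from wardstock.domain import Catalog


@dataclass
class SafetyStockLevels:
    """Per-drug safety-stock floor in doses, plus the residual budget.

    ``selected_profit`` is the total empirical-frequency profit of the
    knapsack selection (0 for the basic policy).
    """

    levels: dict[str, int]
    policy: str  # "basic" | "knapsack"
    residual_budget: float
    selected_profit: float = 0.0

    def __getitem__(self, drug_id: str) -> int:
        return self.levels[drug_id]


def basic_levels(catalog: Catalog, safety_budget: float) -> SafetyStockLevels:
    """One posology of every drug; remaining budget is left for the knapsack.

    Raises if the budget cannot cover the basic reserve, reporting the
    required amount.
    """
    levels = {f: d.daily_posology for f, d in catalog.drugs.items()}
    cost = sum(d.daily_posology * d.cost_per_dose for d in catalog.drugs.values())
    if cost > safety_budget + 1e-9:
        raise ValueError(
            f"safety budget {safety_budget:.2f} cannot cover the basic reserve "
            f"({cost:.2f} required)"
        )
    return SafetyStockLevels(levels, "basic", safety_budget - cost)


@dataclass(frozen=True)
class _Item:
    drug: str
    doses: int
    profit: float
    weight_cents: int


def _solve_knapsack(items: Sequence[_Item], budget_cents: int) -> list[int]:
    """Exact 0/1 knapsack by DP over integer cents; returns chosen indices.

    Ties among equal-profit solutions are broken by lower total weight, then
    by lexicographic (drug, doses) order, so the selection is deterministic.
    """
    order = sorted(range(len(items)), key=lambda i: (items[i].drug, items[i].doses))
    n, B = len(items), budget_cents
    best = np.zeros(B + 1)
    weight = np.zeros(B + 1, dtype=np.int64)
    take = np.zeros((n, B + 1), dtype=bool)
    for stage, i in enumerate(order):
        w = items[i].weight_cents
        if w > B:
            continue
        cand_p = best[: B + 1 - w] + items[i].profit
        cand_w = weight[: B + 1 - w] + w
        cur_p, cur_w = best[w:], weight[w:]
        better = (cand_p > cur_p + 1e-12) | (
            (np.abs(cand_p - cur_p) <= 1e-12) & (cand_w < cur_w)
        )
        best[w:] = np.where(better, cand_p, cur_p)
        weight[w:] = np.where(better, cand_w, cur_w)
        take[stage, w:] = better
    b, selected = B, []
    for stage in range(n - 1, -1, -1):
        if take[stage, b]:
            selected.append(order[stage])
            b -= items[order[stage]].weight_cents
    return selected


def knapsack_levels(
    basic: SafetyStockLevels,
    consumption: ConsumptionDistribution,
    costs: Mapping[str, float],
) -> SafetyStockLevels:
    """Augment the basic levels by an exact 0/1 knapsack over the residual
    budget.

    Item (f, v) carries profit = empirical mass of daily consumption v and
    weight = cost of v doses of f; selected values add to the drug's floor.
    A zero residual budget returns the basic levels unchanged (tagged
    ``knapsack``).
    """
    if basic.residual_budget < 0:
        raise ValueError("residual budget must be >= 0")
    budget_cents = int(round(basic.residual_budget * 100))
    items = []
    for f, pairs in ((f, consumption.items(f)) for f in basic.levels):
        for doses, mass in pairs:
            w = int(round(doses * costs[f] * 100))
            if w <= budget_cents and mass > 0:
                items.append(_Item(f, doses, mass, max(w, 1)))
    selected = _solve_knapsack(items, budget_cents) if items else []
    levels = dict(basic.levels)
    spent = 0
    profit = 0.0
    for i in selected:
        it = items[i]
        levels[it.drug] += it.doses
        spent += it.weight_cents
        profit += it.profit
    return SafetyStockLevels(levels, "knapsack", basic.residual_budget - spent / 100,
                             selected_profit=profit)
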