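"""Independent brute-force oracles used to cross-check the solvers.

These deliberately avoid the production code paths: the lot-sizing oracle
enumerates every (lot size, order-day subset, urgent flag) combination per
drug and evaluates feasibility and the weighted objective directly from
the model's definitions; the knapsack oracle enumerates all item subsets.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from wardstock.domain import SATURDAY
from wardstock.optimizer import MILPInstance, compute_first_day_rush


def _drug_configs(instance: MILPInstance, fi: int):
    """All feasible per-drug plans with their stock/storage trajectories."""
    cat = instance.catalog
    f = cat.drug_ids[fi]
    drug = cat.drugs[f]
    T = instance.n_days
    U, Gam = drug.doses_per_box, drug.max_boxes
    C, Cbar = drug.dedicated_capacity, drug.shared_capacity
    q = instance.demand.values[fi]
    l0 = int(instance.initial_stock.get(f, 0))
    ss = int(instance.safety_stock.get(f, 0))
    ybar = compute_first_day_rush(int(q[0]), ss, l0, U)
    candidates = [t for t in range(T - 1) if instance.weekday(t) != SATURDAY]
    configs = []
    for rho in range(Gam + 1):
        for mask in range(2 ** len(candidates)):
            days = [candidates[i] for i in range(len(candidates)) if mask >> i & 1]
            for nub in (0, 1) if ybar > 0 else (0,):
                s = np.empty(T, dtype=np.int64)
                s[0] = l0 - q[0] + U * ybar * nub
                for t in range(1, T):
                    receipt = U * rho if (rho > 0 and (t - 1) in days) else 0
                    s[t] = s[t - 1] - q[t] + receipt
                if (s < ss).any() or (s < 0).any():
                    continue
                beta = -(-s // U)  # ceil
                if (beta > Gam).any():
                    continue
                x = np.maximum(0, beta - C)
                if (x > Cbar).any():
                    continue
                configs.append(
                    {"rho": rho, "days": frozenset(days), "nub": nub,
                     "s": s, "x": x, "ybar": ybar}
                )
    return configs


def enumerate_milp_objective(instance: MILPInstance) -> float | None:
    """Optimal weighted objective by exhaustive enumeration (None if
    infeasible).  Practical for <= 2 drugs and short horizons."""
    cat = instance.catalog
    F, T = len(cat), instance.n_days
    assert F <= 2, "oracle enumeration is exponential in drugs"
    M = instance.hierarchy_weight
    assert M is not None, "set an explicit hierarchy weight for comparison"
    B, O = instance.daily_budget, instance.rush_cost
    cost = np.array([cat.drugs[f].cost_per_dose for f in cat.drug_ids])
    U = np.array([cat.drugs[f].doses_per_box for f in cat.drug_ids])
    ssv = np.array([instance.safety_stock.get(f, 0) for f in cat.drug_ids])
    vol = np.array([cat.drugs[f].box_volume for f in cat.drug_ids])
    group_caps = {
        g.id: (g.shared_volume, [cat.drug_ids.index(f) for f in g.members])
        for g in cat.groups.values()
    }
    per_drug = [_drug_configs(instance, fi) for fi in range(F)]
    best = None
    for combo in product(*per_drug):
        # shared-shelf volume per group, every day
        ok = True
        for cap, members in group_caps.values():
            used = sum(combo[fi]["x"] * vol[fi] for fi in members)
            if np.any(used > cap):
                ok = False
                break
        if not ok:
            continue
        # order events and homogeneity
        day_counts: dict[int, int] = {}
        for cfg in combo:
            for d in cfg["days"]:
                day_counts[d] = day_counts.get(d, 0) + 1
        if day_counts:
            spread = max(day_counts.values()) - min(day_counts.values())
            if spread > instance.upsilon_bar:
                continue
        # soft budget violation (day 0 excludes urgent arrivals)
        sv = sum(cost[fi] * (combo[fi]["s"] - ssv[fi]) for fi in range(F))
        eps = max(0.0, float(np.max(sv - B)))
        sv0 = sum(
            cost[fi] * (combo[fi]["s"][0] - ssv[fi]
                        - U[fi] * combo[fi]["ybar"] * combo[fi]["nub"])
            for fi in range(F)
        )
        eps = max(eps, sv0 - B)
        obj = (
            eps
            + M * len(day_counts)
            + O * sum(cfg["nub"] for cfg in combo)
            + sum(float(cost[fi] / B * combo[fi]["s"].sum()) for fi in range(F))
        )
        if best is None or obj < best - 1e-12:
            best = obj
    return best


def enumerate_knapsack(profits, weights, budget) -> float:
    """Best total profit over all item subsets with total weight <= budget."""
    n = len(profits)
    assert n <= 20
    idx = np.arange(2 ** n, dtype=np.uint32)
    total_p = np.zeros(2 ** n)
    total_w = np.zeros(2 ** n)
    for i in range(n):
        bit = (idx >> i) & 1
        total_p += bit * profits[i]
        total_w += bit * weights[i]
    feas = total_w <= budget + 1e-9
    return float(total_p[feas].max())


def random_small_instance(rng: np.random.Generator, two_drugs: bool) -> MILPInstance:
    """A random oracle-sized lot-sizing instance: <= 2 drugs, <= 14 days,
    at most 3 boxes of total storage per drug."""
    from wardstock.domain import Catalog, DemandMatrix, Drug, DrugGroup

    n = 2 if two_drugs else 1
    T = 7 if two_drugs else 14
    drugs, members = [], []
    for i in range(n):
        C = int(rng.integers(1, 3))
        Cb = min(int(rng.integers(0, 3)), 3 - C)
        drugs.append(
            Drug(id=f"f{i}", doses_per_box=int(rng.integers(1, 5)),
                 cost_per_dose=round(float(rng.uniform(0.5, 5)), 2),
                 box_volume=int(rng.integers(1, 4)),
                 dedicated_capacity=C, shared_capacity=Cb,
                 group_id="g0", daily_posology=1)
        )
        members.append(f"f{i}")
    cat = Catalog(drugs, [DrugGroup("g0", members, int(rng.integers(2, 7)))])
    q = rng.integers(0, 3, size=(n, T))
    q[:, rng.random(T) < 0.4] = 0
    return MILPInstance(
        catalog=cat,
        demand=DemandMatrix(cat.drug_ids, q),
        initial_stock={f: int(rng.integers(0, 6)) for f in cat.drug_ids},
        safety_stock={f: int(rng.integers(0, 2)) for f in cat.drug_ids},
        daily_budget=float(rng.integers(20, 60)),
        rush_cost=30.0,
        upsilon_bar=int(rng.integers(1, 3)),
        hierarchy_weight=100.0,
    )


def milp_oracle_match_rate(seed: int = 42, n_instances: int = 25) -> float:
    """Fraction of random small instances on which the solver's weighted
    objective equals the enumeration oracle's (infeasibility must agree)."""
    from wardstock.optimizer import build_milp, solve_milp

    rng = np.random.default_rng(seed)
    matches = 0
    for k in range(n_instances):
        inst = random_small_instance(rng, two_drugs=(k % 2 == 0))
        oracle = enumerate_milp_objective(inst)
        sol = solve_milp(build_milp(inst), mode="weighted", gap=1e-9, time_limit=60)
        if oracle is None:
            matches += sol.status == "infeasible"
        else:
            matches += (
                sol.status == "optimal"
                and abs(sol.objective - oracle) <= 1e-5 * (1 + abs(oracle))
            )
    return matches / n_instances


def counting_pd1(days_table) -> dict:
    """Naive admissions-given-vacancy ratio of favourable over possible."""
    out: dict[int, dict[int, float]] = {}
    rows = list(days_table.itertuples())
    for v in {int(r.vacancy) for r in rows}:
        hits = [int(r.admissions) for r in rows if int(r.vacancy) == v]
        out[v] = {i: hits.count(i) / len(hits) for i in set(hits)}
    return out


def counting_share(labels) -> dict:
    labels = list(labels)
    return {c: labels.count(c) / len(labels) for c in set(labels)}
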