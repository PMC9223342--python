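"""Seeded synthetic fixtures: drug catalogs, patient classes, therapy
trees, and event logs.

The generated conditions emulate the study ward: 18 drugs whose dose costs
span 0.30-113 EUR (log-uniform, both extremes attained), boxes of 1-25
doses, daily posologies of 1-8 doses, box volumes spanning a 100-fold
range, 6 patient classes with class shares, death probabilities and
length-of-stay ranges shaped like the observed 3-feature stratification
(class shares roughly 0.7%-35%, death probabilities 0.5%-43%, stays of
1-27 days), and a ward of 8 beds.  Event logs are sampled exactly from the
supplied distributions so estimator recovery can be tested against known
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from wardstock.demand import (
    Patient,
    TherapyNode,
    TherapyTree,
    TreeTherapyModel,
    WardState,
)
from wardstock.distributions import NEVER, AdmissionLog, EmpiricalDistribution
from wardstock.domain import Calendar, Catalog, Drug, DrugGroup, WardConfig


@dataclass(frozen=True)
class FixtureSpec:
    """Ranges the generated drug catalog must honor exactly."""

    n_drugs: int = 18
    cost_range: tuple = (0.30, 113.0)
    box_size_range: tuple = (1, 25)
    posology_range: tuple = (1, 8)
    volume_ratio: int = 100
    n_classes: int = 6
    beds: int = 8
    rush_cost: float = 300.0
    n_groups: int = 3


def make_drug_catalog(spec: FixtureSpec = FixtureSpec(), seed: int = 0) -> Catalog:
    """Drug catalog with the stated attribute ranges, extremes attained.

    Costs are drawn log-uniformly so cheap and expensive drugs are both
    represented; the first two drugs pin the cost extremes, box-size
    extremes and volume extremes.  Drugs are partitioned into
    ``spec.n_groups`` shared-storage groups.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    n = spec.n_drugs
    lo_c, hi_c = spec.cost_range
    costs = np.exp(rng.uniform(math.log(lo_c), math.log(hi_c), size=n))
    box_sizes = rng.integers(spec.box_size_range[0], spec.box_size_range[1] + 1, size=n)
    posologies = rng.integers(spec.posology_range[0], spec.posology_range[1] + 1, size=n)
    volumes = np.exp(
        rng.uniform(0, math.log(spec.volume_ratio), size=n)
    ).round().astype(int).clip(1, spec.volume_ratio)
    if n >= 2:  # pin the stated extremes
        costs[0], costs[1] = lo_c, hi_c
        box_sizes[0], box_sizes[1] = spec.box_size_range
        posologies[0], posologies[1] = spec.posology_range
        volumes[0], volumes[1] = 1, spec.volume_ratio
    drugs = []
    group_of = {}
    for i in range(n):
        gid = f"g{i % spec.n_groups}"
        fid = f"d{i:02d}"
        group_of.setdefault(gid, []).append(fid)
        # shelf sizes cover a worst-case weekend (no Sunday receipt): the
        # dedicated shelf holds ~2.5 days of every-bed demand, the shared
        # overflow another ~1.5 days
        worst_daily = spec.beds * int(posologies[i])
        ded = max(2, math.ceil(2.5 * worst_daily / box_sizes[i]))
        sha = max(1, math.ceil(1.5 * worst_daily / box_sizes[i]))
        drugs.append(
            Drug(
                id=fid,
                doses_per_box=int(box_sizes[i]),
                cost_per_dose=round(float(costs[i]), 2),
                box_volume=int(volumes[i]),
                dedicated_capacity=ded,
                shared_capacity=sha,
                group_id=gid,
                daily_posology=int(posologies[i]),
            )
        )
    groups = []
    for gid, members in group_of.items():
        # shared shelf fits ~60% of the members' overflow allowance at once
        vol = int(
            sum(
                math.ceil(0.6 * d.shared_capacity) * d.box_volume
                for d in drugs
                if d.id in members
            )
        )
        groups.append(DrugGroup(id=gid, members=members, shared_volume=vol))
    return Catalog(drugs, groups)


# ---------------------------------------------------------------------------
# Patient classes


#: (class id, admission type, class share %, death prob %, max LoS) shaped
#: like the observed 3-feature stratification.
_CLASS_SHAPE = [
    ("ES-Med-NoVent", "ElectiveSurgery", 34.99, 0.46, 4),
    ("ES-Med-Vent", "ElectiveSurgery", 30.94, 1.17, 6),
    ("ES-High-Vent", "ElectiveSurgery", 7.01, 18.86, 10),
    ("US-Med-Vent", "UrgentSurgery", 3.81, 6.32, 6),
    ("US-High-Vent", "UrgentSurgery", 6.45, 24.84, 18),
    ("Med-High-Vent", "Medical", 8.06, 43.28, 27),
]


@dataclass
class PatientClasses:
    """Per-class admission, stay and infection parameters plus pd1."""

    pd1: EmpiricalDistribution
    pd2: EmpiricalDistribution
    pd3: EmpiricalDistribution
    pd4: EmpiricalDistribution
    pd5: EmpiricalDistribution
    death_probs: dict[str, float]
    admission_types: dict[str, str]
    beds: int = 8

    def dists(self) -> dict[str, EmpiricalDistribution]:
        return {"pd1": self.pd1, "pd2": self.pd2, "pd3": self.pd3,
                "pd4": self.pd4, "pd5": self.pd5}


def make_admission_distribution(beds: int, daily_rate: float = 1.3,
                                max_batch: int = 4) -> EmpiricalDistribution:
    """Admissions-given-vacancy table: truncated Poisson arrivals.

    For vacancy v the support is 0..min(v, max_batch), so admissions never
    exceed the empty beds, as in an observed log.
    """
    table = {0: {0: 1.0}}
    for v in range(1, beds + 1):
        cap = min(v, max_batch)
        raw = {i: daily_rate**i / math.factorial(i) for i in range(cap + 1)}
        z = sum(raw.values())
        table[v] = {i: p / z for i, p in raw.items()}
    return EmpiricalDistribution(table)


def make_patient_classes(seed: int = 0, beds: int = 8,
                         lab_lag_range: tuple = (3, 7)) -> PatientClasses:
    """Class probabilities, stays, infection onset and lab-lag tables.

    Class shares and death probabilities follow the observed stratification
    (normalized to sum to 1); stays are geometric-tailed within each class
    range; infection onset probability grows with the stay length, with an
    explicit ``NEVER`` mass; lab lags are uniform on 3-7 days, matching the
    usual turnaround of microbiology tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
    shares = np.array([row[2] for row in _CLASS_SHAPE])
    shares = shares / shares.sum()
    pd2 = EmpiricalDistribution({c[0]: float(p) for c, p in zip(_CLASS_SHAPE, shares)})
    pd3_table, pd4_table, pd5_table = {}, {}, {}
    death_probs, admission_types = {}, {}
    for (cls, adm_type, _, death_pct, max_los) in _CLASS_SHAPE:
        death_probs[cls] = death_pct / 100.0
        admission_types[cls] = adm_type
        decay = 0.55 if max_los <= 6 else 0.8
        mass = np.array([decay ** (l - 1) for l in range(1, max_los + 1)])
        mass *= 1.0 + 0.1 * rng.random(max_los)  # seeded jitter
        mass /= mass.sum()
        pd3_table[cls] = {l: float(m) for l, m in zip(range(1, max_los + 1), mass)}
        for los in range(1, max_los + 1):
            key = (cls, los)
            p_inf = min(0.85, 0.08 * los)  # longer stays get infected more
            if los == 1 or p_inf <= 0:
                pd4_table[key] = {NEVER: 1.0}
            else:
                onset = np.array([0.7 ** d for d in range(1, los)])
                onset = onset / onset.sum() * p_inf
                pd4_table[key] = {d: float(p) for d, p in zip(range(1, los), onset)}
                pd4_table[key][NEVER] = float(1.0 - p_inf)
            lags = range(lab_lag_range[0], lab_lag_range[1] + 1)
            pd5_table[key] = {lag: 1.0 / len(list(lags)) for lag in lags}
    return PatientClasses(
        pd1=make_admission_distribution(beds),
        pd2=pd2,
        pd3=EmpiricalDistribution(pd3_table),
        pd4=EmpiricalDistribution(pd4_table),
        pd5=EmpiricalDistribution(pd5_table),
        death_probs=death_probs,
        admission_types=admission_types,
        beds=beds,
    )


def build_therapy_trees(
    classes: PatientClasses,
    catalog: Catalog,
    seed: int = 0,
    et_success_prob: float = 0.6,
) -> TreeTherapyModel:
    """Default three-stage therapy trees wired to the class tables.

    Each class runs a baseline supportive treatment until the (stochastic)
    infection onset; an infection starts a broad-spectrum empirical therapy
    that lasts until the lab responds, then branches into de-escalation
    (success) or a targeted therapy (failure), both kept until discharge.
    Treatments draw the class's drugs from the catalog at their posology.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 33]))
    ids = list(catalog.drug_ids)
    trees = {}
    for cls in classes.death_probs:
        picks = rng.choice(len(ids), size=4, replace=len(ids) < 4)
        base_f, et_f, et2_f, tt_f = (ids[i] for i in picks)
        pos = {f: catalog.drugs[f].daily_posology for f in ids}
        deesc = TherapyNode(f"{cls}-deescalation", {base_f: pos[base_f]})
        tt = TherapyNode(f"{cls}-target", {tt_f: pos[tt_f]})
        et = TherapyNode(
            f"{cls}-empirical",
            {et_f: pos[et_f], et2_f: pos[et2_f]},
            duration="pd5",
            children=[(et_success_prob, deesc), (1.0 - et_success_prob, tt)],
        )
        root = TherapyNode(
            f"{cls}-baseline", {base_f: pos[base_f]}, duration="pd4",
            children=[(1.0, et)],
        )
        trees[cls] = TherapyTree(cls=cls, root=root, death_prob=classes.death_probs[cls])
    return TreeTherapyModel(trees, duration_dists={"pd4": classes.pd4, "pd5": classes.pd5})


# ---------------------------------------------------------------------------
# Event logs with known ground truth


def make_event_logs(
    classes: PatientClasses,
    model: TreeTherapyModel,
    catalog: Catalog,
    length: int,
    seed: int = 0,
) -> tuple[AdmissionLog, pd.DataFrame]:
    """Sample ``length`` ward days exactly from the supplied tables.

    Returns the admission log (daily flow + per-patient outcomes) and the
    per-day per-drug demand table.  Ground truth being the inputs, the
    estimators of the distributions module can be checked for recovery.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 44]))
    beds = classes.beds
    state = WardState(day=0, beds=beds)
    day_rows, patient_objs = [], []
    demand_rows = np.zeros((length, len(catalog.drug_ids)), dtype=np.int64)
    index = {f: i for i, f in enumerate(catalog.drug_ids)}
    occupancy_prev = 0
    for day in range(length):
        leaving = [p for p in state.patients if not p.active]
        state.patients = [p for p in state.patients if p.active]
        out = len(leaving)
        vacancy = beds - occupancy_prev + out
        n_in = 0
        if vacancy > 0:
            key = vacancy if classes.pd1.has_key(vacancy) else classes.pd1.nearest_smaller_key(vacancy)
            n_in = min(int(classes.pd1.sample(rng, key=key)), vacancy)
        for _ in range(n_in):
            cls = classes.pd2.sample(rng)
            los = int(classes.pd3.sample(rng, key=cls))
            patient = Patient(id=state.next_patient_id, cls=cls,
                              admission_day=day, los=los)
            state.next_patient_id += 1
            model.on_admit(patient, rng)
            state.patients.append(patient)
            patient_objs.append(patient)
        for p in state.patients:
            rx = model.step(p, rng)
            for f, d in rx.items():
                demand_rows[day, index[f]] += d
        occupancy = len(state.patients)
        day_rows.append(
            {"day": day, "admissions": n_in, "departures": out,
             "occupancy": occupancy, "vacancy": vacancy}
        )
        occupancy_prev = occupancy
        state.day += 1
    patients = pd.DataFrame(
        {
            "patient_id": [p.id for p in patient_objs],
            "admission_day": [p.admission_day for p in patient_objs],
            "admission_type": [classes.admission_types[p.cls] for p in patient_objs],
            "cls": [p.cls for p in patient_objs],
            "los": [p.los for p in patient_objs],
            "death": [p.died for p in patient_objs],
            "infection_day": [
                np.nan if p.infection_day is None else p.infection_day for p in patient_objs
            ],
            "retest_lag": [
                np.nan if p.retest_lag is None else p.retest_lag for p in patient_objs
            ],
            "year": [2011 + p.admission_day // 365 for p in patient_objs],
        }
    )
    days = pd.DataFrame(day_rows)
    demand = pd.DataFrame(demand_rows, columns=catalog.drug_ids)
    demand.index.name = "day"
    return AdmissionLog(days=days, patients=patients, beds=beds), demand


# ---------------------------------------------------------------------------
# Default study configuration


def default_experiment_config(
    seed: int = 0,
    spec: FixtureSpec = FixtureSpec(),
    horizon: int = 364,
    planning_length: int = 28,
    scheduling_length: int = 7,
    **overrides,
):
    """The default synthetic study: catalog, classes, trees, budgets.

    The daily soft budget is a guard-rail against over-stocking: ten times
    the cost of the basic safety reserve (one posology of every drug).  The
    safety budget is 20% of the daily budget, so the basic reserve is
    always affordable and the knapsack step has a meaningful residual.
    """
    from wardstock.controller import ExperimentConfig

    catalog = make_drug_catalog(spec, seed)
    classes = make_patient_classes(seed, beds=spec.beds)
    model = build_therapy_trees(classes, catalog, seed)
    reserve = sum(d.daily_posology * d.cost_per_dose for d in catalog.drugs.values())
    daily_budget = round(10.0 * reserve, -2)
    ward = WardConfig(
        beds=spec.beds,
        rush_cost=spec.rush_cost,
        daily_budget=daily_budget,
        safety_budget=0.2 * daily_budget,
    )
    calendar = Calendar(
        horizon=horizon,
        planning_length=planning_length,
        scheduling_length=scheduling_length,
    )
    return ExperimentConfig(
        catalog=catalog,
        ward=ward,
        calendar=calendar,
        dists=classes.dists(),
        therapy_model=model,
        **overrides,
    )
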