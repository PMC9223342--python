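"""Therapy-driven stochastic demand generation.

The ward is advanced one day at a time: patients whose stay has ended leave,
new patients are admitted according to the vacancy-conditioned admission
distribution (pd1), each new patient receives a class (pd2) and a length of
stay (pd3), and every hospitalized patient walks one step along a per-class
therapy tree whose nodes carry daily drug prescriptions.  Stochastic node
durations (infection onset from pd4, lab-response lag from pd5) and branch
draws (therapy success/failure) shape each patient's path.  Summing the
individual prescriptions gives the ward's daily drug demand.

The same machinery serves two purposes: inside the simulator it reveals the
realized demand incrementally, and as a predictor it is run forward on a
private copy of the ward to produce the demand matrix for a whole planning
period in one shot.  A drug-driven Poisson forecaster is provided as the
competitor: independent Poisson draws per drug and day, ignoring therapies.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from wardstock.distributions import NEVER, EmpiricalDistribution, PoissonRates
from wardstock.domain import DemandMatrix

#: Sentinel duration for "until the end of the stay".
UNTIL_DISCHARGE = None


@dataclass
class TherapyNode:
    """A treatment stage: daily prescription, duration, stochastic exits.

    ``duration`` is a fixed number of days, ``UNTIL_DISCHARGE`` (absorbing),
    or the name of a duration distribution (``"pd4"`` / ``"pd5"``) resolved
    against the patient's (class, los) key when the node is entered.
    ``children`` are (probability, node) branches sampled when the duration
    elapses; probabilities must sum to 1 when children are present.
    """

    name: str
    treatment: dict[str, int] = field(default_factory=dict)
    duration: int | str | None = UNTIL_DISCHARGE
    children: list = field(default_factory=list)

    def validate(self, max_los: int | None = None, _depth: int = 0) -> None:
        if _depth > 64:
            raise ValueError(f"node {self.name}: tree too deep (cycle?)")
        if any(d < 0 for d in self.treatment.values()):
            raise ValueError(f"node {self.name}: negative prescription")
        if self.children:
            total = sum(p for p, _ in self.children)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"node {self.name}: branch probabilities sum to {total}")
            for _, child in self.children:
                child.validate(max_los, _depth + 1)


@dataclass
class TherapyTree:
    """Rooted per-class therapy evolution tree."""

    cls: str
    root: TherapyNode
    death_prob: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.death_prob <= 1.0:
            raise ValueError(f"class {self.cls}: death_prob out of [0,1]")
        self.root.validate()


@dataclass
class Patient:
    """A hospitalized patient and their position along a therapy path."""

    id: int
    cls: str
    admission_day: int
    los: int
    died: bool = False
    infection_day: object = None
    retest_lag: object = None
    node: TherapyNode | None = None
    node_duration: float = 0.0
    day_in_node: int = 0
    elapsed: int = 0
    prev_drugs: frozenset = frozenset()
    prescription: dict = field(default_factory=dict)

    @property
    def active(self) -> bool:
        return self.elapsed < self.los


@dataclass
class WardState:
    """The ward on a given day: hospitalized patients and bed capacity."""

    day: int
    beds: int
    patients: list = field(default_factory=list)
    next_patient_id: int = 0
    notes: list = field(default_factory=list)

    @property
    def occupancy(self) -> int:
        return len(self.patients)

    @property
    def vacancy(self) -> int:
        return self.beds - self.occupancy

    def copy(self) -> "WardState":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Therapy models


class TreeTherapyModel:
    """Default therapy mechanism: walk the per-class therapy tree."""

    def __init__(self, trees: Mapping[str, TherapyTree],
                 duration_dists: Mapping[str, EmpiricalDistribution] | None = None):
        self.trees = dict(trees)
        for t in self.trees.values():
            t.validate()
        self.duration_dists = dict(duration_dists or {})

    def _realize_duration(self, node: TherapyNode, patient: Patient,
                          rng: np.random.Generator) -> float:
        if node.duration is UNTIL_DISCHARGE:
            return float("inf")
        if isinstance(node.duration, str):
            dist = self.duration_dists[node.duration]
            key = (patient.cls, patient.los)
            if not dist.has_key(key):
                # unseen (class, los) pair: pool over the class
                pooled = [k for k in dist.keys() if isinstance(k, tuple) and k[0] == patient.cls]
                if not pooled:
                    return float("inf")
                key = pooled[int(rng.integers(len(pooled)))]
            value = dist.sample(rng, key=key)
            if value == NEVER:
                return float("inf")
            if node.duration == "pd4":
                patient.infection_day = int(value)
            elif node.duration == "pd5":
                patient.retest_lag = int(value)
            return float(value)
        return float(node.duration)

    def on_admit(self, patient: Patient, rng: np.random.Generator) -> None:
        tree = self.trees[patient.cls]
        patient.died = bool(rng.random() < tree.death_prob)
        patient.node = tree.root
        patient.day_in_node = 0
        patient.node_duration = self._realize_duration(tree.root, patient, rng)

    def step(self, patient: Patient, rng: np.random.Generator) -> dict[str, int]:
        """Advance the patient one day and return today's prescription."""
        if not patient.active:
            raise ValueError(f"patient {patient.id} already discharged")
        while patient.day_in_node >= patient.node_duration:
            if not patient.node.children:
                break  # absorbing stage
            probs = np.array([p for p, _ in patient.node.children])
            idx = int(rng.choice(len(probs), p=probs / probs.sum()))
            patient.node = patient.node.children[idx][1]
            patient.day_in_node = 0
            patient.node_duration = self._realize_duration(patient.node, patient, rng)
        rx = {f: d for f, d in patient.node.treatment.items() if d > 0}
        patient.day_in_node += 1
        patient.elapsed += 1
        patient.prescription = rx
        return rx


class MarkovTherapyModel:
    """First-order Markov alternative: drug use depends on yesterday's drugs.

    For each class and drug the model holds the probability that the drug is
    administered today given that it was (``continue_prob``) or was not
    (``start_prob``) administered yesterday; administered drugs are given at
    their posology.  This reproduces drug persistence without an explicit
    therapy-tree structure.
    """

    def __init__(self, start_prob: Mapping[str, Mapping[str, float]],
                 continue_prob: Mapping[str, Mapping[str, float]],
                 posologies: Mapping[str, int]):
        self.start_prob = {c: dict(p) for c, p in start_prob.items()}
        self.continue_prob = {c: dict(p) for c, p in continue_prob.items()}
        self.posologies = dict(posologies)

    def on_admit(self, patient: Patient, rng: np.random.Generator) -> None:
        patient.prev_drugs = frozenset()

    def step(self, patient: Patient, rng: np.random.Generator) -> dict[str, int]:
        if not patient.active:
            raise ValueError(f"patient {patient.id} already discharged")
        start = self.start_prob[patient.cls]
        cont = self.continue_prob[patient.cls]
        rx: dict[str, int] = {}
        for f in self.posologies:
            p = cont.get(f, 0.0) if f in patient.prev_drugs else start.get(f, 0.0)
            if rng.random() < p:
                rx[f] = self.posologies[f]
        patient.prev_drugs = frozenset(rx)
        patient.elapsed += 1
        patient.prescription = rx
        return rx


# ---------------------------------------------------------------------------
# Daily ward dynamics


def discharge_due(state: WardState) -> int:
    """Remove patients whose stay has ended; return the number removed."""
    leaving = [p for p in state.patients if not p.active]
    state.patients = [p for p in state.patients if p.active]
    return len(leaving)


def admit_patients(
    state: WardState,
    pd1: EmpiricalDistribution,
    pd2: EmpiricalDistribution,
    pd3: EmpiricalDistribution,
    model,
    rng: np.random.Generator,
) -> list[Patient]:
    """Admit today's arrivals; returns the newly created patients.

    The number of arrivals is drawn from pd1 conditioned on the current
    vacancy and truncated at it (a hard bed constraint).  A vacancy never
    observed in the estimation log falls back to the nearest smaller
    observed vacancy; the substitution is recorded in ``state.notes``.
    """
    vacancy = state.vacancy
    if vacancy < 0:
        raise RuntimeError("bed capacity exceeded")
    if vacancy == 0:
        return []
    key = vacancy
    if not pd1.has_key(key):
        fallback = pd1.nearest_smaller_key(vacancy)
        if fallback is None:
            state.notes.append(f"day {state.day}: no pd1 key <= {vacancy}; 0 admissions")
            return []
        state.notes.append(f"day {state.day}: pd1 vacancy {vacancy} unseen, using {fallback}")
        key = fallback
    n = min(int(pd1.sample(rng, key=key)), vacancy)
    admitted = []
    for _ in range(n):
        cls = pd2.sample(rng)
        los = int(pd3.sample(rng, key=cls))
        patient = Patient(id=state.next_patient_id, cls=cls,
                          admission_day=state.day, los=los)
        state.next_patient_id += 1
        model.on_admit(patient, rng)
        state.patients.append(patient)
        admitted.append(patient)
    return admitted


def daily_ward_demand(state: WardState) -> dict[str, int]:
    """Sum the patients' current prescriptions into the ward's daily demand."""
    demand: dict[str, int] = {}
    for p in state.patients:
        for f, d in p.prescription.items():
            demand[f] = demand.get(f, 0) + d
    return demand


def step_ward_day(
    state: WardState,
    dists: Mapping[str, EmpiricalDistribution],
    model,
    rng: np.random.Generator,
) -> dict[str, int]:
    """One ward day: discharges, admissions, therapy evolution; returns demand.

    ``dists`` must contain pd1, pd2, pd3.  ``state.day`` is advanced by one.
    """
    discharge_due(state)
    admit_patients(state, dists["pd1"], dists["pd2"], dists["pd3"], model, rng)
    for p in state.patients:
        model.step(p, rng)
    demand = daily_ward_demand(state)
    state.day += 1
    return demand


# ---------------------------------------------------------------------------
# Forecasters


def forecast_demand(
    state: WardState,
    n_days: int,
    dists: Mapping[str, EmpiricalDistribution],
    model,
    drug_ids: Sequence[str],
    rng: np.random.Generator,
) -> DemandMatrix:
    """One-shot therapy-driven forecast over a planning period.

    Runs the full admission + evolution process forward ``n_days`` days on a
    private copy of the ward; the input state is not mutated.
    """
    if n_days % 7:
        raise ValueError("forecast length must be a multiple of 7")
    shadow = state.copy()
    out = np.zeros((len(drug_ids), n_days), dtype=np.int64)
    index = {f: i for i, f in enumerate(drug_ids)}
    for t in range(n_days):
        demand = step_ward_day(shadow, dists, model, rng)
        for f, d in demand.items():
            out[index[f], t] = d
    return DemandMatrix(list(drug_ids), out)


def forecast_demand_poisson(
    rates: PoissonRates,
    n_days: int,
    drug_ids: Sequence[str],
    rng: np.random.Generator,
) -> DemandMatrix:
    """Drug-driven competitor: independent Poisson(lambda_f) draws per day."""
    lam = np.array([rates[f] for f in drug_ids], dtype=float)
    values = rng.poisson(lam[:, None], size=(len(lam), n_days))
    return DemandMatrix(list(drug_ids), values)
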