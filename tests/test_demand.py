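import numpy as np
import pytest

from wardstock.demand import (
    MarkovTherapyModel,
    Patient,
    TherapyNode,
    TherapyTree,
    TreeTherapyModel,
    WardState,
    admit_patients,
    daily_ward_demand,
    discharge_due,
    forecast_demand,
    forecast_demand_poisson,
    step_ward_day,
)
from wardstock.distributions import EmpiricalDistribution, PoissonRates


def _degenerate_dists(n_admit=2, cls="A", los=3, beds=8):
    return {
        "pd1": EmpiricalDistribution({v: {n_admit if v >= n_admit else 0: 1.0}
                                      for v in range(beds + 1)}),
        "pd2": EmpiricalDistribution({cls: 1.0}),
        "pd3": EmpiricalDistribution({cls: {los: 1.0}}),
    }


def _linear_model(cls="A", treatment=None):
    node = TherapyNode("stay", treatment or {"f1": 4})
    return TreeTherapyModel({cls: TherapyTree(cls, node, death_prob=0.0)})


class TestAdmissions:
    def test_zero_vacancy_admits_nobody(self, rng):
        dists = _degenerate_dists()
        state = WardState(day=0, beds=2)
        state.patients = [Patient(0, "A", 0, 9), Patient(1, "A", 0, 9)]
        admitted = admit_patients(state, dists["pd1"], dists["pd2"], dists["pd3"],
                                  _linear_model(), rng)
        assert admitted == []

    def test_degenerate_chain_gives_exact_patients(self, rng):
        dists = _degenerate_dists(n_admit=2, cls="A", los=3)
        state = WardState(day=0, beds=8)
        admitted = admit_patients(state, dists["pd1"], dists["pd2"], dists["pd3"],
                                  _linear_model(), rng)
        assert len(admitted) == 2
        assert all(p.cls == "A" and p.los == 3 for p in admitted)

    def test_unseen_vacancy_falls_back_to_nearest_smaller(self, rng):
        pd1 = EmpiricalDistribution({2: {1: 1.0}})  # only vacancy 2 observed
        dists = _degenerate_dists()
        state = WardState(day=0, beds=8)
        admitted = admit_patients(state, pd1, dists["pd2"], dists["pd3"],
                                  _linear_model(), rng)
        assert len(admitted) == 1
        assert any("unseen" in note for note in state.notes)

    def test_seeded_admissions_reproducible(self):
        dists = _degenerate_dists()
        runs = []
        for _ in range(2):
            state = WardState(day=0, beds=8)
            r = np.random.default_rng(7)
            admit_patients(state, dists["pd1"], dists["pd2"], dists["pd3"],
                           _linear_model(), r)
            runs.append([(p.id, p.cls, p.los) for p in state.patients])
        assert runs[0] == runs[1]


class TestEvolution:
    def test_linear_path_prescribes_every_day(self, rng):
        model = _linear_model(treatment={"f1": 4})
        p = Patient(0, "A", 0, 3)
        model.on_admit(p, rng)
        for _ in range(3):
            assert model.step(p, rng) == {"f1": 4}
        assert not p.active
        with pytest.raises(ValueError):
            model.step(p, rng)

    def test_deterministic_branch(self, rng):
        a = TherapyNode("a", {"f1": 1})
        b = TherapyNode("b", {"f2": 2})
        root = TherapyNode("root", {"f0": 1}, duration=1,
                           children=[(0.0, a), (1.0, b)])
        model = TreeTherapyModel({"A": TherapyTree("A", root)})
        p = Patient(0, "A", 0, 3)
        model.on_admit(p, rng)
        assert model.step(p, rng) == {"f0": 1}
        assert model.step(p, rng) == {"f2": 2}

    def test_branch_frequencies_match_probabilities(self):
        """Over many seeded traversals of a 2-branch node with p=0.3 the
        empirical branch frequency is within 3 sigma of 0.3."""
        a = TherapyNode("a", {"f1": 1})
        b = TherapyNode("b", {"f2": 1})
        root = TherapyNode("root", {}, duration=1, children=[(0.3, a), (0.7, b)])
        model = TreeTherapyModel({"A": TherapyTree("A", root)})
        rng = np.random.default_rng(5)
        n = 100_000
        hits = 0
        for _ in range(n):
            p = Patient(0, "A", 0, 2)
            model.on_admit(p, rng)
            model.step(p, rng)
            model.step(p, rng)
            hits += p.node.name == "a"
        sigma = np.sqrt(0.3 * 0.7 / n)
        assert abs(hits / n - 0.3) < 3 * sigma

    def test_branch_probabilities_must_sum_to_one(self):
        bad = TherapyNode("root", {}, duration=1,
                          children=[(0.5, TherapyNode("a"))])
        with pytest.raises(ValueError, match="sum"):
            TreeTherapyModel({"A": TherapyTree("A", bad)})


class TestDailyDemand:
    def test_empty_ward_zero_demand(self):
        assert daily_ward_demand(WardState(day=0, beds=8)) == {}

    def test_sum_of_prescriptions(self):
        state = WardState(day=0, beds=8)
        p1 = Patient(0, "A", 0, 3, prescription={"f1": 4})
        p2 = Patient(1, "A", 0, 3, prescription={"f1": 4, "f2": 1})
        state.patients = [p1, p2]
        assert daily_ward_demand(state) == {"f1": 8, "f2": 1}

    def test_mixed_therapies_equal_per_patient_enumeration(self, rng):
        dists = _degenerate_dists(n_admit=3, los=5)
        model = _linear_model()
        state = WardState(day=0, beds=8)
        step_ward_day(state, dists, model, rng)
        total = daily_ward_demand(state)
        brute = {}
        for p in state.patients:
            for f, d in p.prescription.items():
                brute[f] = brute.get(f, 0) + d
        assert total == brute


class TestForecast:
    def test_zero_admissions_zero_matrix(self, rng):
        dists = _degenerate_dists(n_admit=0)
        q = forecast_demand(WardState(day=0, beds=8), 14, dists, _linear_model(),
                            ["f1"], rng)
        assert not q.values.any()

    def test_rejects_non_week_multiple(self, rng):
        with pytest.raises(ValueError):
            forecast_demand(WardState(day=0, beds=8), 10, _degenerate_dists(),
                            _linear_model(), ["f1"], rng)

    def test_degenerate_world_matches_hand_rolled_trajectory(self, rng):
        """2 admissions/day, LoS 3, each prescribing 4 doses of f1: the ward
        fills to 6 patients then plateaus (2 leave, 2 arrive each day) ->
        demand 8,16,24,24,24,..."""
        dists = _degenerate_dists(n_admit=2, los=3, beds=8)
        q = forecast_demand(WardState(day=0, beds=8), 7, dists, _linear_model(),
                            ["f1"], np.random.default_rng(0))
        assert list(q.values[0][:4]) == [8, 16, 24, 24]
        assert all(v == 24 for v in q.values[0][3:])

    def test_forecast_does_not_mutate_ward(self, rng):
        dists = _degenerate_dists()
        state = WardState(day=0, beds=8)
        forecast_demand(state, 14, dists, _linear_model(), ["f1"], rng)
        assert state.day == 0 and state.patients == []

    def test_same_seed_identical_matrices(self, classes, therapy_model, catalog):
        dists = classes.dists()
        out = []
        for _ in range(2):
            q = forecast_demand(WardState(day=0, beds=8), 28, dists, therapy_model,
                                catalog.drug_ids, np.random.default_rng(11))
            out.append(q)
        assert out[0] == out[1]

    def test_forecast_equals_simulation_under_degenerate_rules(self, rng):
        """Forecast mode and day-by-day mode follow the same decision rules:
        with all distributions degenerate they produce identical demand."""
        dists = _degenerate_dists(n_admit=1, los=4)
        model = _linear_model()
        q = forecast_demand(WardState(day=0, beds=8), 14, dists, model,
                            ["f1"], np.random.default_rng(3))
        state = WardState(day=0, beds=8)
        r2 = np.random.default_rng(99)
        days = [step_ward_day(state, dists, model, r2).get("f1", 0) for _ in range(14)]
        assert list(q.values[0]) == days


class TestPoissonForecast:
    def test_zero_rate_zero_matrix(self, rng):
        q = forecast_demand_poisson(PoissonRates({"f1": 0.0}), 28, ["f1"], rng)
        assert not q.values.any()

    def test_sample_mean_matches_rate(self):
        rng = np.random.default_rng(2)
        lam = 3.0
        q = forecast_demand_poisson(PoissonRates({"f1": lam}), 10_000, ["f1"], rng)
        sigma = np.sqrt(lam / 10_000)
        assert abs(q.values.mean() - lam) < 3 * sigma

    def test_same_seed_identical(self):
        rates = PoissonRates({"f1": 2.0, "f2": 0.5})
        a = forecast_demand_poisson(rates, 28, ["f1", "f2"], np.random.default_rng(4))
        b = forecast_demand_poisson(rates, 28, ["f1", "f2"], np.random.default_rng(4))
        assert a == b


class TestWardInvariants:
    def test_occupancy_recursion_and_bed_cap(self, classes, therapy_model):
        """Occupancy follows bol_t = bol_{t-1} - out_t + in_t and the bed
        capacity is never exceeded, across seeds."""
        dists = classes.dists()
        for seed in range(5):
            rng = np.random.default_rng(seed)
            state = WardState(day=0, beds=8)
            occ_prev = 0
            for _ in range(364):
                before = {p.id for p in state.patients}
                discharge_due(state)
                out = len(before) - len(state.patients)
                admit_patients(state, dists["pd1"], dists["pd2"], dists["pd3"],
                               therapy_model, rng)
                inflow = len({p.id for p in state.patients} - before)
                for p in state.patients:
                    therapy_model.step(p, rng)
                assert len(state.patients) == occ_prev - out + inflow
                assert len(state.patients) <= 8
                occ_prev = len(state.patients)
                state.day += 1


def test_markov_model_continuation_dynamics():
    """Drugs persist day-over-day per the continuation probability and are
    prescribed at their posology."""
    model = MarkovTherapyModel(
        start_prob={"A": {"f1": 1.0, "f2": 0.0}},
        continue_prob={"A": {"f1": 1.0, "f2": 1.0}},
        posologies={"f1": 4, "f2": 2},
    )
    rng = np.random.default_rng(0)
    p = Patient(0, "A", 0, 5)
    model.on_admit(p, rng)
    for _ in range(5):
        assert model.step(p, rng) == {"f1": 4}  # f2 never starts
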