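import numpy as np
import pytest

from tests._oracles import (
    enumerate_milp_objective,
    milp_oracle_match_rate,
    random_small_instance,
)
from wardstock.domain import Catalog, DemandMatrix, Drug, DrugGroup
from wardstock.optimizer import (
    MILPInstance,
    build_milp,
    compute_first_day_rush,
    compute_upsilon_bar,
    extract_push_agenda,
    solve_milp,
)


@pytest.mark.parametrize(
    "q,ss,l,U,expected",
    [
        (10, 2, 0, 4, 3),
        (5, 3, 10, 4, 0),   # stock already covers demand + floor
        (1, 0, 0, 25, 1),
        (8, 0, 8, 4, 0),
        (9, 0, 8, 4, 1),
    ],
)
def test_first_day_rush_ceiling(q, ss, l, U, expected):
    assert compute_first_day_rush(q, ss, l, U) == expected


def test_first_day_rush_rejects_bad_inputs():
    with pytest.raises(ValueError):
        compute_first_day_rush(1, 0, 0, 0)
    with pytest.raises(ValueError):
        compute_first_day_rush(-1, 0, 0, 4)


@pytest.mark.parametrize(
    "spreads,t_l,expected",
    [
        ([(3, 0), (3, 0), (3, 0)], 1, 2),
        ([(0, 0)], 0, 0),
        ([(2, 0), (5, 0)], 2, 2),   # ceil(3.5)=4, minus 2
        ([(1, 0)], 5, 0),           # floored at zero
    ],
)
def test_upsilon_bar_from_training_spreads(spreads, t_l, expected):
    assert compute_upsilon_bar(spreads, t_l=t_l) == expected


def test_upsilon_bar_rejects_empty_training_set():
    with pytest.raises(ValueError):
        compute_upsilon_bar([])


def _one_drug_instance(q=None, l=6, ss=0, T=7, U=3, budget=50.0):
    drug = Drug(id="f0", doses_per_box=U, cost_per_dose=1.0, box_volume=1,
                dedicated_capacity=2, shared_capacity=1, group_id="g0",
                daily_posology=1)
    cat = Catalog([drug], [DrugGroup("g0", ["f0"], 5)])
    demand = np.zeros((1, T), dtype=int) if q is None else np.asarray(q).reshape(1, T)
    return MILPInstance(
        catalog=cat, demand=DemandMatrix(["f0"], demand),
        initial_stock={"f0": l}, safety_stock={"f0": ss},
        daily_budget=budget, rush_cost=30.0, upsilon_bar=1,
        hierarchy_weight=100.0,
    )


class TestModelShape:
    def test_variable_and_constraint_counts_one_drug_one_week(self):
        """Counts follow the printed index sets for |F|=1, |D|=7, |W|=1."""
        model = build_milp(_one_drug_instance())
        F, T = 1, 7
        # s,y,nu,x,alpha,beta,gamma per (f,t) + ups per t + nub,rho per f
        # + upsmax, upsmin, eps
        assert model.n_vars == 7 * F * T + T + 2 * F + 3
        sizes = {name: c.A.shape[0] for name, c in model.blocks.items()}
        assert sizes["flow"] == F * T
        # (5),(7),(8),(9),(11),(12) per (f,t) + (6) per (g,t)
        assert sizes["storage"] == 6 * F * T + 1 * T
        assert sizes["budget"] == T + 1          # (14) every day + (13) day 0
        assert sizes["lot"] == 3 * F * T          # (17),(18),(19)
        assert sizes["events"] == F * T + 2 * T + 1  # (20),(21),(22),(23)

    def test_saturday_event_variable_fixed_to_zero(self):
        model = build_milp(_one_drug_instance())
        assert model.ub[model.var("ups", 6)] == 0  # day 6 is Saturday
        assert model.ub[model.var("ups", 5)] == 1

    def test_dimension_mismatch_rejected(self):
        inst = _one_drug_instance()
        with pytest.raises(ValueError):
            MILPInstance(
                catalog=inst.catalog,
                demand=DemandMatrix(["f0"], np.zeros((1, 10), dtype=int)),
                initial_stock={"f0": 0}, safety_stock={"f0": 0},
                daily_budget=10.0, rush_cost=30.0,
            )


class TestSolve:
    def test_zero_demand_no_orders(self):
        inst = _one_drug_instance(l=6, ss=0)
        sol = solve_milp(build_milp(inst), mode="weighted", gap=1e-9)
        assert sol.status == "optimal"
        assert not sol.orders.any()
        assert sol.eps == pytest.approx(0.0)
        # objective reduces to the stock-value term: 7 days * 6 doses / B
        assert sol.objective == pytest.approx(7 * 6 / 50.0)

    def test_capacity_exceeding_demand_infeasible(self):
        # daily receipts are capped at 3 boxes * 3 doses = 9 < demand 10,
        # so stock must eventually go negative
        inst = _one_drug_instance(q=[10, 10, 10, 10, 10, 10, 10], l=9)
        sol = solve_milp(build_milp(inst), mode="weighted")
        assert sol.status == "infeasible"

    def test_first_day_shortfall_triggers_urgent(self):
        inst = _one_drug_instance(q=[5, 0, 0, 0, 0, 0, 0], l=0, ss=1)
        sol = solve_milp(build_milp(inst), mode="weighted", gap=1e-9)
        assert sol.status == "optimal"
        assert sol.urgent_flags[0] == 1
        assert sol.urgent_boxes[0] == 2  # ceil((5+1-0)/3)
        assert sol.stock[0, 0] >= 1

    def test_oracle_equivalence_on_random_small_instances(self):
        """Solver weighted objective equals brute-force enumeration over
        order-day subsets and lot sizes on 25 random instances."""
        assert milp_oracle_match_rate(seed=42, n_instances=25) == 1.0


@pytest.fixture(scope="module")
def solved():
    rng = np.random.default_rng(77)
    out = []
    for k in range(6):
        inst = random_small_instance(rng, two_drugs=(k % 2 == 0))
        sol = solve_milp(build_milp(inst), mode="weighted", gap=1e-9)
        if sol.status == "optimal":
            out.append((inst, sol))
    assert out
    return out


class TestSolutionInvariants:
    def test_lot_size_regularity(self, solved):
        """All positive order quantities of a drug equal its lot size."""
        for inst, sol in solved:
            for fi in range(len(inst.catalog)):
                positive = sol.orders[fi][sol.orders[fi] > 0]
                assert all(v == sol.lot_sizes[fi] for v in positive)

    def test_homogeneity_spread_bounded(self, solved):
        for inst, sol in solved:
            counts = sol.order_flags.sum(axis=0)
            days = counts[sol.event_flags > 0]
            if days.size:
                assert days.max() - days.min() <= inst.upsilon_bar

    def test_no_saturday_order_no_sunday_receipt(self, solved):
        for inst, sol in solved:
            for t in range(inst.n_days):
                if inst.weekday(t) == 6:
                    assert sol.event_flags[t] == 0
                    assert not sol.orders[:, t].any()

    def test_safety_floor_and_storage_split(self, solved):
        from wardstock.domain import InventoryState, validate_inventory

        for inst, sol in solved:
            cat = inst.catalog
            for fi, f in enumerate(cat.drug_ids):
                assert (sol.stock[fi] >= inst.safety_stock.get(f, 0) - 1e-6).all()
            for t in range(inst.n_days):
                doses = {f: int(round(sol.stock[fi, t]))
                         for fi, f in enumerate(cat.drug_ids)}
                state = InventoryState(
                    doses,
                    {f: int(sol.dedicated_boxes[fi, t]) for fi, f in enumerate(cat.drug_ids)},
                    {f: int(sol.shared_boxes[fi, t]) for fi, f in enumerate(cat.drug_ids)},
                )
                assert validate_inventory(state, cat) == []


class TestLexicographic:
    def test_budget_violation_never_traded_for_fewer_events(self):
        """A forced trade-off: holding enough stock through the weekend
        either violates the budget (one big Friday order) or needs an extra
        order day.  The lexicographic mode must keep eps at its minimum and
        pay the extra event; a weighted mode with a large M does the
        opposite."""
        drug = Drug(id="f0", doses_per_box=2, cost_per_dose=10.0, box_volume=1,
                    dedicated_capacity=3, shared_capacity=0, group_id="g0",
                    daily_posology=1)
        cat = Catalog([drug], [DrugGroup("g0", ["f0"], 0)])
        q = np.array([[0, 0, 2, 2, 2, 2, 0, 2, 0, 0, 0, 0, 0, 0]])
        inst = MILPInstance(
            catalog=cat, demand=DemandMatrix(["f0"], q),
            initial_stock={"f0": 2}, safety_stock={"f0": 0},
            daily_budget=40.0, rush_cost=300.0, upsilon_bar=1,
            hierarchy_weight=100_000.0,
        )
        lex = solve_milp(build_milp(inst), mode="lexicographic", gap=1e-9)
        weighted = solve_milp(build_milp(inst), mode="weighted", gap=1e-9)
        assert lex.criteria["eps"] <= weighted.criteria["eps"] + 1e-9
        assert lex.criteria["eps"] == pytest.approx(0.0, abs=1e-6)

    def test_lexicographic_stages_are_monotone(self):
        rng = np.random.default_rng(3)
        inst = random_small_instance(rng, two_drugs=True)
        lex = solve_milp(build_milp(inst), mode="lexicographic", gap=1e-9)
        weighted = solve_milp(build_milp(inst), mode="weighted", gap=1e-9)
        if lex.status == weighted.status == "optimal":
            assert lex.criteria["eps"] <= weighted.criteria["eps"] + 1e-6


class TestAgenda:
    def _solution(self):
        inst = _one_drug_instance(q=[0, 2, 2, 2, 2, 2, 0], l=4, ss=0)
        model = build_milp(inst)
        sol = solve_milp(model, mode="weighted", gap=1e-9)
        assert sol.status == "optimal"
        return model, sol

    def test_full_horizon_keeps_all_orders(self):
        model, sol = self._solution()
        agenda = extract_push_agenda(sol, model, scheduling_length=7)
        days = {o.day for o in agenda}
        assert days == {t for t in range(7) if sol.orders[0, t] > 0}

    def test_short_window_filters_orders(self):
        model, sol = self._solution()
        full = extract_push_agenda(sol, model, scheduling_length=7)
        short = extract_push_agenda(sol, model, scheduling_length=2)
        assert [o.day for o in short] == [o.day for o in full if o.day < 2]

    def test_offset_applies_period_start(self):
        model, sol = self._solution()
        agenda = extract_push_agenda(sol, model, scheduling_length=7, period_start=21)
        assert all(21 <= o.day < 28 for o in agenda)


def test_instance_serialization_roundtrip():
    inst = _one_drug_instance(q=[0, 2, 0, 2, 0, 0, 0], l=4, ss=1)
    back = MILPInstance.from_dict(inst.to_dict())
    assert back.catalog == inst.catalog
    assert back.demand == inst.demand
    assert back.initial_stock == dict(inst.initial_stock)
    assert back.upsilon_bar == inst.upsilon_bar


def test_agenda_frame_lists_one_row_per_line():
    from wardstock.optimizer import agenda_to_frame
    from wardstock.domain import Order

    agenda = [
        Order(kind="push", day=2, lines={"f1": 2, "f0": 1}),
        Order(kind="push", day=4, lines={"f0": 1}),
    ]
    frame = agenda_to_frame(agenda)
    assert list(frame["day"]) == [2, 2, 4]
    assert list(frame["drug"]) == ["f0", "f1", "f0"]
    assert list(frame["boxes"]) == [1, 2, 1]
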