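import math

import numpy as np
import pytest

from taktclinic.clinic_model import (ClinicConfig, Department, Pathway,
                                     ServiceModel)
from taktclinic.demand import ArrivalStream, forecast_demand, ArrivalProfile
from taktclinic.takt_planner import (PlanningError, ResourcePlan,
                                     build_resource_plan, build_static_plan,
                                     compute_takt, replan, required_resources)


def make_clinic(departments, pathways, n_slots=16, L=30.0):
    return ClinicConfig(tuple(departments), tuple(pathways),
                        0.0, n_slots * L, L)


def constant_forecast(clinic, demand):
    prof = ArrivalProfile(base_rates=(float(demand),) * clinic.n_slots)
    return forecast_demand(ArrivalStream(()), prof, clinic, 0.0,
                           method="profile")


@pytest.fixture
def one_dept_clinic():
    d = Department("D", ServiceModel("deterministic", 6.0),
                   min_resources=0, max_resources=99)
    return make_clinic([d], [Pathway("w", ("D",), 1.0)])


class TestComputeTakt:
    @pytest.mark.parametrize("L,D,expected", [
        (60.0, 60.0, 1.0), (30.0, 10.0, 3.0), (30.0, 60.0, 0.5)])
    def test_takt_is_available_time_over_demand(self, L, D, expected):
        t = compute_takt(L, D)
        assert t.takt == expected and not t.no_demand

    def test_zero_demand_yields_no_demand_sentinel(self):
        assert compute_takt(30.0, 0.0).no_demand

    @pytest.mark.parametrize("L,D", [(30.0, -1.0), (0.0, 5.0), (-5.0, 5.0)])
    def test_invalid_inputs_rejected(self, L, D):
        with pytest.raises(PlanningError):
            compute_takt(L, D)


class TestRequiredResources:
    @pytest.mark.parametrize("p,takt,mn,mx,expected", [
        (9.0, 3.0, 0, 99, 3),   # exact division
        (10.0, 3.0, 1, 99, 4),  # ceiling
        (10.0, 3.0, 1, 3, 3),   # capacity clip
        (1.0, 3.0, 2, 9, 2),    # floor staffing binds
    ])
    def test_worked_values(self, p, takt, mn, mx, expected):
        t = compute_takt(30.0, 30.0 / takt)
        assert required_resources(p, t, mn, mx) == expected

    def test_no_demand_gives_min_staffing(self):
        assert required_resources(10.0, compute_takt(30.0, 0.0), 2, 9) == 2

    def test_monotone_in_demand_and_process_time(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            L = rng.uniform(5, 120)
            D = rng.uniform(0.1, 80)
            p = rng.uniform(0.5, 30)
            t = compute_takt(L, D)
            n = required_resources(p, t, 0, 10 ** 6)
            assert (required_resources(p, compute_takt(L, D * 1.25), 0, 10 ** 6)
                    >= n)
            assert required_resources(p * 1.25, t, 0, 10 ** 6) >= n

    def test_work_conservation_bound(self):
        # before clipping: allocated capacity covers expected workload
        rng = np.random.default_rng(1)
        for _ in range(1000):
            L = rng.uniform(5, 120)
            D = rng.uniform(0.1, 80)
            p = rng.uniform(0.5, 30)
            n = required_resources(p, compute_takt(L, D), 0, 10 ** 9)
            assert n * L >= p * D - 1e-6


class TestBuildPlan:
    def test_uniform_demand_arithmetic(self, one_dept_clinic):
        fc = constant_forecast(one_dept_clinic, 10.0)
        plan = build_resource_plan(fc, one_dept_clinic)
        assert (plan.counts == 2).all()  # ceil(6*10/30) = 2
        assert plan.provenance == "predictive"

    def test_class_mix_weighting_halves_department_demand(self):
        a = Department("A", ServiceModel("deterministic", 6.0),
                       max_resources=99)
        b = Department("B", ServiceModel("deterministic", 6.0),
                       max_resources=99)
        clinic = make_clinic(
            [a, b],
            [Pathway("pa", ("A",), 0.5), Pathway("pb", ("B",), 0.5)])
        plan = build_resource_plan(constant_forecast(clinic, 10.0), clinic)
        # each department sees D = 5 -> ceil(6*5/30) = 1
        assert (plan.counts == 1).all()

    def test_zero_forecast_floors_at_min_resources(self):
        d = Department("D", ServiceModel("deterministic", 6.0),
                       min_resources=3, max_resources=9)
        clinic = make_clinic([d], [Pathway("w", ("D",), 1.0)])
        plan = build_resource_plan(constant_forecast(clinic, 0.0), clinic)
        assert (plan.counts == 3).all()

    def test_partial_forecast_rejected(self, one_dept_clinic):
        prof = ArrivalProfile(base_rates=(5.0,) * 16)
        fc = forecast_demand(ArrivalStream(()), prof, one_dept_clinic, 60.0,
                             method="profile")
        with pytest.raises(PlanningError):
            build_resource_plan(fc, one_dept_clinic)


class TestStaticPlan:
    def test_four_times_seven_totals_28(self):
        depts = [Department(f"D{i}", ServiceModel("exponential", 5.0),
                            max_resources=10) for i in range(4)]
        clinic = make_clinic(depts, [Pathway("w", tuple(d.id for d in depts),
                                             1.0)])
        plan = build_static_plan(clinic, {d.id: 7 for d in depts})
        assert plan.counts.shape == (16, 4)
        assert (plan.total_per_slot() == 28).all()
        assert plan.provenance == "static"

    def test_out_of_bounds_count_rejected(self, one_dept_clinic):
        with pytest.raises(PlanningError):
            build_static_plan(one_dept_clinic, {"D": 100})

    def test_floor_staffing_is_valid(self):
        d = Department("D", ServiceModel("exponential", 5.0),
                       min_resources=2, max_resources=9)
        clinic = make_clinic([d], [Pathway("w", ("D",), 1.0)])
        plan = build_static_plan(clinic, {"D": 2})
        assert (plan.counts == 2).all()


class TestReplan:
    def test_zero_reaction_at_open_matches_fresh_build(self, one_dept_clinic):
        fc = constant_forecast(one_dept_clinic, 10.0)
        current = build_static_plan(one_dept_clinic, {"D": 5})
        new = replan(current, fc, 0.0, 0.0, one_dept_clinic)
        assert new == build_resource_plan(fc, one_dept_clinic)

    def test_reaction_beyond_day_freezes_everything(self, one_dept_clinic):
        fc = constant_forecast(one_dept_clinic, 10.0)
        current = build_static_plan(one_dept_clinic, {"D": 5})
        new = replan(current, fc, one_dept_clinic.day_length + 1, 0.0,
                     one_dept_clinic)
        assert (new.counts == current.counts).all()
        assert (new.effective_from == current.effective_from).all()

    def test_freeze_boundary_worked_example(self, one_dept_clinic):
        # now=60, reaction=45: cutoff 105 falls inside slot [90,120), so
        # slots starting at 60 and 90 stay frozen; slot 120 is recomputed.
        current = build_static_plan(one_dept_clinic, {"D": 5})
        fc = constant_forecast(one_dept_clinic, 10.0)
        new = replan(current, fc, 45.0, 60.0, one_dept_clinic)
        assert new.counts[2, 0] == 5 and new.counts[3, 0] == 5
        assert new.counts[4, 0] == 2  # ceil(6*10/30)
        assert new.effective_from[4, 0] == 120.0

    def test_static_degeneracy(self, one_dept_clinic):
        # constant forecast whose implied counts equal the static counts
        fc = constant_forecast(one_dept_clinic, 10.0)  # -> 2 everywhere
        static = build_static_plan(one_dept_clinic, {"D": 2})
        predictive = build_resource_plan(fc, one_dept_clinic)
        assert (predictive.counts == static.counts).all()
        assert (predictive.effective_from == static.effective_from).all()


class TestPlanShapes:
    def test_peaked_demand_varies_while_static_constant(self, full_bundle):
        clinic, profile = full_bundle.clinic, full_bundle.profile
        fc = forecast_demand(ArrivalStream(()), profile, clinic, 0.0,
                             method="profile")
        predictive = build_resource_plan(fc, clinic)
        static = full_bundle.static_plan()
        assert predictive.total_per_slot().min() < predictive.total_per_slot().max()
        assert len(set(static.total_per_slot())) == 1

    def test_csv_roundtrip(self, full_bundle, tmp_path):
        plan = full_bundle.static_plan()
        path = tmp_path / "plan.csv"
        plan.to_csv(path)
        assert ResourcePlan.from_csv(path) == plan
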