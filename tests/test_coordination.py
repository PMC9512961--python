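"""Regional coordination: inflow signals, distribution policies, and the
closed-loop multi-hospital run."""

from __future__ import annotations

import pytest

from surgesim import (
    AmbulanceFleet,
    DistributionPolicy,
    StatusReport,
    TriageCategory,
    default_template,
    distribute,
    generate_scenario,
    inflow_signal,
    large_hospital,
)
from surgesim.coordination import run_region


def report(free, queued=0, accepting=True, hid=0):
    return StatusReport(
        t_min=60, hospital_id=hid, free_trauma_units=free,
        queued_red=queued, free_or=4, free_icu=2, accepting=accepting,
    )


class TestInflowSignal:
    def test_enough_free_units_keeps_accepting(self):
        assert inflow_signal(report(free=4), predicted_arrivals=3) is True

    def test_predicted_overload_with_none_freeing_stops_inflow(self):
        assert inflow_signal(report(free=1), predicted_arrivals=4,
                             freeing_within_lookahead=0) is False

    def test_units_freeing_within_lookahead_count_as_capacity(self):
        assert inflow_signal(report(free=1), predicted_arrivals=4,
                             freeing_within_lookahead=3) is True

    def test_closed_reopens_at_threshold(self):
        assert inflow_signal(report(free=2), predicted_arrivals=0,
                             reopen_threshold=2, currently_accepting=False) is True
        assert inflow_signal(report(free=1), predicted_arrivals=0,
                             reopen_threshold=2, currently_accepting=False) is False


class TestDistribute:
    def reds(self, n):
        return [(f"r{i}", TriageCategory.RED) for i in range(n)]

    def test_single_hospital_takes_everyone(self):
        policy = DistributionPolicy(kind="round-robin")
        assert distribute(self.reds(5), [report(2)], policy) == [0] * 5

    def test_round_robin_splits_evenly(self):
        policy = DistributionPolicy(kind="round-robin")
        out = distribute(self.reds(4), [report(2, hid=0), report(2, hid=1)], policy)
        assert sorted(out) == [0, 0, 1, 1]

    def test_all_red_to_centre_ignores_signals(self):
        policy = DistributionPolicy(kind="all-red-to-centre", centre=1)
        hospitals = [report(5, hid=0), report(0, accepting=False, hid=1)]
        assert distribute(self.reds(3), hospitals, policy) == [1, 1, 1]

    def test_predictive_prefers_accepting_hospital_with_most_free_units(self):
        policy = DistributionPolicy(kind="predictive-lookahead")
        hospitals = [report(1, hid=0), report(3, hid=1)]
        out = distribute(self.reds(4), hospitals, policy)
        assert out == [1, 1, 0, 1]  # internal free-count bookkeeping splits 1/3

    def test_non_red_round_robins_under_red_policies(self):
        policy = DistributionPolicy(kind="all-red-to-centre", centre=0)
        reqs = [("y1", TriageCategory.YELLOW), ("y2", TriageCategory.YELLOW)]
        assert distribute(reqs, [report(2, hid=0), report(2, hid=1)], policy) == [0, 1]

    def test_no_hospitals_is_an_error(self):
        with pytest.raises(ValueError):
            distribute(self.reds(1), [], DistributionPolicy(kind="round-robin"))


@pytest.fixture(scope="module")
def two_hospital_setup():
    template = default_template(n_hospitals=2, transport_time_min=(5, 5))
    fleet = AmbulanceFleet(
        n_ambulances=4, dispatch_delay_min=5, load_min=5, unload_min=0,
        transport_time_min=(5, 5),
    )
    hospitals = [large_hospital(), large_hospital()]
    return template, fleet, hospitals


class TestRegionRun:
    def test_lookahead_splits_reds_and_beats_centre_plan(self, two_hospital_setup):
        template, fleet, hospitals = two_hospital_setup
        scenario = generate_scenario(template, 240, 1)
        centre = DistributionPolicy(kind="all-red-to-centre", centre=0)
        look = DistributionPolicy(kind="predictive-lookahead", lookahead_min=30, reopen_threshold=2)
        rc = run_region(scenario, fleet, hospitals, centre, seed=1, horizon_min=1440)
        rl = run_region(scenario, fleet, hospitals, look, seed=1, horizon_min=1440)
        red_dest_centre = [a.hospital_id for a in rc.stream.arrivals
                           if a.category is TriageCategory.RED]
        red_dest_look = [a.hospital_id for a in rl.stream.arrivals
                         if a.category is TriageCategory.RED]
        assert set(red_dest_centre) == {0}
        assert set(red_dest_look) == {0, 1}
        assert rl.total_preventable < rc.total_preventable

    def test_region_conservation(self, two_hospital_setup):
        template, fleet, hospitals = two_hospital_setup
        scenario = generate_scenario(template, 120, 4)
        policy = DistributionPolicy(kind="predictive-lookahead")
        res = run_region(scenario, fleet, hospitals, policy, seed=4, horizon_min=1200)
        transported = [a.casualty_id for a in res.stream.arrivals]
        assert len(transported) == len(set(transported))
        n_dead_scene = len(scenario.by_category[TriageCategory.DEAD])
        assert len(transported) + n_dead_scene == scenario.n_total
        # Every transported casualty is admitted by exactly one hospital.
        admitted = [e.subject for log in res.logs for e in log.events if e.kind == "arrive"]
        assert sorted(admitted) == sorted(transported)

    def test_region_run_is_reproducible(self, two_hospital_setup):
        template, fleet, hospitals = two_hospital_setup
        scenario = generate_scenario(template, 100, 8)
        policy = DistributionPolicy(kind="predictive-lookahead")
        r1 = run_region(scenario, fleet, hospitals, policy, seed=8, horizon_min=1000)
        r2 = run_region(scenario, fleet, hospitals, policy, seed=8, horizon_min=1000)
        assert r1.logs[0] == r2.logs[0] and r1.logs[1] == r2.logs[1]
        assert [a for a in r1.stream.arrivals] == [a for a in r2.stream.arrivals]

    def test_signals_precede_saturation_on_deterministic_fixture(self, two_hospital_setup):
        """Under predictive lookahead with truthful short-horizon forecasts,
        no RED is routed to a hospital after a preventable ED lapse has
        already occurred there — the stop signal comes first."""
        template, fleet, hospitals = two_hospital_setup
        scenario = generate_scenario(template, 240, 2)
        policy = DistributionPolicy(kind="predictive-lookahead", lookahead_min=30, reopen_threshold=2)
        res = run_region(scenario, fleet, hospitals, policy, seed=2, horizon_min=1440)
        bank = scenario.bank()
        for hid, log in enumerate(res.logs):
            ed_lapses = [
                e.t for e in log.events
                if e.kind == "death" and e.station == "ED"
                and bank[e.subject].survivable_if_optimal and "wait=0" not in e.detail
            ]
            if not ed_lapses:
                continue
            first_lapse = min(ed_lapses)
            late_reds = [
                a for a in res.stream.arrivals
                if a.hospital_id == hid and a.category is TriageCategory.RED
                and a.arrival_min > first_lapse + fleet.transport_time_min[hid]
            ]
            assert not late_reds, (
                f"hospital {hid}: REDs still routed after an ED lapse at {first_lapse}"
            )
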