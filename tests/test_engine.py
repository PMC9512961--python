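"""Hospital engine: hand-traced queues, mobilization, CT, supplies,
conservation laws, and the engine-vs-brute-force oracle."""

from __future__ import annotations

import pytest

from surgesim import (
    Arrival,
    ArrivalStream,
    ConfigurationError,
    HospitalSim,
    Station,
    TriageCategory,
    consume_supplies,
    ct_visit,
    default_fleet,
    default_template,
    generate_scenario,
    large_hospital,
    mobilized,
    run,
    simulate_evacuation,
    simulate_time_stepped,
)

from conftest import AMPLE_ROSTER, make_red, single_unit_hospital


def stream_of(*pairs):
    """(minute, casualty) pairs -> ArrivalStream of REDs to hospital 0."""
    return ArrivalStream(arrivals=tuple(
        Arrival(t, c.id, 0, "ambulance", c.true_category) for t, c in pairs
    ))


class TestMobilization:
    def test_baseline_on_duty_at_time_zero(self, big_hospital):
        assert mobilized(big_hospital, "trauma_units", 0) == 2
        assert mobilized(big_hospital, "staff:doctor", 0, "office") == 8

    def test_non_office_staff_reach_maximum_30_to_60_min_after_alert(self, big_hospital):
        """Off-duty staff can be in the hospital within half to one hour of
        the alert under the shipped rosters."""
        alert = big_hospital.alert_min
        for cat in big_hospital.staff_roster:
            res = f"staff:{cat}"
            peak = big_hospital.staff_max(cat, "non-office")
            assert mobilized(big_hospital, res, alert + 29, "non-office") < peak
            assert mobilized(big_hospital, res, alert + 60, "non-office") == peak

    def test_office_profile_dominates_non_office_pointwise(self, big_hospital, small_hospital):
        for cfg in (big_hospital, small_hospital):
            for cat in cfg.staff_roster:
                for t in range(0, 200):
                    assert (
                        mobilized(cfg, f"staff:{cat}", t, "office")
                        >= mobilized(cfg, f"staff:{cat}", t, "non-office")
                    )

    def test_mobilization_is_non_decreasing(self, big_hospital):
        vals = [mobilized(big_hospital, "trauma_units", t) for t in range(0, 120)]
        assert vals == sorted(vals)
        assert max(vals) == big_hospital.n_trauma_units_max

    def test_or_theatres_cleared_after_alert(self, big_hospital):
        alert, clr = big_hospital.alert_min, big_hospital.or_clearance_min
        before = mobilized(big_hospital, "or_theatres", alert + clr - 1)
        after = mobilized(big_hospital, "or_theatres", alert + clr)
        assert before == big_hospital.n_or_theatres - big_hospital.or_initial_occupied
        assert after == big_hospital.n_or_theatres


class TestHandTraces:
    def test_empty_stream_only_alert_and_mobilization(self, big_hospital):
        log = run(big_hospital, ArrivalStream(), {}, seed=1, horizon_min=200)
        kinds = {e.kind for e in log.events}
        assert kinds == {"alert", "mobilize"}

    def test_single_red_served_immediately(self):
        """RED arriving at 15 with a free unit: treatment 15-35, no death."""
        c = make_red("r1", deadline=60, duration=20)
        log = run(single_unit_hospital(), stream_of((15, c)), {"r1": c}, seed=1, horizon_min=200)
        starts = [(e.t, e.kind) for e in log.events if e.kind == "treatment_start"]
        ends = [(e.t, e.kind) for e in log.events if e.kind == "treatment_end"]
        assert starts == [(15, "treatment_start")]
        assert ends == [(35, "treatment_end")]
        assert not log.of_kind("death")

    def test_second_red_dies_in_queue_at_deadline(self):
        """Single-server queue: the second casualty's 30-minute deadline
        lapses while the unit is still busy with the first."""
        a = make_red("r1", deadline=60, duration=20)
        b = make_red("r2", deadline=30, duration=20)
        bank = {"r1": a, "r2": b}
        log = run(single_unit_hospital(), stream_of((15, a), (16, b)), bank, seed=1, horizon_min=200)
        deaths = log.of_kind("death")
        assert [(e.t, e.subject, e.station) for e in deaths] == [(30, "r2", "ED")]

    def test_deadline_met_exactly_at_completion_is_survival(self):
        c = make_red("r1", deadline=35, duration=20)
        log = run(single_unit_hospital(), stream_of((15, c)), {"r1": c}, seed=1, horizon_min=100)
        assert not log.of_kind("death")
        assert [e.t for e in log.of_kind("treatment_end")] == [35]

    def test_arrival_after_deadline_dies_on_arrival(self):
        c = make_red("r1", deadline=10, duration=20, survivable=False)
        log = run(single_unit_hospital(), stream_of((15, c)), {"r1": c}, seed=1, horizon_min=100)
        deaths = log.of_kind("death")
        assert [(e.t, e.subject) for e in deaths] == [(15, "r1")]

    def test_unmobilizable_staff_demand_rejected_before_simulation(self):
        c = make_red("r1", deadline=60)
        big_demand = c.requirements[0].model_copy(update={"staff_demand": {"nurse": 500}})
        c = c.model_copy(update={"requirements": (big_demand,)})
        with pytest.raises(ConfigurationError, match="roster"):
            HospitalSim(single_unit_hospital(), {"r1": c})


class TestCT:
    def test_ct_in_ed_blocks_team_for_scan_only(self, big_hospital):
        cfg = big_hospital.model_copy(update={"ct_in_ed": True})
        assert ct_visit(cfg, 10) == 10

    def test_ct_outside_ed_adds_round_trip(self, big_hospital):
        cfg = big_hospital.model_copy(update={"ct_in_ed": False, "ct_transport_min": 10})
        assert ct_visit(cfg, 10) == 30

    def test_no_ct_requested_no_ct_events(self):
        c = make_red("r1", deadline=60)
        log = run(single_unit_hospital(), stream_of((15, c)), {"r1": c}, seed=1, horizon_min=100)
        assert not [e for e in log.events if e.station == "CT"]


class TestSupplies:
    def _run_n(self, n, stock):
        cfg = single_unit_hospital(
            n_trauma_units_max=5, trauma_unit_mobilization=((0, 5),),
            supplies={"kit": stock},
        )
        cas = {}
        arrivals = []
        for i in range(n):
            c = make_red(f"r{i}", deadline=None)
            req = c.requirements[0].model_copy(update={"consumables": {"kit": 1}})
            c = c.model_copy(update={"requirements": (req,)})
            cas[c.id] = c
            arrivals.append((15 + i, c))
        log = run(cfg, stream_of(*arrivals), cas, seed=1, horizon_min=300)
        return consume_supplies(log, cfg)

    def test_exact_exhaustion_no_stockout(self):
        usage, stockouts = self._run_n(5, stock=5)
        assert usage == {"kit": 5}
        assert stockouts == []

    def test_one_unit_short_one_stockout(self):
        usage, stockouts = self._run_n(5, stock=4)
        assert usage == {"kit": 5}
        assert len(stockouts) == 1
        assert stockouts[0]["item"] == "kit" and stockouts[0]["short_by"] == 1

    def test_no_consumables_empty_ledger(self):
        c = make_red("r1", deadline=None)
        cfg = single_unit_hospital()
        log = run(cfg, stream_of((15, c)), {"r1": c}, seed=1, horizon_min=100)
        usage, stockouts = consume_supplies(log, cfg)
        assert usage == {} and stockouts == []


def _mobilized_trauma_profile(cfg, log, horizon, profile="office"):
    """Reconstruct per-minute trauma-unit occupancy from the log."""
    busy = [0] * (horizon + 1)
    active = {}
    for e in log.events:
        if e.station != Station.ED.value:
            continue
        if e.kind == "seize" and "trauma_unit" in e.detail:
            active[e.subject] = e.t
        elif e.kind == "release" and e.detail == "resource=trauma_unit":
            t0 = active.pop(e.subject, None)
            if t0 is not None:
                for t in range(t0, e.t):
                    busy[t] += 1
    for cid, t0 in active.items():
        for t in range(t0, horizon + 1):
            busy[t] += 1
    return busy


_HORIZON = 1000


@pytest.fixture(scope="module")
def default_run():
    template, fleet = default_template(), default_fleet()
    scenario = generate_scenario(template, 150, 13)
    stream = simulate_evacuation(scenario, fleet, seed=13)
    log = run(large_hospital(), stream, scenario.bank(), seed=13, horizon_min=_HORIZON)
    return scenario, stream, log


class TestConservation:
    HORIZON = _HORIZON

    def test_seized_never_exceeds_mobilized(self, default_run):
        _, _, log = default_run
        cfg = large_hospital()
        busy = _mobilized_trauma_profile(cfg, log, self.HORIZON)
        for t in range(self.HORIZON + 1):
            assert busy[t] <= mobilized(cfg, "trauma_units", t, "office")

    def test_every_admitted_casualty_reaches_one_terminal_state(self, default_run):
        scenario, stream, log = default_run
        admitted = {e.subject for e in log.events if e.kind == "arrive"}
        deaths = {e.subject for e in log.events if e.kind == "death"}
        discharged = {e.subject for e in log.events if e.kind == "discharge"}
        assert not deaths & discharged
        # Whoever is neither dead nor discharged is still mid-plan (an
        # occupant at the horizon) with at least one event in the log.
        occupants = admitted - deaths - discharged
        for cid in occupants:
            assert any(e.subject == cid for e in log.events)
        assert admitted == deaths | discharged | occupants

    def test_work_conserving_red_queue(self):
        """A RED never waits while a mobilized trauma unit sits idle.  On a
        staff-ample configuration (so only units can bind), every minute a
        RED spends in the ED queue must show zero free mobilized units."""
        template, fleet = default_template(), default_fleet()
        scenario = generate_scenario(template, 150, 13)
        stream = simulate_evacuation(scenario, fleet, seed=13)
        cfg = large_hospital().model_copy(update={"staff_roster": AMPLE_ROSTER})
        log = run(cfg, stream, scenario.bank(), seed=13, horizon_min=self.HORIZON)
        busy = _mobilized_trauma_profile(cfg, log, self.HORIZON)
        cat, enters, starts = {}, {}, {}
        for e in log.events:
            if e.kind == "triage2":
                cat[e.subject] = e.detail.split("=", 1)[1]
            elif e.kind == "queue_enter" and e.station == "ED" and cat.get(e.subject) == "red":
                enters[e.subject] = e.t
            elif e.kind == "queue_exit" and e.station == "ED" and cat.get(e.subject) == "red":
                starts[e.subject] = e.t
        waited = 0
        for cid, t0 in enters.items():
            t1 = starts.get(cid)
            if t1 is None or t1 == t0:
                continue
            waited += 1
            for t in range(t0, t1):
                assert busy[t] >= mobilized(cfg, "trauma_units", t, "office"), (
                    f"{cid} waited at minute {t} with a free trauma unit"
                )
        assert waited > 0, "fixture must actually exercise queueing"


class TestOracleEquivalence:
    def test_engine_matches_brute_force_on_contended_fixture(self):
        """Event-driven engine and 1-minute time-stepped simulator produce
        the identical log on a contended single-server fixture."""
        cas = {f"r{i}": make_red(f"r{i}", deadline=40 + 17 * i) for i in range(5)}
        stream = stream_of(*((15 + 3 * i, c) for i, c in enumerate(cas.values())))
        cfg = single_unit_hospital()
        log_a = run(cfg, stream, cas, seed=0, horizon_min=400)
        log_b = simulate_time_stepped(cfg, stream, cas, seed=0, horizon_min=400)
        assert log_a == log_b

    def test_adding_a_trauma_unit_never_worsens_waits(self):
        """Paired-seed monotonicity: with one extra unit, every casualty's
        ED waiting time is no longer than before."""
        template, fleet = default_template(), default_fleet()
        scenario = generate_scenario(template, 100, 21)
        stream = simulate_evacuation(scenario, fleet, seed=21)
        bank = scenario.bank()

        def waits(cfg):
            log = run(cfg, stream, bank, seed=21, horizon_min=1000)
            out = {}
            for e in log.events:
                if e.kind == "queue_exit" and e.station == "ED":
                    out[e.subject] = int(e.detail.split("wait=", 1)[1])
            return out

        base = single_unit_hospital(
            n_trauma_units_max=2, trauma_unit_mobilization=((0, 2),),
            n_minor_treatment_slots=6, n_or_theatres=8, n_icu_beds=20, n_ct=2,
        )
        more = base.model_copy(update={
            "n_trauma_units_max": 3, "trauma_unit_mobilization": ((0, 3),),
        })
        w1, w2 = waits(base), waits(more)
        for cid, w in w2.items():
            if cid in w1:
                assert w <= w1[cid]
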