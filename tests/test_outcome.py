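"""Outcome scoring, load curves, and capacity determination."""

from __future__ import annotations

import pytest

from surgesim import (
    EventLog,
    default_fleet,
    default_template,
    determine_capacity,
    generate_scenario,
    large_hospital,
    load_curves,
    mobilized,
    run,
    score_outcomes,
    simulate_evacuation,
)
from surgesim.outcome import _component_deaths

from conftest import (
    make_red,
    single_ambulance_fleet,
    single_unit_hospital,
    uniform_red_template,
)
from test_engine import stream_of


class TestScoreOutcomes:
    def test_all_deadlines_met_zero_preventable(self):
        c = make_red("r1", deadline=90)
        log = run(single_unit_hospital(), stream_of((15, c)), {"r1": c}, seed=1, horizon_min=200)
        rep = score_outcomes(log, {"r1": c})
        assert rep.n_preventable == 0 and not rep.non_preventable_deaths
        assert rep.n_admitted == 1

    def test_queue_lapse_is_preventable_and_attributed_to_ed(self):
        a = make_red("r1", deadline=90, duration=20)
        b = make_red("r2", deadline=30, duration=20)
        bank = {"r1": a, "r2": b}
        log = run(single_unit_hospital(), stream_of((15, a), (16, b)), bank, seed=1, horizon_min=200)
        rep = score_outcomes(log, bank)
        assert [d.casualty_id for d in rep.preventable_deaths] == ["r2"]
        d = rep.preventable_deaths[0]
        assert d.station == "ED" and d.deadline_min == 30 and d.wait_min > 0

    def test_unsalvageable_death_is_non_preventable(self):
        # Deadline shorter than the treatment: optimal care cannot save them.
        c = make_red("r1", deadline=10, duration=20)
        assert not c.survivable_if_optimal
        log = run(single_unit_hospital(), stream_of((15, c)), {"r1": c}, seed=1, horizon_min=200)
        rep = score_outcomes(log, {"r1": c})
        assert rep.n_preventable == 0
        assert [d.casualty_id for d in rep.non_preventable_deaths] == ["r1"]

    def test_missed_soft_deadline_is_a_complication_not_a_death(self):
        c = make_red("r1", deadline=200, duration=20)
        req = c.requirements[0].model_copy(update={"complication_deadline_min": 30})
        c = c.model_copy(update={"requirements": (req,)})
        blocker = make_red("r0", deadline=None, duration=40)
        bank = {"r0": blocker, "r1": c}
        log = run(single_unit_hospital(), stream_of((10, blocker), (15, c)), bank,
                  seed=1, horizon_min=300)
        rep = score_outcomes(log, bank)
        assert not rep.preventable_deaths and not rep.non_preventable_deaths
        assert [(x.casualty_id, x.requirement) for x in rep.complications] == [("r1", "r1_treat")]

    def test_unknown_casualty_in_log_is_an_error(self):
        c = make_red("r1", deadline=10, duration=20)
        log = run(single_unit_hospital(), stream_of((15, c)), {"r1": c}, seed=1, horizon_min=100)
        with pytest.raises(KeyError):
            score_outcomes(log, {})


class TestLoadCurves:
    def test_empty_log_all_zero(self):
        curve = load_curves(EventLog(), bin_min=5, horizon_min=60)
        assert (curve.frame["value"] == 0).all()

    def test_single_treatment_occupies_exactly_its_interval(self):
        c = make_red("r1", deadline=90, duration=20)
        log = run(single_unit_hospital(), stream_of((15, c)), {"r1": c}, seed=1, horizon_min=100)
        curve = load_curves(log, bin_min=1, horizon_min=100)
        ed = curve.frame.query("station == 'ED' and metric == 'in_action' and category == 'all'")
        occupied = set(ed.loc[ed.value == 1, "t_bin"])
        assert occupied == set(range(15, 35))

    def test_trauma_team_conservation_identity(self):
        """in_action + at_disposal equals the mobilized team count in every bin."""
        template, fleet = default_template(), default_fleet()
        scenario = generate_scenario(template, 120, 3)
        stream = simulate_evacuation(scenario, fleet, seed=3)
        cfg = large_hospital()
        log = run(cfg, stream, scenario.bank(), seed=3, horizon_min=800)
        curve = load_curves(log, bin_min=5, hospital=cfg, bank=scenario.bank(), horizon_min=800)
        red = curve.frame.query("station == 'ED' and category == 'red'")
        by_metric = red.pivot_table(index="t_bin", columns="metric", values="value")
        for tb, row in by_metric.iterrows():
            assert row["in_action"] + row["at_disposal"] == mobilized(cfg, "trauma_units", int(tb), "office")

    def test_rejects_zero_bin(self):
        with pytest.raises(ValueError):
            load_curves(EventLog(), bin_min=0)


class TestCapacity:
    def test_unlimited_resources_capacity_is_upper_bound(self):
        cfg = single_unit_hospital(
            n_trauma_units_max=50, trauma_unit_mobilization=((0, 50),),
        )
        res = determine_capacity(cfg, uniform_red_template(deadline=400), single_ambulance_fleet(),
                                 search=(1, 12), seeds=(1,))
        assert res.capacity == 12

    def test_closed_form_single_server_capacity_is_three(self):
        """One unit, 20-min services, 75-min deadline, shuttle arrivals at
        15/30/45/...: completions at 35/55/75 fit, the fourth (would finish
        95) does not -> capacity 3, and bisection agrees with a hand sweep."""
        cfg = single_unit_hospital()
        template, fleet = uniform_red_template(deadline=75), single_ambulance_fleet()
        res = determine_capacity(cfg, template, fleet, search=(1, 6), seeds=(1,))
        assert res.capacity == 3
        # Independent exhaustive sweep.
        sweep = []
        for n in range(1, 7):
            sc = generate_scenario(template, n, 1)
            stream = simulate_evacuation(sc, fleet, seed=1)
            log = run(cfg, stream, sc.bank(), seed=1, horizon_min=400)
            sweep.append(score_outcomes(log, sc.bank()).n_preventable == 0)
        assert sweep == [True, True, True, False, False, False]

    def test_zero_capacity_returns_below_lower_bound(self):
        cfg = single_unit_hospital()
        res = determine_capacity(cfg, uniform_red_template(deadline=36), single_ambulance_fleet(),
                                 search=(2, 6), seeds=(1,))
        assert res.capacity == 1  # n_lo - 1: even two casualties overload

    def test_component_attribution_filters_deaths(self):
        rep_stations = ["ED", "ICU"]
        class FakeDeath:
            def __init__(self, s): self.station = s
        class FakeReport:
            preventable_deaths = [FakeDeath(s) for s in rep_stations]
            n_preventable = 2
        assert _component_deaths(FakeReport, "overall") == 2
        assert _component_deaths(FakeReport, "ED") == 1
        assert _component_deaths(FakeReport, "OR") == 0
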