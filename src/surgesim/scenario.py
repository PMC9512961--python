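"""Synthetic incident scenarios.

A :class:`ScenarioTemplate` states the casualty mix of an incident — the
triage-category proportions, the injury panels available per category with
draw weights, per-panel deadline jitter, and the transport geography.  A
:class:`Scenario` is a concrete, seeded draw from a template scaled to a
target casualty count with the category proportions preserved exactly
(largest-remainder apportionment), mirroring how a standardised exercise
scenario is rescaled to the local population without changing its injury mix.

Casualty cards are assembled here: panel injuries, jittered treatment
deadlines, a physiological trajectory consistent with the card's triage
category under the default sieve, trauma scores, and the optimal-outcome flag
computed by a greedy schedule-feasibility check.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .casualty import (
    Casualty,
    Injury,
    PhysiologySnapshot,
    SieveConfig,
    Station,
    Trajectory,
    TrajectoryBreakpoint,
    TreatmentRequirement,
    TriageCategory,
    compute_iss,
    compute_niss,
    compute_rts,
    triage,
)

__all__ = [
    "Geography",
    "InjuryPanel",
    "ScenarioTemplate",
    "Scenario",
    "scale_scenario",
    "generate_scenario",
    "default_template",
    "schedule_feasible",
]

CATEGORY_ORDER = (TriageCategory.RED, TriageCategory.YELLOW, TriageCategory.GREEN, TriageCategory.DEAD)


class Geography(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_hospitals: int = Field(default=1, ge=1)
    transport_time_min: tuple[int, ...] = (5,)

    @model_validator(mode="after")
    def _lengths(self) -> "Geography":
        if len(self.transport_time_min) != self.n_hospitals:
            raise ValueError("transport_time_min must list one time per hospital")
        if any(t < 0 for t in self.transport_time_min):
            raise ValueError("transport times must be >= 0")
        return self


class InjuryPanel(BaseModel):
    """A reusable injury/treatment bundle a casualty card is stamped from."""

    model_config = ConfigDict(extra="forbid")

    id: str
    category: TriageCategory
    injuries: tuple[Injury, ...]
    requirements: tuple[TreatmentRequirement, ...] = ()


class ScenarioTemplate(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    category_proportions: dict[TriageCategory, float]
    panel_weights: dict[TriageCategory, dict[str, float]]
    deadline_jitter_min: dict[str, int] = Field(default_factory=dict)
    geography: Geography = Field(default_factory=Geography)
    panels: dict[str, InjuryPanel]

    @model_validator(mode="after")
    def _check(self) -> "ScenarioTemplate":
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")
        for cat, weights in self.panel_weights.items():
            if self.category_proportions.get(cat, 0.0) > 0:
                if not weights or sum(weights.values()) <= 0:
                    raise ValueError(f"no positive panel weights for {cat.value}")
            for pid, w in weights.items():
                if w < 0:
                    raise ValueError(f"negative weight for panel {pid!r}")
                if pid not in self.panels:
                    raise ValueError(f"panel {pid!r} not defined")
                if self.panels[pid].category is not cat:
                    raise ValueError(f"panel {pid!r} listed under wrong category")
        return self


class Scenario(BaseModel):
    model_config = ConfigDict(extra="forbid")

    template_name: str
    n_total: int = Field(ge=0)
    seed: int
    incident_time_of_day: str = "office"  # office | non-office
    casualties: tuple[Casualty, ...] = ()

    @property
    def by_category(self) -> dict[TriageCategory, list[Casualty]]:
        out: dict[TriageCategory, list[Casualty]] = {c: [] for c in CATEGORY_ORDER}
        for c in self.casualties:
            out[c.true_category].append(c)
        return out

    def bank(self) -> dict[str, Casualty]:
        return {c.id: c for c in self.casualties}


# ---------------------------------------------------------------------------
# Apportionment
# ---------------------------------------------------------------------------

def scale_scenario(template: ScenarioTemplate, n_total: int) -> dict[TriageCategory, int]:
    """Largest-remainder (Hamilton) apportionment of ``n_total`` casualties
    over the template's category proportions.  Ties on the fractional
    remainder break in priority order RED > YELLOW > GREEN > DEAD."""
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    props = [(cat, template.category_proportions.get(cat, 0.0)) for cat in CATEGORY_ORDER]
    quotas = [(cat, n_total * p) for cat, p in props]
    counts = {cat: math.floor(q) for cat, q in quotas}
    leftover = n_total - sum(counts.values())
    remainders = sorted(
        ((q - math.floor(q), -CATEGORY_ORDER.index(cat), cat) for cat, q in quotas),
        reverse=True,
    )
    for _, _, cat in remainders[:leftover]:
        counts[cat] += 1
    return counts


# ---------------------------------------------------------------------------
# Feasibility oracle
# ---------------------------------------------------------------------------

def schedule_feasible(requirements: tuple[TreatmentRequirement, ...]) -> bool:
    """Greedy check that some schedule averts death: running the plan
    back-to-back from t = 0 with unlimited resources, every time-critical
    treatment completes by its hard deadline."""
    t = 0
    for req in requirements:
        t += req.duration_min
        if req.deadline_min is not None and t > req.deadline_min:
            return False
    return True


# ---------------------------------------------------------------------------
# Card assembly
# ---------------------------------------------------------------------------

_INITIAL_VITALS = {
    TriageCategory.RED: PhysiologySnapshot(gcs=12, sbp=80, rr=24, ambulatory=False),
    TriageCategory.YELLOW: PhysiologySnapshot(gcs=15, sbp=110, rr=22, ambulatory=False),
    TriageCategory.GREEN: PhysiologySnapshot(gcs=15, sbp=120, rr=16, ambulatory=True),
    TriageCategory.DEAD: PhysiologySnapshot(gcs=3, sbp=0, rr=0, ambulatory=False),
}

_STABILISED_VITALS = PhysiologySnapshot(gcs=14, sbp=100, rr=18, ambulatory=False)


def _jitter_requirements(
    panel: InjuryPanel, jitter: int, rng: np.random.Generator
) -> tuple[TreatmentRequirement, ...]:
    if jitter <= 0:
        return panel.requirements
    shift = int(rng.integers(-jitter, jitter + 1))
    out = []
    for req in panel.requirements:
        if req.deadline_min is None:
            out.append(req)
            continue
        dl = max(req.duration_min + 1, req.deadline_min + shift)
        cd = req.complication_deadline_min
        if cd is not None:
            cd = min(max(1, cd + shift), dl)
        out.append(req.model_copy(update={"deadline_min": dl, "complication_deadline_min": cd}))
    return tuple(out)


def _build_trajectory(category: TriageCategory, reqs: tuple[TreatmentRequirement, ...]) -> Trajectory:
    deadlines = [r.deadline_min for r in reqs if r.deadline_min is not None]
    death_time = min(deadlines) if deadlines else None
    breakpoints = [TrajectoryBreakpoint(from_min=0, condition=(), snapshot=_INITIAL_VITALS[category])]
    if category is TriageCategory.RED and reqs:
        # Completing the first intervention stabilises the vitals.
        breakpoints.append(
            TrajectoryBreakpoint(from_min=0, condition=(reqs[0].id,), snapshot=_STABILISED_VITALS)
        )
    return Trajectory(breakpoints=tuple(breakpoints), death_time_untreated_min=death_time)


def _make_casualty(cid: str, panel: InjuryPanel, jitter: int, rng: np.random.Generator) -> Casualty:
    reqs = _jitter_requirements(panel, jitter, rng)
    trajectory = _build_trajectory(panel.category, reqs)
    snap0 = trajectory.breakpoints[0].snapshot
    return Casualty(
        id=cid,
        injuries=panel.injuries,
        requirements=reqs,
        trajectory=trajectory,
        survivable_if_optimal=(panel.category is not TriageCategory.DEAD) and schedule_feasible(reqs),
        iss=compute_iss(panel.injuries),
        niss=compute_niss(panel.injuries),
        rts=compute_rts(snap0),
        true_category=panel.category,
    )


def generate_scenario(
    template: ScenarioTemplate,
    n_total: int,
    seed: Optional[int],
    incident_time_of_day: str = "office",
) -> Scenario:
    """Draw a concrete scenario of ``n_total`` casualties from the template.

    Deterministic for fixed (template, n_total, seed); refusing a missing seed
    keeps every scenario reproducible.  RED cards always carry at least one
    time-critical requirement and GREEN cards never do (audited post-draw).
    """
    if seed is None:
        raise ValueError("generate_scenario requires an explicit seed")
    if incident_time_of_day not in ("office", "non-office"):
        raise ValueError("incident_time_of_day must be 'office' or 'non-office'")
    rng = np.random.default_rng(seed)
    counts = scale_scenario(template, n_total)
    casualties: list[Casualty] = []
    serial = 0
    for cat in CATEGORY_ORDER:
        weights = template.panel_weights.get(cat, {})
        panel_ids = sorted(weights)
        if counts[cat] > 0 and not panel_ids:
            raise ValueError(f"template defines no panels for {cat.value}")
        probs = np.asarray([weights[p] for p in panel_ids], dtype=float)
        probs = probs / probs.sum() if probs.size else probs
        for _ in range(counts[cat]):
            serial += 1
            cid = f"c{serial:04d}"
            pid = panel_ids[int(rng.choice(len(panel_ids), p=probs))]
            panel = template.panels[pid]
            c = _make_casualty(cid, panel, template.deadline_jitter_min.get(pid, 0), rng)
            if cat is TriageCategory.RED and not c.time_critical_requirements:
                raise ValueError(f"RED panel {pid!r} generated no time-critical requirement")
            if cat is TriageCategory.GREEN and c.time_critical_requirements:
                raise ValueError(f"GREEN panel {pid!r} generated a time-critical requirement")
            if cat is not TriageCategory.DEAD and triage(c.trajectory.breakpoints[0].snapshot, SieveConfig()) is not cat:
                raise ValueError(f"panel {pid!r}: initial vitals inconsistent with category {cat.value}")
            casualties.append(c)
    return Scenario(
        template_name=template.name,
        n_total=n_total,
        seed=seed,
        incident_time_of_day=incident_time_of_day,
        casualties=tuple(casualties),
    )


# ---------------------------------------------------------------------------
# Shipped default template
# ---------------------------------------------------------------------------

def _req(id: str, station: Station, dur: int, deadline: int | None = None,
         compl: int | None = None, staff: dict[str, int] | None = None,
         consumables: dict[str, int] | None = None) -> TreatmentRequirement:
    return TreatmentRequirement(
        id=id, station=station, duration_min=dur, deadline_min=deadline,
        complication_deadline_min=compl, staff_demand=staff or {"nurse": 1},
        consumables=consumables or {},
    )


def default_panels() -> dict[str, InjuryPanel]:
    """The repo-authored injury panel library.

    Deadlines, durations and staffing are authored exercise values chosen for
    clinical plausibility; they are not taken from any specific casualty card
    set (real card data are proprietary).
    """
    inj = lambda region, ais: Injury(body_region=region, ais=ais)
    panels = [
        InjuryPanel(
            id="red_thorax_abdo", category=TriageCategory.RED,
            injuries=(inj("thorax", 4), inj("abdomen", 3)),
            requirements=(
                _req("ed_resus", Station.ED, 20, deadline=75, compl=55, staff={"doctor": 1, "nurse": 2}),
                _req("ct_scan", Station.CT, 10, staff={"nurse": 1}),
                _req("or_damage_control", Station.OR, 90, deadline=360, compl=240,
                     staff={"doctor": 2, "nurse": 2}, consumables={"or_disposable_set": 1}),
                _req("icu_stay", Station.ICU, 720, staff={"nurse": 1}),
            ),
        ),
        InjuryPanel(
            id="red_head", category=TriageCategory.RED,
            injuries=(inj("head", 4), inj("external", 2)),
            requirements=(
                _req("ed_resus", Station.ED, 20, deadline=100, compl=70, staff={"doctor": 1, "nurse": 2}),
                _req("ct_scan", Station.CT, 10, staff={"nurse": 1}),
                _req("or_craniotomy", Station.OR, 120, deadline=420, compl=300,
                     staff={"doctor": 2, "nurse": 2}, consumables={"or_disposable_set": 1, "neuro_set": 1}),
                _req("icu_stay", Station.ICU, 720, staff={"nurse": 1}),
            ),
        ),
        InjuryPanel(
            id="red_abdo", category=TriageCategory.RED,
            injuries=(inj("abdomen", 4),),
            requirements=(
                _req("ed_resus", Station.ED, 15, deadline=110, compl=75, staff={"doctor": 1, "nurse": 2}),
                _req("or_laparotomy", Station.OR, 60, deadline=300, compl=200,
                     staff={"doctor": 2, "nurse": 2}, consumables={"or_disposable_set": 1}),
                _req("ward_obs", Station.WARD, 240, staff={"nurse": 1}),
            ),
        ),
        InjuryPanel(
            id="red_unsalvageable", category=TriageCategory.RED,
            injuries=(inj("head", 5), inj("thorax", 5)),
            # Deadline shorter than the treatment itself: no schedule can
            # avert death, so any death here is non-preventable.
            requirements=(
                _req("ed_resus", Station.ED, 30, deadline=20, staff={"doctor": 1, "nurse": 2}),
            ),
        ),
        InjuryPanel(
            id="yellow_limb_fx", category=TriageCategory.YELLOW,
            injuries=(inj("lower-extremity", 3),),
            requirements=(
                _req("ed_minor", Station.ED, 15, staff={"nurse": 1}),
                _req("or_ext_fix", Station.OR, 45, compl=600,
                     staff={"doctor": 1, "nurse": 1},
                     consumables={"or_disposable_set": 1, "ext_fix_set": 1}),
                _req("ward_obs", Station.WARD, 120, staff={"nurse": 1}),
            ),
        ),
        InjuryPanel(
            id="yellow_soft_tissue", category=TriageCategory.YELLOW,
            injuries=(inj("upper-extremity", 2), inj("external", 2)),
            requirements=(
                _req("ed_minor", Station.ED, 15, staff={"nurse": 1}),
                _req("ward_obs", Station.WARD, 60, staff={"nurse": 1}),
            ),
        ),
        InjuryPanel(
            id="green_walking", category=TriageCategory.GREEN,
            injuries=(inj("external", 1),),
            requirements=(_req("ed_minor", Station.ED, 10, staff={"nurse": 1}),),
        ),
        InjuryPanel(
            id="green_untreated", category=TriageCategory.GREEN,
            injuries=(inj("upper-extremity", 1),),
            requirements=(),
        ),
        InjuryPanel(
            id="dead_at_scene", category=TriageCategory.DEAD,
            injuries=(inj("head", 6),),
            requirements=(),
        ),
    ]
    return {p.id: p for p in panels}


def default_template(n_hospitals: int = 1, transport_time_min: tuple[int, ...] = (5,)) -> ScenarioTemplate:
    """Shipped fictional scenario mix (authored, not any published incident):
    10% red, 30% yellow, 55% green, 5% dead at scene."""
    return ScenarioTemplate(
        name="default-urban-blast",
        category_proportions={
            TriageCategory.RED: 0.10,
            TriageCategory.YELLOW: 0.30,
            TriageCategory.GREEN: 0.55,
            TriageCategory.DEAD: 0.05,
        },
        panel_weights={
            TriageCategory.RED: {
                "red_thorax_abdo": 0.4, "red_head": 0.25, "red_abdo": 0.29,
                "red_unsalvageable": 0.06,
            },
            TriageCategory.YELLOW: {"yellow_limb_fx": 0.25, "yellow_soft_tissue": 0.75},
            TriageCategory.GREEN: {"green_walking": 0.6, "green_untreated": 0.4},
            TriageCategory.DEAD: {"dead_at_scene": 1.0},
        },
        deadline_jitter_min={"red_thorax_abdo": 15, "red_head": 15, "red_abdo": 15},
        geography=Geography(n_hospitals=n_hospitals, transport_time_min=transport_time_min),
        panels=default_panels(),
    )
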