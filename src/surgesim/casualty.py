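"""In-silico casualty cards.

A casualty card bundles everything a mass-casualty simulation needs to know
about one victim: the anatomical injury panel with AIS severities, the
time-critical treatments each injury demands, a physiological trajectory that
worsens with time and improves with completed treatments, standard trauma
scores (ISS, NISS, RTS), and the flag that makes preventable-mortality
accounting possible — whether the casualty would survive optimal treatment.

Times are integer minutes after the incident (t = 0 is the incident itself).
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "BodyRegion",
    "TriageCategory",
    "Station",
    "Injury",
    "TreatmentRequirement",
    "PhysiologySnapshot",
    "TrajectoryBreakpoint",
    "Trajectory",
    "Casualty",
    "SieveConfig",
    "compute_iss",
    "compute_niss",
    "compute_rts",
    "physiology_at",
    "triage",
    "RTS_MAX",
]


class BodyRegion(str, enum.Enum):
    HEAD = "head"
    FACE = "face"
    NECK = "neck"
    THORAX = "thorax"
    ABDOMEN = "abdomen"
    SPINE = "spine"
    UPPER_EXTREMITY = "upper-extremity"
    LOWER_EXTREMITY = "lower-extremity"
    EXTERNAL = "external"


class TriageCategory(str, enum.Enum):
    """Field triage category. Sort order encodes treatment priority."""

    RED = "red"        # immediate, life-threatening
    YELLOW = "yellow"  # urgent, can wait briefly
    GREEN = "green"    # minor, walking wounded
    DEAD = "dead"

    @property
    def priority(self) -> int:
        return _CATEGORY_PRIORITY[self]


_CATEGORY_PRIORITY = {
    TriageCategory.RED: 0,
    TriageCategory.YELLOW: 1,
    TriageCategory.GREEN: 2,
    TriageCategory.DEAD: 3,
}


class Station(str, enum.Enum):
    """Hospital stations a treatment can be bound to."""

    ED = "ED"
    CT = "CT"
    OR = "OR"
    ICU = "ICU"
    WARD = "WARD"


class Injury(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    body_region: BodyRegion
    ais: int = Field(ge=1, le=6)
    required_treatments: tuple[str, ...] = ()


class TreatmentRequirement(BaseModel):
    """A time-critical intervention.

    ``deadline_min`` is the minute (post-incident) by which the treatment must
    be *completed* to avert death; ``None`` means the treatment is not
    life-critical.  ``complication_deadline_min`` is an earlier soft deadline:
    completing the treatment after it (but before the hard deadline) leaves the
    casualty alive but with a severe complication.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    station: Station
    duration_min: int = Field(gt=0)
    deadline_min: Optional[int] = Field(default=None, gt=0)
    complication_deadline_min: Optional[int] = Field(default=None, gt=0)
    staff_demand: dict[str, int] = Field(default_factory=dict)
    consumables: dict[str, int] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "TreatmentRequirement":
        if not any(v >= 1 for v in self.staff_demand.values()):
            raise ValueError(f"requirement {self.id!r}: staff_demand must name at least one category with count >= 1")
        if any(v < 0 for v in self.consumables.values()):
            raise ValueError(f"requirement {self.id!r}: negative consumable count")
        if (
            self.complication_deadline_min is not None
            and self.deadline_min is not None
            and self.complication_deadline_min > self.deadline_min
        ):
            raise ValueError(f"requirement {self.id!r}: complication deadline after death deadline")
        return self

    @property
    def time_critical(self) -> bool:
        return self.deadline_min is not None


class PhysiologySnapshot(BaseModel):
    """ATLS-style vital signs at one instant."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    gcs: int = Field(ge=3, le=15)
    sbp: int = Field(ge=0)
    rr: int = Field(ge=0)
    ambulatory: bool = False


#: Deceased-marker vitals returned once the untreated death time has passed.
DECEASED_SNAPSHOT = PhysiologySnapshot(gcs=3, sbp=0, rr=0, ambulatory=False)


class TrajectoryBreakpoint(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    from_min: int = Field(ge=0)
    condition: tuple[str, ...] = ()  # treatment ids that must be completed
    snapshot: PhysiologySnapshot


class Trajectory(BaseModel):
    """Piecewise-constant physiology as a function of time and treatments done.

    The active snapshot at (t, done) is the latest breakpoint with
    ``from_min <= t`` whose condition set is a subset of ``done``.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    breakpoints: tuple[TrajectoryBreakpoint, ...]
    death_time_untreated_min: Optional[int] = None

    @model_validator(mode="after")
    def _sorted(self) -> "Trajectory":
        times = [bp.from_min for bp in self.breakpoints]
        if times != sorted(times):
            raise ValueError("trajectory breakpoints must be sorted by from_min")
        return self


class Casualty(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    injuries: tuple[Injury, ...]
    requirements: tuple[TreatmentRequirement, ...] = ()
    trajectory: Trajectory
    survivable_if_optimal: bool
    iss: int = Field(ge=0, le=75)
    niss: int = Field(ge=0, le=75)
    rts: float = Field(ge=0.0, le=7.8408)
    true_category: TriageCategory

    @property
    def time_critical_requirements(self) -> tuple[TreatmentRequirement, ...]:
        return tuple(r for r in self.requirements if r.time_critical)


# ---------------------------------------------------------------------------
# Trauma scores
# ---------------------------------------------------------------------------

def compute_iss(injuries: list[Injury] | tuple[Injury, ...]) -> int:
    """Injury Severity Score: sum of squares of the three highest AIS values
    drawn from distinct body regions; 75 if any injury is AIS 6."""
    if any(inj.ais == 6 for inj in injuries):
        return 75
    worst: dict[BodyRegion, int] = {}
    for inj in injuries:
        if inj.ais > worst.get(inj.body_region, 0):
            worst[inj.body_region] = inj.ais
    top3 = sorted(worst.values(), reverse=True)[:3]
    return sum(a * a for a in top3)


def compute_niss(injuries: list[Injury] | tuple[Injury, ...]) -> int:
    """New ISS: as ISS but the three highest AIS values regardless of region."""
    if any(inj.ais == 6 for inj in injuries):
        return 75
    top3 = sorted((inj.ais for inj in injuries), reverse=True)[:3]
    return sum(a * a for a in top3)


# Standard coded-RTS tables (Champion revision); external to any one exercise.
_GCS_CODE = ((13, 4), (9, 3), (6, 2), (4, 1), (3, 0))
_SBP_CODE = ((90, 4), (76, 3), (50, 2), (1, 1), (0, 0))
_RR_RANGES = (((10, 29), 4), ((30, 10**9), 3), ((6, 9), 2), ((1, 5), 1), ((0, 0), 0))

_RTS_WEIGHTS = (0.9368, 0.7326, 0.2908)  # GCS, SBP, RR
RTS_MAX = 7.8408


def _code_gcs(gcs: int) -> int:
    for lo, code in _GCS_CODE:
        if gcs >= lo:
            return code
    return 0


def _code_sbp(sbp: int) -> int:
    for lo, code in _SBP_CODE:
        if sbp >= lo:
            return code
    return 0


def _code_rr(rr: int) -> int:
    for (lo, hi), code in _RR_RANGES:
        if lo <= rr <= hi:
            return code
    return 0


def compute_rts(snapshot: PhysiologySnapshot) -> float:
    """Revised Trauma Score: 0.9368*GCSc + 0.7326*SBPc + 0.2908*RRc."""
    codes = (_code_gcs(snapshot.gcs), _code_sbp(snapshot.sbp), _code_rr(snapshot.rr))
    return round(sum(w * c for w, c in zip(_RTS_WEIGHTS, codes)), 4)


# ---------------------------------------------------------------------------
# Time/treatment-dependent physiology
# ---------------------------------------------------------------------------

class TrajectoryQueryError(KeyError):
    """Raised when a trajectory has no breakpoint matching a (t, done) query."""


def physiology_at(casualty: Casualty, t: int, done: set[str] | frozenset[str]) -> PhysiologySnapshot:
    """Vital signs of ``casualty`` at minute ``t`` given completed treatments.

    If the untreated death time has passed and no death-averting treatment is
    complete, the deceased marker is returned.  Otherwise the latest applicable
    breakpoint wins.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    traj = casualty.trajectory
    dt = traj.death_time_untreated_min
    if dt is not None and t >= dt:
        # Death is averted only if every time-critical requirement whose
        # deadline has passed was completed.
        lapsed = [r.id for r in casualty.time_critical_requirements if r.deadline_min is not None and r.deadline_min <= t]
        if any(rid not in done for rid in lapsed):
            return DECEASED_SNAPSHOT
    best: PhysiologySnapshot | None = None
    for bp in traj.breakpoints:
        if bp.from_min <= t and set(bp.condition) <= set(done):
            best = bp.snapshot
    if best is None:
        raise TrajectoryQueryError(
            f"casualty {casualty.id!r}: no trajectory branch for t={t}, done={sorted(done)}"
        )
    return best


# ---------------------------------------------------------------------------
# Triage sieve
# ---------------------------------------------------------------------------

class SieveConfig(BaseModel):
    """Physiological triage sieve thresholds.

    The field algorithm itself is course material, not published; the shipped
    defaults follow common sieve practice and live in configuration, not code.
    """

    model_config = ConfigDict(extra="forbid")

    rr_low: int = 10    # rr below this -> RED
    rr_high: int = 29   # rr above this -> RED
    sbp_low: int = 90   # sbp below this -> RED
    gcs_low: int = 13   # gcs at or below this -> RED


def triage(snapshot: PhysiologySnapshot, sieve: SieveConfig | None = None) -> TriageCategory:
    """Deterministic physiological sieve: walking -> GREEN, apnoeic -> DEAD,
    deranged vitals -> RED, otherwise YELLOW."""
    sieve = sieve or SieveConfig()
    if snapshot.ambulatory:
        return TriageCategory.GREEN
    if snapshot.rr == 0:
        return TriageCategory.DEAD
    if (
        snapshot.rr < sieve.rr_low
        or snapshot.rr > sieve.rr_high
        or snapshot.sbp < sieve.sbp_low
        or snapshot.gcs <= sieve.gcs_low
    ):
        return TriageCategory.RED
    return TriageCategory.YELLOW
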