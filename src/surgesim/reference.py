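"""Brute-force time-stepped hospital simulator.

A deliberately simple reference implementation of the hospital flow rules:
instead of jumping between scheduled events it walks every single minute from
0 to the horizon and applies the same phase order as the event-driven engine
(completions, transfer completions, deaths, arrivals, starts).  It exists as
an independent oracle — on any scenario the two simulators must produce
identical event logs — and is kept free of the engine's scheduling machinery
on purpose.  Use it for validation; it is O(horizon) slower than the engine.
"""

from __future__ import annotations

from typing import Optional

from .casualty import Casualty, Station, TriageCategory
from .engine import (
    EventLog,
    HospitalConfig,
    apparent_categories,
    ct_visit,
    mobilization_events,
    mobilized,
)
from .prehospital import ArrivalStream

__all__ = ["simulate_time_stepped"]

_BIG = 10 ** 9
_ORDER = (Station.ED, Station.CT, Station.OR, Station.ICU, Station.WARD)


def simulate_time_stepped(
    hospital: HospitalConfig,
    stream: ArrivalStream,
    bank: dict[str, Casualty],
    seed: Optional[int] = None,
    profile: str = "office",
    horizon_min: int = 1440,
) -> EventLog:
    cfg = hospital
    log = EventLog()
    apparent = apparent_categories(bank, seed, cfg.triage_error_rate)

    arrivals: dict[int, list[str]] = {}
    for a in stream.arrivals:
        arrivals.setdefault(a.arrival_min, []).append(a.casualty_id)

    mob = mobilization_events(cfg, profile)
    mob_i = 0
    alert_done = False

    # Per-casualty mutable state.
    S: dict[str, dict] = {}
    busy = {"tu": 0, "minor": 0, "ct": 0, "or": 0, "icu": 0, "ward": 0, "transport": 0}
    staff_busy: dict[str, int] = {c: 0 for c in cfg.staff_roster}
    committed: set[str] = set()
    queues: dict[Station, list[str]] = {s: [] for s in _ORDER}
    transfer_wait: list[tuple[int, str]] = []
    order_counter = [0]

    def req_of(s):
        reqs = s["c"].requirements
        return reqs[s["stage"]] if s["stage"] < len(reqs) else None

    def min_deadline(s):
        ds = [r.deadline_min for r in s["c"].requirements
              if r.deadline_min is not None and r.id not in s["done"]]
        return min(ds) if ds else None

    def unit_name(u):
        return {"tu": "trauma_unit", "minor": "minor_slot", "ct": "ct", "or": "or_theatre",
                "icu": "icu_bed", "ward": "ward_bed"}[u]

    def release_treatment(t, cid, s, req):
        busy[s["unit"]] -= 1
        name = unit_name(s["unit"])
        for cat in sorted(req.staff_demand):
            staff_busy[cat] -= req.staff_demand[cat]
        s["unit"] = ""
        log.append(t, cid, "release", req.station.value, f"resource={name}")

    def enter_queue(t, cid, s):
        req = req_of(s)
        s["status"] = "queued"
        s["enter_t"] = t
        s["block"] = ""
        queues[req.station].append(cid)
        log.append(t, cid, "queue_enter", req.station.value, f"req={req.id}")

    def staff_free(demand, t):
        return all(
            staff_busy.get(cat, 0) + n <= mobilized(cfg, f"staff:{cat}", t, profile)
            for cat, n in demand.items()
        )

    for t in range(0, horizon_min + 1):
        # phase 0: alert + mobilization bookkeeping
        if not alert_done and t >= cfg.alert_min:
            log.append(cfg.alert_min, "hospital", "alert", "", "major incident alert")
            alert_done = True
        while mob_i < len(mob) and mob[mob_i][0] <= t:
            tm, res, count = mob[mob_i]
            log.append(tm, res, "mobilize", "", f"count={count}")
            mob_i += 1

        # phase 1: completions
        ending = sorted(cid for cid, s in S.items() if s["status"] == "treat" and s["end_t"] == t)
        for cid in ending:
            s = S[cid]
            req = req_of(s)
            log.append(t, cid, "treatment_end", req.station.value, f"req={req.id}")
            release_treatment(t, cid, s, req)
            s["done"].add(req.id)
            s["stage"] += 1
            nxt = req_of(s)
            if nxt is None:
                s["status"] = "terminal"
                log.append(t, cid, "discharge", req.station.value, "plan complete")
            elif nxt.station is not req.station and cfg.transfer_time_min > 0:
                s["status"] = "transfer_wait"
                s["enter_t"] = t
                transfer_wait.append((t, cid))
            else:
                enter_queue(t, cid, s)

        # phase 2: transfer completions
        for cid in sorted(cid for cid, s in S.items() if s["status"] == "transfer" and s["end_t"] == t):
            s = S[cid]
            if s["token"] == "transport":
                busy["transport"] -= 1
            else:
                staff_busy[s["token"].split(":", 1)[1]] -= 1
            s["token"] = ""
            enter_queue(t, cid, s)

        # phase 3: deaths
        for cid in sorted(S):
            s = S[cid]
            if s["status"] in ("terminal", "dead"):
                continue
            d = min_deadline(s)
            if d is None or d > t:
                continue
            missed = min(
                (r for r in s["c"].requirements if r.deadline_min is not None and r.id not in s["done"]),
                key=lambda r: r.deadline_min,
            )
            req = req_of(s)
            if s["block"] == "icu":
                station, blocked_on = Station.ICU.value, "icu"
            elif s["status"] in ("queued", "treat") and req is not None:
                station = req.station.value
                blocked_on = s["block"] or ("in_treatment" if s["status"] == "treat" else "queue")
            elif s["status"] in ("transfer_wait", "transfer") and req is not None:
                station, blocked_on = req.station.value, "transfer"
            else:
                station, blocked_on = missed.station.value, "transit"
            wait = max(0, t - s["enter_t"]) if s["status"] in ("queued", "transfer_wait") and s["enter_t"] >= 0 else 0
            if s["status"] == "treat":
                release_treatment(t, cid, s, req)
            elif s["status"] == "queued":
                queues[req.station].remove(cid)
            elif s["status"] == "transfer_wait":
                transfer_wait[:] = [(rt, c2) for rt, c2 in transfer_wait if c2 != cid]
            elif s["status"] == "transfer":
                if s["token"] == "transport":
                    busy["transport"] -= 1
                else:
                    staff_busy[s["token"].split(":", 1)[1]] -= 1
                s["token"] = ""
            committed.discard(cid)
            s["status"] = "dead"
            log.append(
                t, cid, "death", station,
                f"req={missed.id} deadline={missed.deadline_min} blocked_on={blocked_on} wait={wait}",
            )

        # phase 4: arrivals
        for cid in arrivals.get(t, []):
            c = bank[cid]
            order_counter[0] += 1
            s = {
                "c": c, "cat": apparent[cid], "order": order_counter[0], "stage": 0,
                "status": "pre", "enter_t": -1, "end_t": -1, "done": set(),
                "block": "", "unit": "", "token": "",
            }
            S[cid] = s
            log.append(t, cid, "arrive", "", "")
            log.append(t, cid, "triage2", "", f"category={s['cat'].value}")
            if not c.requirements:
                s["status"] = "terminal"
                log.append(t, cid, "discharge", "", "no treatment required")
                continue
            d = min_deadline(s)
            if d is not None and d <= t:
                missed = min(
                    (r for r in c.requirements if r.deadline_min is not None),
                    key=lambda r: r.deadline_min,
                )
                s["status"] = "dead"
                log.append(
                    t, cid, "death", c.requirements[0].station.value,
                    f"req={missed.id} deadline={missed.deadline_min} blocked_on=queue wait=0",
                )
                continue
            enter_queue(t, cid, s)

        # phase 5a: transfer departures
        still_waiting: list[tuple[int, str]] = []
        for ready_t, cid in sorted(transfer_wait):
            s = S[cid]
            req = req_of(s)
            token = ""
            if busy["transport"] < cfg.transport_staff:
                token = "transport"
                busy["transport"] += 1
            elif staff_free({cfg.indirect_transfer_staff_category: 1}, t):
                token = f"staff:{cfg.indirect_transfer_staff_category}"
                staff_busy[cfg.indirect_transfer_staff_category] += 1
            if not token:
                s["block"] = "transport_staff"
                still_waiting.append((ready_t, cid))
                continue
            s["token"] = token
            s["status"] = "transfer"
            s["block"] = ""
            s["end_t"] = t + cfg.transfer_time_min
            detail = f"to={req.station.value} via={token}"
            if token != "transport":
                detail += " indirect=1"
            log.append(t, cid, "seize", req.station.value, f"resource={token}")
            log.append(t, cid, "transfer", req.station.value, detail)
        transfer_wait = still_waiting

        # phase 5b: station starts
        for station in _ORDER:
            def key(cid):
                s = S[cid]
                d = min_deadline(s)
                return (s["cat"].priority, (d - t) if d is not None else _BIG, s["order"], cid)

            for cid in sorted(list(queues[station]), key=key):
                s = S[cid]
                req = req_of(s)
                needs_icu_later = any(r.station is Station.ICU for r in s["c"].requirements[s["stage"] + 1:])
                # capacity checks
                block = ""
                if station is Station.ED:
                    if s["cat"] is TriageCategory.RED:
                        if busy["tu"] >= mobilized(cfg, "trauma_units", t, profile):
                            block = "trauma_unit"
                    elif busy["minor"] >= cfg.n_minor_treatment_slots:
                        block = "minor_slot"
                elif station is Station.CT:
                    if busy["ct"] >= cfg.n_ct:
                        block = "ct"
                elif station is Station.OR:
                    if busy["or"] >= mobilized(cfg, "or_theatres", t, profile):
                        block = "or_theatre"
                    elif cfg.or_blocks_on_icu and needs_icu_later and cid not in committed and \
                            busy["icu"] + len(committed) >= mobilized(cfg, "icu_beds", t, profile):
                        block = "icu"
                elif station is Station.ICU:
                    if cid not in committed and \
                            busy["icu"] + len(committed) >= mobilized(cfg, "icu_beds", t, profile):
                        block = "icu"
                elif station is Station.WARD:
                    if busy["ward"] >= cfg.n_ward_beds:
                        block = "ward_bed"
                if not block and not staff_free(req.staff_demand, t):
                    block = "staff"
                if block:
                    s["block"] = block
                    continue
                # start
                queues[station].remove(cid)
                resources = []
                if station is Station.ED:
                    u = "tu" if s["cat"] is TriageCategory.RED else "minor"
                    busy[u] += 1
                    s["unit"] = u
                    resources.append(unit_name(u))
                elif station is Station.CT:
                    busy["ct"] += 1
                    s["unit"] = "ct"
                    resources.append("ct")
                elif station is Station.OR:
                    busy["or"] += 1
                    s["unit"] = "or"
                    resources.append("or_theatre")
                    if cfg.or_blocks_on_icu and needs_icu_later and cid not in committed:
                        committed.add(cid)
                        resources.append("icu_bed_committed")
                elif station is Station.ICU:
                    committed.discard(cid)
                    busy["icu"] += 1
                    s["unit"] = "icu"
                    resources.append("icu_bed")
                elif station is Station.WARD:
                    busy["ward"] += 1
                    s["unit"] = "ward"
                    resources.append("ward_bed")
                for cat in sorted(req.staff_demand):
                    staff_busy[cat] = staff_busy.get(cat, 0) + req.staff_demand[cat]
                    resources.append(f"staff:{cat}x{req.staff_demand[cat]}")
                for item in sorted(req.consumables):
                    resources.append(f"use:{item}x{req.consumables[item]}")
                dur = ct_visit(cfg, req.duration_min) if station is Station.CT else req.duration_min
                s["status"] = "treat"
                s["block"] = ""
                s["end_t"] = t + dur
                log.append(t, cid, "queue_exit", station.value, f"req={req.id} wait={t - s['enter_t']}")
                log.append(t, cid, "seize", station.value, ",".join(resources))
                log.append(t, cid, "treatment_start", station.value, f"req={req.id} dur={dur}")

    return log
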