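"""Event-driven semi-MDP engine for two-tiered ambulance operations.

The engine advances the clock event to event (call arrival, scene arrival,
hospital arrival, handover completion, base arrival), maintains the full
system state (ambulance vectors and patient records), enforces the operating
rules — mandatory immediate dispatch whenever an ambulance is available,
classified-high-priority FCFS queues, nearest-hospital transport, base
capacity limits — and invokes a policy at the two decision points: which
ambulance to dispatch to a waiting patient and which base to send a freed
ambulance to.

Two outcome measures are logged per patient: the time-to-proper-care RT_PC
(response time, extended to hospital arrival when a BLS unit transports an
actually high-risk patient) and the risk level index (RLI), a severity-
weighted RT_PC with a fixed penalty when a high-risk patient's RT_PC exceeds
the response-time threshold.
"""

from __future__ import annotations

import math
from collections import deque
from heapq import heappush, heappop
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scenario import (
    Call,
    CallStreams,
    RLIParams,
    Scenario,
    generate_calls,
    travel_time,
)

__all__ = [
    "IDLE",
    "TO_PATIENT",
    "ON_SCENE",
    "TO_HOSPITAL",
    "AT_HOSPITAL",
    "TO_BASE",
    "STATUS_NAMES",
    "Ambulance",
    "Patient",
    "SystemState",
    "DecisionRequest",
    "EpisodeResult",
    "InfeasibleActionError",
    "cell_index",
    "rt_pc",
    "rli",
    "decision_points",
    "feasible_dispatches",
    "feasible_redeployments",
    "run_episode",
]

# ambulance status codes (a3)
IDLE, TO_PATIENT, ON_SCENE, TO_HOSPITAL, AT_HOSPITAL, TO_BASE = range(6)
STATUS_NAMES = ("idle", "to-patient", "on-scene", "to-hospital", "at-hospital", "to-base")

# patient status codes (p3)
WAITING, IN_SERVICE, COMPLETED = range(3)

# event kinds, with the fixed tie-break priority (arrivals that free or move
# resources resolve before call arrivals at the same instant)
EV_BASE, EV_SCENE, EV_HOSPITAL, EV_HANDOVER, EV_CALL = range(5)
EVENT_NAMES = ("base-arrival", "scene-arrival", "hospital-arrival", "handover-complete", "call-arrival")


class InfeasibleActionError(RuntimeError):
    """A policy returned an action outside the feasible set."""


def cell_index(x: float, y: float, bbox: tuple[float, float, float, float]) -> int:
    """Index of the 3x3 aggregation cell containing a point (row-major)."""
    x0, y0, x1, y1 = bbox
    i = int((x - x0) / (x1 - x0) * 3.0)
    j = int((y - y0) / (y1 - y0) * 3.0)
    i = 0 if i < 0 else (2 if i > 2 else i)
    j = 0 if j < 0 else (2 if j > 2 else j)
    return j * 3 + i


def rt_pc(record: "Patient", is_als: bool) -> float:
    """Time to proper care for a completed transport.

    Scene arrival minus report time, except a BLS unit carrying an actually
    high-risk patient: then proper care only starts at the hospital, so the
    interval runs to hospital arrival.
    """
    if record.scene_time is None:
        raise ValueError("scene arrival not realized")
    if (not is_als) and record.actual_high:
        if record.hospital_time is None:
            raise ValueError("hospital arrival not realized")
        return record.hospital_time - record.report_time
    return record.scene_time - record.report_time


def rli(rt_pc_min: float, actual_high: bool, params: RLIParams) -> float:
    """Risk level index of one patient outcome."""
    if rt_pc_min < 0:
        raise ValueError("rt_pc must be >= 0")
    if actual_high:
        pen = params.penalty if rt_pc_min > params.rtt else 0.0
        return params.c_high * rt_pc_min + pen
    return params.c_low * rt_pc_min


class Ambulance:
    """Mutable ambulance state vector (a1-a6)."""

    __slots__ = ("id", "is_als", "x", "y", "status", "patient_id", "dest_kind",
                 "dest_id", "leg_start", "leg_dur", "leg_from", "leg_to",
                 "at_base", "cell", "leg_token", "_reloc_row")

    def __init__(self, aid: int, is_als: bool, x: float, y: float, base: int, cell: int):
        self.id = aid
        self.is_als = is_als
        self.x = x
        self.y = y
        self.status = IDLE
        self.patient_id = None
        self.dest_kind = None   # "patient" | "hospital" | "base"
        self.dest_id = None
        self.leg_start = 0.0
        self.leg_dur = 0.0
        self.leg_from = (x, y)
        self.leg_to = (x, y)
        self.at_base = base     # base index while idle at a base, else None
        self.cell = cell        # aggregation-cell contribution, -1 if none
        self.leg_token = 0      # invalidates stale base-arrival events
        self._reloc_row = None

    @property
    def available(self) -> bool:
        """Dispatchable: idle or relocating back to a base."""
        return self.status == IDLE or self.status == TO_BASE

    def position_at(self, clock: float) -> tuple[float, float]:
        """Current position; linear interpolation along the active leg."""
        if self.status in (IDLE, ON_SCENE, AT_HOSPITAL) or self.leg_dur <= 0.0:
            return (self.x, self.y)
        frac = (clock - self.leg_start) / self.leg_dur
        if frac <= 0.0:
            return self.leg_from
        if frac >= 1.0:
            return self.leg_to
        fx, fy = self.leg_from
        tx, ty = self.leg_to
        return (fx + frac * (tx - fx), fy + frac * (ty - fy))

    @property
    def remaining_time(self) -> float:
        """a6: minutes remaining to destination (0 when not in transit)."""
        return self.leg_dur if self.status in (TO_PATIENT, TO_HOSPITAL, TO_BASE) else 0.0


class Patient:
    """Per-patient record (p1-p4 plus realized outcomes)."""

    __slots__ = ("id", "x", "y", "district", "cell", "report_time", "classified_high",
                 "actual_high", "status", "amb_id", "served_by_als", "dispatch_time",
                 "scene_time", "hospital_time", "handover_time", "hospital_id",
                 "scene_service", "hospital_service", "rt", "rt_pc", "rli")

    def __init__(self, call: Call, cell: int):
        self.id = call.id
        self.x = call.x
        self.y = call.y
        self.district = call.district
        self.cell = cell
        self.report_time = call.time
        self.classified_high = call.classified_high
        self.actual_high = call.actual_high
        self.scene_service = call.scene_service
        self.hospital_service = call.hospital_service
        self.status = WAITING
        self.amb_id = None
        self.served_by_als = None
        self.dispatch_time = None
        self.scene_time = None
        self.hospital_time = None
        self.handover_time = None
        self.hospital_id = None
        self.rt = None
        self.rt_pc = None
        self.rli = None


class SystemState:
    """Full semi-MDP state at an event time.

    Besides the ambulance and patient vectors it carries the running
    aggregation bookkeeping: per-cell counts of idle-or-relocating
    ambulances (relocating units counted at their destination base's cell)
    and of patients awaiting assignment, plus per-base occupied-or-inbound
    slot counts.
    """

    __slots__ = ("clock", "ambulances", "patients", "queue_high", "queue_low",
                 "idle_cells", "pending_cells", "base_slots")

    def __init__(self, scenario: Scenario):
        geom = scenario.geometry
        bbox = geom.bbox
        placement = scenario.fleet.placement(geom)
        types = scenario.fleet.types()
        self.clock = 0.0
        self.ambulances = []
        self.idle_cells = [0] * 9
        self.pending_cells = [0] * 9
        self.base_slots = [0] * len(geom.bases)
        for i in range(scenario.fleet.n_ambulances):
            b = placement[i]
            bx, by = geom.bases[b].location
            c = cell_index(bx, by, bbox)
            self.ambulances.append(Ambulance(i, types[i], bx, by, b, c))
            self.idle_cells[c] += 1
            self.base_slots[b] += 1
        self.patients: dict[int, Patient] = {}
        self.queue_high: deque[int] = deque()
        self.queue_low: deque[int] = deque()

    @property
    def n_waiting(self) -> int:
        return len(self.queue_high) + len(self.queue_low)

    def queue_head(self) -> Patient:
        """Next patient by the priority rule: classified-high first, FCFS within class."""
        q = self.queue_high if self.queue_high else self.queue_low
        return self.patients[q[0]]


class DecisionRequest:
    """What the engine asks a policy at a decision point."""

    __slots__ = ("kind", "patient", "ambulance", "candidates")

    def __init__(self, kind, patient=None, ambulance=None, candidates=()):
        self.kind = kind            # "dispatch" | "redeploy"
        self.patient = patient      # Patient (dispatch)
        self.ambulance = ambulance  # Ambulance (redeploy)
        self.candidates = candidates  # ambulances (dispatch) or base ids (redeploy)


def feasible_dispatches(state: SystemState, patient: Patient) -> list[Ambulance]:
    """Ambulances that may serve a waiting patient: idle or relocating units.

    Dispatch is mandatory whenever this set is nonempty.
    """
    return [a for a in state.ambulances if a.status == IDLE or a.status == TO_BASE]


def feasible_redeployments(state: SystemState, ambulance: Ambulance, scenario: Scenario) -> list[int]:
    """Bases with a free slot (occupied-or-inbound count below capacity)."""
    bases = scenario.geometry.bases
    out = [b.id for b in bases if state.base_slots[b.id] < b.capacity]
    if not out:
        raise InfeasibleActionError(
            "no base has free capacity; total capacity below fleet size"
        )
    return out


def decision_points(state: SystemState, event_kind: int) -> str:
    """Which decision (if any) an event triggers once applied.

    Call arrival with at least one available ambulance -> dispatch; handover
    completion -> dispatch to the queue head if anyone waits, else redeploy.
    """
    if event_kind == EV_CALL:
        return "dispatch" if any(a.available for a in state.ambulances) else "none"
    if event_kind == EV_HANDOVER:
        return "dispatch" if state.n_waiting else "redeploy"
    return "none"


class SimContext:
    """Per-episode caches shared with policies (read-only)."""

    __slots__ = ("scenario", "bbox", "hospitals_xy", "bases_xy", "speed", "metric",
                 "scene_mean", "p_high_given_hc", "p_high_given_lc", "rli_params")

    def __init__(self, scenario: Scenario):
        self.scenario = scenario
        self.bbox = scenario.geometry.bbox
        self.hospitals_xy = [h.location for h in scenario.geometry.hospitals]
        self.bases_xy = [b.location for b in scenario.geometry.bases]
        self.speed = scenario.travel.hourly_speed_kmh
        self.metric = scenario.travel.metric
        self.scene_mean = scenario.service.scene_mean
        p_h_hc, p_l_lc = scenario.posteriors()
        self.p_high_given_hc = p_h_hc
        self.p_high_given_lc = 1.0 - p_l_lc
        self.rli_params = scenario.rli

    def tt(self, ox: float, oy: float, dx: float, dy: float, clock: float) -> float:
        """Travel time in minutes, speed taken at departure."""
        if self.metric == "manhattan":
            d = abs(dx - ox) + abs(dy - oy)
        else:
            d = math.hypot(dx - ox, dy - oy)
        if d == 0.0:
            return 0.0
        return d / self.speed[int(clock % 1440.0) // 60] * 60.0

    def nearest_hospital(self, x: float, y: float) -> int:
        """Hospital minimizing travel time from a scene (ties: lower id).

        A single scalar speed applies to every leg at a given departure
        instant, so the travel-time argmin equals the distance argmin.
        """
        best, best_d = 0, float("inf")
        for hid, (hx, hy) in enumerate(self.hospitals_xy):
            if self.metric == "manhattan":
                d = abs(hx - x) + abs(hy - y)
            else:
                d = math.hypot(hx - x, hy - y)
            if d < best_d:
                best, best_d = hid, d
        return best


class EpisodeResult:
    """Logs and summary metrics of one simulated episode."""

    def __init__(self, scenario, patients, decisions, calls, warmup_min, horizon_min):
        self.scenario = scenario
        self.patients = patients
        self.decisions = decisions
        self.calls = calls
        self.warmup_min = warmup_min
        self.horizon_min = horizon_min

    def measured_patients(self) -> list[Patient]:
        w = self.warmup_min
        return [p for p in self.patients if p.report_time >= w]

    @property
    def mean_rli(self) -> float:
        ps = self.measured_patients()
        return float(np.mean([p.rli for p in ps])) if ps else 0.0

    @property
    def total_rli(self) -> float:
        return float(sum(p.rli for p in self.measured_patients()))

    @property
    def mean_rt(self) -> float:
        ps = self.measured_patients()
        return float(np.mean([p.rt for p in ps])) if ps else 0.0

    def mean_relocation_time(self) -> float | None:
        """Mean base-arrival minus handover-complete over completed relocations."""
        durs = [d["reloc_time"] for d in self.decisions
                if d["kind"] == "redeploy" and d["completed"] and d["time"] >= self.warmup_min]
        return float(np.mean(durs)) if durs else None

    def patient_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append({
                "call_id": p.id, "report_time": p.report_time, "district": p.district,
                "x": p.x, "y": p.y,
                "actual_severity": "H" if p.actual_high else "L",
                "classified_severity": "H" if p.classified_high else "L",
                "ambulance_id": p.amb_id,
                "ambulance_type": ("ALS" if p.served_by_als else "BLS") if p.served_by_als is not None else None,
                "dispatch_time": p.dispatch_time, "scene_time": p.scene_time,
                "hospital_time": p.hospital_time, "handover_time": p.handover_time,
                "hospital_id": p.hospital_id,
                "rt": p.rt, "rt_pc": p.rt_pc, "rli": p.rli,
                "measured": p.report_time >= self.warmup_min,
            })
        return pd.DataFrame(rows)

    def decision_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.decisions)

    def metrics(self) -> dict:
        ps = self.measured_patients()
        out = {
            "n_patients": len(ps),
            "mean_rli": self.mean_rli,
            "total_rli": self.total_rli,
            "mean_rt": self.mean_rt,
        }
        reloc = self.mean_relocation_time()
        if reloc is not None:
            out["mean_relocation_time"] = reloc
        return out


class _Engine:
    """One episode of the discrete-event simulation."""

    def __init__(self, scenario: Scenario, policy, calls: Sequence[Call],
                 collect: bool = True):
        self.scenario = scenario
        self.policy = policy
        self.calls = calls
        self.collect = collect
        self.ctx = SimContext(scenario)
        self.state = SystemState(scenario)
        self.heap: list = []
        self.seq = 0
        self.decisions: list[dict] = []
        self.completed: list[Patient] = []
        self._call_iter = iter(calls)

    # -- event plumbing -------------------------------------------------

    def _push(self, time: float, kind: int, obj_id: int) -> None:
        heappush(self.heap, (time, kind, self.seq, obj_id))
        self.seq += 1

    def _push_next_call(self) -> None:
        call = next(self._call_iter, None)
        if call is not None:
            self._next_call = call
            self._push(call.time, EV_CALL, call.id)

    # -- actions --------------------------------------------------------

    def _apply_dispatch(self, amb: Ambulance, patient: Patient, clock: float) -> None:
        st = self.state
        if not (amb.status == IDLE or amb.status == TO_BASE):
            raise InfeasibleActionError(
                f"ambulance {amb.id} is {STATUS_NAMES[amb.status]}; only idle or "
                "relocating units may be dispatched")
        if patient.status != WAITING:
            raise InfeasibleActionError(f"patient {patient.id} is not waiting")
        pos = amb.position_at(clock)
        # free the reserved base slot (held while idle at a base or inbound)
        if amb.status == IDLE and amb.at_base is not None:
            st.base_slots[amb.at_base] -= 1
        elif amb.status == TO_BASE:
            st.base_slots[amb.dest_id] -= 1
        st.idle_cells[amb.cell] -= 1
        amb.cell = -1
        amb.at_base = None
        # remove patient from queue and pending counts
        q = st.queue_high if patient.classified_high else st.queue_low
        q.remove(patient.id)
        st.pending_cells[patient.cell] -= 1
        tt = self.ctx.tt(pos[0], pos[1], patient.x, patient.y, clock)
        amb.status = TO_PATIENT
        amb.patient_id = patient.id
        amb.dest_kind = "patient"
        amb.dest_id = patient.id
        amb.leg_start = clock
        amb.leg_dur = tt
        amb.leg_from = pos
        amb.leg_to = (patient.x, patient.y)
        amb.leg_token += 1
        amb.x, amb.y = pos
        patient.status = IN_SERVICE
        patient.amb_id = amb.id
        patient.served_by_als = amb.is_als
        patient.dispatch_time = clock
        self._push(clock + tt, EV_SCENE, amb.id)

    def _apply_redeploy(self, amb: Ambulance, base_id: int, clock: float) -> None:
        st = self.state
        base = self.scenario.geometry.bases[base_id]
        if st.base_slots[base_id] >= base.capacity:
            raise InfeasibleActionError(f"base {base_id} has no free slot")
        bx, by = base.location
        tt = self.ctx.tt(amb.x, amb.y, bx, by, clock)
        # relocating units keep counting as available; their aggregation cell
        # moves to the destination base's cell
        st.idle_cells[amb.cell] -= 1
        amb.cell = cell_index(bx, by, self.ctx.bbox)
        st.idle_cells[amb.cell] += 1
        st.base_slots[base_id] += 1
        amb.status = TO_BASE
        amb.dest_kind = "base"
        amb.dest_id = base_id
        amb.leg_start = clock
        amb.leg_dur = tt
        amb.leg_from = (amb.x, amb.y)
        amb.leg_to = (bx, by)
        amb.at_base = None
        amb.leg_token += 1
        self._push(clock + tt, EV_BASE, (amb.id, amb.leg_token))
        if self.collect:
            row = {"time": clock, "kind": "redeploy", "ambulance_id": amb.id,
                   "base_id": base_id, "n_candidates": None, "reloc_time": tt,
                   "completed": False}
            amb._reloc_row = row
            self.decisions.append(row)

    # -- decisions ------------------------------------------------------

    def _decide_dispatch(self, patient: Patient, clock: float) -> None:
        st = self.state
        cands = feasible_dispatches(st, patient)
        req = DecisionRequest("dispatch", patient=patient, candidates=cands)
        amb = self.policy.decide(st, req, self.ctx)
        if amb not in cands:
            raise InfeasibleActionError("policy chose a non-candidate ambulance")
        if self.collect:
            self._log_dispatch(patient, cands, amb, clock)
        self._apply_dispatch(amb, patient, clock)

    def _decide_redeploy(self, amb: Ambulance, clock: float) -> None:
        st = self.state
        bases = feasible_redeployments(st, amb, self.scenario)
        req = DecisionRequest("redeploy", ambulance=amb, candidates=bases)
        base_id = self.policy.decide(st, req, self.ctx)
        if base_id not in bases:
            raise InfeasibleActionError("policy chose a base without free capacity")
        self._apply_redeploy(amb, base_id, clock)

    def _log_dispatch(self, patient, cands, chosen, clock) -> None:
        tts = {}
        for a in cands:
            pos = a.position_at(clock)
            tts[a.id] = self.ctx.tt(pos[0], pos[1], patient.x, patient.y, clock)
        nearest = min(cands, key=lambda a: (tts[a.id], a.id))
        als = [a for a in cands if a.is_als]
        nearest_als = min(als, key=lambda a: (tts[a.id], a.id)) if als else None
        self.decisions.append({
            "time": clock, "kind": "dispatch", "patient_id": patient.id,
            "classified_severity": "H" if patient.classified_high else "L",
            "ambulance_id": chosen.id,
            "chosen_is_als": chosen.is_als,
            "chosen_tt": tts[chosen.id],
            "n_candidates": len(cands),
            "n_als_candidates": len(als),
            "nearest_id": nearest.id,
            "nearest_is_als": nearest.is_als,
            "nearest_tt": tts[nearest.id],
            "chosen_is_nearest": chosen.id == nearest.id,
            "chosen_is_nearest_als": nearest_als is not None and chosen.id == nearest_als.id,
            "base_id": None, "reloc_time": None, "completed": None,
        })

    # -- event handlers -------------------------------------------------

    def run(self) -> None:
        st = self.state
        self._push_next_call()
        heap = self.heap
        while heap:
            time, kind, _seq, obj_id = heappop(heap)
            st.clock = time
            if kind == EV_CALL:
                call = self._next_call
                self._push_next_call()
                p = Patient(call, cell_index(call.x, call.y, self.ctx.bbox))
                st.patients[p.id] = p
                # pre-decision state: patient enters the waiting queue
                (st.queue_high if p.classified_high else st.queue_low).append(p.id)
                st.pending_cells[p.cell] += 1
                if any(a.available for a in st.ambulances):
                    # a delay in allocation is not allowed
                    self._decide_dispatch(p, time)
            elif kind == EV_SCENE:
                amb = st.ambulances[obj_id]
                p = st.patients[amb.patient_id]
                amb.x, amb.y = p.x, p.y
                amb.status = ON_SCENE
                amb.leg_dur = 0.0
                p.scene_time = time
                p.rt = time - p.report_time
                # actual severity becomes known at the scene; transport to the
                # nearest hospital after on-scene care
                hid = self.ctx.nearest_hospital(p.x, p.y)
                depart = time + p.scene_service
                hx, hy = self.ctx.hospitals_xy[hid]
                tt = self.ctx.tt(p.x, p.y, hx, hy, depart)
                p.hospital_id = hid
                amb.dest_kind = "hospital"
                amb.dest_id = hid
                amb.leg_start = depart
                amb.leg_dur = tt
                amb.leg_from = (p.x, p.y)
                amb.leg_to = (hx, hy)
                amb.status = TO_HOSPITAL
                self._push(depart + tt, EV_HOSPITAL, amb.id)
            elif kind == EV_HOSPITAL:
                amb = st.ambulances[obj_id]
                p = st.patients[amb.patient_id]
                hx, hy = self.ctx.hospitals_xy[p.hospital_id]
                amb.x, amb.y = hx, hy
                amb.status = AT_HOSPITAL
                amb.leg_dur = 0.0
                p.hospital_time = time
                self._push(time + p.hospital_service, EV_HANDOVER, amb.id)
            elif kind == EV_HANDOVER:
                amb = st.ambulances[obj_id]
                p = st.patients[amb.patient_id]
                p.handover_time = time
                p.status = COMPLETED
                p.rt_pc = rt_pc(p, amb.is_als)
                p.rli = rli(p.rt_pc, p.actual_high, self.ctx.rli_params)
                self.completed.append(p)
                del st.patients[p.id]
                amb.patient_id = None
                # freed unit counts as idle at the hospital until the decision
                amb.status = IDLE
                amb.at_base = None
                amb.cell = cell_index(amb.x, amb.y, self.ctx.bbox)
                st.idle_cells[amb.cell] += 1
                if st.n_waiting:
                    self._decide_dispatch(st.queue_head(), time)
                else:
                    self._decide_redeploy(amb, time)
            else:  # EV_BASE
                aid, token = obj_id
                amb = st.ambulances[aid]
                if amb.status == TO_BASE and amb.leg_token == token:
                    bx, by = self.ctx.bases_xy[amb.dest_id]
                    amb.x, amb.y = bx, by
                    amb.status = IDLE
                    amb.at_base = amb.dest_id
                    amb.leg_dur = 0.0
                    if amb._reloc_row is not None:
                        amb._reloc_row["completed"] = True
                        amb._reloc_row = None
                # else: the unit was re-dispatched mid-relocation; stale event


def run_episode(
    scenario: Scenario,
    policy,
    horizon_days: float = 7.0,
    warmup_days: float = 1.0,
    streams: CallStreams | None = None,
    calls: Sequence[Call] | None = None,
    collect: bool = True,
) -> EpisodeResult:
    """Simulate one episode and return per-patient and per-decision logs.

    Calls arriving during the warm-up period are simulated but excluded from
    the metrics; every call in ``[warmup, warmup + horizon)`` is followed to
    completion.  Given identical scenario, policy and streams (or an explicit
    ``calls`` table) the logs are bit-identical.
    """
    if horizon_days <= 0 or warmup_days < 0:
        raise ValueError("horizon > 0 and warmup >= 0 required")
    warmup_min = warmup_days * 1440.0
    horizon_min = horizon_days * 1440.0
    if calls is None:
        if streams is None:
            streams = CallStreams(scenario.seed)
        calls = generate_calls(scenario, warmup_min + horizon_min, streams)
    if hasattr(policy, "begin_episode"):
        policy.begin_episode(scenario)
    eng = _Engine(scenario, policy, calls, collect=collect)
    eng.run()
    result = EpisodeResult(scenario, eng.completed, eng.decisions, calls,
                           warmup_min, horizon_min)
    if hasattr(policy, "end_episode"):
        policy.end_episode(result)
    return result
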