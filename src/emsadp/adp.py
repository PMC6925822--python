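"""Mini-batch monotone approximate dynamic programming.

The value function of the semi-MDP is approximated by a lookup table over a
19-dimensional aggregated state: for each of the nine 3x3 spatial cells the
number of idle-or-relocating ambulances and the number of patients awaiting
assignment, plus a time-zone index (1: 01:00-08:00, 2: 08:00-11:00,
3: 11:00-01:00).  Table entries are updated along simulated trajectories
with harmonic step sizes 1/n (n = cumulative visits to the entry), using the
post-decision state: the sampled value at decision t updates the aggregate
of decision t-1's post-decision state.

A dominance relation orders aggregated states within a time zone: a state
with at least as many available ambulances in every cell and at most as many
pending patients in every cell is at least as good, i.e. its value (a
discounted RLI sum to be minimized) must not be larger.  The monotone
projection operator repairs the table against a reference point; at the end
of every training iteration the projection is applied from a visit-weighted
random mini-batch of ten reference states per time zone.

Relocating ambulances are counted in the cell of their destination base.
Counting them at their interpolated position would give every redeployment
action the same post-decision aggregate — the current position at the
decision instant does not depend on the chosen base — and the learner could
then never distinguish redeployment options.
"""

from __future__ import annotations

import copy
import json
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .policies import Action, dispatch_contribution, _dispatch_tt
from .scenario import CallStreams, Scenario
from .simulator import (
    IDLE,
    TO_BASE,
    WAITING,
    DecisionRequest,
    SimContext,
    SystemState,
    cell_index,
    run_episode,
)

__all__ = [
    "N_CELLS",
    "KEY_DIM",
    "time_zone",
    "aggregate",
    "post_decision",
    "dominates",
    "ValueTable",
    "update_value",
    "project_monotone",
    "minibatch_project",
    "adp_action",
    "ADPPolicy",
    "ADPLearner",
    "TrainResult",
    "train",
]

N_CELLS = 9
KEY_DIM = 2 * N_CELLS + 1


def time_zone(clock: float) -> int:
    """Time-zone index of a clock time (half-open intervals, minutes).

    1: 01:00-08:00, 2: 08:00-11:00, 3: 11:00-01:00 (wrapping midnight).
    """
    m = clock % 1440.0
    if 60.0 <= m < 480.0:
        return 1
    if 480.0 <= m < 660.0:
        return 2
    return 3


def aggregate(state: SystemState, clock: float, bbox) -> tuple:
    """Aggregated lookup key recomputed from the raw state.

    Idle ambulances count in the cell of their position, relocating ones in
    the cell of their destination base, waiting patients in the cell of
    their location.  The engine maintains these counts incrementally; this
    recomputation is the reference definition.
    """
    idle = [0] * N_CELLS
    pend = [0] * N_CELLS
    for a in state.ambulances:
        if a.status == IDLE:
            idle[cell_index(a.x, a.y, bbox)] += 1
        elif a.status == TO_BASE:
            tx, ty = a.leg_to
            idle[cell_index(tx, ty, bbox)] += 1
    for pid in list(state.queue_high) + list(state.queue_low):
        p = state.patients[pid]
        pend[cell_index(p.x, p.y, bbox)] += 1
    return (*idle, *pend, time_zone(clock))


def post_decision(state: SystemState, action: Action, ctx: SimContext) -> SystemState:
    """State immediately after applying an action, clock unchanged.

    Returns a deep copy; no external information arrives and no events are
    scheduled.  Used for inspection and testing — the hot path computes the
    post-decision aggregate key directly from the incremental counts.
    """
    new = copy.deepcopy(state)
    amb = new.ambulances[action.ambulance.id]
    if action.kind == "dispatch":
        p = new.patients[action.patient.id]
        if p.status != WAITING or not (amb.status == IDLE or amb.status == TO_BASE):
            raise ValueError("infeasible dispatch")
        q = new.queue_high if p.classified_high else new.queue_low
        q.remove(p.id)
        new.pending_cells[p.cell] -= 1
        new.idle_cells[amb.cell] -= 1
        if amb.status == IDLE and amb.at_base is not None:
            new.base_slots[amb.at_base] -= 1
        elif amb.status == TO_BASE:
            new.base_slots[amb.dest_id] -= 1
        pos = amb.position_at(new.clock)
        amb.x, amb.y = pos
        amb.cell = -1
        amb.at_base = None
        amb.status = 1  # to-patient
        amb.dest_kind = "patient"
        amb.dest_id = p.id
        p.status = 1  # in-service
        p.amb_id = amb.id
    elif action.kind == "redeploy":
        b = action.base_id
        bx, by = ctx.bases_xy[b]
        new.idle_cells[amb.cell] -= 1
        amb.cell = cell_index(bx, by, ctx.bbox)
        new.idle_cells[amb.cell] += 1
        new.base_slots[b] += 1
        amb.status = TO_BASE
        amb.dest_kind = "base"
        amb.dest_id = b
        amb.at_base = None
    else:  # no-op request
        pass
    return new


def dispatch_post_key(state: SystemState, amb, patient, zone: int) -> tuple:
    """Post-decision aggregate key of a dispatch, from incremental counts."""
    idle = list(state.idle_cells)
    idle[amb.cell] -= 1
    pend = list(state.pending_cells)
    pend[patient.cell] -= 1
    return (*idle, *pend, zone)


def redeploy_post_key(state: SystemState, amb, base_cell: int, zone: int) -> tuple:
    idle = list(state.idle_cells)
    idle[amb.cell] -= 1
    idle[base_cell] += 1
    return (*idle, *state.pending_cells, zone)


def dominates(s: tuple, s_other: tuple) -> bool:
    """Whether aggregated state ``s`` is at least as favourable as ``s_other``.

    Requires the same time zone (states in different zones are incomparable
    and the result is False).  ``s`` dominates when it has >= available
    ambulances in every cell and <= pending patients in every cell.
    """
    if s[-1] != s_other[-1]:
        return False
    for i in range(N_CELLS):
        if s[i] < s_other[i]:
            return False
    for i in range(N_CELLS, 2 * N_CELLS):
        if s[i] > s_other[i]:
            return False
    return True


class _ZoneStore:
    """Growable arrays of (key, value, visits) for one time zone."""

    __slots__ = ("index", "keys", "values", "visits", "n")

    def __init__(self, dim: int = KEY_DIM):
        self.index: dict[tuple, int] = {}
        cap = 256
        self.keys = np.zeros((cap, dim), dtype=np.int32)
        self.values = np.zeros(cap)
        self.visits = np.zeros(cap, dtype=np.int64)
        self.n = 0

    def _grow(self) -> None:
        cap = len(self.values) * 2
        self.keys = np.resize(self.keys, (cap, self.keys.shape[1]))
        self.values = np.resize(self.values, cap)
        self.visits = np.resize(self.visits, cap)

    def row(self, key: tuple, create: bool = False) -> int | None:
        idx = self.index.get(key)
        if idx is None and create:
            if self.n == len(self.values):
                self._grow()
            idx = self.n
            key = tuple(int(v) for v in key)  # normalize foreign integer types
            self.index[key] = idx
            self.keys[idx] = key
            self.values[idx] = 0.0
            self.visits[idx] = 0
            self.n += 1
        return idx


class ValueTable:
    """Lookup table mapping aggregated states to approximate values.

    Unseen states have value 0 (the optimistic initialization that drives
    exploration in a minimization problem).  Stores per-state cumulative
    visit counts for the harmonic step sizes and the visit-weighted
    mini-batch sampling.
    """

    def __init__(self) -> None:
        self._zones = {1: _ZoneStore(), 2: _ZoneStore(), 3: _ZoneStore()}

    # -- queries --------------------------------------------------------

    def get(self, key: tuple) -> float:
        store = self._zones[key[-1]]
        idx = store.index.get(key)
        return float(store.values[idx]) if idx is not None else 0.0

    def visit_count(self, key: tuple) -> int:
        store = self._zones[key[-1]]
        idx = store.index.get(key)
        return int(store.visits[idx]) if idx is not None else 0

    @property
    def n_states(self) -> int:
        return sum(z.n for z in self._zones.values())

    def items(self):
        for z in self._zones.values():
            for key, idx in z.index.items():
                yield key, float(z.values[idx]), int(z.visits[idx])

    # -- updates --------------------------------------------------------

    def update(self, key: tuple, v_hat: float) -> float:
        """Harmonic-step update: n += 1, V <- (1 - 1/n) V + (1/n) v_hat."""
        if not np.isfinite(v_hat):
            raise ValueError("v_hat must be finite")
        store = self._zones[key[-1]]
        idx = store.row(key, create=True)
        store.visits[idx] += 1
        delta = 1.0 / store.visits[idx]
        store.values[idx] = (1.0 - delta) * store.values[idx] + delta * v_hat
        return float(store.values[idx])

    def project(self, ref_key: tuple, ref_value: float) -> None:
        """Monotone projection against one reference point.

        Every stored state dominating the reference is capped at the
        reference value; every state the reference dominates is floored at
        it; the reference state itself is set to the reference value.
        """
        store = self._zones[ref_key[-1]]
        ref_idx = store.row(ref_key, create=True)
        n = store.n
        if n > 1:
            keys = store.keys[:n]
            ref = np.asarray(ref_key, dtype=np.int32)
            idle = keys[:, :N_CELLS]
            pend = keys[:, N_CELLS:2 * N_CELLS]
            dom_ref = ((idle >= ref[:N_CELLS]).all(axis=1)
                       & (pend <= ref[N_CELLS:2 * N_CELLS]).all(axis=1))
            ref_dom = ((idle <= ref[:N_CELLS]).all(axis=1)
                       & (pend >= ref[N_CELLS:2 * N_CELLS]).all(axis=1))
            vals = store.values[:n]
            np.minimum(vals, ref_value, out=vals, where=dom_ref)
            np.maximum(vals, ref_value, out=vals, where=ref_dom)
        store.values[ref_idx] = ref_value

    def minibatch_project(self, rng: np.random.Generator, per_zone: int = 10) -> int:
        """Visit-weighted stochastic projection pass; returns #references used.

        Per time zone, samples ``min(per_zone, #visited)`` distinct visited
        states with probability proportional to their visit counts and
        applies the monotone projection sequentially with each sampled state
        and its current value (re-read at application time) as reference.
        """
        n_refs = 0
        for zone in (1, 2, 3):
            store = self._zones[zone]
            visited = np.flatnonzero(store.visits[:store.n] > 0)
            if len(visited) == 0:
                continue
            w = store.visits[visited].astype(float)
            k = min(per_zone, len(visited))
            chosen = rng.choice(visited, size=k, replace=False, p=w / w.sum())
            for idx in chosen:
                key = tuple(int(v) for v in store.keys[idx])
                self.project(key, float(store.values[store.index[key]]))
                n_refs += 1
        return n_refs

    # -- serialization --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [(*key, value, visits) for key, value, visits in self.items()]
        cols = [f"k{i}" for i in range(KEY_DIM)] + ["value", "visits"]
        return pd.DataFrame(rows, columns=cols)

    def save(self, path) -> None:
        path = str(path)
        if path.endswith(".json"):
            payload = [{"key": list(k), "value": v, "visits": n}
                       for k, v, n in self.items()]
            with open(path, "w") as fh:
                json.dump(payload, fh)
        else:
            self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "ValueTable":
        path = str(path)
        table = cls()
        if path.endswith(".json"):
            with open(path) as fh:
                for row in json.load(fh):
                    key = tuple(int(v) for v in row["key"])
                    store = table._zones[key[-1]]
                    idx = store.row(key, create=True)
                    store.values[idx] = float(row["value"])
                    store.visits[idx] = int(row["visits"])
        else:
            df = pd.read_csv(path, float_precision="round_trip")
            kcols = [f"k{i}" for i in range(KEY_DIM)]
            for _, row in df.iterrows():
                key = tuple(int(row[c]) for c in kcols)
                store = table._zones[key[-1]]
                idx = store.row(key, create=True)
                store.values[idx] = float(row["value"])
                store.visits[idx] = int(row["visits"])
        return table


def update_value(table: ValueTable, key: tuple, v_hat: float) -> ValueTable:
    """Functional wrapper over :meth:`ValueTable.update` (mutates and returns)."""
    table.update(key, v_hat)
    return table


def project_monotone(table: ValueTable, ref_key: tuple, ref_value: float) -> ValueTable:
    """Functional wrapper over :meth:`ValueTable.project` (mutates and returns)."""
    table.project(ref_key, ref_value)
    return table


def minibatch_project(table: ValueTable, rng: np.random.Generator,
                      per_zone: int = 10) -> ValueTable:
    table.minibatch_project(rng, per_zone=per_zone)
    return table


# ---------------------------------------------------------------------------
# Acting and learning
# ---------------------------------------------------------------------------


def _argmin_action(state: SystemState, request: DecisionRequest, ctx: SimContext,
                   table: ValueTable, gamma: float):
    """Best action, its sampled value and post-decision key.

    Minimizes contribution + gamma * V(aggregate(post-decision)); ties break
    by shorter travel time then lower ambulance/base id.
    """
    if not request.candidates:
        raise ValueError("empty feasible set")
    clock = state.clock
    zone = time_zone(clock)
    best = None
    if request.kind == "dispatch":
        p = request.patient
        for amb in request.candidates:
            tt = _dispatch_tt(ctx, amb, p, clock)
            c = dispatch_contribution(ctx, amb, p, clock, tt)
            key = dispatch_post_key(state, amb, p, zone)
            q = c + gamma * table.get(key)
            order = (q, tt, amb.id)
            if best is None or order < best[0]:
                best = (order, amb, key)
        (q, _tt, _id), amb, key = best
        return Action("dispatch", amb, patient=p), q, key
    amb = request.ambulance
    for b in request.candidates:
        bx, by = ctx.bases_xy[b]
        tt = ctx.tt(amb.x, amb.y, bx, by, clock)
        key = redeploy_post_key(state, amb, cell_index(bx, by, ctx.bbox), zone)
        q = gamma * table.get(key)
        order = (q, tt, b)
        if best is None or order < best[0]:
            best = (order, b, key)
    (q, _tt, _b), b, key = best
    return Action("redeploy", amb, base_id=b), q, key


def adp_action(state: SystemState, request: DecisionRequest, ctx: SimContext,
               table: ValueTable, gamma: float) -> Action:
    """Action minimizing contribution + gamma * V(post-decision aggregate)."""
    action, _q, _key = _argmin_action(state, request, ctx, table, gamma)
    return action


class ADPPolicy:
    """Frozen policy acting greedily with respect to a learned value table."""

    name = "adp"

    def __init__(self, table: ValueTable, gamma: float = 0.9):
        self.table = table
        self.gamma = gamma

    def decide(self, state, request, ctx):
        act = adp_action(state, request, ctx, self.table, self.gamma)
        return act.ambulance if act.kind == "dispatch" else act.base_id


class ADPLearner:
    """Learning policy: acts by the table argmin and updates it on the fly.

    The sampled value of the current decision updates the post-decision
    aggregate of the previous decision within the same episode.
    """

    name = "adp-learner"

    def __init__(self, table: ValueTable, gamma: float = 0.9):
        self.table = table
        self.gamma = gamma
        self._prev_key: tuple | None = None

    def begin_episode(self, scenario) -> None:
        self._prev_key = None

    def decide(self, state, request, ctx):
        act, v_hat, key = _argmin_action(state, request, ctx, self.table, self.gamma)
        if self._prev_key is not None:
            self.table.update(self._prev_key, v_hat)
        self._prev_key = key
        return act.ambulance if act.kind == "dispatch" else act.base_id


@dataclass
class TrainResult:
    table: ValueTable
    curve: np.ndarray              # per-iteration mean RLI
    iterations: int
    gamma: float
    elapsed_s: float = 0.0

    def curve_frame(self, window: int = 100) -> pd.DataFrame:
        """Windowed learning curve: mean RLI per ``window`` iterations."""
        n = len(self.curve)
        rows = []
        for start in range(0, n, window):
            chunk = self.curve[start:start + window]
            rows.append({"iteration": start + len(chunk),
                         "mean_rli": float(np.mean(chunk))})
        return pd.DataFrame(rows)


def train(
    scenario: Scenario,
    iterations: int,
    gamma: float = 0.9,
    seed: int = 0,
    horizon_days: float = 7.0,
    warmup_days: float = 1.0,
    table: ValueTable | None = None,
    per_zone_refs: int = 10,
    time_limit_min: float | None = None,
    calls=None,
) -> TrainResult:
    """Run the mini-batch monotone-ADP learning loop.

    Each iteration simulates one warm-up + horizon episode, acting and
    updating by the post-decision temporal-difference rule, then applies the
    visit-weighted monotone projection mini-batch.  Training stops after
    ``iterations`` episodes or when ``time_limit_min`` of wall-clock time is
    exceeded, whichever comes first.  Returns the table and the
    per-iteration mean-RLI learning curve.

    ``calls`` optionally fixes the episode call table (deterministic
    systems); otherwise each iteration draws fresh streams from ``seed``.
    """
    if iterations < 1:
        raise ValueError("need at least one iteration")
    if table is None:
        table = ValueTable()
    root = np.random.SeedSequence(seed)
    episode_seeds = root.spawn(iterations + 1)
    proj_rng = np.random.Generator(np.random.PCG64(episode_seeds[-1]))
    learner = ADPLearner(table, gamma)
    curve = []
    t0 = _time.perf_counter()
    for n in range(iterations):
        streams = CallStreams(episode_seeds[n]) if calls is None else None
        result = run_episode(scenario, learner, horizon_days=horizon_days,
                             warmup_days=warmup_days, streams=streams,
                             calls=calls, collect=False)
        table.minibatch_project(proj_rng, per_zone=per_zone_refs)
        curve.append(result.mean_rli)
        if time_limit_min is not None and (_time.perf_counter() - t0) / 60.0 >= time_limit_min:
            break
    return TrainResult(table=table, curve=np.asarray(curve),
                       iterations=len(curve), gamma=gamma,
                       elapsed_s=_time.perf_counter() - t0)
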