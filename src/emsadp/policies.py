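"""Dispatch and redeployment policies.

All policies answer the same two questions the engine asks: which available
ambulance serves a waiting patient, and which base a freed ambulance returns
to.  The greedy policy minimizes the one-step expected risk-level-index
contribution of the dispatch (and relocates to the nearest free base); the
myopic policy simply sends the nearest unit; the value-table-driven policy
(:class:`emsadp.adp.ADPPolicy`, re-exported here via :func:`adp_action`)
adds a discounted approximate value of the post-decision state.

The expected contribution of a dispatch weighs the risk-level-index of both
actual severities by the triage posteriors given the classified severity.
The response time is not yet known at decision time, so the deterministic
expected travel time for the ambulance-patient distance stands in for it;
for the basic-life-support/actually-high branch the index runs to hospital
arrival, so the expected on-scene service time and the scene-to-hospital
travel time are added.
"""

from __future__ import annotations

from typing import NamedTuple

from .simulator import (
    Ambulance,
    DecisionRequest,
    Patient,
    SimContext,
    SystemState,
    rli,
)

__all__ = [
    "Action",
    "expected_contribution",
    "greedy_action",
    "myopic_nearest",
    "adp_action",
    "GreedyPolicy",
    "MyopicPolicy",
]


class Action(NamedTuple):
    """A dispatch (ambulance -> patient) or a redeployment (ambulance -> base)."""

    kind: str                      # "dispatch" | "redeploy"
    ambulance: Ambulance
    patient: Patient | None = None
    base_id: int | None = None


def _dispatch_tt(ctx: SimContext, amb: Ambulance, patient: Patient, clock: float) -> float:
    pos = amb.position_at(clock)
    return ctx.tt(pos[0], pos[1], patient.x, patient.y, clock)


def dispatch_contribution(ctx: SimContext, amb: Ambulance, patient: Patient,
                          clock: float, tt: float) -> float:
    """Posterior-weighted expected RLI of dispatching ``amb`` to ``patient``.

    ``tt`` is the expected travel time of this dispatch; any time the patient
    has already spent waiting is part of the expected response time.
    """
    rt_hat = (clock - patient.report_time) + tt
    w_h = ctx.p_high_given_hc if patient.classified_high else ctx.p_high_given_lc
    params = ctx.rli_params
    if amb.is_als:
        high_branch = rli(rt_hat, True, params)
    else:
        # proper care for an actually high-risk patient in a BLS unit only
        # starts at the hospital: extend by expected on-scene care and the
        # scene-to-nearest-hospital leg
        hx, hy = ctx.hospitals_xy[ctx.nearest_hospital(patient.x, patient.y)]
        tt_h = ctx.tt(patient.x, patient.y, hx, hy, clock)
        high_branch = rli(rt_hat + ctx.scene_mean + tt_h, True, params)
    return w_h * high_branch + (1.0 - w_h) * rli(rt_hat, False, params)


def expected_contribution(state: SystemState, action: Action, ctx: SimContext) -> float:
    """One-step expected RLI of an action; redeployments contribute zero."""
    if action.kind != "dispatch":
        return 0.0
    tt = _dispatch_tt(ctx, action.ambulance, action.patient, state.clock)
    return dispatch_contribution(ctx, action.ambulance, action.patient, state.clock, tt)


def greedy_action(state: SystemState, request: DecisionRequest, ctx: SimContext) -> Action:
    """Minimize the immediate expected contribution.

    Dispatch: argmin of the expected RLI over the candidate ambulances, ties
    broken by shorter travel time then lower ambulance id.  Redeployment has
    zero one-step contribution, so the greedy rule is the nearest free base
    (it returns the unit to idle as quickly as possible), ties to lower id.
    """
    if not request.candidates:
        raise ValueError("empty feasible set")
    clock = state.clock
    if request.kind == "dispatch":
        p = request.patient
        best = None
        for amb in request.candidates:
            tt = _dispatch_tt(ctx, amb, p, clock)
            c = dispatch_contribution(ctx, amb, p, clock, tt)
            key = (c, tt, amb.id)
            if best is None or key < best[0]:
                best = (key, amb)
        return Action("dispatch", best[1], patient=p)
    amb = request.ambulance
    best = None
    for b in request.candidates:
        bx, by = ctx.bases_xy[b]
        tt = ctx.tt(amb.x, amb.y, bx, by, clock)
        key = (tt, b)
        if best is None or key < best[0]:
            best = (key, b)
    return Action("redeploy", amb, base_id=best[1])


def myopic_nearest(state: SystemState, request: DecisionRequest, ctx: SimContext) -> Action:
    """Nearest available ambulance / nearest free base, ties to lower id."""
    if not request.candidates:
        raise ValueError("empty feasible set")
    clock = state.clock
    if request.kind == "dispatch":
        p = request.patient
        best = min(request.candidates,
                   key=lambda a: (_dispatch_tt(ctx, a, p, clock), a.id))
        return Action("dispatch", best, patient=p)
    amb = request.ambulance
    best = min(request.candidates,
               key=lambda b: (ctx.tt(amb.x, amb.y, ctx.bases_xy[b][0],
                                     ctx.bases_xy[b][1], clock), b))
    return Action("redeploy", amb, base_id=best)


def adp_action(state: SystemState, request: DecisionRequest, ctx: SimContext,
               table, gamma: float) -> Action:
    """Value-table action: argmin of contribution + gamma * V(post-decision).

    Thin delegate to :func:`emsadp.adp.adp_action`; with an all-zero table it
    coincides with :func:`greedy_action` on dispatches.
    """
    from .adp import adp_action as _impl

    return _impl(state, request, ctx, table, gamma)


class GreedyPolicy:
    """Expected-contribution greedy dispatch, nearest-base redeployment."""

    name = "greedy"

    def decide(self, state: SystemState, request: DecisionRequest, ctx: SimContext):
        act = greedy_action(state, request, ctx)
        return act.ambulance if act.kind == "dispatch" else act.base_id


class MyopicPolicy:
    """Nearest-ambulance dispatch, nearest-base redeployment."""

    name = "myopic"

    def decide(self, state: SystemState, request: DecisionRequest, ctx: SimContext):
        act = myopic_nearest(state, request, ctx)
        return act.ambulance if act.kind == "dispatch" else act.base_id
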