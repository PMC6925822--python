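"""An enumerable single-ambulance micro-system for validating the learner.

One ALS ambulance, two bases, two call sites and fully deterministic
dynamics: high-risk calls arrive every hour at an eastern site, low-risk
calls every three hours at a western site, service times are constant and
severity classification is error-free.  With deterministic inter-arrival
and service times the long-run cost of any stationary redeployment rule can
be computed exactly by simulation, and the space of stationary rules (which
base to return to, possibly depending on the site just served) is small
enough to enumerate exhaustively.  The mini-batch monotone-ADP learner is
expected to reach the cost of the best stationary rule on this system.

The geometry is tuned so that the two rules genuinely differ: the western
base sits next to the hospital (the quickest way to become idle, i.e. the
greedy relocation), while the eastern base is the only position from which
the hourly high-risk calls can be reached inside the response-time
threshold.
"""

from __future__ import annotations

import itertools

import numpy as np

from .scenario import (
    Base,
    Call,
    DemandModel,
    District,
    FleetConfig,
    Geometry,
    Hospital,
    RLIParams,
    Scenario,
    ServiceModel,
    TravelModel,
    TriageModel,
)
from .simulator import run_episode

__all__ = [
    "SITE_WEST",
    "SITE_EAST",
    "build_toy_scenario",
    "toy_calls",
    "FixedRedeployPolicy",
    "enumerate_stationary_policies",
    "evaluate_policy",
]

SITE_WEST = (1.5, 4.5)   # low-risk calls, every 3 h
SITE_EAST = (8.5, 4.5)   # high-risk calls, every 1 h
_HOSPITAL = (4.5, 4.5)
_BASE_W = (4.0, 4.5)     # next to the hospital
_BASE_E = (6.5, 4.5)     # covers the eastern site within the threshold


def build_toy_scenario() -> Scenario:
    """1 ALS ambulance, 2 bases, 2 call sites, constant 30 km/h, fixed services."""
    side = 9.0
    cell = side / 3.0
    districts = tuple(
        District(j * 3 + i, (i * cell, j * cell, (i + 1) * cell, (j + 1) * cell), 1.0)
        for j in range(3) for i in range(3)
    )
    geometry = Geometry(
        bbox=(0.0, 0.0, side, side),
        bases=(Base(0, _BASE_W), Base(1, _BASE_E)),
        hospitals=(Hospital(0, _HOSPITAL),),
        districts=districts,
    )
    return Scenario(
        geometry=geometry,
        demand=DemandModel(daily_calls=32.0, hourly_profile=tuple([1.0] * 24),
                           prior_high=0.75),
        triage=TriageModel(alpha=0.0, beta=0.0),
        travel=TravelModel(hourly_speed_kmh=tuple([30.0] * 24)),
        service=ServiceModel(scene_scale=1.0, scene_shape=10.0,
                             hospital_scale=2.0, hospital_shape=5.0,
                             deterministic=True),
        rli=RLIParams(),
        fleet=FleetConfig(n_ambulances=1, als_ratio=1.0, initial_bases=(0,)),
        seed=0,
        name="toy",
    )


def toy_calls(horizon_days: float) -> list[Call]:
    """Deterministic call schedule over ``[0, horizon_days)``.

    High-risk calls at the eastern site on the hour (offset 60 min),
    low-risk calls at the western site every 180 min (offset 30 min);
    on-scene service 10 min, hospital handover 10 min for every call.
    """
    horizon = horizon_days * 1440.0
    events = []
    t = 60.0
    while t < horizon:
        events.append((t, SITE_EAST, True))
        t += 60.0
    t = 30.0
    while t < horizon:
        events.append((t, SITE_WEST, False))
        t += 180.0
    events.sort()
    out = []
    for i, (time, (x, y), high) in enumerate(events):
        out.append(Call(i, time, x, y, district=0, actual_high=high,
                        classified_high=high, scene_service=10.0,
                        hospital_service=10.0))
    return out


class FixedRedeployPolicy:
    """Stationary rule: dispatch is forced (one ambulance); redeploy by rule.

    ``rule`` maps the classified severity of the last served patient
    (``True`` = high) to a base id; a constant rule uses the same base for
    both.
    """

    def __init__(self, rule: dict[bool, int]):
        self.rule = dict(rule)
        self.name = f"fixed-{self.rule[True]}{self.rule[False]}"
        self._last_high = True

    def decide(self, state, request, ctx):
        if request.kind == "dispatch":
            p = request.patient
            self._last_high = p.classified_high
            return min(request.candidates, key=lambda a: a.id)
        base = self.rule[self._last_high]
        if base in request.candidates:
            return base
        return request.candidates[0]


def evaluate_policy(policy, horizon_days: float = 3.0, warmup_days: float = 0.5) -> float:
    """Long-run mean RLI of a policy on the deterministic toy schedule."""
    scenario = build_toy_scenario()
    calls = toy_calls(warmup_days + horizon_days)
    result = run_episode(scenario, policy, horizon_days=horizon_days,
                         warmup_days=warmup_days, calls=calls)
    return result.mean_rli


def enumerate_stationary_policies(horizon_days: float = 3.0,
                                  warmup_days: float = 0.5) -> dict[str, float]:
    """Mean RLI of every stationary redeployment rule, exhaustively.

    The rule space is every mapping {last severity -> base}: four rules,
    including the two constant ones.
    """
    out = {}
    for hi, lo in itertools.product((0, 1), repeat=2):
        pol = FixedRedeployPolicy({True: hi, False: lo})
        out[pol.name] = evaluate_policy(pol, horizon_days, warmup_days)
    return out
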