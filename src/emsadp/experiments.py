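"""Policy comparison and factorial experiments.

Policies are compared replication by replication under common random
numbers: within a replication every policy faces the identical call stream
(occurrence times, locations, actual and classified severities) and the
identical per-call service-time draws, so differences in mean RLI are due to
the decisions alone and a paired t-test applies.

Three operational indices summarise how a policy dispatches:

* FHI (future orientation, classified-high) — among dispatches to a
  classified-high patient with at least two available units including an
  ALS, the fraction where neither the nearest ALS nor the nearest unit
  overall was sent.
* PLI (present orientation, classified-low) — among dispatches to a
  classified-low patient where the nearest available unit is an ALS and
  alternatives exist, the fraction where that nearest ALS was sent.
* IAI (ALS inefficiency) — the fraction of classified-low dispatches served
  by an ALS.

"Nearest" is resolved by expected travel time at the decision instant, ties
to the lower ambulance id, consistently with the dispatch rules themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scenario import CallStreams, Scenario, default_seoul_like_scenario, generate_calls
from .simulator import EpisodeResult, run_episode

__all__ = [
    "ExperimentGrid",
    "PairedResult",
    "crn_compare",
    "fhi",
    "pli",
    "iai",
    "mean_relocation_time",
    "factorial_run",
    "summarize_cells",
    "main_effects",
]


def fhi(decisions: pd.DataFrame) -> float | None:
    """Future-orientation index for classified-high dispatches; None if no
    eligible decision exists."""
    if len(decisions) == 0:
        return None
    d = decisions
    elig = d[(d["kind"] == "dispatch") & (d["classified_severity"] == "H")
             & (d["n_candidates"] >= 2) & (d["n_als_candidates"] >= 1)]
    if len(elig) == 0:
        return None
    deviation = ~(elig["chosen_is_nearest_als"] | elig["chosen_is_nearest"])
    return float(deviation.mean())


def pli(decisions: pd.DataFrame) -> float | None:
    """Present-orientation index for classified-low dispatches."""
    if len(decisions) == 0:
        return None
    d = decisions
    elig = d[(d["kind"] == "dispatch") & (d["classified_severity"] == "L")
             & (d["n_candidates"] >= 2) & (d["nearest_is_als"] == True)]  # noqa: E712
    if len(elig) == 0:
        return None
    return float(elig["chosen_is_nearest"].mean())


def iai(decisions: pd.DataFrame) -> float | None:
    """Fraction of classified-low dispatches served by an ALS unit."""
    if len(decisions) == 0:
        return None
    d = decisions
    elig = d[(d["kind"] == "dispatch") & (d["classified_severity"] == "L")]
    if len(elig) == 0:
        return None
    return float(elig["chosen_is_als"].mean())


def mean_relocation_time(decisions: pd.DataFrame, warmup_min: float = 0.0) -> float | None:
    """Mean (base arrival - handover completion) over completed relocations."""
    if len(decisions) == 0:
        return None
    d = decisions
    elig = d[(d["kind"] == "redeploy") & (d["completed"] == True)  # noqa: E712
             & (d["time"] >= warmup_min)]
    if len(elig) == 0:
        return None
    return float(elig["reloc_time"].mean())


class CRNBreachError(RuntimeError):
    """Call streams diverged between policies within a replication."""


def _episode_metrics(result: EpisodeResult) -> dict:
    decisions = result.decision_frame()
    return {
        "mean_rli": result.mean_rli,
        "mean_rt": result.mean_rt,
        "n_patients": len(result.measured_patients()),
        "fhi": fhi(decisions),
        "pli": pli(decisions),
        "iai": iai(decisions),
        "reloc_time": mean_relocation_time(decisions, result.warmup_min),
    }


@dataclass
class PairedResult:
    """Per-replication metrics for each policy on identical CRN streams."""

    frame: pd.DataFrame          # columns: rep, policy, mean_rli, ...
    policies: tuple[str, ...]

    def per_policy(self, metric: str = "mean_rli") -> pd.DataFrame:
        return self.frame.pivot(index="rep", columns="policy", values=metric)

    def differences(self, a: str, b: str, metric: str = "mean_rli") -> np.ndarray:
        wide = self.per_policy(metric)
        return (wide[a] - wide[b]).to_numpy()

    def paired_t(self, a: str, b: str, metric: str = "mean_rli",
                 alternative: str = "two-sided") -> tuple[float, float]:
        """Paired t-test of policy ``a`` vs ``b``; returns (t, p).

        ``alternative='less'`` tests whether ``a``'s metric is smaller.
        """
        wide = self.per_policy(metric)
        res = stats.ttest_rel(wide[a], wide[b], alternative=alternative)
        return float(res.statistic), float(res.pvalue)

    def mean(self, policy: str, metric: str = "mean_rli") -> float:
        return float(self.per_policy(metric)[policy].mean())


def crn_compare(
    scenario: Scenario,
    policies: Mapping[str, object],
    replications: int = 30,
    seed: int = 0,
    horizon_days: float = 7.0,
    warmup_days: float = 1.0,
) -> PairedResult:
    """Run every policy on the same per-replication call streams.

    The call table (arrivals and service draws) is generated once per
    replication and shared by every policy, so the synchronization of the
    common-random-number streams is exact by construction; the call logs are
    still compared defensively and a mismatch raises :class:`CRNBreachError`.
    """
    if len(policies) < 1:
        raise ValueError("need at least one policy")
    if replications < 2:
        raise ValueError("need >= 2 replications for paired tests")
    rows = []
    horizon_min = (warmup_days + horizon_days) * 1440.0
    for rep in range(replications):
        streams = CallStreams.for_replication(seed, rep)
        calls = generate_calls(scenario, horizon_min, streams)
        signature = None
        for name, policy in policies.items():
            result = run_episode(scenario, policy, horizon_days=horizon_days,
                                 warmup_days=warmup_days, calls=calls)
            sig = tuple((c.id, c.time, c.x, c.y, c.actual_high, c.classified_high)
                        for c in result.calls)
            if signature is None:
                signature = sig
            elif sig != signature:
                raise CRNBreachError(f"call stream diverged for policy {name!r} in rep {rep}")
            rows.append({"rep": rep, "policy": name, **_episode_metrics(result)})
    return PairedResult(frame=pd.DataFrame(rows), policies=tuple(policies))


@dataclass(frozen=True)
class ExperimentGrid:
    """Full-factorial design over ALS ratio and the two triage error rates."""

    als_ratios: tuple[float, ...] = (0.5, 0.67, 0.83, 1.0)
    alphas: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4)
    betas: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4)
    replications: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for levels in (self.als_ratios, self.alphas, self.betas):
            if any(not 0.0 <= v <= 1.0 for v in levels):
                raise ValueError("factor levels must be in [0, 1]")
        if self.replications < 2:
            raise ValueError("replications must be >= 2 for paired tests")

    def cells(self):
        for r in self.als_ratios:
            for a in self.alphas:
                for b in self.betas:
                    yield (r, a, b)


def factorial_run(
    grid: ExperimentGrid,
    policy_factory: Callable[[Scenario, tuple[float, float, float]], Mapping[str, object]],
    scenario_factory: Callable[..., Scenario] = default_seoul_like_scenario,
    horizon_days: float = 7.0,
    warmup_days: float = 1.0,
) -> pd.DataFrame:
    """CRN-paired factorial experiment; returns a long-format results table.

    ``policy_factory(scenario, cell)`` returns the named policies to compare
    in that cell (this is where per-cell trained value tables enter).  The
    same replication seeds are reused across cells so factor effects are
    also CRN-paired.
    """
    frames = []
    for cell in grid.cells():
        ratio, alpha, beta = cell
        scenario = scenario_factory(seed=grid.seed, als_ratio=ratio,
                                    alpha=alpha, beta=beta)
        policies = policy_factory(scenario, cell)
        res = crn_compare(scenario, policies, replications=grid.replications,
                          seed=grid.seed, horizon_days=horizon_days,
                          warmup_days=warmup_days)
        df = res.frame.copy()
        df.insert(0, "als_ratio", ratio)
        df.insert(1, "alpha", alpha)
        df.insert(2, "beta", beta)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summarize_cells(results: pd.DataFrame) -> pd.DataFrame:
    """Cell x policy means of every metric in a long-format results table."""
    metrics = [c for c in ("mean_rli", "mean_rt", "fhi", "pli", "iai", "reloc_time")
               if c in results.columns]
    return (results.groupby(["als_ratio", "alpha", "beta", "policy"])[metrics]
            .mean().reset_index())


def main_effects(results: pd.DataFrame, metric: str = "mean_rli") -> dict[str, pd.Series]:
    """Factor-level means of ``metric`` per policy-averaged cell.

    A lightweight replacement for a formal multiway ANOVA: for each factor,
    the mean of the metric at each of its levels averaged over the other
    factors and replications.
    """
    out = {}
    for factor in ("als_ratio", "alpha", "beta"):
        out[factor] = results.groupby(factor)[metric].mean()
    return out
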