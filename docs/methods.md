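# Methods

## System model

The simulator is a discrete-event semi-MDP: the clock jumps from event to
event (call arrival, scene arrival, hospital arrival, handover completion,
base arrival), and a policy is consulted at exactly two kinds of decision
point. On a call arrival with at least one available unit — *available*
means idle at a base, idle at a hospital after a handover, or relocating to
a base — dispatch is mandatory and immediate. On a handover completion the
freed unit either serves the head of the waiting queue (classified-high
calls outrank classified-low ones regardless of arrival order; FCFS within
a class; exactly one assignment per handover) or, if nobody waits, is
redeployed to a base with a free slot. Units en route to a patient or
hospital cannot be diverted; relocating units can be dispatched, from their
linearly interpolated position, and free their reserved base slot at that
moment. Transport always goes to the hospital with the smallest travel
time from the scene; since one scalar speed applies to all legs at a given
departure time, that is the nearest hospital by distance. Events are
processed in `(time, kind, insertion order)` order with a fixed kind
priority so runs are bit-reproducible; simultaneous events have
probability zero under the continuous arrival process anyway.

Patient outcomes: the response time RT runs from the report to scene
arrival. The time-to-proper-care RT_PC equals RT unless a BLS unit
transports an actually high-risk patient, in which case it runs to hospital
arrival (proper care only starts there). The risk level index is
`C_H·RT_PC + Penalty·1{RT_PC > RTT}` for actually high-risk patients
(strict inequality at the threshold) and `C_L·RT_PC` otherwise.

## Parameters

| parameter | default | meaning |
|---|---|---|
| daily calls | 127.9 | mean of the diurnal arrival profile (calls/day) |
| Pr(H^A) | 0.248 | prior share of actually high-risk calls |
| α, β | scenario factors | undertriage / overtriage rates |
| on-scene service | Gamma(k=6.2, θ=3.57) | mean 22.13 min |
| hospital handover | Gamma(k=3.0, θ=5.02) | mean 15.06 min |
| C_H, C_L | 1, 0.25 /min | RLI slopes by actual severity |
| Penalty, RTT | 30, 7 min | threshold penalty for high-risk patients |
| fleet | 6 units, ALS ratio r | `round(6r)` ALS units, listed first |
| bases | 6 × 2 slots | occupied-or-inbound slots bound redeployment |
| γ | 0.9 | discount per decision epoch (not per unit time) |
| step size | 1/n | n = cumulative visits of the aggregated state |

## The synthetic scenario

No real demand, travel or map data ships with the package; the default
scenario is a synthetic stand-in built to the stated study conditions. It
covers a 5.8 × 5.8 km planar square (≈34 km², the area of the dense Seoul
district the setting emulates) with Euclidean travel, a 3×3 grid of demand
districts whose weights rise toward the north-east, six spread-out bases
and three hospitals clustered toward the south-west. The diurnal call
profile (±25% around the mean, overnight trough, late-morning peak) and the
diurnal speed profile (28–44 km/h, slow at the rush hours) are
piecewise-constant per hour; the speed at departure applies to a whole leg,
a deliberate simplification defensible because legs last minutes while the
speed bins last an hour.

Two calibration notes. First, the printed workload parameters (127.9
calls/day at 37.2 min of fleet-occupying service before any travel, on six
units) put the offered load near 4 erlangs, so queueing cannot be rare at
the daily peak no matter how the free parameters are chosen; the defaults
accept a moderately congested regime in which 30–45% of calls queue. The
directional conclusions (policy ranking, factor effects) are all evaluated
inside this regime. Second, hospitals are deliberately not placed in the
demand core: the value of forward-looking redeployment comes precisely
from the tension between returning to a base quickly (near the hospital
you just left) and covering future demand (elsewhere). With hospitals
inside the demand core the two coincide and every redeployment rule is
equally good; the decoupled layout reflects the structure under which the
greedy-vs-learned gap is a meaningful quantity at all.

What the generator does not emulate: road-network travel and turn
restrictions, hospital congestion or diversion, multi-patient incidents,
call cancellation, and spatial demand gradients finer than the 3×3 grid.
Passing tests therefore certify the decision logic and the learning
machinery under plausible urban dynamics, not calibration to any real
city's numbers.

## Randomness and common random numbers

Six named substreams (call times, locations, actual severities, classified
severities, on-scene services, hospital services) derive from one seed via
`numpy` seed sequences. An episode's call table — including its per-call
service draws — is generated before simulation starts, so two policies
compared on the same replication face literally the same object: the CRN
contract is exact by construction, and `crn_compare` still verifies the
logged streams defensively. Arrival times come from thinning a homogeneous
process at the peak rate, which is exact for piecewise-constant profiles.
Actual severity is drawn first (Bernoulli prior), then the classification
conditionally on it; policies never see the actual severity before scene
arrival.

## Learning algorithm

The learner acts at every decision point by minimizing
`C(S,a) + γ·V̄(aggregate(post-decision state))` over the feasible actions
(ties: shorter travel time, then lower id), where `C` is the
posterior-weighted expected RLI of a dispatch (redeployments cost 0), and
the BLS/actually-high branch of `C` extends the expected response time by
the mean on-scene service and the scene-to-nearest-hospital leg. The
sampled value v̂ of the current decision updates the post-decision
aggregate of the *previous* decision with step 1/n. At the end of each
iteration (one warm-up + 7-day episode) the monotone projection is applied
sequentially from ten visit-weighted, distinct reference states per time
zone, re-reading each reference value at application time. Unseen states
default to 0, which in a minimization makes the initial policy explore.

Aggregation: per 3×3 cell, the number of available (idle-or-relocating)
units and of waiting patients, plus the time zone (01:00–08:00,
08:00–11:00, 11:00–01:00; half-open). Relocating units are counted at
their **destination** base's cell. This is a deliberate design choice: at
the decision instant a relocating unit's physical position does not depend
on the chosen base, so counting positions would collapse every
redeployment action onto one post-decision key and the learner could never
rank bases. Destination counting also matches what the key is for —
describing where capacity will be.

Dominance (within a time zone): componentwise ≥ on the nine available
counts and ≤ on the nine pending counts. The table stores one value and a
visit count per key; the projection caps every stored dominating state at
the reference value and floors every dominated one, vectorized per zone.
A finer aggregation that splits counts by unit type and severity class
would support the richer four-condition dominance order; the 19-dimensional
order used here is the sound restriction of it to what the key stores.

Numerical notes: harmonic steps make the stored value the running mean of
its samples; the projection is idempotent for a fixed reference; training
is deterministic given the seed; mini-batch sampling is without
replacement to maximize projection coverage. Training stops on an
iteration budget (a wall-clock cap is also available); there is no
ε-exploration beyond the optimistic initialization.

## Experiments

Policies are compared CRN-paired with two-sided or one-sided paired
t-tests at 95%, no multiplicity correction across factorial cells (each
cell is reported on its own). The factorial driver reuses the same
replication seeds in every cell so factor contrasts are paired too. The
operational indices restrict their denominators to decisions where the
defining condition holds (e.g. FHI requires a classified-high dispatch with
at least two candidates including an ALS) and report "missing" rather than
0 when no decision qualifies; "nearest" always means smallest expected
travel time at the decision instant, ties to the lower id. The mean
relocation time averages base-arrival minus handover-completion over
relocations that completed (a unit dispatched mid-relocation contributes
nothing). A multiway ANOVA is deliberately out of scope; `main_effects`
reports factor-level means instead.

Problem sizes used by the shipped validation runs: 2,000 training
iterations and 30 CRN-paired replications for the headline comparison
(7-day horizon, 1-day warm-up throughout), 20 replications per cell for the
factor sweeps, 10^6 draws for the service-time Monte Carlo, 1,000 random
tables (≤200 states) for the projection oracle, and a 60-iteration run on
the deterministic toy system, whose optimum is known by exhaustive
enumeration of its four stationary redeployment rules.

## Known limitations

* The one-step expected contribution uses the speed at the decision
  instant for both the response and hospital legs of its estimate.
* γ discounts per decision epoch; epochs have variable real duration.
* The learned table is scenario-specific; no transfer across geographies.
* With ALS ratios below 0.5 the system is ALS-starved and, in the variant
  where BLS cannot transport high-risk patients at all, the queue grows
  without bound; analyses restrict to ratios ≥ 0.5.
* Whether a classified severity could be revised after scene arrival is
  unspecified in the operating rules as modelled; the actual severity is
  treated as known from scene arrival onward and no re-dispatch occurs.
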