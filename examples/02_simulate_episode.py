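"""Simulate one week of two-tiered EMS operations under the greedy policy.

Builds the default synthetic dense-urban scenario (6 ambulances at ALS
ratio 0.83, ~127.9 calls/day, 20% under- and overtriage), runs one episode
with a one-day warm-up and prints the outcome measures.
"""

from emsadp import CallStreams, GreedyPolicy, default_seoul_like_scenario, run_episode

scenario = default_seoul_like_scenario(seed=0, als_ratio=0.83, alpha=0.2, beta=0.2)
result = run_episode(scenario, GreedyPolicy(), horizon_days=7.0,
                     warmup_days=1.0, streams=CallStreams(0))

m = result.metrics()
print(f"patients measured      : {m['n_patients']}")
print(f"mean response time     : {m['mean_rt']:.2f} min (call to scene)")
print(f"mean risk level index  : {m['mean_rli']:.2f}")
print(f"mean relocation time   : {m['mean_relocation_time']:.2f} min")
print()
print("The risk level index weights each patient's time-to-proper-care by")
print("severity (slope 1/min high, 0.25/min low) and adds a 30-point")
print("penalty when a high-risk patient waits beyond 7 minutes; BLS")
print("transports of actually high-risk patients run until hospital arrival.")
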