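"""Triage error model: from error rates to severity posteriors.

The dispatcher only sees the classified severity of a call. Given the
undertriage rate alpha = P(classified low | actually high), the overtriage
rate beta = P(classified high | actually low) and the prior share of
actually high-risk calls, Bayes' rule gives the probability that a
classified-high call is actually high-risk (and vice versa) — the weights
the dispatch policies use to value an assignment.
"""

from emsadp import posterior_probs

prior = 0.248  # share of calls that are actually high-risk

print(f"{'alpha':>6} {'beta':>6} {'P(high|class.high)':>20} {'P(low|class.low)':>18}")
for alpha, beta in [(0.0, 0.0), (0.1, 0.2), (0.2, 0.2), (0.4, 0.1)]:
    p_h, p_l = posterior_probs(alpha, beta, prior)
    print(f"{alpha:>6.1f} {beta:>6.1f} {p_h:>20.4f} {p_l:>18.4f}")

print()
print("With no errors both posteriors are 1. As undertriage grows, a")
print("classified-low call is increasingly likely to hide a high-risk")
print("patient, which is what makes undertriage the costly error.")
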