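"""Score a simulated training session and compute the PavCA index.

Simulates one sign-tracker and one goal-tracker session, reduces the event
logs to the six session measures, and prints each rat's component scores and
composite index. Positive indices mean lever-directed (sign-tracking)
responding, negative means magazine-directed (goal-tracking).
"""

import numpy as np

from pavca import make_agent, pavca_index, simulate_pavca_session, summarize_session

rng = np.random.default_rng(42)

for phenotype in ("ST", "GT"):
    agent = make_agent(phenotype, seed=1)
    trials = simulate_pavca_session(agent, session=5, rng=rng)
    summary = summarize_session(trials)
    score = pavca_index(summary)
    print(f"\n{phenotype} rat, session 5 ({summary.n_trials} trials)")
    print(f"  lever contacts {summary.lever_contacts:3d}   magazine entries {summary.mag_entries_cs:3d}")
    print(f"  P(lever) {summary.prob_lever:.2f}   P(magazine) {summary.prob_mag:.2f}")
    print(f"  latency lever {summary.lat_lever_s:.2f} s   magazine {summary.lat_mag_s:.2f} s")
    print(f"  response bias {score.response_bias:+.3f}  prob diff {score.prob_diff:+.3f}  "
          f"latency diff {score.latency_diff:+.3f}")
    print(f"  PavCA index {score.index:+.3f}  (+1 extreme sign-tracker, -1 extreme goal-tracker)")
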