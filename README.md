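# moodnet

Collective-sentiment dynamics on mention networks: temporal broadcast
centrality, community sentiment and endurance statistics, and a calibratable
agent-based sentiment-contagion simulator with what-if scenario analysis.

`moodnet` is aimed at computational social scientists studying how mood
moves through online conversation networks (e.g. Twitter/X @-mention
graphs).  It consumes sentiment-scored message logs — the scoring itself
(SentiStrength-style, LIWC-style, or any integer scale) is done upstream —
and answers three kinds of question:

1. **Who can reach the network?**  Over daily adjacency snapshots
   `A_1 … A_n`, the *dynamic communicability* matrix

   `Q = ∏_{t=1..n} (I − αA_t)⁻¹,   α < 1 / max_t ρ(A_t)`

   counts every time-respecting walk, penalising a walk of length `L` by
   `α^L`.  Row sums of `Q` are *broadcast* indices, column sums *receive*
   indices.  `Q` is accumulated by successive sparse/dense linear solves,
   never explicit inversion; above a size threshold only the index vectors
   are computed.

2. **How healthy is a community?**  For a candidate member set `S` the
   package computes internal activity, connectivity, edge-weighted mean
   sentiment, participation histograms, daily sentiment series with
   deviation flags, the user loss factor between observation windows, and
   (weighted) conductance

   `φ_w(S) = Σ_{i∈S, j∉S} W_ij / min(a(S), a(S̄)),  a(S) = Σ_{i∈S} Σ_{j∈V} W_ij`

   on the symmetric message-exchange graph (low conductance = tight,
   well-separated community).  Community *detection* is out of scope: feed
   in membership lists from Louvain, k-clique percolation, etc.

3. **What drives the mood?**  An agent-based model: agents on a static
   undirected graph initiate, reply to and propagate bursts of messages
   (`1 + Poisson(mean_burst − 1)` messages per burst), each carrying the
   sender's current sentiment plus Gaussian noise; received messages pull an
   agent's sentiment towards/away from its neutral level (sentiment
   contagion), with occasional resets to its baseline.  Per-agent
   probabilities and sentiment levels are estimated from historical logs by
   opportunity/action counting; the six global parameters are fitted by an
   iterative zooming grid search that matches activity and sentiment moments
   between simulation and data (method of simulated moments, scored by
   `ρ = αΣ|⟨C_i⟩−⟨Ĉ_i⟩| + βΣ|std(C_i)−std(Ĉ_i)| + γ|⟨E_c⟩−⟨Ê_c⟩| + δ|std(E_c)−std(Ê_c)|`
   with defaults `(1, 0.1, 10, 100)`).  New-user scenarios predict how
   wiring a vocal newcomer to chosen members shifts community activity and
   sentiment.

A `synthetic_data` generator produces seeded message logs, communities and
evolving networks with known ground truth, so the whole pipeline runs and is
tested fully offline.

## Worked example

`examples/new_user_scenario.py` builds a 16-user synthetic community with
heterogeneous sentiment, then asks which three members a vocal newcomer
should befriend:

```
 most_positive: activity   194.0 ->   431.8 msg/day, sentiment +0.88 -> +10.92
 most_negative: activity   194.0 ->   325.1 msg/day, sentiment +0.88 -> -5.19
 highest_reply: activity   194.0 ->   472.5 msg/day, sentiment +0.88 -> +10.29
  lowest_reply: activity   194.0 ->   254.3 msg/day, sentiment +0.88 -> -1.00
```

Each line compares the baseline community (no new user) with the modified
model, averaged over 50 seeded runs: befriending the most positive users
pulls the community's daily message-weighted sentiment up (+0.88 → +10.92 on
the −25…+25 scale) while the most negative users pull it down; wiring to the
most eager repliers produces the largest activity boost (194 → 472 messages
per day).  The other example scripts cover broadcast ranking
(`broadcast_ranking.py`), community vetting and event-day flagging
(`community_health.py`) and moment-matching calibration
(`simulate_and_calibrate.py`).

A thin CLI mirrors the main pipelines
(`moodnet extract | communicability | attributes | compare | community-stats
| endure | simulate | calibrate | scenario | synth`); run
`moodnet --help` for details.

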