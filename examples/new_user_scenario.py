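"""What happens if a vocal new user joins the community?

Adds one agent whose initiation/reply/propagation probabilities are three
times the community maxima and whose sentiment sits at the community level,
wires it to three chosen members, and compares community activity and
sentiment against the baseline model, averaged over seeded runs.
"""

import numpy as np

from moodnet import GlobalParams, new_user_scenario
from moodnet.synthetic import CharacteristicsSampler, community_graph

rng = np.random.default_rng(11)
graph = community_graph(16, rng, chord_prob=0.2)
sampler = CharacteristicsSampler(mean_p_init=0.15, mean_p_reply=0.4,
                                 mean_p_prop=0.1, concentration=4.0,
                                 s_baseline_mean=0.5, s_baseline_sd=8.0)
characteristics = sampler.sample(sorted(graph.nodes()), rng)
params = GlobalParams(iterations_per_day=24, mean_burst=2.1, contagion=0.2,
                      reset_prob=0.1, noise_sd=1.5)

for rule in ("most_positive", "most_negative", "highest_reply", "lowest_reply"):
    report = new_user_scenario(graph, characteristics, params, rule,
                               n_days=10, n_runs=50, seed=2)
    print(f"{rule:>14}: activity {report.baseline['activity_mean']:7.1f} -> "
          f"{report.modified['activity_mean']:7.1f} msg/day, "
          f"sentiment {report.baseline['sentiment_mean']:+.2f} -> "
          f"{report.modified['sentiment_mean']:+.2f}")
# Befriending positive users should pull community sentiment up and negative
# users down; befriending eager repliers should boost activity the most.
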