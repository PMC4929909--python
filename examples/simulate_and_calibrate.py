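"""Fit the agent-based model to a community log by simulated moments.

Treats one synthetic log as the "real" data: estimates per-agent
characteristics from it, then grid-searches the contagion factor and reset
probability so that simulated activity/sentiment moments match the real
ones under the rho score (smaller is better; constants (1, 0.1, 10, 100)
weight sentiment volatility most heavily).
"""

from moodnet import (
    GlobalParams,
    build_agent_graph,
    calibrate,
    estimate_characteristics,
    extract_edges,
    summarize,
)
from moodnet.synthetic import generate_community_log

true_params = GlobalParams(iterations_per_day=48, mean_burst=2.1, contagion=0.25,
                           reset_prob=0.1, noise_sd=1.5, neighbour_threshold=0)
records, truth = generate_community_log(12, 10, true_params, seed=21)
edges = extract_edges(records)
members = sorted(truth.graph.nodes())

graph = build_agent_graph(edges, members, true_params.neighbour_threshold)
est = estimate_characteristics(edges, members, graph, true_params, "MC", n_days=10)
real_stats = summarize(edges, n_days=10, users=tuple(members), measure="MC")
print(f"estimated characteristics for {len(est.characteristics)} agents; "
      f"community neutral sentiment {est.s_neutral:.2f}")

result = calibrate(
    real_stats, graph, est.characteristics,
    ranges={"contagion": (0.0, 0.5), "reset_prob": (0.0, 0.3)},
    grid_points=3, n_zooms=2, runs_per_combo=10, seed=4,
    base_params=true_params, n_days=10,
)
best = result.best_params
print(f"calibrated contagion {best.contagion:.3f} (generator used "
      f"{true_params.contagion}), reset probability {best.reset_prob:.3f} "
      f"(generator used {true_params.reset_prob})")
print(f"best mean rho {result.best_score:.1f} over "
      f"{result.runs_per_combo} runs/point, {result.n_zooms} zooms")
# rho aggregates per-user activity gaps, so its scale grows with community
# size; only relative comparisons between parameter settings matter.
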