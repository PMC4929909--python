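"""Score a community's cohesion, sentiment and endurance.

Generates a synthetic community message log with one planted event day,
then computes the statistics used to vet candidate communities: internal
activity, conductance (how well separated the group is from the rest of
the network), edge-weighted mean sentiment, a daily sentiment series with
deviation flags, and the user loss factor between two windows.
"""

from moodnet import (
    GlobalParams,
    active_members,
    community_report,
    daily_sentiment_series,
    extract_edges,
    user_loss_factor,
)
from moodnet.synthetic import generate_community_log

params = GlobalParams(iterations_per_day=48, mean_burst=2.1, contagion=0.1,
                      reset_prob=0.1, noise_sd=1.5)
records, truth = generate_community_log(
    n_users=12, n_days=28, params=params, planted_events=[(19, 12.0)], seed=3
)
edges = extract_edges(records)
members = sorted(truth.graph.nodes())

report = community_report(edges, members, measures=("MC",))
print(f"community of {report.n_nodes} users, "
      f"{report.n_internal_mentions} internal mentions "
      f"({report.internal_mentions_per_node:.1f} per node)")
print(f"connected: {report.connected}; "
      f"mean (MC) sentiment {report.mean_sentiment['MC']:.2f}; "
      f"non-zero-sentiment fraction {report.nonzero_sentiment_fraction:.2f}")

series = daily_sentiment_series(edges, "MC", truth.start.date(), 28, z=2.5)
flagged = series.index[series["flag"]].tolist()
print(f"daily sentiment mean {series['mean_sentiment'].mean():.2f}; "
      f"flagged deviation days: {[d.isoformat() for d in flagged]}")

first_half = [e for e in edges if e.day_index < 14]
second_half = [e for e in edges if e.day_index >= 14]
endurance = user_loss_factor(
    active_members(first_half, members),
    active_members(second_half, members),
    members,
)
print(f"user loss factor {endurance.user_loss_factor:.2f} "
      f"({endurance.active_autumn} -> {endurance.active_spring} active users); "
      "1.0 means the community retained everyone")
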