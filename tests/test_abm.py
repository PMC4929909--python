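"""Agent-based model: graph construction, simulation mechanics, estimation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from moodnet.abm import (
    AgentCharacteristics,
    GlobalParams,
    build_agent_graph,
    community_moments,
    estimate_characteristics,
    simulate,
    summarize,
)
from moodnet.message_log import extract_edges
from moodnet.synthetic import CharacteristicsSampler, generate_community_log

from conftest import edge


def chars(p_init=0.0, p_reply=0.0, p_prop=0.0, s_baseline=0.0, s_neutral=0.0):
    return AgentCharacteristics(p_init, p_reply, p_prop, s_baseline, s_neutral)


def pair_graph():
    g = nx.Graph()
    g.add_edge("a", "b")
    return g


class TestBuildAgentGraph:
    def test_threshold_is_strict(self):
        edges = [edge("a", "b", mc=0) for _ in range(10)] + [
            edge("b", "a", mc=0) for _ in range(9)
        ]
        assert build_agent_graph(edges, {"a", "b"}, 18).has_edge("a", "b")
        assert not build_agent_graph(edges, {"a", "b"}, 19).has_edge("a", "b")

    def test_zero_threshold_connects_all_exchanging_pairs(self):
        edges = [edge("a", "b", mc=0), edge("c", "b", mc=0)]
        g = build_agent_graph(edges, {"a", "b", "c"}, 0)
        assert set(g.edges()) == {("a", "b"), ("b", "c")}

    def test_empty_member_set_errors(self):
        with pytest.raises(ValueError, match="empty member"):
            build_agent_graph([], set(), 0)

    def test_planted_multigraph_matches_pair_tally(self, rng):
        users = [f"u{i}" for i in range(6)]
        edges = []
        for _ in range(300):
            i, j = rng.choice(6, size=2, replace=False)
            edges.append(edge(users[i], users[j], mc=0))
        threshold = 10
        g = build_agent_graph(edges, users, threshold)
        tally: dict[tuple, int] = {}
        for e in edges:
            key = tuple(sorted((e.source, e.target)))
            tally[key] = tally.get(key, 0) + 1
        expected = {k for k, c in tally.items() if c > threshold}
        assert {tuple(sorted(e)) for e in g.edges()} == expected


class TestSimulateDegenerate:
    def test_zero_probabilities_give_empty_log(self):
        g = pair_graph()
        cs = {u: chars() for u in g}
        log = simulate(g, cs, GlobalParams(iterations_per_day=10), 2, seed=0)
        assert len(log.entries) == 0

    def test_no_contagion_no_noise_pins_sentiment_to_baseline(self):
        g = nx.complete_graph(["a", "b", "c"])
        cs = {
            "a": chars(p_init=1.0, p_reply=0.8, s_baseline=3.0),
            "b": chars(p_init=0.5, p_reply=0.9, s_baseline=-2.0),
            "c": chars(p_init=0.7, p_prop=0.5, s_baseline=0.5),
        }
        params = GlobalParams(iterations_per_day=20, contagion=0.0, noise_sd=0.0)
        log = simulate(g, cs, params, 2, seed=1)
        base = {u: cs[u].s_baseline for u in cs}
        assert len(log.entries) > 0
        for row in log.entries.itertuples(index=False):
            assert row.sentiment == base[row.sender]

    def test_reset_prob_one_restarts_every_step_from_baseline(self):
        g = pair_graph()
        cs = {
            "a": chars(p_init=1.0, p_reply=1.0, s_baseline=5.0, s_neutral=0.0),
            "b": chars(p_reply=1.0, s_baseline=-5.0, s_neutral=0.0),
        }
        params = GlobalParams(
            iterations_per_day=30, contagion=0.9, noise_sd=0.0, reset_prob=1.0
        )
        log = simulate(g, cs, params, 1, seed=2)
        base = {u: cs[u].s_baseline for u in cs}
        for row in log.entries.itertuples(index=False):
            assert row.sentiment == base[row.sender]

    def test_missing_characteristics_rejected(self):
        g = pair_graph()
        with pytest.raises(ValueError, match="missing characteristics"):
            simulate(g, {"a": chars()}, GlobalParams(iterations_per_day=5), 1, seed=0)


class TestSimulateStochasticProperties:
    def test_identical_seed_identical_log(self):
        g = nx.complete_graph([f"u{i}" for i in range(5)])
        cs = {u: chars(p_init=0.3, p_reply=0.6, p_prop=0.2, s_baseline=1.0) for u in g}
        params = GlobalParams(iterations_per_day=50, noise_sd=2.0, contagion=0.2)
        a = simulate(g, cs, params, 2, seed=42)
        b = simulate(g, cs, params, 2, seed=42)
        pd.testing.assert_frame_equal(a.entries, b.entries)
        c = simulate(g, cs, params, 2, seed=43)
        assert not a.entries.equals(c.entries)

    def test_isolated_pair_daily_message_count(self):
        """Initiator with p_init=1 and an inert partner sends one burst per
        step: expected daily messages = iterations_per_day * mean_burst."""
        g = pair_graph()
        cs = {"a": chars(p_init=1.0), "b": chars()}
        params = GlobalParams(iterations_per_day=96, mean_burst=2.1, noise_sd=0.0)
        n_days = 20
        log = simulate(g, cs, params, n_days, seed=7)
        daily = log.entries.groupby("day")["n_messages"].sum()
        mean_daily = daily.reindex(range(n_days), fill_value=0).mean()
        expected = 96 * 2.1
        sigma = np.sqrt(96 * 1.1 / n_days)  # burst variance = mean_burst - 1
        assert abs(mean_daily - expected) < 3 * sigma

    def test_burst_sizes_at_least_one_with_configured_mean(self):
        g = pair_graph()
        cs = {"a": chars(p_init=1.0), "b": chars()}
        params = GlobalParams(iterations_per_day=500, mean_burst=2.1)
        log = simulate(g, cs, params, 25, seed=3)  # >= 10^4 bursts
        k = log.entries["n_messages"].to_numpy()
        assert len(k) >= 10_000
        assert k.min() >= 1
        se = np.sqrt(1.1 / len(k))
        assert abs(k.mean() - 2.1) < 3 * se

    def test_contagion_pulls_towards_message_sentiment(self):
        """An agent bombarded with above-neutral messages drifts monotonically
        upward (no noise, no reset); below-neutral messages drift it down.
        The replying agent's own outgoing sentiments expose its state."""
        for sender_base, direction in ((4.0, 1.0), (-4.0, -1.0)):
            g = pair_graph()
            cs = {
                "a": chars(p_init=1.0, p_reply=1.0, s_baseline=sender_base, s_neutral=0.0),
                "b": chars(p_reply=1.0, s_baseline=0.0, s_neutral=0.0),
            }
            params = GlobalParams(
                iterations_per_day=40, contagion=0.3, noise_sd=0.0, reset_prob=0.0
            )
            log = simulate(g, cs, params, 1, seed=5)
            from_b = log.entries[log.entries["sender"] == "b"]["sentiment"].to_numpy()
            assert len(from_b) > 5
            diffs = np.diff(np.concatenate(([0.0], from_b))) * direction
            assert np.all(diffs >= -1e-12)

    def test_all_bursts_between_measure_bounds(self):
        g = nx.complete_graph(["a", "b", "c"])
        cs = {u: chars(p_init=0.8, p_reply=0.8, s_baseline=3.5) for u in g}
        params = GlobalParams(iterations_per_day=50, noise_sd=6.0, contagion=0.5)
        log = simulate(g, cs, params, 2, seed=9, measure="SS")
        s = log.entries["sentiment"].to_numpy()
        assert s.min() >= -4.0 and s.max() <= 4.0


class TestEstimateCharacteristics:
    def test_always_sending_user_has_unit_initiation(self):
        g = pair_graph()
        cs = {"a": chars(p_init=1.0, s_baseline=2.0), "b": chars()}
        params = GlobalParams(iterations_per_day=24, noise_sd=0.0)
        records, truth = _log_from(g, cs, params, n_days=4)
        est = estimate_characteristics(
            records, {"a", "b"}, g, params, "MC", n_days=4
        )
        assert est.characteristics["a"].p_init == 1.0

    def test_silent_user_has_zero_probabilities_with_warning(self):
        g = pair_graph()
        cs = {"a": chars(p_init=1.0, s_baseline=2.0), "b": chars()}
        params = GlobalParams(iterations_per_day=24, noise_sd=0.0)
        records, truth = _log_from(g, cs, params, n_days=4)
        est = estimate_characteristics(records, {"a", "b"}, g, params, "MC", n_days=4)
        b = est.characteristics["b"]
        assert (b.p_init, b.p_reply, b.p_prop) == (0.0, 0.0, 0.0)
        assert "b" in est.warnings  # never sent a scored message

    def test_recovers_generating_probabilities(self):
        params = GlobalParams(
            iterations_per_day=500, mean_burst=2.1, contagion=0.1,
            reset_prob=0.1, noise_sd=1.5,
        )
        sampler = CharacteristicsSampler(
            mean_p_init=0.15, mean_p_reply=0.5, mean_p_prop=0.15
        )
        records, truth = generate_community_log(
            15, 20, params, sampler=sampler, seed=11
        )
        edges = extract_edges(records)
        est = estimate_characteristics(
            edges, truth.graph.nodes(), truth.graph, params, "MC",
            n_days=20, start=truth.start,
        )
        failures = 0
        total = 0
        for u, true_c in truth.characteristics.items():
            est_c = est.characteristics[u]
            init_den, rep_den = est.opportunities[u]
            for name, den in (
                ("p_init", init_den), ("p_reply", rep_den), ("p_prop", rep_den)
            ):
                if den == 0:
                    continue
                p = getattr(true_c, name)
                se = max(np.sqrt(p * (1 - p) / den), 1e-12)
                total += 1
                if abs(getattr(est_c, name) - p) > 3 * se:
                    failures += 1
        assert total >= 40
        assert failures / total <= 0.05

    def test_baselines_recovered_without_noise(self):
        g = pair_graph()
        cs = {"a": chars(p_init=1.0, s_baseline=3.0), "b": chars(s_baseline=-1.0)}
        params = GlobalParams(iterations_per_day=24, noise_sd=0.0, contagion=0.0)
        records, truth = _log_from(g, cs, params, n_days=3)
        est = estimate_characteristics(records, {"a", "b"}, g, params, "MC", n_days=3)
        assert est.characteristics["a"].s_baseline == pytest.approx(3.0)
        assert est.s_neutral == pytest.approx(3.0)  # only a's messages exist


def _log_from(g, cs, params, n_days):
    """Simulate and serialise through the synthetic generator's conversion."""
    from datetime import datetime, timedelta, timezone

    from moodnet.message_log import MessageRecord, extract_edges
    from moodnet.synthetic import _scores_for

    log = simulate(g, cs, params, n_days, seed=17)
    start = datetime(2014, 9, 22, tzinfo=timezone.utc)
    day_us = 86_400_000_000
    records = []
    for i, row in enumerate(log.entries.itertuples(index=False)):
        ts = start + timedelta(microseconds=row.step * day_us // params.iterations_per_day)
        records.append(
            MessageRecord(
                message_id=f"m{i}",
                author=row.sender,
                timestamp=ts,
                mentions=(row.receiver,),
                scores=_scores_for(row.sentiment, "MC"),
            )
        )
    return extract_edges(records), log


class TestSummarize:
    def test_two_day_hand_example(self):
        rows = []
        # one user: 4 messages on day 0, 6 on day 1
        entries = pd.DataFrame(
            {
                "step": [0, 1],
                "day": [0, 1],
                "sender": ["a", "a"],
                "receiver": ["b", "b"],
                "n_messages": [4, 6],
                "sentiment": [1.0, 1.0],
            }
        )
        from moodnet.abm import SimulationLog

        log = SimulationLog(entries, 0, GlobalParams(iterations_per_day=1), "MC", ("a", "b"), 2)
        stats = summarize(log)
        i = stats.users.index("a")
        assert stats.count_mean[i] == pytest.approx(5.0)
        assert stats.count_std[i] == pytest.approx(1.0)

    def test_uniform_sentiment_has_zero_volatility(self):
        g = pair_graph()
        cs = {"a": chars(p_init=1.0, s_baseline=2.5), "b": chars()}
        params = GlobalParams(iterations_per_day=20, noise_sd=0.0, contagion=0.0)
        log = simulate(g, cs, params, 3, seed=1)
        stats = summarize(log)
        assert stats.sentiment_mean == pytest.approx(2.5)
        assert stats.sentiment_std == pytest.approx(0.0)

    def test_matches_independent_groupby_recount(self):
        g = nx.complete_graph([f"u{i}" for i in range(4)])
        cs = {u: chars(p_init=0.5, p_reply=0.5, s_baseline=1.0) for u in g}
        params = GlobalParams(iterations_per_day=40, noise_sd=1.0, contagion=0.1)
        log = simulate(g, cs, params, 5, seed=21)
        stats = summarize(log)
        df = log.entries
        for i, u in enumerate(stats.users):
            per_day = (
                df[df["sender"] == u].groupby("day")["n_messages"].sum()
                .reindex(range(5), fill_value=0)
            )
            assert stats.count_mean[i] == pytest.approx(per_day.mean())
            assert stats.count_std[i] == pytest.approx(per_day.std(ddof=0))
        weighted = df.assign(ws=df["n_messages"] * df["sentiment"])
        daily = weighted.groupby("day").agg(w=("n_messages", "sum"), ws=("ws", "sum"))
        daily_sent = daily["ws"] / daily["w"]
        assert stats.sentiment_mean == pytest.approx(daily_sent.mean())
        assert stats.sentiment_std == pytest.approx(daily_sent.std(ddof=0))

    def test_zero_messages_errors(self):
        g = pair_graph()
        cs = {u: chars() for u in g}
        log = simulate(g, cs, GlobalParams(iterations_per_day=5), 2, seed=0)
        with pytest.raises(ValueError, match="zero total messages"):
            summarize(log)

    def test_community_moments_recount(self):
        g = pair_graph()
        cs = {"a": chars(p_init=1.0, s_baseline=1.0), "b": chars()}
        params = GlobalParams(iterations_per_day=10, noise_sd=0.0, contagion=0.0)
        log = simulate(g, cs, params, 4, seed=2)
        m = community_moments(log)
        daily = log.entries.groupby("day")["n_messages"].sum().reindex(range(4), fill_value=0)
        assert m["activity_mean"] == pytest.approx(daily.mean())
        assert m["activity_std"] == pytest.approx(daily.std(ddof=0))
        assert m["sentiment_mean"] == pytest.approx(1.0)
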