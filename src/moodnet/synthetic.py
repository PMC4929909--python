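"""Seeded synthetic communities, message logs and evolving networks.

Real mention-network corpora are large and access-restricted, so every
pipeline stage here is exercised against generated data with known ground
truth.  Community logs are produced by the agent-based simulator itself on
a sampled graph with sampled per-agent characteristics, then serialised in
the standard JSON-Lines message schema, which gives bursty per-user
messaging with reply structure, per-user baseline sentiment plus noise, and
(optionally) planted event days that shift all of a day's scores.  Evolving
networks for centrality tests are independent per-day directed Bernoulli
graphs.  Identical seeds give byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Sequence

import networkx as nx
import numpy as np

from .abm import AgentCharacteristics, GlobalParams, SimulationLog, simulate
from .measures import MEASURE_RANGES, _check_measure
from .message_log import EvolvingNetwork, MessageRecord, SentimentScores

DEFAULT_START = datetime(2014, 9, 22, tzinfo=timezone.utc)


@dataclass(frozen=True)
class CharacteristicsSampler:
    """Sampling spec for heterogeneous agent characteristics.

    Probabilities are Beta-distributed around the given means (common
    ``concentration``; initiation and reply are sampled independently, so
    their correlation is 0 by default).  Baselines are Normal, truncated to
    the measure range; every agent's neutral level is the community mean of
    the sampled baselines.
    """

    mean_p_init: float = 0.1
    mean_p_reply: float = 0.5
    mean_p_prop: float = 0.1
    concentration: float = 10.0
    s_baseline_mean: float = 0.8
    s_baseline_sd: float = 5.0
    measure: str = "MC"

    def sample(self, users: Sequence[str], rng: np.random.Generator) -> dict[str, AgentCharacteristics]:
        _check_measure(self.measure)
        lo, hi = MEASURE_RANGES[self.measure]
        n = len(users)

        def beta(mean: float) -> np.ndarray:
            if mean <= 0.0:
                return np.zeros(n)
            if mean >= 1.0:
                return np.ones(n)
            a = mean * self.concentration
            b = (1.0 - mean) * self.concentration
            return rng.beta(a, b, size=n)

        p_init = beta(self.mean_p_init)
        p_reply = beta(self.mean_p_reply)
        p_prop = beta(self.mean_p_prop)
        baselines = np.clip(
            rng.normal(self.s_baseline_mean, self.s_baseline_sd, size=n), lo, hi
        )
        neutral = float(baselines.mean())
        return {
            u: AgentCharacteristics(
                p_init=float(p_init[i]),
                p_reply=float(p_reply[i]),
                p_prop=float(p_prop[i]),
                s_baseline=float(baselines[i]),
                s_neutral=neutral,
            )
            for i, u in enumerate(users)
        }


@dataclass
class GroundTruth:
    """Everything the generator knows about an emitted log."""

    graph: nx.Graph
    characteristics: dict[str, AgentCharacteristics]
    params: GlobalParams
    partition: dict[str, int]
    planted_events: tuple[tuple[int, float], ...]
    measure: str
    start: datetime
    n_days: int
    seed: int
    simulation_log: SimulationLog | None = None


def _scores_for(value: float, measure: str) -> SentimentScores:
    """Encode a combined sentiment value in the components of one measure."""
    lo, hi = MEASURE_RANGES[measure]
    v = min(max(value, lo), hi)
    if measure == "MC":
        return SentimentScores(mc=int(round(v)))
    if measure == "SS":
        s = int(round(v))
        if s >= 0:
            return SentimentScores(ss_pos=1 + s, ss_neg=1)
        return SentimentScores(ss_pos=1, ss_neg=1 - s)
    return SentimentScores(l_posemo=max(v, 0.0), l_negemo=max(-v, 0.0))


def community_graph(n_users: int, rng: np.random.Generator, chord_prob: float = 0.2) -> nx.Graph:
    """A connected undirected graph: a ring plus random chords."""
    users = [f"u{i:03d}" for i in range(n_users)]
    g = nx.Graph()
    g.add_nodes_from(users)
    for i in range(n_users):
        g.add_edge(users[i], users[(i + 1) % n_users])
    for i in range(n_users):
        for j in range(i + 2, n_users):
            if (i, j) != (0, n_users - 1) and rng.random() < chord_prob:
                g.add_edge(users[i], users[j])
    return g


def generate_community_log(
    n_users: int,
    n_days: int,
    params: GlobalParams,
    sampler: CharacteristicsSampler | None = None,
    planted_events: Sequence[tuple[int, float]] = (),
    seed: int = 0,
    start: datetime = DEFAULT_START,
) -> tuple[list[MessageRecord], GroundTruth]:
    """Generate a community message log with known ground truth.

    The log is produced by the agent-based simulator on a sampled connected
    graph with sampled characteristics, serialised as one
    :class:`MessageRecord` per message; step ``s`` of day ``d`` maps to the
    wall-clock instant ``start + d days + s * (86400 / iterations_per_day)``
    seconds.  Planted events add a fixed sentiment offset to every message
    on the given (0-based) days before scoring.
    """
    if n_users < 2:
        raise ValueError("n_users must be >= 2")
    for day, _ in planted_events:
        if not 0 <= day < n_days:
            raise ValueError(f"planted event day {day} outside the run")
    sampler = sampler or CharacteristicsSampler()
    measure = sampler.measure
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    graph = community_graph(n_users, rng)
    characteristics = sampler.sample(sorted(graph.nodes()), rng)
    log = simulate(
        graph,
        characteristics,
        params,
        n_days,
        np.random.default_rng(np.random.SeedSequence([seed, 1])),
        measure,
    )
    shift_by_day = {int(day): float(off) for day, off in planted_events}
    day_us = 86_400_000_000
    records: list[MessageRecord] = []
    counter = 0
    for row in log.entries.itertuples(index=False):
        ts = start + timedelta(microseconds=row.step * day_us // params.iterations_per_day)
        value = row.sentiment + shift_by_day.get(row.day, 0.0)
        scores = _scores_for(value, measure)
        for _ in range(int(row.n_messages)):
            records.append(
                MessageRecord(
                    message_id=f"m{counter:08d}",
                    author=row.sender,
                    timestamp=ts,
                    mentions=(row.receiver,),
                    scores=scores,
                )
            )
            counter += 1
    truth = GroundTruth(
        graph=graph,
        characteristics=characteristics,
        params=params,
        partition={u: 0 for u in graph.nodes()},
        planted_events=tuple((int(d), float(o)) for d, o in planted_events),
        measure=measure,
        start=start,
        n_days=n_days,
        seed=seed,
        simulation_log=log,
    )
    return records, truth


def generate_evolving_network(
    n_users: int,
    n_days: int,
    edge_prob: float,
    seed: int = 0,
) -> EvolvingNetwork:
    """Independent directed Bernoulli edges per day, no self-loops."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    users = [f"u{i:03d}" for i in range(n_users)]
    snapshots = []
    for _ in range(n_days):
        a = (rng.random((n_users, n_users)) < edge_prob).astype(np.int8)
        np.fill_diagonal(a, 0)
        snapshots.append(a)
    return EvolvingNetwork(users, snapshots)
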