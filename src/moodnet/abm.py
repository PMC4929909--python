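"""Agent-based sentiment-contagion simulator for online communities.

Agents (users) sit on a static undirected graph built by connecting pairs
who exchanged strictly more messages than a *neighbour frequency threshold*.
Time advances in discrete steps (``iterations_per_day`` per day).  Each
agent carries five constant characteristics — initiation, reply and
propagation probabilities, a baseline sentiment and a neutral sentiment —
and an evolving state: its current sentiment and the set of neighbours who
messaged it at the previous step.

Per step, synchronously from end-of-previous-step states:

1. *Actions.*  An agent with no recent senders initiates with probability
   ``p_init``, sending a burst to one uniformly chosen neighbour.  An agent
   with recent senders replies with probability ``p_reply`` (a burst to each
   recent sender) and, independently, propagates with probability ``p_prop``
   (a burst to one uniformly chosen non-sender neighbour).  One decision per
   behavioural context keeps the estimators below unbiased: the frequency of
   "sent given no recent receipt" windows is exactly ``p_init``, and
   likewise for replies and propagations.
2. *Burst.*  Each burst contains ``1 + Poisson(mean_burst - 1)`` messages
   sharing one sentiment: the sender's current sentiment plus Gaussian noise
   (``noise_sd``), clamped to the measure range.
3. *Contagion.*  An agent that received messages with (message-weighted)
   mean sentiment m updates ``current += contagion * (m - s_neutral)``:
   messages warmer than its neutral level pull it up, colder pull it down.
4. *Reset.*  With probability ``reset_prob`` the agent snaps back to its
   baseline sentiment.  Finally the recent-sender sets are reassigned.

Characteristics are estimated from historical logs by splitting time into
windows of one step's length and counting opportunities versus actions, and
baselines/neutral levels from per-user and community mean message sentiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .measures import MEASURE_RANGES, _check_measure
from .message_log import MentionEdge


@dataclass(frozen=True)
class AgentCharacteristics:
    """Constant per-agent behaviour: action probabilities and sentiment levels."""

    p_init: float
    p_reply: float
    p_prop: float
    s_baseline: float
    s_neutral: float

    def __post_init__(self) -> None:
        for name in ("p_init", "p_reply", "p_prop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class GlobalParams:
    """The six global model parameters."""

    iterations_per_day: int = 1536
    mean_burst: float = 2.1
    contagion: float = 0.1
    reset_prob: float = 0.1
    noise_sd: float = 1.0
    neighbour_threshold: int = 18

    def __post_init__(self) -> None:
        if self.iterations_per_day < 1:
            raise ValueError("iterations_per_day must be a positive integer")
        if self.mean_burst < 1:
            raise ValueError("mean_burst must be >= 1")
        if self.contagion < 0:
            raise ValueError("contagion must be >= 0")
        if not 0.0 <= self.reset_prob <= 1.0:
            raise ValueError("reset_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.neighbour_threshold < 0:
            raise ValueError("neighbour_threshold must be a nonnegative integer")


@dataclass
class SimulationLog:
    """Messages recorded during one simulation run.

    ``entries`` has one row per burst: step, day, sender, receiver,
    n_messages, sentiment.  ``day = step // iterations_per_day``.
    """

    entries: pd.DataFrame
    seed: object
    params: GlobalParams
    measure: str
    nodes: tuple[str, ...]
    n_days: int


@dataclass(frozen=True)
class FitStatistics:
    """Moment summaries compared between real and simulated data.

    Per-user mean and (population) standard deviation of daily sent-message
    counts, and the mean and standard deviation of the daily
    message-weighted community sentiment (days with no messages are excluded
    from the sentiment series but contribute zero counts).
    """

    users: tuple[str, ...]
    count_mean: np.ndarray
    count_std: np.ndarray
    sentiment_mean: float
    sentiment_std: float
    n_days: int


@dataclass(frozen=True)
class EstimationResult:
    characteristics: dict[str, AgentCharacteristics]
    warnings: dict[str, tuple[str, ...]]
    s_neutral: float
    #: per-agent sample sizes: (initiation-opportunity windows, receipt windows)
    opportunities: dict[str, tuple[int, int]] = field(default_factory=dict)


def build_agent_graph(
    edges: Iterable[MentionEdge],
    members: Iterable[str],
    neighbour_threshold: int,
) -> nx.Graph:
    """Undirected agent graph: connect member pairs that exchanged strictly
    more messages than the threshold.  All members appear as nodes."""
    members = set(members)
    if not members:
        raise ValueError("empty member set")
    if neighbour_threshold < 0:
        raise ValueError("neighbour_threshold must be >= 0")
    counts: dict[tuple[str, str], int] = {}
    for e in edges:
        if e.source in members and e.target in members:
            key = (min(e.source, e.target), max(e.source, e.target))
            counts[key] = counts.get(key, 0) + 1
    g = nx.Graph()
    g.add_nodes_from(sorted(members))
    for (u, v), c in counts.items():
        if c > neighbour_threshold:
            g.add_edge(u, v)
    return g


def estimate_characteristics(
    log: Sequence[MentionEdge],
    members: Iterable[str],
    graph: nx.Graph,
    params: GlobalParams,
    measure: str,
    n_days: int | None = None,
    start: datetime | None = None,
) -> EstimationResult:
    """Estimate agent characteristics from a historical message log.

    Time is split into windows of length one step (one day divided by
    ``iterations_per_day``).  For each agent A, over windows with a defined
    predecessor:

    * ``p_init``   = #(previous window silent to A and A sent) /
      #(previous window silent to A);
    * ``p_reply``  = #(A sent to >=1 previous-window sender) /
      #(A received >=1 message in the previous window);
    * ``p_prop``   = #(A sent to >=1 non-sender neighbour | received) /
      the same denominator.

    ``s_baseline`` is the mean combined score of A's messages and
    ``s_neutral`` the community-wide mean (identical for all agents).
    Zero-denominator cases yield probability 0 with a warning flag.
    """
    _check_measure(measure)
    members = sorted(set(members))
    if not log:
        raise ValueError("empty log")
    member_set = set(members)
    if start is None:
        earliest = min(e.timestamp for e in log)
        start = earliest.astimezone(timezone.utc).replace(
            hour=0, minute=0, second=0, microsecond=0
        )
    day_us = 86_400_000_000
    sent: dict[int, dict[str, set[str]]] = {}
    received: dict[int, dict[str, set[str]]] = {}
    scores: dict[str, list[float]] = {u: [] for u in members}
    all_scores: list[float] = []
    max_w = 0
    for e in log:
        if e.source not in member_set or e.target not in member_set:
            continue
        # integer microsecond arithmetic with <1us slack: timestamps sitting
        # on a window boundary must not leak into the previous window
        delta = e.timestamp - start
        delta_us = (delta.days * 86_400 + delta.seconds) * 1_000_000 + delta.microseconds
        ipd = params.iterations_per_day
        w = (delta_us * ipd + ipd - 1) // day_us
        if w < 0:
            raise ValueError("log entry precedes the start instant")
        max_w = max(max_w, w)
        sent.setdefault(w, {}).setdefault(e.source, set()).add(e.target)
        received.setdefault(w, {}).setdefault(e.target, set()).add(e.source)
        v = e.scores.combined(measure)
        if v is not None:
            scores[e.source].append(v)
            all_scores.append(v)
    if not all_scores:
        raise ValueError("log contains no scored messages among members")
    n_windows = (
        n_days * params.iterations_per_day if n_days is not None else max_w + 1
    )
    s_neutral = float(np.mean(all_scores))
    chars: dict[str, AgentCharacteristics] = {}
    warns: dict[str, tuple[str, ...]] = {}
    opps: dict[str, tuple[int, int]] = {}
    for a in members:
        neighbours = set(graph.neighbors(a)) if a in graph else set()
        init_num = init_den = rep_num = prop_num = rep_den = 0
        for w in range(1, n_windows):
            prev_senders = received.get(w - 1, {}).get(a, frozenset())
            sent_now = sent.get(w, {}).get(a, frozenset())
            if prev_senders:
                rep_den += 1
                if sent_now & prev_senders:
                    rep_num += 1
                if (sent_now & neighbours) - prev_senders:
                    prop_num += 1
            else:
                init_den += 1
                if sent_now:
                    init_num += 1
        flags: list[str] = []
        if init_den == 0:
            flags.append("p_init: no opportunity windows")
        if rep_den == 0:
            flags.append("p_reply/p_prop: never received in a previous window")
        if not scores[a]:
            flags.append("s_baseline: user sent no scored messages")
        chars[a] = AgentCharacteristics(
            p_init=init_num / init_den if init_den else 0.0,
            p_reply=rep_num / rep_den if rep_den else 0.0,
            p_prop=prop_num / rep_den if rep_den else 0.0,
            s_baseline=float(np.mean(scores[a])) if scores[a] else s_neutral,
            s_neutral=s_neutral,
        )
        opps[a] = (init_den, rep_den)
        if flags:
            warns[a] = tuple(flags)
    return EstimationResult(
        characteristics=chars, warnings=warns, s_neutral=s_neutral, opportunities=opps
    )


def simulate(
    graph: nx.Graph,
    characteristics: Mapping[str, AgentCharacteristics],
    params: GlobalParams,
    n_days: int,
    seed: int | np.random.Generator | None,
    measure: str = "MC",
    passive_targets: frozenset[str] | set[str] = frozenset(),
) -> SimulationLog:
    """Run the agent-based model for ``n_days`` and record every burst.

    Initial state: each agent's sentiment equals its baseline and it has no
    recent senders.  Steps are synchronous: all actions draw on the previous
    step's states.  Identical inputs and seed give an identical log.

    ``passive_targets`` marks nodes (e.g. a newly introduced user) that other
    agents will reply to but never spontaneously initiate or propagate
    towards: incumbents respond to a newcomer's messages but do not have the
    newcomer in their routine contact set yet.  A silent passive node then
    leaves the dynamics of everyone else untouched.
    """
    _check_measure(measure)
    lo, hi = MEASURE_RANGES[measure]
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    nodes = tuple(sorted(graph.nodes()))
    missing = [u for u in nodes if u not in characteristics]
    if missing:
        raise ValueError(f"nodes missing characteristics: {missing[:5]}")
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    neigh = [np.array(sorted(idx[v] for v in graph.neighbors(u)), dtype=int) for u in nodes]
    passive = np.zeros(n, dtype=bool)
    for u in passive_targets:
        if u in idx:
            passive[idx[u]] = True
    # spontaneous (initiation/propagation) targets exclude passive nodes
    spont = [nb[~passive[nb]] for nb in neigh]
    p_init = np.array([characteristics[u].p_init for u in nodes])
    p_reply = np.array([characteristics[u].p_reply for u in nodes])
    p_prop = np.array([characteristics[u].p_prop for u in nodes])
    s_base = np.array([characteristics[u].s_baseline for u in nodes])
    s_neutral = np.array([characteristics[u].s_neutral for u in nodes])
    rng = np.random.default_rng(seed)
    cur = s_base.copy()
    recent = np.zeros((n, n), dtype=bool)  # recent[a, s]: s messaged a last step
    ipd = params.iterations_per_day
    steps = n_days * ipd
    col_step: list[np.ndarray] = []
    col_src: list[np.ndarray] = []
    col_dst: list[np.ndarray] = []
    col_k: list[np.ndarray] = []
    col_s: list[np.ndarray] = []
    send = np.zeros((n, n), dtype=bool)
    for step in range(steps):
        send[:] = False
        u3 = rng.random((n, 3))
        for a in range(n):
            nb = neigh[a]
            if nb.size == 0:
                continue
            recent_a = np.flatnonzero(recent[a])
            if recent_a.size == 0:
                sp = spont[a]
                if sp.size and u3[a, 0] < p_init[a]:
                    send[a, sp[rng.integers(sp.size)]] = True
            else:
                if u3[a, 1] < p_reply[a]:
                    send[a, recent_a] = True
                sp = spont[a]
                others = sp[~recent[a, sp]]
                if others.size and u3[a, 2] < p_prop[a]:
                    send[a, others[rng.integers(others.size)]] = True
        pairs = np.argwhere(send)
        if pairs.size:
            src, dst = pairs[:, 0], pairs[:, 1]
            k = 1 + rng.poisson(params.mean_burst - 1.0, size=src.size)
            noise = rng.normal(0.0, params.noise_sd, size=src.size)
            sent_s = np.clip(cur[src] + noise, lo, hi)
            recv_cnt = np.zeros(n)
            recv_sum = np.zeros(n)
            np.add.at(recv_cnt, dst, k)
            np.add.at(recv_sum, dst, k * sent_s)
            got = recv_cnt > 0
            cur[got] += params.contagion * (recv_sum[got] / recv_cnt[got] - s_neutral[got])
            np.clip(cur, lo, hi, out=cur)
            col_step.append(np.full(src.size, step))
            col_src.append(src.copy())
            col_dst.append(dst.copy())
            col_k.append(k)
            col_s.append(sent_s)
        resets = rng.random(n) < params.reset_prob
        cur[resets] = s_base[resets]
        recent = send.T.copy()
    if col_step:
        step_arr = np.concatenate(col_step)
        src_arr = np.concatenate(col_src)
        dst_arr = np.concatenate(col_dst)
        k_arr = np.concatenate(col_k)
        s_arr = np.concatenate(col_s)
    else:
        step_arr = np.empty(0, dtype=int)
        src_arr = dst_arr = k_arr = np.empty(0, dtype=int)
        s_arr = np.empty(0)
    node_arr = np.array(nodes, dtype=object)
    entries = pd.DataFrame(
        {
            "step": step_arr.astype(int),
            "day": (step_arr // ipd).astype(int),
            "sender": node_arr[src_arr] if src_arr.size else np.empty(0, dtype=object),
            "receiver": node_arr[dst_arr] if dst_arr.size else np.empty(0, dtype=object),
            "n_messages": k_arr.astype(int),
            "sentiment": s_arr.astype(float),
        }
    )
    return SimulationLog(
        entries=entries,
        seed=seed if isinstance(seed, int) else None,
        params=params,
        measure=measure,
        nodes=nodes,
        n_days=n_days,
    )


def _daily_counts_and_sentiment(
    days: np.ndarray,
    senders: np.ndarray,
    weights: np.ndarray,
    sentiments: np.ndarray,
    users: Sequence[str],
    n_days: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-user-per-day message counts plus daily weighted sentiment sums."""
    uindex = {u: i for i, u in enumerate(users)}
    counts = np.zeros((len(users), n_days))
    day_w = np.zeros(n_days)
    day_ws = np.zeros(n_days)
    for d, snd, w, s in zip(days, senders, weights, sentiments):
        counts[uindex[snd], d] += w
        if not np.isnan(s):
            day_w[d] += w
            day_ws[d] += w * s
    return counts, day_w, day_ws


def summarize(
    log: SimulationLog | Sequence[MentionEdge],
    n_days: int | None = None,
    users: Sequence[str] | None = None,
    measure: str | None = None,
    start: datetime | None = None,
) -> FitStatistics:
    """Compute the moment summaries used for model-data comparison.

    Works on a :class:`SimulationLog` or on a real :class:`MentionEdge` list
    (then ``measure`` is required and each edge counts as one message, dated
    by UTC day from ``start``, default the first day present).
    """
    if isinstance(log, SimulationLog):
        if n_days is None:
            n_days = log.n_days
        if users is None:
            users = log.nodes
        df = log.entries
        days = df["day"].to_numpy()
        senders = df["sender"].to_numpy()
        weights = df["n_messages"].to_numpy(dtype=float)
        sentiments = df["sentiment"].to_numpy(dtype=float)
    else:
        edges = list(log)
        if measure is None:
            raise ValueError("measure is required for edge-list input")
        if n_days is None:
            raise ValueError("n_days is required for edge-list input")
        if not edges:
            raise ValueError("zero total messages")
        if start is None:
            earliest = min(e.timestamp for e in edges)
            start = earliest.astimezone(timezone.utc).replace(
                hour=0, minute=0, second=0, microsecond=0
            )
        start_date = start.astimezone(timezone.utc).date()
        rows = []
        for e in edges:
            d = (e.timestamp.astimezone(timezone.utc).date() - start_date).days
            if 0 <= d < n_days:
                v = e.scores.combined(measure)
                rows.append((d, e.source, 1.0, np.nan if v is None else v))
        if users is None:
            users = sorted({r[1] for r in rows})
        days = np.array([r[0] for r in rows], dtype=int)
        senders = np.array([r[1] for r in rows], dtype=object)
        weights = np.array([r[2] for r in rows])
        sentiments = np.array([r[3] for r in rows])
    if n_days < 2:
        raise ValueError("n_days must be >= 2 so standard deviations are defined")
    users = tuple(users)
    if weights.sum() == 0:
        raise ValueError("zero total messages")
    user_set = set(users)
    keep = np.array([s in user_set for s in senders], dtype=bool)
    counts, day_w, day_ws = _daily_counts_and_sentiment(
        days[keep], senders[keep], weights[keep], sentiments[keep], users, n_days
    )
    has = day_w > 0
    daily_sent = day_ws[has] / day_w[has]
    if daily_sent.size == 0:
        raise ValueError("no scored messages to summarise")
    return FitStatistics(
        users=users,
        count_mean=counts.mean(axis=1),
        count_std=counts.std(axis=1, ddof=0),
        sentiment_mean=float(daily_sent.mean()),
        sentiment_std=float(daily_sent.std(ddof=0)),
        n_days=n_days,
    )


def community_moments(log: SimulationLog, n_days: int | None = None) -> dict[str, float]:
    """Community-level activity and sentiment moments of one run.

    Returns daily-total message count mean/SD (all days, zero-message days
    count 0) and daily message-weighted sentiment mean/SD (zero-message days
    excluded), the four quantities reported in scenario analyses.
    """
    if n_days is None:
        n_days = log.n_days
    df = log.entries
    totals = np.zeros(n_days)
    day_w = np.zeros(n_days)
    day_ws = np.zeros(n_days)
    if len(df):
        d = df["day"].to_numpy()
        w = df["n_messages"].to_numpy(dtype=float)
        s = df["sentiment"].to_numpy(dtype=float)
        np.add.at(totals, d, w)
        np.add.at(day_w, d, w)
        np.add.at(day_ws, d, w * s)
    has = day_w > 0
    daily_sent = day_ws[has] / day_w[has] if has.any() else np.array([np.nan])
    return {
        "activity_mean": float(totals.mean()),
        "activity_std": float(totals.std(ddof=0)),
        "sentiment_mean": float(np.mean(daily_sent)),
        "sentiment_std": float(np.std(daily_sent, ddof=0)),
    }


def export_simulation_log(log: SimulationLog, dest) -> None:
    """Write a simulation log as TSV (step, day, sender, receiver, n_messages, sentiment)."""
    from pathlib import Path

    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            export_simulation_log(log, fh)
        return
    log.entries.to_csv(dest, sep="\t", index=False)
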