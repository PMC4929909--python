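"""Community quality, endurance and daily sentiment series.

Candidate communities (membership lists produced by any detection algorithm)
are scored on the *exchange graph*: an undirected graph whose edge weight
between users i and j is the number of messages exchanged in either
direction, ``W_ij + W_ji``.  Conductance is the ratio of the cut between a
community S and the rest to the smaller side's volume; values near 0 mean a
tightly knit, well-separated group.  The weighted variant uses message
counts:

    phi_w(S) = sum_{i in S, j not in S} W_ij / min(a(S), a(S-bar)),

with ``a(S) = sum_{i in S} sum_{j in V} W_ij`` on exchange weights.

Endurance between two observation windows is summarised by the *user loss
factor*: members active (incident to at least one internal mention) in the
first window divided by those active in the second; 1 means full retention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta, timezone
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .measures import MEASURES, _check_measure
from .message_log import MentionEdge

PARTICIPATION_BIN_LABELS = ("0-20%", "20-40%", "40-60%", "60-80%", "80-100%")


class WeightedMentionGraph:
    """Directed message counts between users plus the symmetric exchange view."""

    def __init__(self, weights: Mapping[tuple[str, str], int]) -> None:
        self._w: dict[tuple[str, str], int] = {}
        nodes: set[str] = set()
        for (u, v), w in weights.items():
            if u == v:
                raise ValueError("self-loops are not allowed")
            if w < 0:
                raise ValueError("weights must be nonnegative")
            if w:
                self._w[(u, v)] = int(w)
            nodes.update((u, v))
        self.nodes: frozenset[str] = frozenset(nodes)

    @classmethod
    def from_edges(cls, edges: Iterable[MentionEdge]) -> "WeightedMentionGraph":
        weights: dict[tuple[str, str], int] = {}
        for e in edges:
            key = (e.source, e.target)
            weights[key] = weights.get(key, 0) + 1
        return cls(weights)

    def weight(self, u: str, v: str) -> int:
        return self._w.get((u, v), 0)

    def exchange_weight(self, u: str, v: str) -> int:
        return self.weight(u, v) + self.weight(v, u)

    def exchange_graph(self) -> nx.Graph:
        """Undirected graph with ``weight`` = messages exchanged either way."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self._w.items():
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
            else:
                g.add_edge(u, v, weight=w)
        return g


def _check_community(graph: WeightedMentionGraph, members: Iterable[str]) -> set[str]:
    s = set(members)
    if not s:
        raise ValueError("community must be nonempty")
    s_in = s & graph.nodes
    if not s_in:
        raise ValueError("community has no members present in the graph")
    if s_in == graph.nodes:
        raise ValueError("community equals the whole vertex set")
    return s_in


def _conductance(g: nx.Graph, s: set[str], weight: str | None) -> float:
    t = set(g.nodes) - s
    cut = nx.cut_size(g, s, t, weight=weight)
    if cut == 0:
        return 0.0
    vol_s = nx.volume(g, s, weight=weight)
    vol_t = nx.volume(g, t, weight=weight)
    return float(cut / min(vol_s, vol_t))


def conductance(graph: WeightedMentionGraph, members: Iterable[str]) -> float:
    """Unweighted conductance of a community on the exchange graph.

    Counts each undirected exchange edge once in the cut and each
    edge-endpoint incidence once in the volumes; 0 iff no boundary edges.
    """
    s = _check_community(graph, members)
    return _conductance(graph.exchange_graph(), s, weight=None)


def weighted_conductance(graph: WeightedMentionGraph, members: Iterable[str]) -> float:
    """Message-count-weighted conductance of a community."""
    s = _check_community(graph, members)
    g = graph.exchange_graph()
    if sum(d["weight"] for _, _, d in g.edges(data=True)) == 0:
        raise ValueError("zero-weight graph")
    return _conductance(g, s, weight="weight")


@dataclass(frozen=True)
class ParticipationBreakdown:
    """Average participation percentage and its five-bin histogram."""

    average_pct: float
    bins: tuple[float, float, float, float, float]


@dataclass(frozen=True)
class CommunityReport:
    """Summary statistics for one candidate community."""

    members: frozenset[str]
    n_nodes: int
    n_internal_mentions: int
    internal_mentions_per_node: float
    conductance: float | None
    weighted_conductance: float | None
    mean_sentiment: dict[str, float | None]
    connected: bool
    nonzero_sentiment_fraction: float
    participation: ParticipationBreakdown | None = None


@dataclass(frozen=True)
class EnduranceRecord:
    """Active-member counts in two windows and their ratio (user loss factor)."""

    community_id: str
    active_autumn: int
    active_spring: int
    user_loss_factor: float


def community_report(
    edges: Sequence[MentionEdge],
    members: Iterable[str],
    measures: Iterable[str] = MEASURES,
    primary_measure: str = "MC",
    participation: ParticipationBreakdown | None = None,
) -> CommunityReport:
    """Score one community against the full edge list.

    Internal mentions are edges with both endpoints in the community.
    Mean sentiment is edge-weighted (per mention) over internal edges for
    each requested measure; the non-zero-sentiment fraction uses
    ``primary_measure`` and treats an absent score as zero ("neutral or not
    detected").  Connectedness is evaluated on the undirected internal graph
    over all members.  Conductance is relative to the whole network and is
    ``None`` when undefined (community spans every user in the edge list).
    """
    _check_measure(primary_measure)
    s = set(members)
    if not s:
        raise ValueError("community must be nonempty")
    internal = [e for e in edges if e.source in s and e.target in s]
    n_internal = len(internal)
    if n_internal == 0:
        warnings.warn("community has no internal mentions", stacklevel=2)
    mean_sent: dict[str, float | None] = {}
    for m in measures:
        vals = [v for e in internal if (v := e.scores.combined(m)) is not None]
        mean_sent[m] = float(np.mean(vals)) if vals else None
    nonzero = sum(
        1 for e in internal if (e.scores.combined(primary_measure) or 0.0) != 0.0
    )
    g_int = nx.Graph()
    g_int.add_nodes_from(s)
    g_int.add_edges_from((e.source, e.target) for e in internal)
    connected = n_internal > 0 and nx.is_connected(g_int)
    graph = WeightedMentionGraph.from_edges(edges)
    cond: float | None = None
    wcond: float | None = None
    try:
        cond = conductance(graph, s)
        wcond = weighted_conductance(graph, s)
    except ValueError:
        pass
    return CommunityReport(
        members=frozenset(s),
        n_nodes=len(s),
        n_internal_mentions=n_internal,
        internal_mentions_per_node=n_internal / len(s),
        conductance=cond,
        weighted_conductance=wcond,
        mean_sentiment=mean_sent,
        connected=connected,
        nonzero_sentiment_fraction=(nonzero / n_internal) if n_internal else 0.0,
        participation=participation,
    )


def participation_breakdown(
    overall_active_days: Mapping[str, set],
    community_active_days: Mapping[str, set],
) -> ParticipationBreakdown:
    """Average participation percentage and five-bin histogram across users.

    For each user, participation is the percentage of their overall active
    days on which they posted within the community.  Bins are
    [0,20), [20,40), [40,60), [60,80), [80,100] — a 100% participant falls
    in the top bin.
    """
    users = sorted(overall_active_days)
    if not users:
        raise ValueError("no users")
    pcts = []
    counts = np.zeros(5)
    for u in users:
        overall = overall_active_days[u]
        if not overall:
            raise ValueError(f"user {u} has zero overall active days")
        within = community_active_days.get(u, set()) & set(overall)
        pct = 100.0 * len(within) / len(overall)
        pcts.append(pct)
        counts[min(int(pct // 20), 4)] += 1
    bins = tuple(counts / len(users))
    return ParticipationBreakdown(average_pct=float(np.mean(pcts)), bins=bins)


def user_loss_factor(
    active_window1: Iterable[str],
    active_window2: Iterable[str],
    members: Iterable[str],
    community_id: str = "",
) -> EnduranceRecord:
    """User loss factor between two windows for one community.

    Counts members active (mentioned or were mentioned within the community)
    in each window; the factor is ``active_window1 / active_window2``.
    """
    s = set(members)
    a1 = len(set(active_window1) & s)
    a2 = len(set(active_window2) & s)
    if a1 == 0:
        raise ValueError("no members active in window 1")
    if a2 == 0:
        raise ValueError("community dissolved: no members active in window 2")
    return EnduranceRecord(
        community_id=community_id,
        active_autumn=a1,
        active_spring=a2,
        user_loss_factor=a1 / a2,
    )


def active_members(edges: Iterable[MentionEdge], members: Iterable[str]) -> set[str]:
    """Members incident to at least one internal mention in the edge list."""
    s = set(members)
    active: set[str] = set()
    for e in edges:
        if e.source in s and e.target in s:
            active.update((e.source, e.target))
    return active


def daily_sentiment_series(
    edges: Iterable[MentionEdge],
    measure: str,
    start_day: date,
    n_days: int,
    z: float = 2.5,
) -> pd.DataFrame:
    """Per-day mean sentiment of internal mentions, with deviation flags.

    Returns a DataFrame indexed by date with columns ``mean_sentiment``
    (NaN on days with no scored edges), ``n_edges`` and ``flag``.  A day is
    flagged when its mean deviates from the series mean by more than ``z``
    series standard deviations (population SD over days with data) —
    candidate dates for attributing sentiment spikes to external events.
    """
    _check_measure(measure)
    if n_days < 1:
        raise ValueError("window must be nonempty")
    sums = np.zeros(n_days)
    counts = np.zeros(n_days, dtype=int)
    for e in edges:
        d = (e.timestamp.astimezone(timezone.utc).date() - start_day).days
        if not 0 <= d < n_days:
            continue
        v = e.scores.combined(measure)
        if v is None:
            continue
        sums[d] += v
        counts[d] += 1
    means = np.full(n_days, np.nan)
    has = counts > 0
    means[has] = sums[has] / counts[has]
    flags = np.zeros(n_days, dtype=bool)
    if has.any():
        centre = float(means[has].mean())
        sd = float(means[has].std(ddof=0))
        flags[has] = np.abs(means[has] - centre) > z * sd
    dates = [start_day + timedelta(days=d) for d in range(n_days)]
    return pd.DataFrame(
        {"mean_sentiment": means, "n_edges": counts, "flag": flags},
        index=pd.Index(dates, name="date"),
    )
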