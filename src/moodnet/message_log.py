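"""Scored message logs, mention edges, daily snapshot networks and outlier
screening.

The on-disk format is JSON Lines (UTF-8): one object per message with keys
``message_id``, ``author``, ``timestamp`` (ISO-8601 with a zone), ``mentions``
(array of user ids) and ``scores`` (object with any of ``mc``, ``ss_pos``,
``ss_neg``, ``l_posemo``, ``l_negemo``; a missing key means the score is
absent, never zero).

A message mentioning several distinct users induces one directed mention edge
per distinct recipient.  Self-mentions are dropped and duplicate mentions of
the same user within one message collapse to a single edge, so the networks
connect distinct users and daily adjacency snapshots are binary with a zero
diagonal.  Day boundaries fall at 00:00 UTC and windows are half-open.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timezone
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .measures import combine_liwc, combine_ss

SCHEMA_VERSIONS = ("1",)


class MessageLogError(ValueError):
    """Raised for malformed message-log input."""


@dataclass(frozen=True)
class SentimentScores:
    """Per-message sentiment components; ``None`` marks an absent score."""

    mc: int | None = None
    ss_pos: int | None = None
    ss_neg: int | None = None
    l_posemo: float | None = None
    l_negemo: float | None = None

    def __post_init__(self) -> None:
        if self.mc is not None and not -25 <= self.mc <= 25:
            raise ValueError(f"mc must be in [-25, 25], got {self.mc}")
        for name in ("ss_pos", "ss_neg"):
            v = getattr(self, name)
            if v is not None and not 1 <= v <= 5:
                raise ValueError(f"{name} must be in [1, 5], got {v}")
        for name in ("l_posemo", "l_negemo"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")

    @property
    def ss(self) -> int | None:
        """Combined SentiStrength score (``ss_pos - ss_neg``), or ``None``."""
        if self.ss_pos is None or self.ss_neg is None:
            return None
        return combine_ss(self.ss_pos, self.ss_neg)

    @property
    def l(self) -> float | None:
        """Combined LIWC score (``l_posemo - l_negemo``), or ``None``."""
        if self.l_posemo is None or self.l_negemo is None:
            return None
        return combine_liwc(self.l_posemo, self.l_negemo)

    def combined(self, measure: str) -> float | None:
        """The combined score on the given measure, or ``None`` if absent."""
        if measure == "MC":
            return None if self.mc is None else float(self.mc)
        if measure == "SS":
            v = self.ss
            return None if v is None else float(v)
        if measure == "L":
            return self.l
        raise ValueError(f"unknown measure {measure!r}")

    def to_json_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("mc", "ss_pos", "ss_neg", "l_posemo", "l_negemo")
            if getattr(self, k) is not None
        }


@dataclass(frozen=True)
class MessageRecord:
    """One scored public message: author, UTC instant, mentioned users."""

    message_id: str
    author: str
    timestamp: datetime
    mentions: tuple[str, ...]
    scores: SentimentScores = field(default_factory=SentimentScores)

    def __post_init__(self) -> None:
        if not self.author:
            raise ValueError("author must be nonempty")
        if self.timestamp.tzinfo is None:
            raise ValueError("timestamp must be timezone-resolved")
        object.__setattr__(self, "mentions", tuple(self.mentions))

    def to_json_dict(self) -> dict:
        return {
            "message_id": self.message_id,
            "author": self.author,
            "timestamp": self.timestamp.astimezone(timezone.utc).isoformat(),
            "mentions": list(self.mentions),
            "scores": self.scores.to_json_dict(),
        }


@dataclass(frozen=True)
class MentionEdge:
    """A directed mention ``source -> target`` carrying its message's scores."""

    source: str
    target: str
    timestamp: datetime
    day_index: int
    scores: SentimentScores = field(default_factory=SentimentScores)

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-mention edges are not allowed")


class EvolvingNetwork:
    """An ordered sequence of daily binary directed adjacency snapshots.

    All snapshots share one node index (user id -> 0..N-1); entries are 0/1
    with a zero diagonal and are stored sparsely.
    """

    def __init__(
        self,
        users: Sequence[str],
        snapshots: Sequence[sp.spmatrix],
        start_day: date | None = None,
    ) -> None:
        self.users: tuple[str, ...] = tuple(users)
        self.node_index: dict[str, int] = {u: i for i, u in enumerate(self.users)}
        if len(self.node_index) != len(self.users):
            raise ValueError("duplicate user ids in node index")
        n = len(self.users)
        snaps = []
        for a in snapshots:
            a = sp.csr_matrix(a, shape=(n, n), dtype=np.int8)
            if a.diagonal().any():
                raise ValueError("snapshot has nonzero diagonal (self-loop)")
            a.data = np.minimum(a.data, 1).astype(np.int8)
            snaps.append(a)
        self.snapshots: tuple[sp.csr_matrix, ...] = tuple(snaps)
        self.start_day = start_day

    def __len__(self) -> int:
        return len(self.users)

    @property
    def n_days(self) -> int:
        return len(self.snapshots)


@dataclass(frozen=True)
class FilterConfig:
    """Caps for screening outlier users over an observation window.

    ``celebrity_cap``: maximum distinct inbound mentioners a user may have.
    ``bot_cap``: maximum distinct outbound mentionees an author may have.
    Users exceeding a cap are excluded.  ``math.inf`` disables a cap.
    """

    celebrity_cap: float = 5000
    bot_cap: float = 5000

    def __post_init__(self) -> None:
        if self.celebrity_cap <= 0 or self.bot_cap <= 0:
            raise ValueError("filter caps must be positive")


@dataclass(frozen=True)
class FilterReport:
    """Users removed by :func:`filter_outliers`, by reason."""

    celebrities: frozenset[str]
    bots: frozenset[str]

    @property
    def excluded(self) -> frozenset[str]:
        return self.celebrities | self.bots


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        raise ValueError("timestamp lacks a timezone")
    return ts.astimezone(timezone.utc)


def read_message_log(
    stream: IO[str] | str | Path | Iterable[str],
    schema_version: str = "1",
) -> list[MessageRecord]:
    """Read a JSON-Lines message log, preserving file order.

    ``stream`` may be a path, an open text file, or any iterable of lines.
    Malformed lines raise :class:`MessageLogError` naming the line number.
    """
    if schema_version not in SCHEMA_VERSIONS:
        raise MessageLogError(f"unknown schema_version {schema_version!r}")
    if isinstance(stream, (str, Path)):
        with open(stream, "r", encoding="utf-8") as fh:
            return read_message_log(fh, schema_version)
    records: list[MessageRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise MessageLogError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
        try:
            scores = SentimentScores(**obj.get("scores", {}))
            record = MessageRecord(
                message_id=str(obj["message_id"]),
                author=obj["author"],
                timestamp=_parse_timestamp(obj["timestamp"]),
                mentions=tuple(obj.get("mentions", ())),
                scores=scores,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise MessageLogError(f"line {lineno}: {exc}") from exc
        records.append(record)
    return records


def write_message_log(records: Iterable[MessageRecord], dest: IO[str] | str | Path) -> None:
    """Write records as JSON Lines (inverse of :func:`read_message_log`)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            write_message_log(records, fh)
        return
    for record in records:
        dest.write(json.dumps(record.to_json_dict()) + "\n")


def _utc_date(ts: datetime) -> date:
    return ts.astimezone(timezone.utc).date()


def extract_edges(
    records: Iterable[MessageRecord],
    epoch: date | None = None,
) -> list[MentionEdge]:
    """Derive directed mention edges: one per (message, distinct recipient).

    Self-mentions and repeated mentions of the same user within one message
    are dropped.  ``day_index`` is the 0-based UTC day offset from ``epoch``
    (default: the UTC date of the earliest record).
    """
    records = list(records)
    if epoch is None:
        if not records:
            return []
        epoch = min(_utc_date(r.timestamp) for r in records)
    edges: list[MentionEdge] = []
    for record in records:
        seen: set[str] = set()
        for target in record.mentions:
            if target == record.author or target in seen:
                continue
            seen.add(target)
            edges.append(
                MentionEdge(
                    source=record.author,
                    target=target,
                    timestamp=record.timestamp,
                    day_index=(_utc_date(record.timestamp) - epoch).days,
                    scores=record.scores,
                )
            )
    return edges


def build_daily_snapshots(
    edges: Iterable[MentionEdge],
    start_day: date,
    n_days: int,
) -> EvolvingNetwork:
    """Build binary daily adjacency snapshots over ``[start_day, start_day+n_days)``.

    ``A_t[i, j] = 1`` iff at least one mention ``i -> j`` is dated (UTC) to day
    ``t``.  Edges outside the window are ignored; the node index covers exactly
    the users incident to retained edges, in sorted order.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    retained: list[tuple[int, str, str]] = []
    for e in edges:
        d = (_utc_date(e.timestamp) - start_day).days
        if 0 <= d < n_days:
            retained.append((d, e.source, e.target))
    if not retained:
        raise ValueError("empty network: no edges fall inside the window")
    users = sorted({u for _, s, t in retained for u in (s, t)})
    index = {u: i for i, u in enumerate(users)}
    n = len(users)
    by_day: list[list[tuple[int, int]]] = [[] for _ in range(n_days)]
    for d, s, t in retained:
        by_day[d].append((index[s], index[t]))
    snapshots = []
    for pairs in by_day:
        if pairs:
            rows, cols = zip(*pairs)
            a = sp.coo_matrix(
                (np.ones(len(pairs), dtype=np.int8), (rows, cols)), shape=(n, n)
            ).tocsr()
            a.data = np.minimum(a.data, 1).astype(np.int8)
        else:
            a = sp.csr_matrix((n, n), dtype=np.int8)
        snapshots.append(a)
    return EvolvingNetwork(users, snapshots, start_day=start_day)


def filter_outliers(
    records: Iterable[MessageRecord],
    caps: FilterConfig,
) -> tuple[list[MessageRecord], FilterReport]:
    """Screen out outlier users (celebrities and bots) from a message log.

    A *celebrity* is mentioned by more distinct users than ``caps.celebrity_cap``;
    a *bot* mentions more distinct users than ``caps.bot_cap`` (distinct,
    non-self recipients over the whole log).  Records authored by excluded
    users are removed, and mentions pointing at excluded users are stripped
    from the remaining records.
    """
    records = list(records)
    inbound: dict[str, set[str]] = {}
    outbound: dict[str, set[str]] = {}
    for r in records:
        targets = {m for m in r.mentions if m != r.author}
        outbound.setdefault(r.author, set()).update(targets)
        for t in targets:
            inbound.setdefault(t, set()).add(r.author)
    celebrities = frozenset(
        u for u, who in inbound.items() if len(who) > caps.celebrity_cap
    )
    bots = frozenset(u for u, whom in outbound.items() if len(whom) > caps.bot_cap)
    excluded = celebrities | bots
    kept: list[MessageRecord] = []
    for r in records:
        if r.author in excluded:
            continue
        if any(m in excluded for m in r.mentions):
            r = replace(r, mentions=tuple(m for m in r.mentions if m not in excluded))
        kept.append(r)
    return kept, FilterReport(celebrities=celebrities, bots=bots)


# ---------------------------------------------------------------------------
# Tabular exports

def export_edges_tsv(edges: Iterable[MentionEdge], dest: IO[str] | str | Path) -> None:
    """Export edges as TSV: source, target, timestamp, day_index, mc, ss, l."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            export_edges_tsv(edges, fh)
        return
    dest.write("source\ttarget\ttimestamp\tday_index\tmc\tss\tl\n")
    for e in edges:
        combined = [e.scores.combined(m) for m in ("MC", "SS", "L")]
        cells = [
            e.source,
            e.target,
            e.timestamp.astimezone(timezone.utc).isoformat(),
            str(e.day_index),
            *["" if c is None else f"{c:g}" for c in combined],
        ]
        dest.write("\t".join(cells) + "\n")


def export_snapshots(network: EvolvingNetwork, out_dir: str | Path) -> None:
    """Write snapshots as TSV triplets ``(t, i, j)`` plus a node-index sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "nodes.tsv", "w", encoding="utf-8") as fh:
        fh.write("index\tuser\n")
        for i, u in enumerate(network.users):
            fh.write(f"{i}\t{u}\n")
    with open(out / "snapshots.tsv", "w", encoding="utf-8") as fh:
        fh.write("t\ti\tj\n")
        for t, a in enumerate(network.snapshots):
            coo = a.tocoo()
            for i, j in zip(coo.row, coo.col):
                fh.write(f"{t}\t{i}\t{j}\n")
    if network.start_day is not None:
        (out / "start_day.txt").write_text(network.start_day.isoformat() + "\n")


def read_snapshots(in_dir: str | Path) -> EvolvingNetwork:
    """Read an :class:`EvolvingNetwork` written by :func:`export_snapshots`."""
    src = Path(in_dir)
    users: list[str] = []
    with open(src / "nodes.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            _, u = line.rstrip("\n").split("\t")
            users.append(u)
    n = len(users)
    triplets: list[tuple[int, int, int]] = []
    with open(src / "snapshots.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            t, i, j = (int(x) for x in line.split("\t"))
            triplets.append((t, i, j))
    n_days = max(t for t, _, _ in triplets) + 1 if triplets else 0
    snapshots = []
    for t in range(n_days):
        pairs = [(i, j) for tt, i, j in triplets if tt == t]
        if pairs:
            rows, cols = zip(*pairs)
            a = sp.coo_matrix((np.ones(len(pairs)), (rows, cols)), shape=(n, n)).tocsr()
        else:
            a = sp.csr_matrix((n, n))
        snapshots.append(a)
    start_file = src / "start_day.txt"
    start = date.fromisoformat(start_file.read_text().strip()) if start_file.exists() else None
    return EvolvingNetwork(users, snapshots, start_day=start)
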