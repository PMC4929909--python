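"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from moodnet.message_log import MentionEdge, MessageRecord, SentimentScores

T0 = datetime(2014, 10, 9, tzinfo=timezone.utc)


def record(
    author: str,
    mentions: tuple[str, ...] = (),
    ts: datetime | None = None,
    message_id: str = "m0",
    **scores,
) -> MessageRecord:
    return MessageRecord(
        message_id=message_id,
        author=author,
        timestamp=ts or T0,
        mentions=mentions,
        scores=SentimentScores(**scores),
    )


def edge(
    source: str,
    target: str,
    day: int = 0,
    hour: int = 0,
    **scores,
) -> MentionEdge:
    return MentionEdge(
        source=source,
        target=target,
        timestamp=T0 + timedelta(days=day, hours=hour),
        day_index=day,
        scores=SentimentScores(**scores),
    )


def mc_edges(user: str, values, target: str = "x") -> list[MentionEdge]:
    """Outgoing MC-scored edges for one user, one edge per value."""
    return [edge(user, f"{target}{i}", mc=int(v)) for i, v in enumerate(values)]


def walk_count_oracle(snapshots, alpha: float, max_len: int = 12) -> np.ndarray:
    """Truncated time-respecting walk counting, independent of the resolvent
    path: dynamic programme over (snapshots used, total walk length), with
    walks weighted by alpha**length.  Hops may use snapshots only in
    non-decreasing time order, any number of consecutive hops per snapshot.
    """
    import scipy.sparse as sp

    mats = [
        a.toarray().astype(float) if sp.issparse(a) else np.asarray(a, dtype=float)
        for a in snapshots
    ]
    n = mats[0].shape[0]
    by_len = [np.eye(n)] + [np.zeros((n, n)) for _ in range(max_len)]
    for a in mats:
        powers = [np.eye(n)]
        for _ in range(max_len):
            powers.append(powers[-1] @ a)
        new = []
        for total in range(max_len + 1):
            acc = np.zeros((n, n))
            for k in range(total + 1):
                acc += by_len[total - k] @ powers[k]
            new.append(acc)
        by_len = new
    q = np.zeros((n, n))
    for length, m in enumerate(by_len):
        q += alpha**length * m
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(20140922)
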