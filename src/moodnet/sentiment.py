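"""User-level sentiment attributes and group comparisons.

Sentiment is scored per message, but questions about *users* (do the top
broadcasters use sentiment differently?) need per-user aggregates.  Seven
attributes summarise the combined scores on a user's outgoing mention edges:
mean, mean absolute value, the positive/zero/negative fractions, and the
average positive and negative strengths (each strength normalised by the
total outgoing-edge count, so that
``avg_pos_strength - avg_neg_strength == mean_sentiment``).

Group-vs-population differences are assessed with one-sided randomization
tests: the observed group mean is compared with means of uniformly drawn
same-size subsets, and the p-value uses the ``(r+1)/(n+1)`` estimator with
ties counted as exceedances, so it is conservative and never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .measures import _check_measure
from .message_log import MentionEdge


@dataclass(frozen=True)
class UserSentimentProfile:
    """The seven aggregate sentiment attributes for one user and measure."""

    measure: str
    mean_sentiment: float
    mean_abs_sentiment: float
    pos_fraction: float
    zero_fraction: float
    neg_fraction: float
    avg_pos_strength: float
    avg_neg_strength: float
    n_edges: int


@dataclass(frozen=True)
class GroupComparison:
    """Result of a one-sided randomization test of a group mean."""

    attribute: str
    group_mean: float
    population_mean: float
    p_value: float
    n_resamples: int
    side: str


def _combined_scores(edges: Sequence[MentionEdge], measure: str) -> np.ndarray:
    scores = []
    for e in edges:
        v = e.scores.combined(measure)
        if v is None:
            raise ValueError(
                f"edge {e.source}->{e.target} lacks the components of measure {measure}"
            )
        scores.append(v)
    return np.asarray(scores, dtype=float)


def user_attributes(
    outgoing: Sequence[MentionEdge],
    measure: str,
) -> UserSentimentProfile:
    """Compute the seven sentiment attributes from one user's outgoing edges.

    For ``MC`` (no separate components) the mean absolute sentiment is the
    mean of ``|score|``; for ``SS`` and ``L`` it is the mean, over edges, of
    the sum of the absolute values of the positive and negative components.
    """
    _check_measure(measure)
    outgoing = list(outgoing)
    if not outgoing:
        raise ValueError("no outgoing edges")
    s = _combined_scores(outgoing, measure)
    n = len(s)
    if measure == "MC":
        mean_abs = float(np.mean(np.abs(s)))
    elif measure == "SS":
        comps = [(e.scores.ss_pos, e.scores.ss_neg) for e in outgoing]
        mean_abs = float(np.mean([abs(p) + abs(q) for p, q in comps]))
    else:  # L
        comps = [(e.scores.l_posemo, e.scores.l_negemo) for e in outgoing]
        mean_abs = float(np.mean([abs(p) + abs(q) for p, q in comps]))
    return UserSentimentProfile(
        measure=measure,
        mean_sentiment=float(np.mean(s)),
        mean_abs_sentiment=mean_abs,
        pos_fraction=float(np.mean(s > 0)),
        zero_fraction=float(np.mean(s == 0)),
        neg_fraction=float(np.mean(s < 0)),
        avg_pos_strength=float(s[s > 0].sum() / n),
        avg_neg_strength=float(-s[s < 0].sum() / n),
        n_edges=n,
    )


def randomization_test(
    values: Sequence[float] | np.ndarray,
    group: Sequence[int],
    side: str = "greater",
    n_resamples: int = 999,
    seed: int | np.random.Generator | None = None,
    attribute: str = "",
) -> GroupComparison:
    """One-sided randomization test of a group mean against the population.

    The null distribution consists of means of ``n_resamples`` subsets of size
    ``len(group)`` drawn uniformly without replacement from the whole
    population.  ``p = (r + 1) / (n_resamples + 1)`` where ``r`` counts null
    means ``>=`` (side ``"greater"``) or ``<=`` (side ``"less"``) the observed
    group mean; ties count as exceedances.  Deterministic given ``seed``.
    """
    if side not in ("greater", "less"):
        raise ValueError(f"side must be 'greater' or 'less', got {side!r}")
    if n_resamples < 99:
        raise ValueError("n_resamples must be >= 99")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n <= 1:
        raise ValueError("degenerate population (size <= 1)")
    group_idx = np.asarray(list(group), dtype=int)
    g = len(group_idx)
    if not 1 <= g < n:
        raise ValueError("group size must be >= 1 and < population size")
    observed = float(values[group_idx].mean())
    rng = np.random.default_rng(seed)
    if n * n_resamples <= 50_000_000:
        # vectorised: each row of a random key matrix selects a subset
        keys = rng.random((n_resamples, n))
        subsets = np.argpartition(keys, g - 1, axis=1)[:, :g]
        null_means = values[subsets].mean(axis=1)
    else:
        null_means = np.empty(n_resamples)
        for i in range(n_resamples):
            null_means[i] = values[rng.choice(n, size=g, replace=False)].mean()
    if side == "greater":
        r = int(np.sum(null_means >= observed))
    else:
        r = int(np.sum(null_means <= observed))
    return GroupComparison(
        attribute=attribute,
        group_mean=observed,
        population_mean=float(values.mean()),
        p_value=(r + 1) / (n_resamples + 1),
        n_resamples=n_resamples,
        side=side,
    )


def rank_moving_average(
    values_by_rank: Sequence[float] | np.ndarray,
    window: int,
) -> np.ndarray:
    """Moving average over a rank-ordered attribute vector.

    ``out[k]`` is the mean of ``values_by_rank[k : k + window]``; the output
    has length ``len(values) - window + 1``.  Used to smooth noisy per-rank
    curves (e.g. sentiment fraction against broadcast rank) with windows on
    the order of 1000 observations.
    """
    values = np.asarray(values_by_rank, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(values):
        raise ValueError("window exceeds vector length")
    windows = np.lib.stride_tricks.sliding_window_view(values, window)
    return windows.mean(axis=1)


def attribute_table(
    edges_by_user: dict[str, Sequence[MentionEdge]],
    measures: Iterable[str] = ("MC", "SS", "L"),
):
    """Per-user attribute table as a pandas DataFrame (one row per user/measure)."""
    import pandas as pd

    rows = []
    for user in sorted(edges_by_user):
        for m in measures:
            try:
                prof = user_attributes(edges_by_user[user], m)
            except ValueError:
                continue
            rows.append({"user": user, **prof.__dict__})
    return pd.DataFrame(rows)
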