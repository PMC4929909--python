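"""Method-of-simulated-moments calibration and what-if scenarios.

A simulation run is scored against real data with

    rho = a * sum_i |<C_i> - <C^_i>|  +  b * sum_i |std(C_i) - std(C^_i)|
        + g * |<E_c> - <E^_c>|        +  d * |std(E_c) - std(E^_c)|,

where ``<C_i>``/``std(C_i)`` are the mean and SD of user i's daily message
count and ``<E_c>``/``std(E_c)`` those of the daily community sentiment
(hats denote simulated values).  Smaller is better.  The default constants
``(a, b, g, d) = (1, 0.1, 10, 100)`` put strong emphasis on matching the
volatility of daily community sentiment and prioritise activity levels over
activity volatility.

Calibration runs an iterative grid search: at each zoom the full parameter
grid is evaluated (mean rho over several seeded runs per point), then the
grid re-centres on the best point with its span halved, clipped to the
original ranges.  The *new-user scenario* adds a vocal agent (probabilities
a multiple of the community maxima, sentiment at the community level) wired
to chosen neighbours and compares community moments against baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .abm import (
    AgentCharacteristics,
    FitStatistics,
    GlobalParams,
    community_moments,
    simulate,
    summarize,
)

#: Parameters searched on integer grids.
INTEGER_PARAMS = frozenset({"iterations_per_day", "neighbour_threshold"})

#: Default search ranges bracketing plausibly calibrated values.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "iterations_per_day": (96, 3072),
    "mean_burst": (1.0, 4.0),
    "contagion": (0.0, 0.5),
    "reset_prob": (0.0, 0.3),
    "noise_sd": (0.0, 12.0),
    "neighbour_threshold": (0, 40),
}

SCENARIO_RULES = ("most_positive", "most_negative", "highest_reply", "lowest_reply")


@dataclass(frozen=True)
class RhoConstants:
    """Weights of the four terms of the rho score."""

    alpha_rho: float = 1.0
    beta_rho: float = 0.1
    gamma_rho: float = 10.0
    delta_rho: float = 100.0

    def __post_init__(self) -> None:
        vals = (self.alpha_rho, self.beta_rho, self.gamma_rho, self.delta_rho)
        if any(v < 0 for v in vals):
            raise ValueError("rho constants must be nonnegative")
        if all(v == 0 for v in vals):
            raise ValueError("rho constants must not all be zero")


@dataclass
class CalibrationResult:
    best_params: GlobalParams
    best_score: float
    trace: list[dict]
    runs_per_combo: int
    n_zooms: int
    seed: int


@dataclass(frozen=True)
class ScenarioReport:
    """Baseline vs modified community moments for one wiring rule."""

    rule: str
    baseline: dict[str, float]
    modified: dict[str, float]
    n_runs: int


def rho(
    real: FitStatistics,
    sim: FitStatistics,
    constants: RhoConstants = RhoConstants(),
) -> float:
    """Score a simulation's moment summaries against the real ones (>= 0)."""
    if real.users != sim.users:
        raise ValueError("mismatched user sets between real and simulated summaries")
    return float(
        constants.alpha_rho * np.abs(real.count_mean - sim.count_mean).sum()
        + constants.beta_rho * np.abs(real.count_std - sim.count_std).sum()
        + constants.gamma_rho * abs(real.sentiment_mean - sim.sentiment_mean)
        + constants.delta_rho * abs(real.sentiment_std - sim.sentiment_std)
    )


def _grid_values(lo: float, hi: float, grid_points: int, integer: bool) -> list[float]:
    if lo > hi:
        raise ValueError("empty range")
    raw = np.linspace(lo, hi, grid_points)
    if integer:
        vals = sorted(set(int(round(v)) for v in raw))
        return [float(v) for v in vals]
    return [float(v) for v in raw]


def mean_rho_at(
    params: GlobalParams,
    real_stats: FitStatistics,
    graph: nx.Graph,
    characteristics: Mapping[str, AgentCharacteristics],
    n_runs: int,
    seed_entropy: Sequence[int],
    n_days: int,
    measure: str,
    constants: RhoConstants = RhoConstants(),
) -> tuple[float, float]:
    """Mean and standard error of rho over ``n_runs`` seeded simulation runs."""
    ss = np.random.SeedSequence(list(seed_entropy))
    scores = []
    for child in ss.spawn(n_runs):
        log = simulate(graph, characteristics, params, n_days, np.random.default_rng(child), measure)
        try:
            sim_stats = summarize(log, n_days=n_days, users=real_stats.users)
            scores.append(rho(real_stats, sim_stats, constants))
        except ValueError:
            scores.append(float("inf"))
    scores = np.asarray(scores)
    if np.isinf(scores).any():
        return float("inf"), float("inf")
    se = float(scores.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else 0.0
    return float(scores.mean()), se


def calibrate(
    real_stats: FitStatistics,
    graph: nx.Graph,
    characteristics: Mapping[str, AgentCharacteristics],
    ranges: Mapping[str, tuple[float, float]],
    grid_points: int = 4,
    n_zooms: int = 5,
    runs_per_combo: int = 50,
    seed: int = 0,
    base_params: GlobalParams = GlobalParams(),
    n_days: int | None = None,
    measure: str = "MC",
    constants: RhoConstants = RhoConstants(),
) -> CalibrationResult:
    """Fit global parameters by iterative grid search with zooming.

    ``ranges`` maps the free parameter names to (low, high) intervals;
    parameters not listed stay at their ``base_params`` values.  At each of
    ``n_zooms`` rounds the full grid (``grid_points`` per free dimension,
    integer parameters on integer grids) is evaluated by averaging rho over
    ``runs_per_combo`` seeded runs; the next round halves each span around
    the incumbent best, clipped to the original ranges.  Per-combination
    seeds derive from ``(seed, zoom, grid coordinates)`` so combinations are
    independent and re-runs reproducible.  The neighbour threshold is a
    structural input (it shapes ``graph``), so it is not searchable here.
    """
    if not ranges:
        raise ValueError("empty range specification")
    for name in ranges:
        if name == "neighbour_threshold":
            raise ValueError(
                "neighbour_threshold shapes the agent graph; rebuild the graph "
                "per threshold instead of searching it here"
            )
        if not hasattr(base_params, name):
            raise ValueError(f"unknown parameter {name!r}")
        lo, hi = ranges[name]
        if lo > hi:
            raise ValueError(f"empty range for {name!r}")
    if grid_points < 2 and any(lo < hi for lo, hi in ranges.values()):
        raise ValueError("grid_points must be >= 2 per searched dimension")
    if n_days is None:
        n_days = real_stats.n_days
    names = sorted(ranges)
    orig = {k: (float(ranges[k][0]), float(ranges[k][1])) for k in names}
    current = dict(orig)
    best_score = float("inf")
    best_values: dict[str, float] = {}
    trace: list[dict] = []
    for zoom in range(n_zooms):
        axes = [
            _grid_values(*current[k], grid_points, k in INTEGER_PARAMS) for k in names
        ]
        evaluated = []
        zoom_best = None
        for combo_idx, point in enumerate(itertools.product(*axes)):
            values = dict(zip(names, point))
            cast = {
                k: int(v) if k in INTEGER_PARAMS else v for k, v in values.items()
            }
            params = replace(base_params, **cast)
            score, _ = mean_rho_at(
                params,
                real_stats,
                graph,
                characteristics,
                runs_per_combo,
                (seed, zoom, combo_idx),
                n_days,
                measure,
                constants,
            )
            evaluated.append({"values": values, "mean_rho": score})
            if zoom_best is None or score < zoom_best[0]:
                zoom_best = (score, values)
            if score < best_score:
                best_score = score
                best_values = values
        trace.append(
            {"zoom": zoom, "bounds": dict(current), "points": evaluated, "best": zoom_best}
        )
        # re-centre on the best point seen so far with halved span
        for k in names:
            lo0, hi0 = orig[k]
            span = (current[k][1] - current[k][0]) / 2.0
            c = best_values[k]
            lo = max(lo0, c - span / 2.0)
            hi = min(hi0, c + span / 2.0)
            current[k] = (lo, hi)
    cast_best = {
        k: int(v) if k in INTEGER_PARAMS else v for k, v in best_values.items()
    }
    return CalibrationResult(
        best_params=replace(base_params, **cast_best),
        best_score=best_score,
        trace=trace,
        runs_per_combo=runs_per_combo,
        n_zooms=n_zooms,
        seed=seed,
    )


def _select_neighbours(
    characteristics: Mapping[str, AgentCharacteristics],
    rule: str,
    n_neighbours: int,
) -> list[str]:
    if rule not in SCENARIO_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {SCENARIO_RULES}")
    if rule in ("most_positive", "most_negative"):
        key = lambda u: characteristics[u].s_baseline
    else:
        key = lambda u: characteristics[u].p_reply
    descending = rule in ("most_positive", "highest_reply")
    ordered = sorted(
        characteristics,
        key=lambda u: ((-key(u)) if descending else key(u), u),
    )
    return ordered[:n_neighbours]


def new_user_scenario(
    graph: nx.Graph,
    characteristics: Mapping[str, AgentCharacteristics],
    params: GlobalParams,
    rule: str,
    multiplier: float = 3.0,
    n_neighbours: int = 3,
    n_days: int = 28,
    n_runs: int = 100,
    seed: int = 0,
    measure: str = "MC",
    new_user_id: str = "~new_user",
) -> ScenarioReport:
    """Predict the community-level effect of introducing one new user.

    The new user's initiation/reply/propagation probabilities are
    ``multiplier`` times the community maxima (capped at 1); its baseline and
    neutral sentiment equal the community sentiment level (the mean neutral
    level of existing agents).  Its ``n_neighbours`` neighbours are the top
    or bottom users by baseline sentiment (``most_positive`` /
    ``most_negative``) or by reply probability (``highest_reply`` /
    ``lowest_reply``), ties broken by user id.  Reports the four community
    moments for the baseline and modified models, each averaged over
    ``n_runs`` seeded runs.
    """
    if len(characteristics) < n_neighbours:
        raise ValueError("community smaller than n_neighbours")
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    if new_user_id in characteristics:
        raise ValueError("new_user_id collides with an existing user")
    neighbours = _select_neighbours(characteristics, rule, n_neighbours)
    community_level = float(np.mean([c.s_neutral for c in characteristics.values()]))
    new_char = AgentCharacteristics(
        p_init=min(1.0, multiplier * max(c.p_init for c in characteristics.values())),
        p_reply=min(1.0, multiplier * max(c.p_reply for c in characteristics.values())),
        p_prop=min(1.0, multiplier * max(c.p_prop for c in characteristics.values())),
        s_baseline=community_level,
        s_neutral=community_level,
    )
    g_mod = graph.copy()
    g_mod.add_node(new_user_id)
    g_mod.add_edges_from((new_user_id, v) for v in neighbours)
    chars_mod = dict(characteristics)
    chars_mod[new_user_id] = new_char

    def _avg_moments(g, chars, arm: int) -> dict[str, float]:
        ss = np.random.SeedSequence([seed, arm])
        acc: dict[str, float] = {}
        # incumbents reply to the newcomer but do not initiate towards it
        passive = frozenset({new_user_id}) if arm else frozenset()
        for child in ss.spawn(n_runs):
            log = simulate(
                g, chars, params, n_days, np.random.default_rng(child), measure,
                passive_targets=passive,
            )
            m = community_moments(log, n_days)
            for k, v in m.items():
                acc[k] = acc.get(k, 0.0) + v
        return {k: v / n_runs for k, v in acc.items()}

    baseline = _avg_moments(graph, characteristics, 0)
    modified = _avg_moments(g_mod, chars_mod, 1)
    return ScenarioReport(rule=rule, baseline=baseline, modified=modified, n_runs=n_runs)
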