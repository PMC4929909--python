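"""Sentiment measure definitions and component-combination rules.

Three per-message sentiment measures are supported throughout the package.
The scoring algorithms themselves are external; scores arrive as input.

* ``MC`` — integer score from a proprietary classifier, from -25 (extremely
  negative) through 0 (neutral) to +25 (extremely positive).
* ``SS`` — SentiStrength-style: positive strength (1..5) minus negative
  strength (1..5), giving an integer in -4..+4.
* ``L`` — LIWC-style: the *posemo* percentage minus the *negemo* percentage,
  a real number in -100..+100.
"""

from __future__ import annotations

MEASURES: tuple[str, ...] = ("MC", "SS", "L")

#: Inclusive (low, high) range of each combined measure.
MEASURE_RANGES: dict[str, tuple[float, float]] = {
    "MC": (-25.0, 25.0),
    "SS": (-4.0, 4.0),
    "L": (-100.0, 100.0),
}


def _check_measure(measure: str) -> str:
    if measure not in MEASURES:
        raise ValueError(f"unknown sentiment measure {measure!r}; expected one of {MEASURES}")
    return measure


def combine_ss(ss_pos: int, ss_neg: int) -> int:
    """Combine SentiStrength components into a single score in -4..+4.

    ``ss_pos`` and ``ss_neg`` are the positive and negative strength
    components, each an integer from 1 (none) to 5 (very strong).  The
    combined score is ``ss_pos - ss_neg``.
    """
    for name, v in (("ss_pos", ss_pos), ("ss_neg", ss_neg)):
        if v != int(v):
            raise ValueError(f"{name} must be an integer, got {v!r}")
        if not 1 <= int(v) <= 5:
            raise ValueError(f"{name} must be in [1, 5], got {v!r}")
    return int(ss_pos) - int(ss_neg)


def combine_liwc(l_posemo: float, l_negemo: float) -> float:
    """Combine LIWC *posemo*/*negemo* percentages into a score in -100..+100."""
    for name, v in (("l_posemo", l_posemo), ("l_negemo", l_negemo)):
        if not 0.0 <= float(v) <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v!r}")
    return float(l_posemo) - float(l_negemo)
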