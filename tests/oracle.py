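"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the greedy segmentation they
check: run legality is re-derived from first principles and the minimum
cover is found by exhaustive search over all partitions.
"""

from __future__ import annotations

from typing import Sequence

from zahnreihen.analysis import PlottedPoint
from zahnreihen.model import (
    FunctionalStage,
    ReplacementStage,
    ToothKind,
    ToothObservation,
)


def make_point(position: int, score: int) -> PlottedPoint:
    """Build a plotted point directly from a maturity score (1..7)."""
    if score >= 4:
        obs = ToothObservation(
            position, ToothKind.FUNCTIONAL, functional_stage=FunctionalStage(score - 3)
        )
    else:
        obs = ToothObservation(
            position, ToothKind.REPLACEMENT, replacement_stage=ReplacementStage(score)
        )
    return PlottedPoint(position, score, obs)


def _legal_next(
    a: PlottedPoint, b: PlottedPoint, occupied: set[int], allow_gap: int
) -> bool:
    """May ``b`` directly follow ``a`` in one run?

    Positions strictly increase, scores strictly decrease, every
    intermediate position is empty, and at most ``allow_gap`` of them.
    """
    if not (b.position > a.position and b.score < a.score):
        return False
    between = range(a.position + 1, b.position)
    if any(p in occupied for p in between):
        return False
    return len(between) <= allow_gap


def min_run_cover(points: Sequence[PlottedPoint], allow_gap: int = 1) -> int:
    """Minimum number of parts in any partition of ``points`` into legal
    descending runs (singletons count as parts), by exhaustive search.

    Exponential; intended for rows of <= 8 positions.
    """
    occupied = {p.position for p in points}
    pts = sorted(points, key=lambda p: (p.position, -p.score))
    n = len(pts)
    best = [n]

    def recurse(i: int, ends: list[PlottedPoint], parts: int) -> None:
        if parts >= best[0]:
            return
        if i == n:
            best[0] = parts
            return
        pt = pts[i]
        for j, end in enumerate(ends):
            if _legal_next(end, pt, occupied, allow_gap):
                saved = ends[j]
                ends[j] = pt
                recurse(i + 1, ends, parts)
                ends[j] = saved
        ends.append(pt)
        recurse(i + 1, ends, parts + 1)
        ends.pop()

    recurse(0, [], 0)
    return best[0]
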