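"""Zahnreihe reconstruction and Z-spacing estimation.

Every staged tooth in a jaw quadrant is plotted as a point with x = tooth
position and y = maturity score (1..7).  A Zahnreihe is a maximal caudally
descending run of such points: maturity decreases strictly from rostral to
caudal along the run.  The positional offset between successive runs,
measured at matched maturity levels, is the Z-spacing.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from zahnreihen.model import (
    JawElement,
    JawQuadrant,
    NoScoreError,
    Side,
    Specimen,
    ToothKind,
    ToothObservation,
    ValidationError,
    maturity_score,
)

__all__ = [
    "PlottedPoint",
    "Zahnreihe",
    "WaveDirection",
    "PairSpacing",
    "ZSpacingReport",
    "plotted_points",
    "segment_zahnreihen",
    "compute_z_spacing",
    "aggregate_mean_spacing",
    "classify_wave_direction",
    "regional_z_spacing",
    "replacement_ratio",
    "ontogenetic_series",
    "analyze_quadrant",
]


@dataclass(frozen=True)
class PlottedPoint:
    """One point of the Zahnreihen graph: (position, maturity score)."""

    position: int
    score: int
    source: ToothObservation

    @property
    def is_functional(self) -> bool:
        return self.source.kind is ToothKind.FUNCTIONAL

    @property
    def label(self) -> str:
        return self.source.label


@dataclass
class Zahnreihe:
    """A maximal caudally-descending maturity run of >= 2 plotted points."""

    points: list[PlottedPoint]
    index: int = 0  # rostral->caudal rank among the quadrant's runs

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValidationError("a Zahnreihe needs at least 2 points")
        for a, b in zip(self.points, self.points[1:]):
            if not (b.position > a.position and b.score < a.score):
                raise ValidationError(
                    "Zahnreihe points must strictly increase in position "
                    "and strictly decrease in score"
                )

    @property
    def positions(self) -> list[int]:
        return [p.position for p in self.points]

    @property
    def scores(self) -> list[int]:
        return [p.score for p in self.points]

    def position_at_score(self, score: float) -> float:
        """Position along the run at a maturity level, by exact match or
        linear interpolation between bracketing points.

        ``score`` must lie within the run's score range.
        """
        scores = self.scores
        if not (min(scores) <= score <= max(scores)):
            raise ValueError(f"score {score} outside run range {min(scores)}..{max(scores)}")
        for pt in self.points:
            if pt.score == score:
                return float(pt.position)
        for a, b in zip(self.points, self.points[1:]):
            if b.score < score < a.score:
                frac = (a.score - score) / (a.score - b.score)
                return a.position + frac * (b.position - a.position)
        raise AssertionError("unreachable: score inside range must bracket")


class WaveDirection(str, Enum):
    """Replacement-wave direction inferred from the mean Z-spacing."""

    ROSTRAL_TO_CAUDAL = "rostral_to_caudal"
    ALTERNATING = "alternating"
    CAUDAL_TO_ROSTRAL = "caudal_to_rostral"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class PairSpacing:
    """Z-spacing between Zahnreihen ``pair_index`` and ``pair_index + 1``."""

    pair_index: int
    spacing: float
    midpoint_position: float


@dataclass
class ZSpacingReport:
    """Full Zahnreihen analysis of one jaw quadrant."""

    specimen_id: str = ""
    element: str = ""
    side: str = ""
    zahnreihen: list[Zahnreihe] = field(default_factory=list)
    exceptions: list[PlottedPoint] = field(default_factory=list)
    pair_spacings: list[PairSpacing] = field(default_factory=list)
    skipped_pairs: list[int] = field(default_factory=list)
    mean_spacing: Optional[float] = None
    rostral_mean: Optional[float] = None
    caudal_mean: Optional[float] = None
    direction: WaveDirection = WaveDirection.UNDETERMINED

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "element": self.element,
            "side": self.side,
            "zahnreihen": [
                [
                    {"position": p.position, "score": p.score, "label": p.label}
                    for p in run.points
                ]
                for run in self.zahnreihen
            ],
            "exceptions": [
                {"position": p.position, "score": p.score, "label": p.label}
                for p in self.exceptions
            ],
            "pair_spacings": [
                {
                    "pair_index": s.pair_index,
                    "spacing": s.spacing,
                    "midpoint_position": s.midpoint_position,
                }
                for s in self.pair_spacings
            ],
            "skipped_pairs": list(self.skipped_pairs),
            "mean_spacing": self.mean_spacing,
            "rostral_mean": self.rostral_mean,
            "caudal_mean": self.caudal_mean,
            "direction": self.direction.value,
        }


def plotted_points(quadrant: JawQuadrant) -> list[PlottedPoint]:
    """Project a quadrant's staged teeth onto the Zahnreihen graph.

    Empty alveoli and remnants carry no maturity and are omitted.  A
    position undergoing replacement contributes two points (functional
    and replacement); the functional point is ordered first.
    """
    pts: list[PlottedPoint] = []
    for obs in quadrant.teeth:
        if obs.kind in (ToothKind.FUNCTIONAL, ToothKind.REPLACEMENT):
            pts.append(PlottedPoint(obs.position, maturity_score(obs), obs))
    pts.sort(key=lambda p: (p.position, not p.is_functional))
    return pts


def segment_zahnreihen(
    points: Sequence[PlottedPoint], allow_gap: int = 1
) -> tuple[list[Zahnreihe], list[PlottedPoint]]:
    """Partition plotted points into Zahnreihen and exception points.

    Greedy left-to-right construction: starting from the rostral-most
    unassigned point, the run is extended caudally to the nearest
    unassigned point with a strictly lower score, tolerating at most
    ``allow_gap`` empty positions (positions with no plotted points,
    i.e. empty alveoli or unrecorded).  A position that has points but
    offers no eligible candidate terminates the run: maturity must
    descend tooth by tooth, so an ineligible occupied position marks the
    boundary with the next replacement wave.  Where a position offers
    both a functional and a replacement candidate, the functional point
    is consumed first.  Runs of length >= 2 become Zahnreihen (indexed
    rostral to caudal by first position); leftover single points are
    exceptions, excluded from spacing estimation.
    """
    pts = list(points)
    for a, b in zip(pts, pts[1:]):
        if b.position < a.position:
            raise ValidationError("plotted points must be sorted by position")
    by_pos: dict[int, list[PlottedPoint]] = {}
    for p in pts:
        by_pos.setdefault(p.position, []).append(p)
    for pos, group in by_pos.items():
        if len(group) > 2:
            raise ValidationError(f"more than 2 points at position {pos}")
        # functional candidate offered before the replacement candidate
        group.sort(key=lambda p: not p.is_functional)

    assigned: set[int] = set()  # id() of assigned points
    runs: list[list[PlottedPoint]] = []
    exceptions: list[PlottedPoint] = []

    for start in pts:
        if id(start) in assigned:
            continue
        run = [start]
        assigned.add(id(start))
        current = start
        while True:
            nxt = None
            gaps = 0
            pos = current.position + 1
            while gaps <= allow_gap:
                group = by_pos.get(pos, [])
                if not group:
                    gaps += 1  # empty position: tolerated up to allow_gap
                    pos += 1
                    continue
                candidates = [
                    p
                    for p in group
                    if id(p) not in assigned and p.score < current.score
                ]
                if candidates:
                    nxt = candidates[0]
                break  # occupied position: take the candidate or end the run
            if nxt is None:
                break
            run.append(nxt)
            assigned.add(id(nxt))
            current = nxt
        if len(run) >= 2:
            runs.append(run)
        else:
            exceptions.append(start)

    # rostral->caudal by first position; when two runs start at the same
    # position (a functional-led and a replacement-led run), the one with
    # the lower score is the more rostral wave: it reaches any shared
    # maturity level at a more rostral position.
    runs.sort(key=lambda r: (r[0].position, r[0].score))
    zahnreihen = [Zahnreihe(points=r, index=i) for i, r in enumerate(runs)]
    return zahnreihen, exceptions


def compute_z_spacing(
    zahnreihen: Sequence[Zahnreihe],
) -> tuple[list[PairSpacing], Optional[float], list[int]]:
    """Z-spacing between each adjacent pair of Zahnreihen, and their mean.

    For a pair (i, i+1), the spacing is the mean positional offset
    ``position_{i+1}(s) - position_i(s)`` over every integer maturity
    level ``s`` shared by both runs' score ranges; positions at a level
    are read off each run by exact match or linear interpolation.  Pairs
    with disjoint score ranges are skipped and flagged.  The mean spacing
    is the arithmetic mean over pairs (``None`` with < 2 runs or no
    measurable pair).  Units are tooth positions and may be fractional.
    """
    pair_spacings: list[PairSpacing] = []
    skipped: list[int] = []
    for i in range(len(zahnreihen) - 1):
        a, b = zahnreihen[i], zahnreihen[i + 1]
        lo = max(min(a.scores), min(b.scores))
        hi = min(max(a.scores), max(b.scores))
        levels = [s for s in range(math.ceil(lo), math.floor(hi) + 1)]
        if not levels:
            skipped.append(i)
            continue
        offsets = []
        midpoints = []
        for s in levels:
            pa = a.position_at_score(s)
            pb = b.position_at_score(s)
            offsets.append(pb - pa)
            midpoints.append((pa + pb) / 2.0)
        pair_spacings.append(
            PairSpacing(
                pair_index=i,
                spacing=float(np.mean(offsets)),
                midpoint_position=float(np.mean(midpoints)),
            )
        )
    mean_spacing = (
        float(np.mean([p.spacing for p in pair_spacings])) if pair_spacings else None
    )
    return pair_spacings, mean_spacing, skipped


def aggregate_mean_spacing(spacings: Sequence[float], ndigits: int = 2) -> float:
    """Pool Z-spacing measurements into a single mean, rounded half-up.

    Used to combine per-quadrant (or per-pair) spacings into a taxon-level
    value, e.g. pooling maxillary and dentary measurements of one
    specimen.  Rounding is decimal half-up to ``ndigits`` places, the
    convention used for published Z-spacing summaries.
    """
    if len(spacings) == 0:
        raise ValidationError("cannot aggregate an empty collection of spacings")
    mean = float(np.mean(np.asarray(spacings, dtype=float)))
    exp = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(mean)).quantize(exp, rounding=decimal.ROUND_HALF_UP)
    )


def classify_wave_direction(
    mean_spacing: Optional[float], eps: float = 0.05
) -> WaveDirection:
    """Call the replacement-wave direction from the mean Z-spacing.

    Z-spacing greater than 2.0 indicates waves sweeping rostral to
    caudal, less than 2.0 the reverse, and exactly 2.0 simple alternation
    between odd- and even-numbered tooth positions.  ``eps`` is the
    half-width of the band treated as "exactly 2.0".
    """
    if mean_spacing is None:
        return WaveDirection.UNDETERMINED
    if not mean_spacing > 0:
        raise ValidationError(f"mean_spacing must be positive, got {mean_spacing}")
    if abs(mean_spacing - 2.0) <= eps:
        return WaveDirection.ALTERNATING
    if mean_spacing > 2.0 + eps:
        return WaveDirection.ROSTRAL_TO_CAUDAL
    return WaveDirection.CAUDAL_TO_ROSTRAL


def regional_z_spacing(
    pair_spacings: Sequence[PairSpacing], row_length: int
) -> tuple[Optional[float], Optional[float]]:
    """Mean Z-spacing in the rostral and caudal halves of the tooth row.

    A pair is rostral when its midpoint position is <= ``row_length / 2``,
    caudal otherwise.  Returns ``(rostral_mean, caudal_mean)``; a region
    with no pairs yields ``None``.
    """
    half = row_length / 2.0
    rostral = [p.spacing for p in pair_spacings if p.midpoint_position <= half]
    caudal = [p.spacing for p in pair_spacings if p.midpoint_position > half]
    rostral_mean = float(np.mean(rostral)) if rostral else None
    caudal_mean = float(np.mean(caudal)) if caudal else None
    return rostral_mean, caudal_mean


def replacement_ratio(quadrant: JawQuadrant) -> tuple[int, int, float]:
    """Replacement-to-functional tooth ratio of one quadrant.

    Returns ``(n_functional, n_replacement, ratio)`` where ``ratio`` is
    RT/FT.  Empty alveoli and remnants are never counted.  A higher ratio
    in a smaller individual indicates a faster replacement turnover early
    in ontogeny.
    """
    n_f = quadrant.n_functional
    n_r = quadrant.n_replacement
    if n_f == 0:
        raise ValidationError(
            f"{quadrant.specimen_id} {quadrant.element.value}/{quadrant.side.value}: "
            "replacement ratio undefined with zero functional teeth"
        )
    return n_f, n_r, n_r / n_f


def ontogenetic_series(
    specimens: Iterable[Specimen],
    element: JawElement | str = JawElement.MAXILLA,
    side_policy: str = "pool_sides",
) -> pd.DataFrame:
    """Replacement-ratio series across an ontogenetic (size-ordered) sample.

    Counts functional and replacement teeth of ``element`` per specimen
    (``pool_sides``: summed over sides; ``per_side``: one row per side)
    and orders rows by ascending skull length.  The returned frame carries
    a ``ratio_non_increasing`` attribute in ``.attrs``: True when the
    ratio never rises along the size ordering (ties allowed), evaluated
    over rows with known skull length; None when fewer than 2 such rows.
    """
    element = JawElement(element) if isinstance(element, str) else element
    if side_policy not in ("pool_sides", "per_side"):
        raise ValidationError(f"unknown side_policy {side_policy!r}")
    rows = []
    for sp in specimens:
        quads = [q for q in sp.quadrants if q.element is element]
        if not quads:
            continue
        if side_policy == "pool_sides":
            n_f = sum(q.n_functional for q in quads)
            n_r = sum(q.n_replacement for q in quads)
            rows.append(
                {
                    "specimen_id": sp.specimen_id,
                    "taxon": sp.taxon,
                    "side": "both",
                    "skull_length_cm": sp.skull_length_cm,
                    "n_functional": n_f,
                    "n_replacement": n_r,
                    "ratio": n_r / n_f if n_f else np.nan,
                }
            )
        else:
            for q in quads:
                rows.append(
                    {
                        "specimen_id": sp.specimen_id,
                        "taxon": sp.taxon,
                        "side": q.side.value,
                        "skull_length_cm": sp.skull_length_cm,
                        "n_functional": q.n_functional,
                        "n_replacement": q.n_replacement,
                        "ratio": q.n_replacement / q.n_functional
                        if q.n_functional
                        else np.nan,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "specimen_id",
            "taxon",
            "side",
            "skull_length_cm",
            "n_functional",
            "n_replacement",
            "ratio",
        ],
    )
    table = table.sort_values(
        ["skull_length_cm", "specimen_id"], na_position="last"
    ).reset_index(drop=True)
    known = table.dropna(subset=["skull_length_cm", "ratio"])
    if len(known) < 2:
        table.attrs["ratio_non_increasing"] = None
    else:
        r = known["ratio"].to_numpy()
        table.attrs["ratio_non_increasing"] = bool(np.all(np.diff(r) <= 1e-12))
    return table


def analyze_quadrant(
    quadrant: JawQuadrant, allow_gap: int = 1, eps: float = 0.05
) -> ZSpacingReport:
    """Run the full Zahnreihen pipeline on one jaw quadrant.

    Plots the staged teeth, segments Zahnreihen, computes pairwise and
    mean Z-spacing, regional means (split at the row midpoint) and the
    wave-direction call.
    """
    pts = plotted_points(quadrant)
    zahnreihen, exceptions = segment_zahnreihen(pts, allow_gap=allow_gap)
    pair_spacings, mean_spacing, skipped = compute_z_spacing(zahnreihen)
    row_length = quadrant.max_position
    rostral_mean, caudal_mean = regional_z_spacing(pair_spacings, row_length)
    return ZSpacingReport(
        specimen_id=quadrant.specimen_id,
        element=quadrant.element.value,
        side=quadrant.side.value,
        zahnreihen=zahnreihen,
        exceptions=exceptions,
        pair_spacings=pair_spacings,
        skipped_pairs=skipped,
        mean_spacing=mean_spacing,
        rostral_mean=rostral_mean,
        caudal_mean=caudal_mean,
        direction=classify_wave_direction(mean_spacing, eps=eps),
    )
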