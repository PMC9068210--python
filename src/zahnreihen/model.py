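"""Domain types and ordinal staging for polyphyodont dentitions.

Functional (erupted, occluding) teeth are staged F1-F4 by wear, wear-facet
concavity, pulp-cavity development and evidence of an incoming successor.
Unerupted replacement teeth are staged R1-R3 by crown development.  Both
ladders are unified onto a single 7-step maturity score (R1=1 ... F4=7)
used as the y-axis of the Zahnreihen graph: every replacement tooth is
younger than every erupted functional tooth, so R-stages sit below
F-stages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "DenticleWear",
    "LingualFacet",
    "PulpCavity",
    "FunctionalStage",
    "ReplacementStage",
    "ReplacementCrownDescriptor",
    "ToothFeatures",
    "ToothKind",
    "JawElement",
    "Side",
    "ToothObservation",
    "JawQuadrant",
    "Specimen",
    "StagingConflictError",
    "NoScoreError",
    "ValidationError",
    "stage_functional_tooth",
    "stage_replacement_tooth",
    "maturity_score",
    "MATURITY_LADDER",
]


class ValidationError(ValueError):
    """A domain object violates one of its structural invariants."""


class StagingConflictError(ValidationError):
    """Feature combination is internally contradictory for staging.

    Carries the names of the clashing fields in :attr:`fields`.
    """

    def __init__(self, message: str, fields: tuple[str, ...]):
        super().__init__(message)
        self.fields = fields


class NoScoreError(ValidationError):
    """Observation has no stage to score (empty alveolus or remnant)."""


class DenticleWear(enum.IntEnum):
    """Ordinal wear state of the marginal denticles."""

    NONE_OR_SLIGHT = 0
    WORN = 1
    EXTENSIVE = 2
    POLISHED = 3


class LingualFacet(enum.IntEnum):
    """Ordinal concavity of the lingual wear facet."""

    FLAT = 0
    SLIGHTLY_CONCAVE = 1
    CONCAVE = 2
    HIGHLY_CONCAVE = 3


class PulpCavity(enum.Enum):
    """Developmental state of the pulp cavity.

    ``OPEN_AT_TIP`` marks a newly erupted tooth; the cavity is
    progressively reduced with maturity and finally broken by the
    successor's resorption.
    """

    OPEN_AT_TIP = "open_at_tip"
    LARGE = "large"
    REDUCED = "reduced"
    BROKEN = "broken"


@enum.unique
class FunctionalStage(enum.IntEnum):
    """Wear/maturity stage of a functional tooth, F1 < F2 < F3 < F4."""

    F1 = 1
    F2 = 2
    F3 = 3
    F4 = 4

    def __str__(self) -> str:  # "F1" .. "F4"
        return self.name


@enum.unique
class ReplacementStage(enum.IntEnum):
    """Crown-development stage of a replacement tooth, R1 < R2 < R3."""

    R1 = 1
    R2 = 2
    R3 = 3

    def __str__(self) -> str:
        return self.name


class ReplacementCrownDescriptor(enum.Enum):
    """Qualitative crown-development descriptors mapping onto R1-R3."""

    TIP_OF_CROWN_ONLY = "tip_of_crown_only"
    CROWN_COMPLETE = "crown_complete"
    CROWN_AT_FUNCTIONAL_CROWN_BASE = "crown_at_functional_crown_base"


class ToothKind(enum.Enum):
    FUNCTIONAL = "functional"
    REPLACEMENT = "replacement"
    EMPTY_ALVEOLUS = "empty_alveolus"
    REMNANT = "remnant"


class JawElement(enum.Enum):
    PREMAXILLA = "premaxilla"
    MAXILLA = "maxilla"
    DENTARY = "dentary"


class Side(enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class ToothFeatures:
    """Observable characters of one functional tooth.

    All fields are required; an unknown character must be represented by
    the caller as a missing :class:`ToothFeatures` (never silently
    defaulted), because the staging rules are conjunctions over the full
    character set.
    """

    denticle_wear: DenticleWear
    lingual_facet: LingualFacet
    pulp_cavity: PulpCavity
    root_resorption_depression: bool = False
    replacement_bud_present: bool = False
    replacement_emerged: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.denticle_wear, DenticleWear):
            raise ValidationError(f"denticle_wear must be DenticleWear, got {self.denticle_wear!r}")
        if not isinstance(self.lingual_facet, LingualFacet):
            raise ValidationError(f"lingual_facet must be LingualFacet, got {self.lingual_facet!r}")
        if not isinstance(self.pulp_cavity, PulpCavity):
            raise ValidationError(f"pulp_cavity must be PulpCavity, got {self.pulp_cavity!r}")


def stage_functional_tooth(features: ToothFeatures) -> FunctionalStage:
    """Stage a functional tooth from its observed characters.

    The four stages are conjunctive descriptions, not a decision tree;
    the highest stage whose defining criteria are met is returned:

    * F1 — no or slight wear on the marginal denticles, open pulp cavity;
    * F2 — worn denticles with a slightly concave lingual wear facet;
    * F3 — extensive wear, concave facet, plus either a resorption
      depression on the root or a replacement-tooth bud;
    * F4 — polished denticles, highly concave facet, plus either a broken
      pulp cavity or an emerged replacement tooth.

    Wear and facet criteria are thresholds (``>=``), so worsening either
    character can never lower the returned stage.  A tooth that exceeds
    the F1 description but does not reach F2 (e.g. worn denticles with a
    still-flat facet) is conservatively staged F1.

    Raises
    ------
    StagingConflictError
        If the characters contradict each other, e.g. heavy denticle wear
        on a pulp cavity still open at the tip (open cavities mark newly
        erupted teeth), or an emerged successor on an unworn crown.
    """
    w, f, p = features.denticle_wear, features.lingual_facet, features.pulp_cavity
    if w >= DenticleWear.EXTENSIVE and p is PulpCavity.OPEN_AT_TIP:
        raise StagingConflictError(
            f"denticle_wear={w.name} is incompatible with pulp_cavity=OPEN_AT_TIP "
            "(an open pulp cavity marks a newly erupted tooth)",
            ("denticle_wear", "pulp_cavity"),
        )
    if features.replacement_emerged and w is DenticleWear.NONE_OR_SLIGHT and f is LingualFacet.FLAT:
        raise StagingConflictError(
            "replacement_emerged=True on an unworn crown with a flat facet",
            ("replacement_emerged", "denticle_wear", "lingual_facet"),
        )

    if (
        w >= DenticleWear.POLISHED
        and f >= LingualFacet.HIGHLY_CONCAVE
        and (p is PulpCavity.BROKEN or features.replacement_emerged)
    ):
        return FunctionalStage.F4
    if (
        w >= DenticleWear.EXTENSIVE
        and f >= LingualFacet.CONCAVE
        and (features.root_resorption_depression or features.replacement_bud_present)
    ):
        return FunctionalStage.F3
    if w >= DenticleWear.WORN and f >= LingualFacet.SLIGHTLY_CONCAVE:
        return FunctionalStage.F2
    return FunctionalStage.F1


_DESCRIPTOR_TO_STAGE = {
    ReplacementCrownDescriptor.TIP_OF_CROWN_ONLY: ReplacementStage.R1,
    ReplacementCrownDescriptor.CROWN_COMPLETE: ReplacementStage.R2,
    ReplacementCrownDescriptor.CROWN_AT_FUNCTIONAL_CROWN_BASE: ReplacementStage.R3,
}


def stage_replacement_tooth(
    descriptor: ReplacementCrownDescriptor | str,
) -> ReplacementStage:
    """Stage a replacement tooth from its crown-development descriptor.

    ``tip_of_crown_only`` (small incipient tooth) -> R1,
    ``crown_complete`` -> R2,
    ``crown_at_functional_crown_base`` (apex reaches the base of the
    functional crown) -> R3.
    """
    if isinstance(descriptor, str):
        try:
            descriptor = ReplacementCrownDescriptor(descriptor)
        except ValueError:
            valid = ", ".join(d.value for d in ReplacementCrownDescriptor)
            raise ValidationError(
                f"unknown replacement crown descriptor {descriptor!r}; expected one of: {valid}"
            ) from None
    return _DESCRIPTOR_TO_STAGE[descriptor]


@dataclass(frozen=True)
class ToothObservation:
    """One tooth record (or empty alveolus / resorbed remnant) at a jaw position.

    ``position`` is 1-based and counted rostral to caudal within the
    quadrant, matching conventional M1/D1/PM1 labelling.  A position
    undergoing replacement yields two observations: the functional tooth
    and its unerupted successor.
    """

    position: int
    kind: ToothKind
    functional_stage: Optional[FunctionalStage] = None
    replacement_stage: Optional[ReplacementStage] = None
    features: Optional[ToothFeatures] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.position, int) or self.position < 1:
            raise ValidationError(f"position must be an integer >= 1, got {self.position!r}")
        if self.kind is ToothKind.FUNCTIONAL and self.replacement_stage is not None:
            raise ValidationError(
                f"functional tooth at position {self.position} carries a replacement stage"
            )
        if self.kind is ToothKind.REPLACEMENT and self.functional_stage is not None:
            raise ValidationError(
                f"replacement tooth at position {self.position} carries a functional stage"
            )
        if self.kind in (ToothKind.EMPTY_ALVEOLUS, ToothKind.REMNANT) and (
            self.functional_stage is not None or self.replacement_stage is not None
        ):
            raise ValidationError(
                f"{self.kind.value} at position {self.position} must not carry a stage"
            )

    @property
    def stage_token(self) -> str:
        """Serialized stage token: 'F1'..'F4', 'R1'..'R3' or 'NA'."""
        if self.functional_stage is not None:
            return self.functional_stage.name
        if self.replacement_stage is not None:
            return self.replacement_stage.name
        return "NA"


#: Unified maturity ladder: stage label -> score 1..7.
MATURITY_LADDER: dict[str, int] = {
    "R1": 1,
    "R2": 2,
    "R3": 3,
    "F1": 4,
    "F2": 5,
    "F3": 6,
    "F4": 7,
}


def maturity_score(obs: ToothObservation) -> int:
    """Score a tooth on the unified 7-step maturity ladder.

    R1 -> 1, R2 -> 2, R3 -> 3, F1 -> 4, F2 -> 5, F3 -> 6, F4 -> 7.
    Replacement stages sit below functional stages because an unerupted
    successor is younger than any erupted, occluding tooth; this is what
    lets a Zahnreihe chain an old functional tooth onto the replacement
    tooth of a more caudal position.
    """
    if obs.kind is ToothKind.FUNCTIONAL:
        if obs.functional_stage is None:
            raise NoScoreError(f"functional tooth at position {obs.position} has no stage")
        return int(obs.functional_stage) + 3
    if obs.kind is ToothKind.REPLACEMENT:
        if obs.replacement_stage is None:
            raise NoScoreError(f"replacement tooth at position {obs.position} has no stage")
        return int(obs.replacement_stage)
    raise NoScoreError(f"{obs.kind.value} at position {obs.position} cannot be scored")


@dataclass
class JawQuadrant:
    """Ordered tooth row for one jaw element and side of one specimen.

    The unit of Zahnreihen analysis.  Invariants: at most one functional
    and at most one replacement record per position (these taxa carry at
    most one replacement tooth per alveolus); positions non-decreasing,
    with gaps allowed where a position is genuinely unrecorded.
    """

    specimen_id: str
    taxon: str
    element: JawElement
    side: Side
    teeth: list[ToothObservation] = field(default_factory=list)
    incomplete: bool = False  # element damaged, alveolus count is a minimum
    metadata: dict = field(default_factory=dict, compare=False)  # extra CSV columns

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[tuple[int, ToothKind], int] = {}
        last_pos = 0
        for obs in self.teeth:
            if obs.position < last_pos:
                raise ValidationError(
                    f"{self.specimen_id} {self.element.value}/{self.side.value}: "
                    f"positions out of order at position {obs.position}"
                )
            last_pos = obs.position
            key = (obs.position, obs.kind)
            if obs.kind in (ToothKind.FUNCTIONAL, ToothKind.REPLACEMENT):
                if key in seen:
                    raise ValidationError(
                        f"{self.specimen_id} {self.element.value}/{self.side.value}: "
                        f"duplicate {obs.kind.value} record at position {obs.position}"
                    )
                seen[key] = 1

    def records(self, kind: ToothKind) -> list[ToothObservation]:
        return [t for t in self.teeth if t.kind is kind]

    @property
    def n_functional(self) -> int:
        return len(self.records(ToothKind.FUNCTIONAL))

    @property
    def n_replacement(self) -> int:
        return len(self.records(ToothKind.REPLACEMENT))

    @property
    def n_positions(self) -> int:
        """Number of distinct recorded positions (alveoli)."""
        return len({t.position for t in self.teeth})

    @property
    def max_position(self) -> int:
        return max((t.position for t in self.teeth), default=0)


@dataclass
class Specimen:
    """One individual: identifier, taxon, skull length and its jaw quadrants."""

    specimen_id: str
    taxon: str
    skull_length_cm: Optional[float] = None
    quadrants: list[JawQuadrant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.skull_length_cm is not None and not self.skull_length_cm > 0:
            raise ValidationError(
                f"{self.specimen_id}: skull_length_cm must be positive, got {self.skull_length_cm}"
            )

    def quadrant(self, element: JawElement | str, side: Side | str) -> JawQuadrant:
        element = JawElement(element) if isinstance(element, str) else element
        side = Side(side) if isinstance(side, str) else side
        for q in self.quadrants:
            if q.element is element and q.side is side:
                return q
        raise KeyError(
            f"{self.specimen_id} has no {element.value}/{side.value} quadrant"
        )
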