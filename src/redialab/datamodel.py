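"""Shared data model for redia colony analyses.

A *colony* is the clonal population of trematode rediae inside one infected
snail; it is the unit of analysis throughout the package.  Each redia is
described by a :class:`RediaRecord` carrying its raw linear measurements (in
micrometres) and the derived morphometric quantities filled in by
:mod:`redialab.morphometrics`.  Ordinal presence scores, activity distances
and attack-trial counts are held in their own small record types because they
are collected on different subsamples of the colony.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Section(str, enum.Enum):
    """Snail body section a redia was recovered from."""

    APICAL = "apical"  # gonad / digestive gland
    MID = "mid"
    FOOT = "foot"  # head/foot
    UNKNOWN = "unknown"


#: accepted aliases when reading section labels from files
SECTION_ALIASES = {
    "apical": Section.APICAL,
    "gonad": Section.APICAL,
    "mid": Section.MID,
    "middle": Section.MID,
    "foot": Section.FOOT,
    "head/foot": Section.FOOT,
    "head_foot": Section.FOOT,
    "unknown": Section.UNKNOWN,
    "": Section.UNKNOWN,
}


class SizeClass(str, enum.Enum):
    SMALL = "small"
    INTERMEDIATE = "intermediate"
    LARGE = "large"
    UNASSIGNED = "unassigned"


class Extremum(str, enum.Enum):
    """Which end of the colony size ranking a scored redia belongs to."""

    SMALLEST5 = "smallest5"
    LARGEST5 = "largest5"


class SizeLabel(str, enum.Enum):
    """Coarse small/large label used for behavioural subsamples."""

    SMALL = "small"
    LARGE = "large"


class TargetType(str, enum.Enum):
    COLONY_MATE = "colony_mate"
    CONSPECIFIC = "conspecific"
    HETEROSPECIFIC = "heterospecific"


class Medium(str, enum.Enum):
    WATER = "water"
    SALINE = "saline"


class SnailFamily(str, enum.Enum):
    HYDROBIIDAE = "Hydrobiidae"
    PHYSIDAE = "Physidae"
    PLANORBIDAE = "Planorbidae"
    VIVIPARIDAE = "Viviparidae"
    LYMNAIDAE = "Lymnaidae"
    VALVATIDAE = "Valvatidae"


def _check_positive(name: str, value: float | None) -> None:
    if value is not None and not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass
class RediaRecord:
    """One measured redia.

    Raw measurements are ``length_um``, ``width_um`` and ``pharynx_um``
    (pharynx diameter); derived quantities stay ``None`` until the record is
    enriched.  ``excluded`` marks measurements judged unreliable (damaged or
    obscured rediae); excluded records are kept in the colony but skipped by
    every statistical routine.
    """

    redia_id: str
    colony_id: str
    section: Section = Section.UNKNOWN
    length_um: float | None = None
    width_um: float | None = None
    pharynx_um: float | None = None
    body_volume_um3: float | None = None
    pharynx_volume_um3: float | None = None
    relative_pharynx: float | None = None
    sls_um: float | None = None
    size_class: SizeClass = SizeClass.UNASSIGNED
    excluded: bool = False
    exclude_reason: str = ""
    implausible_pharynx: bool = False

    def __post_init__(self) -> None:
        _check_positive("length_um", self.length_um)
        _check_positive("width_um", self.width_um)
        _check_positive("pharynx_um", self.pharynx_um)
        if self.excluded and not self.exclude_reason:
            self.exclude_reason = "unspecified"

    @property
    def measured(self) -> bool:
        return self.length_um is not None and self.width_um is not None


@dataclass
class PresenceScores:
    """Ordinal 0-4 visibility scores for one of the five smallest or five
    largest rediae of a colony.

    0 = definitely not present, 1 = probably not, 2 = unclear,
    3 = probably present, 4 = definitely present.
    """

    redia_id: str
    extremum: Extremum
    anterior_score: int
    posterior_score: int
    embryo_score: int

    def __post_init__(self) -> None:
        for name in ("anterior_score", "posterior_score", "embryo_score"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3, 4):
                raise ValueError(f"{name} must be an integer in 0..4, got {v!r}")


@dataclass
class ActivityRecord:
    """Distance moved in 2 s at two timepoints (0 and 15 min) by one redia."""

    redia_id: str
    size_label: SizeLabel
    distance_t0_um: float
    distance_t15_um: float | None
    body_length_um: float

    def __post_init__(self) -> None:
        if self.distance_t0_um < 0:
            raise ValueError("distance_t0_um must be >= 0")
        if self.distance_t15_um is not None and self.distance_t15_um < 0:
            raise ValueError("distance_t15_um must be >= 0")
        _check_positive("body_length_um", self.body_length_um)

    @property
    def mean_distance_um(self) -> float:
        if self.distance_t15_um is None:
            return self.distance_t0_um
        return 0.5 * (self.distance_t0_um + self.distance_t15_um)

    @property
    def relative_distance(self) -> float:
        return self.mean_distance_um / self.body_length_um


@dataclass
class AttackTrial:
    """One well of an attack test: rediae of one size class offered targets."""

    trial_id: str
    attacker_size: SizeLabel
    target_type: TargetType
    n_attacks_observed: int
    n_rediae: int

    def __post_init__(self) -> None:
        if self.n_rediae <= 0:
            raise ValueError("n_rediae must be positive")
        if not 0 <= self.n_attacks_observed <= self.n_rediae:
            raise ValueError("n_attacks_observed must be in 0..n_rediae")


@dataclass
class Colony:
    """All data collected from one infected snail."""

    colony_id: str
    coi_species: str | None = None
    snail_family: SnailFamily | None = None
    dissection_medium: Medium = Medium.WATER
    records: list[RediaRecord] = field(default_factory=list)
    scores: list[PresenceScores] = field(default_factory=list)
    activity: list[ActivityRecord] = field(default_factory=list)
    attacks: list[AttackTrial] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.colony_id != self.colony_id:
                raise ValueError(
                    f"record {r.redia_id!r} belongs to colony {r.colony_id!r}, "
                    f"not {self.colony_id!r}"
                )

    @property
    def included_records(self) -> list[RediaRecord]:
        return [r for r in self.records if not r.excluded]

    def volumes(self) -> list[float]:
        """Body volumes (um^3) of included, fully measured rediae."""
        return [
            r.body_volume_um3
            for r in self.included_records
            if r.body_volume_um3 is not None
        ]
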