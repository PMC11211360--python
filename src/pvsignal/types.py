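"""Domain types for spontaneous adverse-event case reports.

A spontaneous-report database (FAERS-style) is modelled as a collection of
:class:`CaseReport` objects.  Each report carries demographics, one or more
drug mentions with a suspect-role code, and one or more adverse reactions
coded as MedDRA preferred terms (PT) with their system organ class (SOC).
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class AgeGroup(str, enum.Enum):
    UNDER_18 = "<18"
    ADULT = "18-64"
    ELDERLY = ">=65"
    UNKNOWN = "unknown"


class ReporterType(str, enum.Enum):
    HEALTHCARE_PROFESSIONAL = "healthcare_professional"
    CONSUMER = "consumer"
    UNKNOWN = "unknown"


class Seriousness(str, enum.Enum):
    SERIOUS = "serious"
    NON_SERIOUS = "non_serious"


class SeriousOutcome(str, enum.Enum):
    DEATH = "death"
    LIFE_THREATENING = "life_threatening"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    CONGENITAL_ANOMALY = "congenital_anomaly"
    OTHER_SERIOUS = "other_serious"


class DrugRole(str, enum.Enum):
    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


def age_group_from_years(age_years: Optional[float]) -> AgeGroup:
    """Bin an age in years into the standard reporting age groups.

    Boundary ages fall into the higher-inclusive bin: 18 -> "18-64",
    65 -> ">=65".  ``None`` (or negative) ages map to ``unknown``.
    """
    if age_years is None or age_years < 0:
        return AgeGroup.UNKNOWN
    if age_years < 18:
        return AgeGroup.UNDER_18
    if age_years < 65:
        return AgeGroup.ADULT
    return AgeGroup.ELDERLY


def normalize_ingredient(name: str) -> str:
    """Normalize a free-text drug name for matching.

    Case-folds and strips whitespace and punctuation so that e.g.
    ``"ESKETAMINE  HYDROCHLORIDE."`` and ``"esketamine hydrochloride"``
    compare equal.
    """
    out = []
    for ch in name.casefold():
        if ch.isalnum():
            out.append(ch)
        elif out and out[-1] != " ":
            out.append(" ")
    return "".join(out).strip()


@dataclass(frozen=True)
class DrugMention:
    """One drug listed on a case report."""

    active_ingredient: str
    role: DrugRole
    product_name: Optional[str] = None
    reason_for_use: Optional[str] = None

    def matches(self, ingredient: str) -> bool:
        """True if this mention's ingredient or product name matches
        ``ingredient`` after normalization."""
        target = normalize_ingredient(ingredient)
        if normalize_ingredient(self.active_ingredient) == target:
            return True
        if self.product_name is not None:
            return normalize_ingredient(self.product_name) == target
        return False


@dataclass(frozen=True)
class ReactionRecord:
    """One adverse reaction on a case report: a MedDRA PT and its SOC."""

    pt: str
    soc: str


@dataclass
class CaseReport:
    """A single safety report.

    ``case_id`` identifies the case; ``version`` distinguishes successive
    follow-up versions of the same case (higher supersedes lower).
    """

    case_id: str
    version: int = 0
    sex: Sex = Sex.UNKNOWN
    age_group: AgeGroup = AgeGroup.UNKNOWN
    weight_kg: Optional[float] = None
    country: str = "unknown"
    reporter_type: ReporterType = ReporterType.UNKNOWN
    received_year: int = 1968
    event_date: Optional[dt.date] = None
    seriousness: Seriousness = Seriousness.NON_SERIOUS
    serious_outcomes: frozenset[SeriousOutcome] = frozenset()
    drugs: list[DrugMention] = field(default_factory=list)
    reactions: list[ReactionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.version < 0:
            raise ValueError(f"version must be >= 0, got {self.version}")
        if self.received_year < 1968:
            raise ValueError(
                f"received_year must be >= 1968, got {self.received_year}"
            )
        self.serious_outcomes = frozenset(self.serious_outcomes)

    def has_drug(self, ingredient: str, role: Optional[DrugRole] = None) -> bool:
        """True if the report mentions ``ingredient`` (optionally with the
        given role code)."""
        for d in self.drugs:
            if d.matches(ingredient) and (role is None or d.role == role):
                return True
        return False

    def pt_multiset(self) -> tuple[str, ...]:
        """Sorted tuple of reaction PTs (used as part of the dedup key)."""
        return tuple(sorted(r.pt for r in self.reactions))

    def dedup_key(self) -> tuple:
        """The demographic tuple used to collapse cross-case duplicates."""
        return (
            self.sex,
            self.age_group,
            self.country,
            self.event_date,
            self.pt_multiset(),
            self.seriousness,
        )


@dataclass
class ReportDatabase:
    """A collection of case reports plus a free-text provenance note."""

    reports: list[CaseReport] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[CaseReport]:
        return iter(self.reports)

    @classmethod
    def from_reports(
        cls, reports: Iterable[CaseReport], provenance: str = ""
    ) -> "ReportDatabase":
        return cls(reports=list(reports), provenance=provenance)


class FormatError(ValueError):
    """Raised when an input file violates its documented format contract."""
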