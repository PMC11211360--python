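"""Record cleaning for spontaneous-report databases.

Three explicit stages, each a pure function on :class:`ReportDatabase`:

1. :func:`filter_by_date` — drop low-informative early records (default:
   anything dated strictly before 2019-03-05, the first marketing date of
   the target product).
2. :func:`select_target_reports` — restrict to reports naming the target
   ingredient with a given suspect role (default: primary suspect).
3. :func:`deduplicate` — two-stage duplicate removal: (i) among versions of
   one case keep the highest version; (ii) among distinct cases collapse
   reports identical on the demographic tuple (sex, age group, country,
   event date, sorted PT multiset, seriousness) to the most recently
   received one, ties broken by lexicographically smallest case id.

:func:`clean` chains the stages and returns an audit trail
(:class:`CleaningReport`).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import asdict, dataclass
from typing import Optional

from .types import CaseReport, DrugRole, ReportDatabase

#: first marketing authorization date of the seed analysis' target product
DEFAULT_CUTOFF = dt.date(2019, 3, 5)


@dataclass(frozen=True)
class CleaningReport:
    """Audit counts for one cleaning run."""

    n_input: int
    n_after_date_filter: int
    n_duplicates_removed: int
    n_output: int

    def __post_init__(self):
        if self.n_output != self.n_after_date_filter - self.n_duplicates_removed:
            raise ValueError("inconsistent cleaning counts")
        if self.n_output > self.n_input:
            raise ValueError("output larger than input")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_by_date(
    db: ReportDatabase, cutoff_date: dt.date = DEFAULT_CUTOFF
) -> ReportDatabase:
    """Remove reports dated strictly before ``cutoff_date``.

    Reports with an explicit ``event_date`` are compared directly ("earlier
    than" is strict: a report dated exactly on the cutoff is kept).  Reports
    with no event date are kept iff their ``received_year`` is at least the
    cutoff year — year-level data cannot be placed within the cutoff year,
    so the whole year is retained.
    """
    kept = []
    for r in db.reports:
        if r.event_date is not None:
            if r.event_date >= cutoff_date:
                kept.append(r)
        elif r.received_year >= cutoff_date.year:
            kept.append(r)
    return ReportDatabase(reports=kept, provenance=db.provenance)


def drop_reaction_free(db: ReportDatabase) -> tuple[ReportDatabase, int]:
    """Drop reports with zero coded reactions (unanalyzable); return count."""
    kept = [r for r in db.reports if r.reactions]
    return ReportDatabase(kept, db.provenance), len(db.reports) - len(kept)


def select_target_reports(
    db: ReportDatabase,
    ingredient: str,
    role: DrugRole = DrugRole.PRIMARY_SUSPECT,
) -> ReportDatabase:
    """Keep reports with >= 1 drug mention matching ``ingredient`` in ``role``."""
    if not isinstance(role, DrugRole):
        raise ValueError(f"unknown drug role: {role!r}")
    kept = [r for r in db.reports if r.has_drug(ingredient, role)]
    return ReportDatabase(kept, db.provenance)


def _dedup_versions(reports: list[CaseReport]) -> list[CaseReport]:
    # sort so the preferred survivor of each case_id is visited last, then
    # overwrite into a dict keyed by case_id
    ordered = sorted(
        reports,
        key=lambda r: (r.case_id, r.version, r.received_year, str(r.dedup_key())),
    )
    best: dict[str, CaseReport] = {}
    for r in ordered:
        best[r.case_id] = r
    return list(best.values())


def _dedup_tuples(reports: list[CaseReport]) -> list[CaseReport]:
    # survivor of a tuple group: most recent received_year, ties broken by
    # lexicographically smallest case_id.  Stable two-pass sort puts the
    # survivor last within each group.
    ordered = sorted(reports, key=lambda r: r.case_id, reverse=True)
    ordered = sorted(ordered, key=lambda r: r.received_year)
    groups: dict[tuple, CaseReport] = {}
    for r in ordered:
        groups[r.dedup_key()] = r
    return list(groups.values())


def deduplicate(
    db: ReportDatabase, mode: str = "full"
) -> tuple[ReportDatabase, CleaningReport]:
    """Remove duplicate reports.

    ``mode="version"`` applies only stage (i) (case-version supersession);
    ``mode="full"`` (default) additionally collapses distinct cases that are
    identical on the demographic dedup tuple.  Deterministic and
    order-insensitive: survivors are returned sorted by (case_id, version).
    """
    if mode not in ("version", "full"):
        raise ValueError(f"dedup mode must be 'version' or 'full', got {mode!r}")
    n_in = len(db.reports)
    reports = _dedup_versions(list(db.reports))
    if mode == "full":
        reports = _dedup_tuples(reports)
    reports = sorted(reports, key=lambda r: (r.case_id, r.version))
    report = CleaningReport(
        n_input=n_in,
        n_after_date_filter=n_in,
        n_duplicates_removed=n_in - len(reports),
        n_output=len(reports),
    )
    return ReportDatabase(reports, db.provenance), report


def clean(
    db: ReportDatabase,
    cutoff_date: dt.date = DEFAULT_CUTOFF,
    dedup_mode: str = "full",
    ingredient: Optional[str] = None,
    role: DrugRole = DrugRole.PRIMARY_SUSPECT,
) -> tuple[ReportDatabase, CleaningReport]:
    """Full cleaning pipeline: date filter, reaction-free drop, dedup, and
    (optionally) target-drug restriction when ``ingredient`` is given.

    The date filter and the target restriction commute; dedup runs last so
    that version supersession sees every surviving version.
    """
    n_input = len(db.reports)
    db = filter_by_date(db, cutoff_date)
    db, n_empty = drop_reaction_free(db)
    n_after_date = len(db.reports)
    if ingredient is not None:
        db = select_target_reports(db, ingredient, role)
        n_after_date = len(db.reports)
    db, dd = deduplicate(db, mode=dedup_mode)
    return db, CleaningReport(
        n_input=n_input,
        n_after_date_filter=n_after_date,
        n_duplicates_removed=dd.n_duplicates_removed,
        n_output=len(db.reports),
    )
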