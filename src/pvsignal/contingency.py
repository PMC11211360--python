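"""Four-grid (2x2) contingency tables for drug-event pairs.

For a target drug and one event term, the table partitions the database:

==============  ============  ============
                target event  other events
==============  ============  ============
target drug     a             b
other drugs     c             d
==============  ============  ============

Two counting units are supported.  With ``counting_unit="event_record"``
(default) every case-reaction pair is one countable record, so ``a + b``
equals the number of target-drug reaction records.  With
``counting_unit="case"`` each case counts once, contributing to ``a`` when
it carries the event and to ``b`` otherwise.  Identical PTs within a case
are collapsed to one record before counting in either unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import DrugRole, ReportDatabase

PT_LEVEL = "PT"
SOC_LEVEL = "SOC"


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d four-grid counts for one drug-event pair.

    Cells are floats so that tables of *expected* counts (from the synthetic
    generator's closed form) share the type; observed tables hold integers.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n_total <= 0:
            raise ValueError("contingency table must have N > 0")

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected count of cell ``a`` under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n_total

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def record_frame(
    db: ReportDatabase,
    target_ingredient: str,
    level: str = PT_LEVEL,
    role: DrugRole = DrugRole.PRIMARY_SUSPECT,
) -> pd.DataFrame:
    """Flatten a database to one row per (case, term) reaction record.

    Columns: ``case_id``, ``is_target`` (the case names the target
    ingredient with the given role), ``term`` (PT or SOC per ``level``).
    Identical terms within a case are collapsed.
    """
    if level not in (PT_LEVEL, SOC_LEVEL):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    case_ids, targets, terms = [], [], []
    for idx, r in enumerate(db.reports):
        is_target = r.has_drug(target_ingredient, role)
        seen: set[str] = set()
        for rec in r.reactions:
            term = rec.pt if level == PT_LEVEL else rec.soc
            if term in seen:
                continue
            seen.add(term)
            # index disambiguates pre-dedup databases with repeated case_ids
            case_ids.append(f"{r.case_id}#{idx}")
            targets.append(is_target)
            terms.append(term)
    return pd.DataFrame({"case_id": case_ids, "is_target": targets, "term": terms})


def _table_from_counts(
    a: int, n_target: int, c: int, n_other: int, counting_unit: str
) -> ContingencyTable:
    return ContingencyTable(a=a, b=n_target - a, c=c, d=n_other - c)


def build_contingency(
    db: ReportDatabase,
    target_ingredient: str,
    event_term: str,
    level: str = PT_LEVEL,
    counting_unit: str = "event_record",
    role: DrugRole = DrugRole.PRIMARY_SUSPECT,
) -> ContingencyTable:
    """Build the 2x2 table for one drug-event pair.

    A term absent from the whole database yields ``a = c = 0`` (a valid
    table that will fail the ``a >= 3`` screen), not an error.  An empty
    database (N = 0) is a precondition violation.
    """
    frame = record_frame(db, target_ingredient, level, role)
    if frame.empty:
        raise ValueError("empty database: no reaction records to tabulate")
    return _single_table(frame, event_term, counting_unit)


def _single_table(
    frame: pd.DataFrame, event_term: str, counting_unit: str
) -> ContingencyTable:
    if counting_unit == "event_record":
        n_target = int(frame["is_target"].sum())
        n_other = len(frame) - n_target
        match = frame["term"] == event_term
        a = int((match & frame["is_target"]).sum())
        c = int((match & ~frame["is_target"]).sum())
    elif counting_unit == "case":
        cases = frame.groupby("case_id").agg(
            is_target=("is_target", "first"),
            has_event=("term", lambda t: event_term in set(t)),
        )
        n_target = int(cases["is_target"].sum())
        n_other = len(cases) - n_target
        a = int((cases["is_target"] & cases["has_event"]).sum())
        c = int((~cases["is_target"] & cases["has_event"]).sum())
    else:
        raise ValueError(
            f"counting_unit must be 'event_record' or 'case', got {counting_unit!r}"
        )
    return _table_from_counts(a, n_target, c, n_other, counting_unit)


def build_all_contingencies(
    db: ReportDatabase,
    target_ingredient: str,
    level: str = PT_LEVEL,
    counting_unit: str = "event_record",
    role: DrugRole = DrugRole.PRIMARY_SUSPECT,
) -> dict[str, ContingencyTable]:
    """One table per distinct term observed on target-drug records.

    Terms never reported with the target drug are omitted (their ``a`` is 0
    by construction and they carry no signal information for the target).
    Returns an empty mapping when the target drug is absent.
    """
    frame = record_frame(db, target_ingredient, level, role)
    if frame.empty:
        return {}
    target_terms = sorted(frame.loc[frame["is_target"], "term"].unique())
    if not target_terms:
        return {}

    out: dict[str, ContingencyTable] = {}
    if counting_unit == "event_record":
        n_target = int(frame["is_target"].sum())
        n_other = len(frame) - n_target
        counts = (
            frame.groupby(["term", "is_target"]).size().unstack(fill_value=0)
        )
        for term in target_terms:
            row = counts.loc[term]
            a = int(row.get(True, 0))
            c = int(row.get(False, 0))
            out[term] = _table_from_counts(a, n_target, c, n_other, counting_unit)
    else:
        for term in target_terms:
            out[term] = _single_table(frame, term, counting_unit)
    return out
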