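"""Shared fixtures: tiny hand-built databases and one generated database."""

from __future__ import annotations

import datetime as dt

import pytest

from pvsignal import (
    CaseReport,
    DrugMention,
    DrugRole,
    ReactionRecord,
    ReportDatabase,
    default_config,
    generate_database,
)

TARGET = "esketamine"
OTHER = "quetiapine"


def mk_report(
    case_id: str,
    pts: list[str],
    ingredient: str = TARGET,
    role: DrugRole = DrugRole.PRIMARY_SUSPECT,
    version: int = 0,
    year: int = 2020,
    event_date: dt.date | None = None,
    **kwargs,
) -> CaseReport:
    """Minimal report with one drug mention and the given reaction PTs."""
    return CaseReport(
        case_id=case_id,
        version=version,
        received_year=year,
        event_date=event_date,
        drugs=[DrugMention(ingredient, role)],
        reactions=[ReactionRecord(pt, "Unmapped") for pt in pts],
        **kwargs,
    )


@pytest.fixture
def report_factory():
    return mk_report


@pytest.fixture
def toy_db() -> ReportDatabase:
    """Six reports, seven reaction records: the worked contingency example.

    Target reports carry [PT1, PT2] and [PT1]; the four non-target reports
    carry [PT1], [PT2], [PT2], [PT3].  At PT1 in the event-record unit the
    four-grid is a=2, b=1, c=1, d=3.
    """
    reports = [
        mk_report("T1", ["PT1", "PT2"]),
        mk_report("T2", ["PT1"]),
        mk_report("O1", ["PT1"], ingredient=OTHER),
        mk_report("O2", ["PT2"], ingredient=OTHER),
        mk_report("O3", ["PT2"], ingredient=OTHER),
        mk_report("O4", ["PT3"], ingredient=OTHER),
    ]
    return ReportDatabase(reports=reports)


@pytest.fixture(scope="session")
def generated():
    """One mid-size generated database with its ground-truth ledger."""
    cfg = default_config(n_reports=1500, seed=42)
    db, ledger = generate_database(cfg)
    return cfg, db, ledger
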