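"""Readers and writers for FAERS-style spontaneous-report files.

Two input shapes are supported:

* **Quarterly ASCII extracts** — the four dollar-delimited tables
  DEMO/DRUG/REAC/OUTC keyed by ``primaryid`` (:func:`load_faers_ascii`).
* **Dashboard-style CSV** — one row per case (or per case-reaction) in the
  flat export style of the FAERS Public Dashboard, with a configurable
  column mapping (:func:`load_dashboard_csv`).

Both produce the same in-memory :class:`~pvsignal.types.ReportDatabase`.
Unparseable optional fields degrade to ``unknown`` — rows are never dropped
at load time; cleaning is a separate, explicit stage.
"""

from __future__ import annotations

import datetime as dt
import warnings
from typing import Optional

import pandas as pd

from .meddra import PtSocMapping, map_pt_to_soc
from .types import (
    AgeGroup,
    CaseReport,
    DrugMention,
    DrugRole,
    FormatError,
    ReactionRecord,
    ReportDatabase,
    ReporterType,
    Seriousness,
    SeriousOutcome,
    Sex,
    age_group_from_years,
)

# FAERS role_cod values
_ROLE_CODES = {
    "PS": DrugRole.PRIMARY_SUSPECT,
    "SS": DrugRole.SECONDARY_SUSPECT,
    "C": DrugRole.CONCOMITANT,
    "I": DrugRole.INTERACTING,
}

# FAERS outc_cod values
_OUTCOME_CODES = {
    "DE": SeriousOutcome.DEATH,
    "LT": SeriousOutcome.LIFE_THREATENING,
    "HO": SeriousOutcome.HOSPITALIZATION,
    "DS": SeriousOutcome.DISABILITY,
    "CA": SeriousOutcome.CONGENITAL_ANOMALY,
    "OT": SeriousOutcome.OTHER_SERIOUS,
    "RI": SeriousOutcome.OTHER_SERIOUS,  # required intervention
}

# FAERS occp_cod values
_REPORTER_CODES = {
    "MD": ReporterType.HEALTHCARE_PROFESSIONAL,
    "PH": ReporterType.HEALTHCARE_PROFESSIONAL,
    "OT": ReporterType.HEALTHCARE_PROFESSIONAL,
    "HP": ReporterType.HEALTHCARE_PROFESSIONAL,
    "RN": ReporterType.HEALTHCARE_PROFESSIONAL,
    "CN": ReporterType.CONSUMER,
}

_SEX_CODES = {"F": Sex.FEMALE, "M": Sex.MALE}


def _read_table(path, sep: str) -> pd.DataFrame:
    """Read a delimited text table as strings; UTF-8 with latin-1 fallback."""
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    except UnicodeDecodeError:
        df = pd.read_csv(path, sep=sep, dtype=str, encoding="latin-1")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _require(df: pd.DataFrame, path, columns: list[str]) -> None:
    for col in columns:
        if col not in df.columns and not df.empty:
            raise FormatError(f"{path}: missing mandatory column '{col}'")


def _opt(row, col: str) -> Optional[str]:
    val = row.get(col)
    if val is None or pd.isna(val) or str(val).strip() == "":
        return None
    return str(val).strip()


def _parse_float(s: Optional[str]) -> Optional[float]:
    if s is None:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _parse_date(s: Optional[str]) -> Optional[dt.date]:
    """FAERS dates are YYYYMMDD, possibly truncated to YYYYMM or YYYY."""
    if s is None:
        return None
    digits = "".join(ch for ch in s if ch.isdigit())
    if len(digits) >= 8:
        try:
            return dt.date(int(digits[:4]), int(digits[4:6]), int(digits[6:8]))
        except ValueError:
            return None
    if len(digits) in (4, 6):
        # year or year-month precision is not a full event date
        return None
    # also accept ISO strings
    try:
        return dt.date.fromisoformat(s)
    except ValueError:
        return None


def _age_in_years(age: Optional[str], unit: Optional[str]) -> Optional[float]:
    val = _parse_float(age)
    if val is None:
        return None
    unit = (unit or "YR").strip().upper()
    factor = {
        "YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.18,
        "DY": 1 / 365.25, "HR": 1 / 8766.0,
    }.get(unit)
    return val * factor if factor is not None else None


def _split_primaryid(primaryid: str) -> tuple[str, int]:
    """FAERS primaryid = caseid immediately followed by a one-digit version."""
    pid = primaryid.strip()
    if pid.isdigit() and len(pid) > 1:
        return pid[:-1], int(pid[-1])
    return pid, 0


def load_faers_ascii(
    demo_path,
    drug_path,
    reac_path,
    outc_path,
    mapping: Optional[PtSocMapping] = None,
) -> ReportDatabase:
    """Load a FAERS quarterly extract (dollar-delimited DEMO/DRUG/REAC/OUTC).

    One :class:`CaseReport` is built per ``primaryid`` in DEMO, joined with
    its drug, reaction and outcome rows.  A report is serious iff it has at
    least one outcome row.
    """
    demo = _read_table(demo_path, "$")
    drug = _read_table(drug_path, "$")
    reac = _read_table(reac_path, "$")
    outc = _read_table(outc_path, "$")

    _require(demo, demo_path, ["primaryid"])
    _require(drug, drug_path, ["primaryid", "role_cod"])
    if not drug.empty and "prod_ai" not in drug.columns and "drugname" not in drug.columns:
        raise FormatError(f"{drug_path}: missing mandatory column 'drugname' (or 'prod_ai')")
    _require(reac, reac_path, ["primaryid", "pt"])
    _require(outc, outc_path, ["primaryid", "outc_cod"])

    if demo.empty:
        warnings.warn(f"{demo_path}: no data rows; returning empty database")
        return ReportDatabase(provenance=f"faers_ascii:{demo_path}")

    drug_by_id: dict[str, list[DrugMention]] = {}
    for _, row in drug.iterrows():
        pid = _opt(row, "primaryid")
        if pid is None:
            continue
        ingredient = _opt(row, "prod_ai") or _opt(row, "drugname") or ""
        role = _ROLE_CODES.get((_opt(row, "role_cod") or "").upper(),
                               DrugRole.CONCOMITANT)
        drug_by_id.setdefault(pid, []).append(
            DrugMention(
                active_ingredient=ingredient,
                role=role,
                product_name=_opt(row, "drugname"),
                reason_for_use=_opt(row, "indi_pt"),
            )
        )

    reac_by_id: dict[str, list[ReactionRecord]] = {}
    for _, row in reac.iterrows():
        pid = _opt(row, "primaryid")
        pt = _opt(row, "pt")
        if pid is None or pt is None:
            continue
        reac_by_id.setdefault(pid, []).append(
            ReactionRecord(pt=pt, soc=map_pt_to_soc(pt, mapping))
        )

    outc_by_id: dict[str, set[SeriousOutcome]] = {}
    for _, row in outc.iterrows():
        pid = _opt(row, "primaryid")
        code = (_opt(row, "outc_cod") or "").upper()
        if pid is None or code not in _OUTCOME_CODES:
            continue
        outc_by_id.setdefault(pid, set()).add(_OUTCOME_CODES[code])

    reports = []
    for _, row in demo.iterrows():
        pid = _opt(row, "primaryid")
        if pid is None:
            continue
        case_id = _opt(row, "caseid")
        version_s = _opt(row, "caseversion")
        if case_id is None:
            case_id, version = _split_primaryid(pid)
        else:
            version = int(version_s) if version_s and version_s.isdigit() else 0

        age_years = _age_in_years(_opt(row, "age"), _opt(row, "age_cod"))
        recv = _opt(row, "fda_dt") or _opt(row, "rept_dt") or _opt(row, "init_fda_dt")
        recv_date = _parse_date(recv)
        recv_year = recv_date.year if recv_date else (
            int(recv[:4]) if recv and recv[:4].isdigit() and len(recv) >= 4 else 1968
        )
        outcomes = frozenset(outc_by_id.get(pid, set()))
        reports.append(
            CaseReport(
                case_id=case_id,
                version=version,
                sex=_SEX_CODES.get((_opt(row, "sex") or "").upper(), Sex.UNKNOWN),
                age_group=age_group_from_years(age_years),
                weight_kg=_parse_float(_opt(row, "wt")),
                country=_opt(row, "occr_country") or _opt(row, "reporter_country")
                or "unknown",
                reporter_type=_REPORTER_CODES.get(
                    (_opt(row, "occp_cod") or "").upper(), ReporterType.UNKNOWN
                ),
                received_year=max(recv_year, 1968),
                event_date=_parse_date(_opt(row, "event_dt")),
                seriousness=Seriousness.SERIOUS if outcomes else Seriousness.NON_SERIOUS,
                serious_outcomes=outcomes,
                drugs=drug_by_id.get(pid, []),
                reactions=reac_by_id.get(pid, []),
            )
        )
    return ReportDatabase(reports=reports, provenance=f"faers_ascii:{demo_path}")


# ---------------------------------------------------------------------------
# Dashboard-style flat CSV

#: default column names for dashboard-style CSV files; override any entry
#: via the ``column_map`` argument of :func:`load_dashboard_csv`.
DASHBOARD_COLUMNS = {
    "case_id": "case_id",
    "version": "version",
    "sex": "sex",
    "age_group": "age_group",
    "weight_kg": "weight_kg",
    "country": "country",
    "reporter_type": "reporter_type",
    "received_year": "received_year",
    "event_date": "event_date",
    "seriousness": "seriousness",
    "serious_outcomes": "serious_outcomes",
    "drugs": "drugs",
    "reactions": "reactions",
}

_SEX_VALUES = {
    "f": Sex.FEMALE, "female": Sex.FEMALE,
    "m": Sex.MALE, "male": Sex.MALE,
}
_AGE_VALUES = {g.value: g for g in AgeGroup} | {"65+": AgeGroup.ELDERLY,
                                                "≥65": AgeGroup.ELDERLY,
                                                "18–64": AgeGroup.ADULT}
_REPORTER_VALUES = {
    "healthcare_professional": ReporterType.HEALTHCARE_PROFESSIONAL,
    "healthcare professional": ReporterType.HEALTHCARE_PROFESSIONAL,
    "hcp": ReporterType.HEALTHCARE_PROFESSIONAL,
    "consumer": ReporterType.CONSUMER,
}
_ROLE_VALUES = {r.value: r for r in DrugRole} | {
    "ps": DrugRole.PRIMARY_SUSPECT,
    "ss": DrugRole.SECONDARY_SUSPECT,
    "c": DrugRole.CONCOMITANT,
    "i": DrugRole.INTERACTING,
    "primary suspect": DrugRole.PRIMARY_SUSPECT,
    "concomitant": DrugRole.CONCOMITANT,
}
_OUTCOME_VALUES = {o.value: o for o in SeriousOutcome} | {
    "died": SeriousOutcome.DEATH,
    "hospitalized": SeriousOutcome.HOSPITALIZATION,
    "life threatening": SeriousOutcome.LIFE_THREATENING,
    "congenital anomaly": SeriousOutcome.CONGENITAL_ANOMALY,
    "other serious": SeriousOutcome.OTHER_SERIOUS,
}


def _parse_drug_cell(cell: str) -> list[DrugMention]:
    """Parse 'ingredient:role; ingredient:role' (role optional, default PS)."""
    mentions = []
    for part in cell.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            name, _, role_s = part.rpartition(":")
            role = _ROLE_VALUES.get(role_s.strip().lower(), DrugRole.PRIMARY_SUSPECT)
        else:
            name, role = part, DrugRole.PRIMARY_SUSPECT
        mentions.append(DrugMention(active_ingredient=name.strip(), role=role))
    return mentions


def load_dashboard_csv(
    path,
    column_map: Optional[dict[str, str]] = None,
    mapping: Optional[PtSocMapping] = None,
) -> ReportDatabase:
    """Load a dashboard-style flat CSV into a :class:`ReportDatabase`.

    Each row describes one case (or one case-reaction); rows sharing a case
    id are merged, multi-valued cells (reactions, drugs, outcomes) split on
    ``';'``.  Column names default to :data:`DASHBOARD_COLUMNS` and may be
    remapped via ``column_map``.  When no version column exists and the case
    id is all digits, the trailing digit is taken as the version (FAERS
    primaryid convention).
    """
    cols = dict(DASHBOARD_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = _read_table(path, ",")
    if df.empty:
        warnings.warn(f"{path}: no data rows; returning empty database")
        return ReportDatabase(provenance=f"dashboard_csv:{path}")
    if cols["case_id"] not in df.columns:
        raise FormatError(f"{path}: missing mandatory column '{cols['case_id']}'")
    if cols["reactions"] not in df.columns:
        raise FormatError(f"{path}: missing mandatory column '{cols['reactions']}'")

    by_case: dict[tuple[str, int], CaseReport] = {}
    order: list[tuple[str, int]] = []
    for _, row in df.iterrows():
        raw_id = _opt(row, cols["case_id"])
        if raw_id is None:
            continue
        version_s = _opt(row, cols["version"])
        if version_s is not None and version_s.lstrip("-").isdigit():
            case_id, version = raw_id, int(version_s)
        elif cols["version"] in df.columns:
            case_id, version = raw_id, 0
        else:
            case_id, version = _split_primaryid(raw_id)

        key = (case_id, version)
        reactions = []
        for pt in (_opt(row, cols["reactions"]) or "").split(";"):
            pt = pt.strip()
            if pt:
                reactions.append(ReactionRecord(pt=pt, soc=map_pt_to_soc(pt, mapping)))
        drugs = _parse_drug_cell(_opt(row, cols["drugs"]) or "")

        if key in by_case:
            rpt = by_case[key]
            seen_pts = {r.pt for r in rpt.reactions}
            rpt.reactions.extend(r for r in reactions if r.pt not in seen_pts)
            seen_drugs = {(d.active_ingredient, d.role) for d in rpt.drugs}
            rpt.drugs.extend(
                d for d in drugs if (d.active_ingredient, d.role) not in seen_drugs
            )
            continue

        outcomes = set()
        for tok in (_opt(row, cols["serious_outcomes"]) or "").split(";"):
            tok = tok.strip().lower().replace("-", " ")
            if tok in _OUTCOME_VALUES:
                outcomes.add(_OUTCOME_VALUES[tok])
            elif tok.replace(" ", "_") in _OUTCOME_VALUES:
                outcomes.add(_OUTCOME_VALUES[tok.replace(" ", "_")])
        serious_s = (_opt(row, cols["seriousness"]) or "").strip().lower()
        serious = serious_s in {"serious", "yes", "y", "s", "1", "true"} or bool(outcomes)

        year_s = _opt(row, cols["received_year"])
        age_s = (_opt(row, cols["age_group"]) or "").strip()
        rpt = CaseReport(
            case_id=case_id,
            version=version,
            sex=_SEX_VALUES.get((_opt(row, cols["sex"]) or "").strip().lower(),
                                Sex.UNKNOWN),
            age_group=_AGE_VALUES.get(age_s, age_group_from_years(_parse_float(age_s))),
            weight_kg=_parse_float(_opt(row, cols["weight_kg"])),
            country=_opt(row, cols["country"]) or "unknown",
            reporter_type=_REPORTER_VALUES.get(
                (_opt(row, cols["reporter_type"]) or "").strip().lower(),
                ReporterType.UNKNOWN,
            ),
            received_year=int(year_s) if year_s and year_s.isdigit() else 1968,
            event_date=_parse_date(_opt(row, cols["event_date"])),
            seriousness=Seriousness.SERIOUS if serious else Seriousness.NON_SERIOUS,
            serious_outcomes=frozenset(outcomes),
            drugs=drugs,
            reactions=reactions,
        )
        by_case[key] = rpt
        order.append(key)

    return ReportDatabase(
        reports=[by_case[k] for k in order],
        provenance=f"dashboard_csv:{path}",
    )


def write_dashboard_csv(db: ReportDatabase, path) -> None:
    """Write ``db`` as a dashboard-style CSV (one row per case).

    Inverse of :func:`load_dashboard_csv` for all counted fields: report
    count, reaction multisets, drug mentions and demographic enums survive a
    write/read round trip.
    """
    rows = []
    for r in db.reports:
        rows.append(
            {
                "case_id": r.case_id,
                "version": r.version,
                "sex": r.sex.value,
                "age_group": r.age_group.value,
                "weight_kg": r.weight_kg if r.weight_kg is not None else "",
                "country": r.country,
                "reporter_type": r.reporter_type.value,
                "received_year": r.received_year,
                "event_date": r.event_date.isoformat() if r.event_date else "",
                "seriousness": r.seriousness.value,
                "serious_outcomes": ";".join(
                    sorted(o.value for o in r.serious_outcomes)
                ),
                "drugs": ";".join(
                    f"{d.active_ingredient}:{d.role.value}" for d in r.drugs
                ),
                "reactions": ";".join(x.pt for x in r.reactions),
            }
        )
    pd.DataFrame(rows, columns=list(DASHBOARD_COLUMNS)).to_csv(path, index=False)
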