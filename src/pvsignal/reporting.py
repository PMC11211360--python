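"""Descriptive summary tables for a cleaned report database.

Three table shapes, mirroring the standard pharmacovigilance write-up:

* :func:`demographics_summary` — per-category counts and percentages over
  the *case* denominator (sex, age group, reporter type, top-k countries,
  report year, seriousness);
* :func:`soc_summary` — per-SOC reaction-record counts with percentages
  over the *record* denominator, plus the number of screened signal PTs
  falling in each SOC;
* :func:`top_signals` — the top-N event terms ranked by a chosen statistic
  (EBGM by default).

The two denominators coexist on purpose: demographic blocks count cases,
SOC blocks count case-reaction records; every output labels which one it
used.  Percentages are rounded half-up to 2 decimals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .disproportionality import SignalStatistics
from .types import DrugRole, ReportDatabase


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (matches hand-tabulated percentages)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct_block(counts: dict[str, int], denominator: int) -> dict[str, tuple[int, float]]:
    return {
        k: (v, round_half_up(100.0 * v / denominator) if denominator else 0.0)
        for k, v in counts.items()
    }


@dataclass
class DemographicsSummary:
    """Count/percentage blocks over the deduplicated case denominator."""

    denominator: int
    denominator_unit: str = "cases"
    blocks: dict[str, dict[str, tuple[int, float]]] = field(default_factory=dict)

    def counts(self, block: str) -> dict[str, int]:
        return {k: v[0] for k, v in self.blocks[block].items()}

    def percentages(self, block: str) -> dict[str, float]:
        return {k: v[1] for k, v in self.blocks[block].items()}


def demographics_summary(db: ReportDatabase, top_k_countries: int = 5) -> DemographicsSummary:
    """Tabulate sex, age group, reporter type, top-k countries, report year
    and seriousness, each with percentages over the case count."""
    n = len(db.reports)
    sex = Counter(r.sex.value for r in db.reports)
    age = Counter(r.age_group.value for r in db.reports)
    reporter = Counter(r.reporter_type.value for r in db.reports)
    country = Counter(r.country for r in db.reports)
    year = Counter(str(r.received_year) for r in db.reports)
    serious = Counter(r.seriousness.value for r in db.reports)

    top_countries = dict(
        sorted(country.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k_countries]
    )
    summary = DemographicsSummary(denominator=n)
    summary.blocks = {
        "sex": _pct_block(dict(sex), n),
        "age_group": _pct_block(dict(age), n),
        "reporter_type": _pct_block(dict(reporter), n),
        "country_top": _pct_block(top_countries, n),
        "report_year": _pct_block(dict(sorted(year.items())), n),
        "seriousness": _pct_block(dict(serious), n),
    }
    return summary


@dataclass
class SocSummary:
    """Per-SOC record counts, percentage of total records, and signal tallies."""

    denominator: int
    denominator_unit: str = "reaction_records"
    rows: dict[str, tuple[int, float, int]] = field(default_factory=dict)
    #: signal counts per SOC under each individual criterion, for reports
    #: that need the per-method tallies alongside the conjunction count
    per_criterion: dict[str, dict[str, int]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {k: v[0] for k, v in self.rows.items()}

    def percentages(self) -> dict[str, float]:
        return {k: v[1] for k, v in self.rows.items()}

    def signal_counts(self) -> dict[str, int]:
        return {k: v[2] for k, v in self.rows.items()}


def soc_summary(
    db: ReportDatabase,
    screen_result: Optional[Sequence[SignalStatistics]] = None,
    target_ingredient: Optional[str] = None,
    role: DrugRole = DrugRole.PRIMARY_SUSPECT,
) -> SocSummary:
    """Per-SOC reaction-record counts for the target drug's reports.

    When ``target_ingredient`` is given, only records of reports naming it
    (with ``role``) are counted; otherwise all records count.  When a
    PT-level ``screen_result`` is supplied, each SOC row carries the number
    of its PTs with ``is_signal`` set (conjunction of criteria), and
    ``per_criterion`` tallies each individual criterion's flag.
    """
    # one record per distinct (case, PT) pair, grouped by the PT's SOC, so
    # the SOC counts sum to the total reaction-record count
    soc_counts: Counter = Counter()
    for r in db.reports:
        if target_ingredient is not None and not r.has_drug(target_ingredient, role):
            continue
        seen: set[str] = set()
        for rec in r.reactions:
            if rec.pt in seen:
                continue
            seen.add(rec.pt)
            soc_counts[rec.soc] += 1

    total = sum(soc_counts.values())
    signal_by_soc: Counter = Counter()
    per_criterion: dict[str, Counter] = {
        "ror": Counter(), "prr": Counter(), "ebgm": Counter()
    }
    if screen_result is not None:
        for s in screen_result:
            if s.is_signal:
                signal_by_soc[s.soc] += 1
            if s.flag_ror:
                per_criterion["ror"][s.soc] += 1
            if s.flag_prr:
                per_criterion["prr"][s.soc] += 1
            if s.flag_ebgm:
                per_criterion["ebgm"][s.soc] += 1

    rows = {}
    for soc, cnt in sorted(soc_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        pct = round_half_up(100.0 * cnt / total) if total else 0.0
        rows[soc] = (cnt, pct, int(signal_by_soc.get(soc, 0)))
    return SocSummary(
        denominator=total,
        rows=rows,
        per_criterion={k: dict(v) for k, v in per_criterion.items()},
    )


def top_signals(
    screen_result: Sequence[SignalStatistics],
    k: int = 50,
    rank_key: str = "ebgm",
    signals_only: bool = True,
) -> list[SignalStatistics]:
    """Top-``k`` terms by ``rank_key`` (descending).

    Ties break by larger ``n`` first, then term lexicographically.  With
    ``signals_only`` the input is first filtered to ``is_signal`` rows, so
    the result is a permutation of that subset truncated to ``k``.
    """
    if k <= 0:
        return []
    pool = [s for s in screen_result if s.is_signal] if signals_only \
        else list(screen_result)

    def key(s: SignalStatistics):
        val = getattr(s, rank_key)
        point = val.point if hasattr(val, "point") else float(val)
        if point != point:  # NaN ranks last
            point = float("-inf")
        return (-point, -s.n, s.term)

    return sorted(pool, key=key)[:k]
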