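"""Disproportionality statistics and signal screening.

For a 2x2 table (a, b, c, d) with N = a+b+c+d the classical measures are

* ROR  = (a/b) / (c/d) = ad/bc, with the Woolf log-normal 95% CI
  ``exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d))``;
* PRR  = (a/(a+b)) / (c/(c+d)), CI
  ``exp(ln PRR ± z * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))``;
* EBGM (unshrunk form) = a*N / ((a+c)*(a+b)), i.e. the relative reporting
  ratio observed/expected, CI ``exp(ln EBGM ± z * sqrt(1/a+1/b+1/c+1/d))``;
  its CI lower limit is reported as EBGM05;
* Pearson chi-square, Yates-corrected by default.

A drug-event pair is screened as a signal when (all three, by default):
``a >= 3`` with the ROR CI lower limit > 1, the same for PRR, and
EBGM05 > 2.  A shrunk empirical-Bayes EBGM (gamma-Poisson mixture, see
:mod:`pvsignal.mgps`) is available via ``ebgm_mode="mgps"``.

Zero cells leave a statistic undefined (NaN; the flag fails) unless the
Haldane +0.5 correction is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

from .contingency import PT_LEVEL, ContingencyTable, build_all_contingencies
from .meddra import PtSocMapping, map_pt_to_soc
from .types import DrugRole, ReportDatabase

NAN = float("nan")


class EstimateCI(NamedTuple):
    """A point estimate with its two-sided confidence bounds."""

    point: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.point)


_UNDEFINED = EstimateCI(NAN, NAN, NAN)


def _cells(table: ContingencyTable, haldane: bool) -> tuple[float, float, float, float]:
    a, b, c, d = table.as_tuple()
    if haldane and min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def compute_ror(
    table: ContingencyTable, z: float = 1.96, haldane: bool = False
) -> EstimateCI:
    """Reporting odds ratio ad/bc with Woolf log-normal CI.

    Any zero cell leaves the statistic undefined unless ``haldane`` adds 0.5
    to every cell.
    """
    a, b, c, d = _cells(table, haldane)
    if min(a, b, c, d) == 0:
        return _UNDEFINED
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EstimateCI(ror, ror * math.exp(-z * se), ror * math.exp(z * se))


def compute_prr(
    table: ContingencyTable, z: float = 1.96, haldane: bool = False
) -> EstimateCI:
    """Proportional reporting ratio (a/(a+b)) / (c/(c+d)) with log-normal CI."""
    a, b, c, d = _cells(table, haldane)
    if a == 0 or c == 0 or (a + b) == 0 or (c + d) == 0:
        return _UNDEFINED
    prr = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    return EstimateCI(prr, prr * math.exp(-z * se), prr * math.exp(z * se))


def compute_rr_ebgm(
    table: ContingencyTable, z: float = 1.96, haldane: bool = False
) -> EstimateCI:
    """Unshrunk EBGM: the relative reporting ratio a*N/((a+c)(a+b)).

    This is the observed count over its independence expectation; the CI
    lower limit is reported as EBGM05 when this estimator is selected.
    """
    a, b, c, d = _cells(table, haldane)
    if min(a, b, c, d) == 0:
        return _UNDEFINED
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EstimateCI(ebgm, ebgm * math.exp(-z * se), ebgm * math.exp(z * se))


def compute_chi2(table: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the 2x2 table (Yates-corrected by default).

    Yates: ``N * (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))``, floored at
    zero when the correction exceeds |ad - bc|.  Any zero margin -> NaN.
    """
    a, b, c, d = table.as_tuple()
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return NAN
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff * diff / denom


@dataclass(frozen=True)
class SignalCriteria:
    """Screening thresholds for calling a drug-event pair a signal.

    Defaults: ``a >= 3`` with the 95% CI lower limit > 1 for both ROR and
    PRR, and EBGM05 > 2; a pair must pass all three (``combine="all"``).
    """

    min_a: int = 3
    ci_low_threshold: float = 1.0
    ebgm05_threshold: float = 2.0
    z: float = 1.96
    combine: str = "all"

    def __post_init__(self):
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")
        if self.z <= 0:
            raise ValueError("z must be > 0")
        if self.combine not in ("all", "any"):
            raise ValueError("combine must be 'all' or 'any'")

    @classmethod
    def from_confidence_level(cls, level: float = 0.95, **kwargs) -> "SignalCriteria":
        from scipy.stats import norm

        return cls(z=float(norm.ppf(0.5 + level / 2)), **kwargs)


@dataclass
class SignalStatistics:
    """All disproportionality statistics and screening flags for one term."""

    term: str
    level: str
    soc: str
    n: int  # the a cell
    ror: EstimateCI = _UNDEFINED
    prr: EstimateCI = _UNDEFINED
    ebgm: EstimateCI = _UNDEFINED  # ci_low is EBGM05
    chi2: float = NAN
    flag_ror: bool = False
    flag_prr: bool = False
    flag_ebgm: bool = False
    is_signal: bool = False
    table: Optional[ContingencyTable] = field(default=None, repr=False)

    @property
    def ebgm05(self) -> float:
        return self.ebgm.ci_low


def evaluate_signal(
    stats: SignalStatistics, criteria: SignalCriteria = SignalCriteria()
) -> SignalStatistics:
    """Apply the screening thresholds; undefined statistics fail their flag."""
    n_ok = stats.n >= criteria.min_a
    flag_ror = bool(
        n_ok and stats.ror.defined and stats.ror.ci_low > criteria.ci_low_threshold
    )
    flag_prr = bool(
        n_ok and stats.prr.defined and stats.prr.ci_low > criteria.ci_low_threshold
    )
    flag_ebgm = bool(
        stats.ebgm.defined and stats.ebgm.ci_low > criteria.ebgm05_threshold
    )
    flags = (flag_ror, flag_prr, flag_ebgm)
    is_signal = all(flags) if criteria.combine == "all" else any(flags)
    return replace(
        stats,
        flag_ror=flag_ror,
        flag_prr=flag_prr,
        flag_ebgm=flag_ebgm,
        is_signal=is_signal,
    )


def compute_statistics(
    term: str,
    table: ContingencyTable,
    level: str = PT_LEVEL,
    soc: str = "",
    z: float = 1.96,
    haldane: bool = False,
    yates: bool = True,
) -> SignalStatistics:
    """All frequentist statistics for one table (no screening flags yet)."""
    return SignalStatistics(
        term=term,
        level=level,
        soc=soc,
        n=int(table.a),
        ror=compute_ror(table, z, haldane),
        prr=compute_prr(table, z, haldane),
        ebgm=compute_rr_ebgm(table, z, haldane),
        chi2=compute_chi2(table, yates),
        table=table,
    )


def screen_signals(
    db: ReportDatabase,
    target_ingredient: str,
    level: str = PT_LEVEL,
    criteria: SignalCriteria = SignalCriteria(),
    ebgm_mode: str = "unshrunk",
    counting_unit: str = "event_record",
    role: DrugRole = DrugRole.PRIMARY_SUSPECT,
    haldane: bool = False,
    yates: bool = True,
    mapping: Optional[PtSocMapping] = None,
) -> list[SignalStatistics]:
    """Screen every event term reported with the target drug.

    Returns one :class:`SignalStatistics` per term (sorted by term so the
    output is independent of database row order), with flags set; filter on
    ``is_signal`` for the screened subset.

    ``ebgm_mode="unshrunk"`` (default) uses the unshrunk relative
    reporting ratio; ``"mgps"`` fits a two-gamma empirical-Bayes prior over
    all tables and replaces the EBGM column with the shrunk posterior
    geometric mean (EB05/EB95 as its interval).
    """
    if ebgm_mode not in ("unshrunk", "mgps"):
        raise ValueError(f"unknown ebgm_mode: {ebgm_mode!r}")
    tables = build_all_contingencies(
        db, target_ingredient, level=level, counting_unit=counting_unit, role=role
    )
    out = []
    for term in sorted(tables):
        soc = map_pt_to_soc(term, mapping) if level == PT_LEVEL else term
        stats = compute_statistics(
            term, tables[term], level=level, soc=soc, z=criteria.z,
            haldane=haldane, yates=yates,
        )
        out.append(stats)

    if ebgm_mode == "mgps" and out:
        from .mgps import fit_gps_prior, posterior_ebgm
        from .types import normalize_ingredient

        # the empirical-Bayes prior pools every drug-event cell in the
        # database, not just the target drug's rows
        seen_norm: set[str] = set()
        counts: list[float] = []
        expecteds: list[float] = []
        for r in db.reports:
            for d in r.drugs:
                if d.role != role:
                    continue
                key = normalize_ingredient(d.active_ingredient)
                if key in seen_norm:
                    continue
                seen_norm.add(key)
                for t in build_all_contingencies(
                    db, d.active_ingredient, level=level,
                    counting_unit=counting_unit, role=role,
                ).values():
                    counts.append(t.a)
                    expecteds.append(t.expected_a)
        prior = fit_gps_prior(counts=counts, expected=expecteds)
        for i, s in enumerate(out):
            t = s.table
            e = t.expected_a
            if e > 0:
                out[i] = replace(s, ebgm=posterior_ebgm(int(t.a), e, prior))

    return [evaluate_signal(s, criteria) for s in out]
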