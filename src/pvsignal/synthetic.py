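"""Synthetic FAERS-like report databases with known ground truth.

The generator draws independent case reports: drugs by per-drug marginal
probabilities (at least one drug per report, enforced by redraw), reactions
by per-PT marginal probabilities (at least one reaction per report, same
mechanism), demographics from configured categorical distributions.  Signal
pairs are implanted multiplicatively: when an implanted pair's drug is
present as primary suspect, that PT's inclusion probability is multiplied
by the pair's rate ratio (capped at 1).  Duplicate contamination clones a
sample of reports under fresh case ids with identical dedup tuples, and a
configurable fraction of reports is dated before the marketing cutoff.

Everything is a pure function of the config (including its seed), and a
:class:`GroundTruthLedger` records exactly which records were injected, so
pipeline tests can assert exact removal.  :func:`expected_contingency`
evaluates the generative model's expected 2x2 cells in closed form (by
enumeration over drug presence/suspect-role states), giving an independent
oracle for estimator-recovery experiments.
"""

from __future__ import annotations

import datetime as dt
import itertools
import math
import statistics
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .contingency import ContingencyTable
from .disproportionality import SignalCriteria, screen_signals
from .meddra import PtSocMapping
from .preprocessing import DEFAULT_CUTOFF, deduplicate, filter_by_date
from .types import (
    CaseReport,
    DrugMention,
    DrugRole,
    ReactionRecord,
    ReportDatabase,
    ReporterType,
    Seriousness,
    SeriousOutcome,
    Sex,
    AgeGroup,
)


TARGET_INGREDIENT = "esketamine"


@dataclass(frozen=True)
class DrugSpec:
    ingredient: str
    marginal: float  # P(drug mentioned on a report), before >=1-drug redraw
    ps_prob: float   # P(role = primary suspect | mentioned)


@dataclass(frozen=True)
class EventSpec:
    pt: str
    soc: str
    marginal: float  # baseline P(PT on a report), before >=1-reaction redraw


@dataclass(frozen=True)
class ImplantedSignal:
    ingredient: str
    pt: str
    rate_ratio: float


@dataclass(frozen=True)
class Demographics:
    """Categorical distributions for the demographic fields."""

    sex: dict = field(default_factory=lambda: {
        Sex.FEMALE: 0.53, Sex.MALE: 0.30, Sex.UNKNOWN: 0.17})
    age: dict = field(default_factory=lambda: {
        AgeGroup.UNDER_18: 0.01, AgeGroup.ADULT: 0.49,
        AgeGroup.ELDERLY: 0.08, AgeGroup.UNKNOWN: 0.42})
    country: dict = field(default_factory=lambda: {
        "US": 0.80, "FR": 0.04, "BR": 0.02, "DE": 0.02, "ES": 0.02,
        "other": 0.10})
    reporter: dict = field(default_factory=lambda: {
        ReporterType.HEALTHCARE_PROFESSIONAL: 0.79,
        ReporterType.CONSUMER: 0.21})
    year: dict = field(default_factory=lambda: {
        2019: 0.10, 2020: 0.16, 2021: 0.19, 2022: 0.22, 2023: 0.33})
    seriousness: dict = field(default_factory=lambda: {
        Seriousness.SERIOUS: 0.60, Seriousness.NON_SERIOUS: 0.40})
    outcome: dict = field(default_factory=lambda: {
        SeriousOutcome.HOSPITALIZATION: 0.50,
        SeriousOutcome.OTHER_SERIOUS: 0.30,
        SeriousOutcome.LIFE_THREATENING: 0.08,
        SeriousOutcome.DISABILITY: 0.06,
        SeriousOutcome.DEATH: 0.05,
        SeriousOutcome.CONGENITAL_ANOMALY: 0.01})


def _check_dist(name: str, dist: dict) -> None:
    total = sum(dist.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"{name} distribution sums to {total}, expected 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} distribution has negative probability")


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic report database."""

    n_reports: int
    drug_catalog: Sequence[DrugSpec]
    event_catalog: Sequence[EventSpec]
    implanted_signals: Sequence[ImplantedSignal] = ()
    duplicate_rate: float = 0.0
    demographics: Demographics = field(default_factory=Demographics)
    pre_cutoff_fraction: float = 0.0
    seed: int = 0
    strict_caps: bool = False  # error (vs warn) when rate_ratio * marginal > 1

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        if not 0 <= self.pre_cutoff_fraction < 1:
            raise ValueError("pre_cutoff_fraction must be in [0, 1)")
        drugs = {d.ingredient for d in self.drug_catalog}
        events = {e.pt for e in self.event_catalog}
        if not self.drug_catalog or not self.event_catalog:
            raise ValueError("drug and event catalogs must be non-empty")
        for d in self.drug_catalog:
            if not 0 < d.marginal < 1 or not 0 < d.ps_prob <= 1:
                raise ValueError(f"invalid probabilities for drug {d.ingredient}")
        for e in self.event_catalog:
            if not 0 < e.marginal < 1:
                raise ValueError(f"invalid marginal for PT {e.pt}")
        marg = {e.pt: e.marginal for e in self.event_catalog}
        for s in self.implanted_signals:
            if s.rate_ratio <= 0:
                raise ValueError(f"rate ratio must be > 0 for {s.ingredient}/{s.pt}")
            if s.ingredient not in drugs or s.pt not in events:
                raise ValueError(f"implanted pair {s.ingredient}/{s.pt} not in catalogs")
            if s.rate_ratio * marg[s.pt] > 1:
                msg = (f"implanted pair {s.ingredient}/{s.pt}: rate_ratio x "
                       f"marginal = {s.rate_ratio * marg[s.pt]:.3g} > 1; "
                       "inclusion probability capped at 1")
                if self.strict_caps:
                    raise ValueError(msg)
                warnings.warn(msg)
        for name in ("sex", "age", "country", "reporter", "year",
                     "seriousness", "outcome"):
            _check_dist(name, getattr(self.demographics, name))


@dataclass
class GroundTruthLedger:
    """Bookkeeping of everything the generator injected."""

    implanted: list[tuple[str, str, float, float]]  # (drug, pt, rr, effective rr)
    duplicate_case_ids: list[str]
    pre_cutoff_case_ids: list[str]
    primary_suspect_case_ids: dict[str, list[str]]  # ingredient -> case ids
    expected_cells: dict[tuple[str, str], ContingencyTable]

    def effective_rate_ratio(self, ingredient: str, pt: str) -> float:
        for ing, p, _, eff in self.implanted:
            if ing == ingredient and p == pt:
                return eff
        raise KeyError((ingredient, pt))


def _sample_categorical(rng: np.random.Generator, dist: dict, size: int):
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def _redraw_nonempty(
    rng: np.random.Generator, probs: np.ndarray
) -> np.ndarray:
    """Bernoulli matrix with every row redrawn until non-empty.

    Equivalent to sampling each row's independent Bernoullis conditioned on
    at least one success; the redraw is part of the seeded stream.
    """
    out = rng.random(probs.shape) < probs
    empty = ~out.any(axis=1)
    while empty.any():
        rows = np.flatnonzero(empty)
        out[rows] = rng.random((rows.size, probs.shape[1])) < probs[rows]
        empty[rows] = ~out[rows].any(axis=1)
    return out


_PRE_CUTOFF_DAYS = (DEFAULT_CUTOFF - dt.date(2019, 1, 1)).days  # 63


def generate_database(
    config: GeneratorConfig,
    mapping: Optional[PtSocMapping] = None,
) -> tuple[ReportDatabase, GroundTruthLedger]:
    """Generate a synthetic database plus its ground-truth ledger.

    Fully deterministic given ``config`` (same config => equal databases).
    Duplicate clones get case ids starting with ``"Z"`` (originals start
    with ``"C"``) so the dedup tie-break keeps the original.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = list(config.drug_catalog)
    events = list(config.event_catalog)
    G, J = len(drugs), len(events)

    sex = _sample_categorical(rng, config.demographics.sex, n)
    age = _sample_categorical(rng, config.demographics.age, n)
    country = _sample_categorical(rng, config.demographics.country, n)
    reporter = _sample_categorical(rng, config.demographics.reporter, n)
    year = _sample_categorical(rng, config.demographics.year, n)
    serious = _sample_categorical(rng, config.demographics.seriousness, n)
    outcome = _sample_categorical(rng, config.demographics.outcome, n)

    # event dates: a fixed-size sample of reports predates the cutoff
    n_pre = round(config.pre_cutoff_fraction * n)
    pre_idx = set(rng.choice(n, size=n_pre, replace=False).tolist()) if n_pre else set()
    day_pre = rng.integers(0, _PRE_CUTOFF_DAYS, size=n)
    day_2019 = rng.integers(_PRE_CUTOFF_DAYS, 365, size=n)
    day_any = rng.integers(0, 365, size=n)
    event_dates: list[dt.date] = []
    for i in range(n):
        if i in pre_idx:
            year[i] = 2019
            event_dates.append(dt.date(2019, 1, 1) + dt.timedelta(int(day_pre[i])))
        elif year[i] == 2019:
            event_dates.append(dt.date(2019, 1, 1) + dt.timedelta(int(day_2019[i])))
        else:
            event_dates.append(dt.date(int(year[i]), 1, 1) + dt.timedelta(int(day_any[i])))

    drug_marg = np.array([d.marginal for d in drugs])
    present = _redraw_nonempty(rng, np.broadcast_to(drug_marg, (n, G)))
    ps_prob = np.array([d.ps_prob for d in drugs])
    is_ps = present & (rng.random((n, G)) < ps_prob)

    base = np.array([e.marginal for e in events])
    mult = np.ones((n, J))
    drug_index = {d.ingredient: g for g, d in enumerate(drugs)}
    event_index = {e.pt: j for j, e in enumerate(events)}
    implanted_ledger = []
    for s in config.implanted_signals:
        g, j = drug_index[s.ingredient], event_index[s.pt]
        mult[is_ps[:, g], j] *= s.rate_ratio
        eff = min(1.0, base[j] * s.rate_ratio) / base[j]
        implanted_ledger.append((s.ingredient, s.pt, s.rate_ratio, eff))
    probs = np.minimum(base * mult, 1.0)
    has_event = _redraw_nonempty(rng, probs)

    # originals must be pairwise distinct on the dedup tuple, otherwise the
    # cleaning stage would collapse genuinely independent reports and the
    # injected-duplicate bookkeeping would no longer be exact.  Resolve the
    # (rare) accidental collisions by resampling the event date; the redraw
    # is part of the seeded stream.
    def _tuple_key(i: int):
        pts = tuple(sorted(events[j].pt for j in np.flatnonzero(has_event[i])))
        return (sex[i], age[i], country[i], event_dates[i], pts, serious[i])

    seen_keys: dict[tuple, int] = {}
    for i in range(n):
        attempts = 0
        while _tuple_key(i) in seen_keys:
            if i in pre_idx:
                off = int(rng.integers(0, _PRE_CUTOFF_DAYS))
                event_dates[i] = dt.date(2019, 1, 1) + dt.timedelta(off)
            elif year[i] == 2019:
                off = int(rng.integers(_PRE_CUTOFF_DAYS, 365))
                event_dates[i] = dt.date(2019, 1, 1) + dt.timedelta(off)
            else:
                off = int(rng.integers(0, 365))
                event_dates[i] = dt.date(int(year[i]), 1, 1) + dt.timedelta(off)
            attempts += 1
            if attempts > 1000:
                raise RuntimeError(
                    "could not make report tuples unique; catalogs too coarse"
                )
        seen_keys[_tuple_key(i)] = i

    socs = {e.pt: e.soc for e in events}
    reports: list[CaseReport] = []
    ps_ids: dict[str, list[str]] = {d.ingredient: [] for d in drugs}
    for i in range(n):
        case_id = f"C{i:07d}"
        mentions = []
        for g in np.flatnonzero(present[i]):
            role = DrugRole.PRIMARY_SUSPECT if is_ps[i, g] else DrugRole.CONCOMITANT
            mentions.append(DrugMention(drugs[g].ingredient, role))
            if is_ps[i, g]:
                ps_ids[drugs[g].ingredient].append(case_id)
        reactions = [
            ReactionRecord(events[j].pt, socs[events[j].pt])
            for j in np.flatnonzero(has_event[i])
        ]
        is_serious = serious[i] == Seriousness.SERIOUS
        reports.append(
            CaseReport(
                case_id=case_id,
                version=0,
                sex=sex[i],
                age_group=age[i],
                country=country[i],
                reporter_type=reporter[i],
                received_year=int(year[i]),
                event_date=event_dates[i],
                seriousness=serious[i],
                serious_outcomes=frozenset({outcome[i]}) if is_serious else frozenset(),
                drugs=mentions,
                reactions=reactions,
            )
        )

    # duplicate contamination: clone post-cutoff reports under new case ids
    n_dup = round(config.duplicate_rate * n)
    candidates = np.array([i for i in range(n) if i not in pre_idx])
    if n_dup > candidates.size:
        raise ValueError("duplicate_rate too high for the post-cutoff pool")
    dup_ids = []
    if n_dup:
        chosen = rng.choice(candidates, size=n_dup, replace=False)
        for k, i in enumerate(sorted(chosen.tolist())):
            src = reports[i]
            clone_id = f"Z{k:07d}"
            clone = replace(
                src,
                case_id=clone_id,
                drugs=list(src.drugs),
                reactions=list(src.reactions),
            )
            reports.append(clone)
            dup_ids.append(clone_id)
            for d in src.drugs:
                if d.role == DrugRole.PRIMARY_SUSPECT:
                    ps_ids[d.active_ingredient].append(clone_id)

    expected = {
        (s.ingredient, s.pt): expected_contingency(config, s.ingredient, s.pt)
        for s in config.implanted_signals
    }
    ledger = GroundTruthLedger(
        implanted=implanted_ledger,
        duplicate_case_ids=dup_ids,
        pre_cutoff_case_ids=sorted(f"C{i:07d}" for i in pre_idx),
        primary_suspect_case_ids=ps_ids,
        expected_cells=expected,
    )
    db = ReportDatabase(
        reports=reports,
        provenance=f"synthetic:seed={config.seed},n={n}",
    )
    return db, ledger


def expected_contingency(
    config: GeneratorConfig, ingredient: str, pt: str
) -> ContingencyTable:
    """Closed-form expected 2x2 cells (event-record unit, pre-duplicates).

    Enumerates drug presence vectors (renormalized to exclude the empty
    set, matching the >=1-drug redraw) and, within each, the primary-
    suspect states of the drugs that can alter reaction probabilities; the
    reaction expectations condition on >=1 reaction per report, matching
    the generator's redraw.
    """
    drugs = list(config.drug_catalog)
    events = list(config.event_catalog)
    G = len(drugs)
    if G > 16:
        raise ValueError("closed form limited to <= 16 drugs")
    drug_index = {d.ingredient: g for g, d in enumerate(drugs)}
    event_index = {e.pt: j for j, e in enumerate(events)}
    if ingredient not in drug_index or pt not in event_index:
        raise KeyError(f"pair ({ingredient!r}, {pt!r}) not in catalogs")
    target_g = drug_index[ingredient]
    j_target = event_index[pt]

    base = np.array([e.marginal for e in events])
    m = np.array([d.marginal for d in drugs])
    q = np.array([d.ps_prob for d in drugs])
    signals = [
        (drug_index[s.ingredient], event_index[s.pt], s.rate_ratio)
        for s in config.implanted_signals
    ]
    relevant = sorted({g for g, _, _ in signals} | {target_g})

    p_any_drug = 1.0 - np.prod(1.0 - m)
    a = b = c = d_cell = 0.0
    for v in itertools.product((0, 1), repeat=G):
        if not any(v):
            continue
        w_v = np.prod(np.where(np.array(v) == 1, m, 1.0 - m)) / p_any_drug
        rel_present = [g for g in relevant if v[g]]
        for ps_state in itertools.product((0, 1), repeat=len(rel_present)):
            ps = dict(zip(rel_present, ps_state))
            w_s = w_v
            for g in rel_present:
                w_s *= q[g] if ps[g] else 1.0 - q[g]
            mult = np.ones(len(events))
            for g, j, rr in signals:
                if ps.get(g, 0):
                    mult[j] *= rr
            p = np.minimum(base * mult, 1.0)
            z = 1.0 - np.prod(1.0 - p)
            e_rec = p / z  # expected records per report, given >=1 reaction
            ej = e_rec[j_target]
            e_other = e_rec.sum() - ej
            if ps.get(target_g, 0):
                a += w_s * ej
                b += w_s * e_other
            else:
                c += w_s * ej
                d_cell += w_s * e_other
    n = config.n_reports
    return ContingencyTable(a=a * n, b=b * n, c=c * n, d=d_cell * n)


@dataclass
class PairRecovery:
    """Estimator behaviour for one implanted (or probed) pair."""

    true_odds_ratio: float
    median_ror: float
    ci_coverage: float
    power: float


@dataclass
class RecoverySummary:
    n_replicates: int
    per_pair: dict[tuple[str, str], PairRecovery]
    null_false_flag_rate: float


def recovery_experiment(
    config: GeneratorConfig,
    n_replicates: int = 20,
    criteria: SignalCriteria = SignalCriteria(),
    mapping: Optional[PtSocMapping] = None,
) -> RecoverySummary:
    """Replicate the generate -> clean -> screen pipeline and summarize
    estimator bias, CI coverage and detection power per implanted pair,
    plus the false-flag rate over null terms.

    The generative odds ratio per pair comes from the closed-form expected
    cells; coverage is the fraction of replicates whose ROR CI contains it.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    implanted = {(s.ingredient, s.pt) for s in config.implanted_signals}
    target_drugs = sorted({s.ingredient for s in config.implanted_signals})
    rors: dict[tuple[str, str], list[float]] = {p: [] for p in implanted}
    covered: dict[tuple[str, str], int] = {p: 0 for p in implanted}
    flagged: dict[tuple[str, str], int] = {p: 0 for p in implanted}
    true_or = {
        p: _odds_ratio(expected_contingency(config, *p)) for p in implanted
    }
    null_flags = 0
    null_terms = 0
    for rep in range(n_replicates):
        cfg = replace(config, seed=config.seed + rep)
        db, _ = generate_database(cfg, mapping)
        db = filter_by_date(db)
        db, _ = deduplicate(db)
        for ingredient in target_drugs:
            for s in screen_signals(db, ingredient, criteria=criteria,
                                    mapping=mapping):
                pair = (ingredient, s.term)
                if pair in implanted:
                    if s.ror.defined:
                        rors[pair].append(s.ror.point)
                        if s.ror.ci_low <= true_or[pair] <= s.ror.ci_high:
                            covered[pair] += 1
                    if s.is_signal:
                        flagged[pair] += 1
                else:
                    null_terms += 1
                    if s.is_signal:
                        null_flags += 1
    per_pair = {
        p: PairRecovery(
            true_odds_ratio=true_or[p],
            median_ror=statistics.median(rors[p]) if rors[p] else float("nan"),
            ci_coverage=covered[p] / n_replicates,
            power=flagged[p] / n_replicates,
        )
        for p in implanted
    }
    return RecoverySummary(
        n_replicates=n_replicates,
        per_pair=per_pair,
        null_false_flag_rate=null_flags / null_terms if null_terms else 0.0,
    )


def _odds_ratio(t: ContingencyTable) -> float:
    return (t.a * t.d) / (t.b * t.c)


def database_from_marginals(
    sex_counts: dict[Sex, int],
    age_counts: dict[AgeGroup, int],
    reporter_counts: dict[ReporterType, int],
    country_counts: dict[str, int],
    year_counts: dict[int, int],
    serious_counts: dict[Seriousness, int],
    soc_record_counts: Optional[dict[str, int]] = None,
    pt_for_soc: Optional[dict[str, str]] = None,
    ingredient: str = TARGET_INGREDIENT,
) -> ReportDatabase:
    """Deterministic target-drug database with exact marginal counts.

    Builds one case per unit of the (equal-total) demographic blocks and
    distributes ``soc_record_counts`` reaction records round-robin over the
    cases, so that :func:`~pvsignal.reporting.demographics_summary` and
    :func:`~pvsignal.reporting.soc_summary` reproduce exactly the given
    counts.  ``country_counts`` may sum to less than the case total; the
    remainder is labelled ``"other"``.  Attributes are assigned
    independently block-by-block (their joint distribution is arbitrary,
    which is irrelevant for marginal summaries).
    """
    n = sum(sex_counts.values())
    for name, block in (("age", age_counts), ("reporter", reporter_counts),
                        ("year", year_counts), ("seriousness", serious_counts)):
        if sum(block.values()) != n:
            raise ValueError(f"{name} counts sum to {sum(block.values())}, "
                             f"expected {n}")
    if sum(country_counts.values()) > n:
        raise ValueError("country counts exceed the case total")
    country_full = dict(country_counts)
    rem = n - sum(country_counts.values())
    if rem:
        country_full["other"] = country_full.get("other", 0) + rem

    def expand(block: dict) -> list:
        out = []
        for key, cnt in block.items():
            out.extend([key] * cnt)
        return out

    sexes = expand(sex_counts)
    ages = expand(age_counts)
    reporters = expand(reporter_counts)
    countries = expand(country_full)
    years = expand(year_counts)
    serious = expand(serious_counts)

    # reaction records: one PT per SOC, distributed round-robin over cases
    if soc_record_counts is None:
        soc_record_counts = {"Unmapped": n}
    if pt_for_soc is None:
        # reverse lookup: first bundled PT of each SOC
        import csv as _csv
        from importlib import resources as _res

        pt_for_soc = {}
        with _res.as_file(
            _res.files("pvsignal.data").joinpath("pt_soc.csv")
        ) as path:
            with open(path, newline="", encoding="utf-8") as fh:
                for row in _csv.DictReader(fh):
                    pt_for_soc.setdefault(row["soc"], row["pt"])
    total_records = sum(soc_record_counts.values())
    if total_records < n:
        raise ValueError("need at least one reaction record per case")
    flat_pts = []
    for soc, cnt in soc_record_counts.items():
        pt = pt_for_soc.get(soc)
        if pt is None:
            raise ValueError(f"no PT available for SOC {soc!r}")
        flat_pts.extend([(pt, soc)] * cnt)

    per_case: list[list[ReactionRecord]] = [[] for _ in range(n)]
    for pos, (pt, soc) in enumerate(flat_pts):
        per_case[pos % n].append(ReactionRecord(pt, soc))
    for recs in per_case:
        pts = [r.pt for r in recs]
        if len(pts) != len(set(pts)):
            raise ValueError(
                "a SOC block larger than the case total would place the same "
                "PT twice in one case; supply more PTs per SOC"
            )

    reports = []
    for i in range(n):
        is_serious = serious[i] == Seriousness.SERIOUS
        reports.append(
            CaseReport(
                case_id=f"M{i:07d}",
                sex=sexes[i],
                age_group=ages[i],
                country=countries[i],
                reporter_type=reporters[i],
                received_year=int(years[i]),
                seriousness=serious[i],
                serious_outcomes=(
                    frozenset({SeriousOutcome.OTHER_SERIOUS})
                    if is_serious else frozenset()
                ),
                drugs=[DrugMention(ingredient, DrugRole.PRIMARY_SUSPECT)],
                reactions=per_case[i],
            )
        )
    return ReportDatabase(reports=reports, provenance="synthetic:marginals")


# ---------------------------------------------------------------------------
# Default study conditions

_DEFAULT_DRUGS = (
    DrugSpec("esketamine", 0.06, 0.80),
    DrugSpec("quetiapine", 0.20, 0.40),
    DrugSpec("sertraline", 0.25, 0.40),
    DrugSpec("duloxetine", 0.20, 0.40),
    DrugSpec("olanzapine", 0.15, 0.40),
    DrugSpec("alprazolam", 0.15, 0.30),
    DrugSpec("gabapentin", 0.12, 0.30),
    DrugSpec("lithium", 0.10, 0.40),
)

_DEFAULT_EVENTS = (
    EventSpec("Dissociation", "Psychiatric disorders", 0.008),
    EventSpec("Sedation", "Nervous system disorders", 0.008),
    EventSpec("Dizziness", "Nervous system disorders", 0.05),
    EventSpec("Nausea", "Gastrointestinal disorders", 0.06),
    EventSpec("Headache", "Nervous system disorders", 0.05),
    EventSpec("Vomiting", "Gastrointestinal disorders", 0.03),
    EventSpec("Anxiety", "Psychiatric disorders", 0.04),
    EventSpec("Insomnia", "Psychiatric disorders", 0.04),
    EventSpec("Somnolence", "Nervous system disorders", 0.03),
    EventSpec("Fatigue", "General disorders and administration site conditions", 0.05),
    EventSpec("Drug ineffective", "General disorders and administration site conditions", 0.08),
    EventSpec("Suicidal ideation", "Psychiatric disorders", 0.01),
    EventSpec("Euphoric mood", "Psychiatric disorders", 0.005),
    EventSpec("Hypertension", "Vascular disorders", 0.03),
    EventSpec("Vision blurred", "Eye disorders", 0.02),
    EventSpec("Tremor", "Nervous system disorders", 0.02),
    EventSpec("Rash", "Skin and subcutaneous tissue disorders", 0.03),
    EventSpec("Diarrhoea", "Gastrointestinal disorders", 0.03),
    EventSpec("Weight increased", "Investigations", 0.02),
    EventSpec("Palpitations", "Cardiac disorders", 0.02),
)

_DEFAULT_SIGNALS = (
    ImplantedSignal("esketamine", "Dissociation", 20.0),
    ImplantedSignal("esketamine", "Sedation", 20.0),
)


def default_config(
    n_reports: int = 10_000,
    seed: int = 0,
    implanted_signals: Sequence[ImplantedSignal] = _DEFAULT_SIGNALS,
    duplicate_rate: float = 0.05,
    pre_cutoff_fraction: float = 0.02,
) -> GeneratorConfig:
    """A realistic small FAERS-like configuration.

    One target antidepressant among seven common psychiatric co-medications,
    twenty PTs across eleven SOCs, demographics mirroring a typical
    spontaneous-report mix, 5% duplicate contamination and 2% of reports
    predating the marketing cutoff.  Implanted pairs default to the target
    drug's two hallmark reactions at a reporting rate ratio of 20.
    """
    return GeneratorConfig(
        n_reports=n_reports,
        drug_catalog=_DEFAULT_DRUGS,
        event_catalog=_DEFAULT_EVENTS,
        implanted_signals=tuple(implanted_signals),
        duplicate_rate=duplicate_rate,
        pre_cutoff_fraction=pre_cutoff_fraction,
        seed=seed,
    )
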