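"""Generator determinism, ground-truth bookkeeping and the closed-form oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import poisson

from pvsignal import (
    DrugSpec,
    EventSpec,
    GeneratorConfig,
    ImplantedSignal,
    build_contingency,
    default_config,
    expected_contingency,
    generate_database,
    recovery_experiment,
)
from pvsignal.synthetic import TARGET_INGREDIENT


def _null_config(n=10_000, seed=0):
    """Target drug marginal 0.02, probe PT marginal 0.01, no signals."""
    return GeneratorConfig(
        n_reports=n,
        drug_catalog=(
            DrugSpec(TARGET_INGREDIENT, 0.02, 1.0),
            DrugSpec("sertraline", 0.40, 0.5),
            DrugSpec("quetiapine", 0.40, 0.5),
        ),
        event_catalog=(
            EventSpec("Dissociation", "Psychiatric disorders", 0.01),
            EventSpec("Nausea", "Gastrointestinal disorders", 0.30),
            EventSpec("Headache", "Nervous system disorders", 0.30),
            EventSpec("Dizziness", "Nervous system disorders", 0.20),
        ),
        seed=seed,
    )


class TestDeterminism:
    def test_same_seed_identical_databases(self):
        cfg = default_config(n_reports=400, seed=11)
        db1, led1 = generate_database(cfg)
        db2, led2 = generate_database(cfg)
        assert db1.reports == db2.reports
        assert led1.duplicate_case_ids == led2.duplicate_case_ids
        assert led1.pre_cutoff_case_ids == led2.pre_cutoff_case_ids

    def test_different_seeds_differ(self):
        db1, _ = generate_database(default_config(n_reports=400, seed=1))
        db2, _ = generate_database(default_config(n_reports=400, seed=2))
        assert db1.reports != db2.reports


class TestInjection:
    def test_duplicate_count_is_exact(self):
        cfg = default_config(n_reports=1000, seed=4, duplicate_rate=0.05)
        db, ledger = generate_database(cfg)
        assert len(ledger.duplicate_case_ids) == 50
        assert len(db) == 1050

    def test_pre_cutoff_count_is_exact(self):
        cfg = default_config(n_reports=1000, seed=4, pre_cutoff_fraction=0.08)
        _, ledger = generate_database(cfg)
        assert len(ledger.pre_cutoff_case_ids) == 80

    def test_every_report_has_drug_and_reaction(self, generated):
        _, db, _ = generated
        for r in db.reports:
            assert r.drugs and r.reactions

    def test_cap_warning_and_strict_error(self):
        cfg = default_config(
            n_reports=100, seed=0,
            implanted_signals=(ImplantedSignal(TARGET_INGREDIENT,
                                               "Dizziness", 30.0),),
        )
        with pytest.warns(UserWarning, match="capped"):
            generate_database(cfg)
        cfg.strict_caps = True
        with pytest.raises(ValueError, match="capped"):
            cfg.validate()


class TestExpectedContingency:
    def test_null_pair_expected_ror_is_one(self):
        cfg = _null_config()
        t = expected_contingency(cfg, TARGET_INGREDIENT, "Dissociation")
        assert (t.a * t.d) / (t.b * t.c) == pytest.approx(1.0, abs=1e-12)

    def test_implanted_pair_expected_ror_near_rate_ratio(self):
        cfg = default_config(
            n_reports=2500, seed=0,
            implanted_signals=(ImplantedSignal(TARGET_INGREDIENT,
                                               "Dissociation", 20.0),),
        )
        t = expected_contingency(cfg, TARGET_INGREDIENT, "Dissociation")
        ror = (t.a * t.d) / (t.b * t.c)
        assert 19 <= ror <= 21

    def test_partition_accounting_identity(self):
        cfg = _null_config(n=2000)
        tables = [expected_contingency(cfg, TARGET_INGREDIENT, e.pt)
                  for e in cfg.event_catalog]
        n_records = tables[0].n_total
        for t in tables:
            assert t.n_total == pytest.approx(n_records, abs=1e-9)
        assert sum(t.a + t.c for t in tables) == pytest.approx(n_records,
                                                               abs=1e-9)

    def test_unknown_pair_rejected(self):
        with pytest.raises(KeyError):
            expected_contingency(_null_config(), "warfarin", "Dissociation")

    def test_observed_a_within_poisson_bounds_of_closed_form(self):
        cfg = _null_config()
        lam = expected_contingency(cfg, TARGET_INGREDIENT, "Dissociation").a
        lo, hi = poisson.ppf(0.005, lam), poisson.ppf(0.995, lam)
        misses = 0
        for seed in range(20):
            db, _ = generate_database(_null_config(seed=seed))
            t = build_contingency(db, TARGET_INGREDIENT, "Dissociation")
            if not lo <= t.a <= hi:
                misses += 1
        assert misses <= 1  # 20 draws at the 99% level


@pytest.fixture(scope="module")
def summary():
    cfg = default_config(
        n_reports=2500, seed=100,
        implanted_signals=(
            ImplantedSignal(TARGET_INGREDIENT, "Dissociation", 20.0),
            ImplantedSignal(TARGET_INGREDIENT, "Drug ineffective", 1.0),
        ),
    )
    return recovery_experiment(cfg, n_replicates=20)


class TestRecoveryExperiment:
    def test_large_effect_power_is_one(self, summary):
        pair = (TARGET_INGREDIENT, "Dissociation")
        assert summary.per_pair[pair].power == 1.0

    def test_unit_rate_ratio_pair_estimates_near_one(self, summary):
        pair = (TARGET_INGREDIENT, "Drug ineffective")
        assert 0.8 <= summary.per_pair[pair].median_ror <= 1.25

    def test_null_false_flag_rate_below_5pct(self, summary):
        assert summary.null_false_flag_rate < 0.05

    def test_ci_coverage_reasonable(self, summary):
        pair = (TARGET_INGREDIENT, "Dissociation")
        assert summary.per_pair[pair].ci_coverage >= 0.8

    def test_replicate_floor(self):
        with pytest.raises(ValueError):
            recovery_experiment(default_config(n_reports=100), n_replicates=1)
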