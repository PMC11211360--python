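"""ROR / PRR / EBGM / chi-square estimators and threshold screening.

Frozen expected values were computed independently of the package: the
odds-ratio confidence bounds with a 40-digit evaluation of the closed
formulas, and chi-square against scipy's contingency-table test.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency, norm

from pvsignal import (
    ContingencyTable,
    ReportDatabase,
    SignalCriteria,
    compute_chi2,
    compute_prr,
    compute_ror,
    compute_rr_ebgm,
    compute_statistics,
    evaluate_signal,
    screen_signals,
)
from conftest import TARGET

T_10 = ContingencyTable(10, 90, 100, 9900)
T_3 = ContingencyTable(3, 97, 100, 9900)
T_INDEP = ContingencyTable(5, 50, 50, 500)  # proportional rows: all stats 1


class TestWorkedExamples:
    """Hand-calculator oracles, agreement to 1e-9."""

    @pytest.mark.parametrize(
        "fn, table, point, lo, hi",
        [
            (compute_ror, T_10, 11.0, 5.5595149288946258, 21.764488727446929),
            (compute_prr, T_10, 10.0, 5.3821539275173551, 18.579921969293685),
            (compute_rr_ebgm, T_10, 9.1818181818181818, 4.6405868414740265,
             18.167052574149916),
            (compute_ror, T_3, 3.0618556701030928, 0.95435906388739692,
             9.8233049795276988),
            (compute_prr, T_3, 3.0, 0.96770839179850989, 9.3003223659901081),
            (compute_rr_ebgm, T_3, 2.941747572815534, 0.91692220740461191,
             9.4379639976888168),
        ],
    )
    def test_point_and_ci(self, fn, table, point, lo, hi):
        est = fn(table)
        assert est.point == pytest.approx(point, abs=1e-9)
        assert est.ci_low == pytest.approx(lo, abs=1e-9)
        assert est.ci_high == pytest.approx(hi, abs=1e-9)

    def test_independence_table_returns_exactly_one(self):
        assert compute_ror(T_INDEP).point == 1.0
        assert compute_prr(T_INDEP).point == 1.0
        assert compute_rr_ebgm(T_INDEP).point == 1.0

    def test_chi2_yates_worked_example(self):
        assert compute_chi2(T_10) == pytest.approx(66.326940804440804, abs=1e-9)

    def test_chi2_uncorrected_zero_at_independence(self):
        assert compute_chi2(T_INDEP, yates=False) == 0.0


class TestZeroCells:
    def test_zero_cell_undefined_by_default(self):
        t = ContingencyTable(0, 100, 50, 9850)
        assert not compute_ror(t).defined
        assert not compute_prr(t).defined
        assert not compute_rr_ebgm(t).defined

    def test_haldane_correction_defines_statistics(self):
        t = ContingencyTable(0, 100, 50, 9850)
        est = compute_ror(t, haldane=True)
        assert est.defined
        # 0.5 added to every cell
        assert est.point == pytest.approx(
            (0.5 * 9850.5) / (100.5 * 50.5), rel=1e-12
        )

    def test_zero_margin_chi2_is_nan(self):
        assert math.isnan(compute_chi2(ContingencyTable(0, 0, 5, 5)))


class TestAgainstScipy:
    def test_uncorrected_chi2_matches_reference(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            cells = rng.integers(1, 500, size=4)
            t = ContingencyTable(*cells)
            ref = chi2_contingency(cells.reshape(2, 2), correction=False)[0]
            assert compute_chi2(t, yates=False) == pytest.approx(ref, abs=1e-9)

    def test_yates_chi2_matches_reference(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 50:
            a, b, c, d = rng.integers(5, 500, size=4)
            # restrict to tables where the correction does not exceed the
            # cell deviation (this package floors at zero there; the
            # reference overshoots)
            if abs(a * d - b * c) <= (a + b + c + d) / 2:
                continue
            ref = chi2_contingency(
                np.array([[a, b], [c, d]]), correction=True
            )[0]
            assert compute_chi2(ContingencyTable(a, b, c, d)) == \
                pytest.approx(ref, abs=1e-9)
            checked += 1

    def test_ror_ci_matches_statsmodels_at_exact_quantile(self):
        from statsmodels.stats.contingency_tables import Table2x2

        z = float(norm.ppf(0.975))
        for cells in [(10, 90, 100, 9900), (7, 13, 29, 331), (40, 60, 55, 45)]:
            est = compute_ror(ContingencyTable(*cells), z=z)
            ref = Table2x2(np.array(cells).reshape(2, 2))
            lo, hi = ref.oddsratio_confint(0.05)
            assert est.point == pytest.approx(ref.oddsratio, abs=1e-9)
            assert est.ci_low == pytest.approx(lo, abs=1e-9)
            assert est.ci_high == pytest.approx(hi, abs=1e-9)


class TestOrderingProperties:
    def _random_tables(self, n, seed):
        rng = np.random.default_rng(seed)
        while n:
            a, b, c, d = rng.integers(1, 400, size=4)
            yield ContingencyTable(a, b, c, d)
            n -= 1

    def test_ror_exceeds_prr_exceeds_one_when_overreported(self):
        for t in self._random_tables(500, 21):
            if t.a * t.d <= t.b * t.c:
                continue
            ror = compute_ror(t).point
            prr = compute_prr(t).point
            rr = compute_rr_ebgm(t).point
            assert ror > prr > 1
            assert rr <= prr + 1e-12

    def test_monotone_in_a(self):
        # strict monotonicity of the relative reporting ratio needs the
        # background cell d to dominate (the usual regime: one drug's
        # reports are a sliver of the database); with a tiny d the N term
        # in a*N/((a+c)(a+b)) can locally decrease
        for b, c, d in [(90, 100, 9900), (60, 300, 20000), (200, 50, 4000)]:
            rors, prrs, rrs = [], [], []
            for a in range(1, 30):
                t = ContingencyTable(a, b, c, d)
                rors.append(compute_ror(t).point)
                prrs.append(compute_prr(t).point)
                rrs.append(compute_rr_ebgm(t).point)
            assert all(x < y for x, y in zip(rors, rors[1:]))
            assert all(x < y for x, y in zip(prrs, prrs[1:]))
            assert all(x < y for x, y in zip(rrs, rrs[1:]))


class TestEvaluateSignal:
    def test_min_count_floor_blocks_signal(self):
        # n = 2 with huge effect still fails the a >= 3 floor for ROR/PRR
        t = ContingencyTable(2, 8, 10, 99000)
        stats = evaluate_signal(compute_statistics("x", t))
        assert not stats.flag_ror and not stats.flag_prr
        assert not stats.is_signal

    def test_worked_example_is_signal(self):
        stats = evaluate_signal(compute_statistics("x", T_10))
        assert stats.flag_ror and stats.flag_prr and stats.flag_ebgm
        # EBGM05 of the unshrunk estimator: 4.64 > 2
        assert stats.ebgm05 == pytest.approx(4.6405868414740265, abs=1e-9)
        assert stats.is_signal

    def test_independence_table_all_flags_false(self):
        stats = evaluate_signal(compute_statistics("x", T_INDEP))
        assert not (stats.flag_ror or stats.flag_prr or stats.flag_ebgm)

    def test_any_combination(self):
        t = ContingencyTable(4, 8, 10, 99000)
        crit_all = SignalCriteria(combine="all", ebgm05_threshold=1e9)
        crit_any = SignalCriteria(combine="any", ebgm05_threshold=1e9)
        assert not evaluate_signal(compute_statistics("x", t), crit_all).is_signal
        assert evaluate_signal(compute_statistics("x", t), crit_any).is_signal

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            SignalCriteria(min_a=0)
        with pytest.raises(ValueError):
            SignalCriteria(combine="most")


class TestScreenSignals:
    def test_empty_target_gives_empty_list(self, toy_db):
        assert screen_signals(toy_db, "no-such-drug") == []

    def test_output_invariant_to_row_order(self, generated):
        import random

        _, db, _ = generated
        shuffled = list(db.reports)
        random.Random(3).shuffle(shuffled)
        res1 = screen_signals(db, TARGET)
        res2 = screen_signals(ReportDatabase(shuffled), TARGET)
        assert [(s.term, s.n, s.is_signal) for s in res1] == \
            [(s.term, s.n, s.is_signal) for s in res2]

    def test_implanted_pairs_flagged(self, generated):
        _, db, ledger = generated
        from pvsignal import clean

        cleaned, _ = clean(db)
        res = {s.term: s for s in screen_signals(cleaned, TARGET)}
        for ingredient, pt, _, _ in ledger.implanted:
            assert res[pt].is_signal, pt

    def test_unknown_mode_rejected(self, toy_db):
        with pytest.raises(ValueError):
            screen_signals(toy_db, TARGET, ebgm_mode="bayes")
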