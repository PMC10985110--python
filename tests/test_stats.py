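import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig.cohort import PairCounts
from faersig.stats import (
    BcpnnHyperparameters,
    ContingencyTable,
    SignalCriteria,
    analyze_all,
    analyze_table,
    build_contingency,
    compute_bcpnn,
    compute_chi2,
    compute_ebgm,
    compute_prr,
    compute_ror,
    evaluate_signal,
    ic_expect_large_n,
)

from _oracle import oracle_stats

SYM = ContingencyTable(5, 5, 5, 5)


class TestBuildContingency:
    def test_margin_subtraction(self):
        pc = PairCounts("pt", {"X": 10}, {"X": 30}, 30, 270)
        ct = build_contingency(pc, "X")
        assert (ct.a, ct.b, ct.c, ct.d) == (10, 20, 30, 240)
        assert ct.n == 300

    def test_event_absent_from_other_side(self):
        pc = PairCounts("pt", {"X": 2}, {}, 5, 7)
        ct = build_contingency(pc, "X")
        assert ct.c == 0 and ct.d == 7


class TestWorkedExample:
    """Frozen values for the table (10, 20, 30, 240), verified by hand."""

    def test_ror(self, worked_table):
        r = compute_ror(worked_table)
        assert r.value == pytest.approx(4.000, abs=5e-4)
        assert r.low == pytest.approx(1.712, abs=5e-4)
        assert r.high == pytest.approx(9.3465, abs=5e-4)
        assert not r.corrected

    def test_prr(self, worked_table):
        r = compute_prr(worked_table)
        assert r.value == pytest.approx(3.000, abs=5e-4)
        assert r.low == pytest.approx(1.633, abs=5e-4)
        assert r.high == pytest.approx(5.511, abs=5e-4)

    def test_chi2(self, worked_table):
        chi2, degenerate = compute_chi2(worked_table)
        assert chi2 == pytest.approx(11.538, abs=5e-4)
        assert not degenerate

    def test_chi2_yates(self, worked_table):
        # |ad-bc| - n/2 = 1650; 300 * 1650^2 / 84,240,000
        chi2, _ = compute_chi2(worked_table, yates=True)
        assert chi2 == pytest.approx(9.6955, abs=5e-4)

    def test_chi2_matches_scipy(self, worked_table):
        scipy_stats = pytest.importorskip("scipy.stats")
        table = [[10, 20], [30, 240]]
        for yates in (False, True):
            expected = scipy_stats.chi2_contingency(table, correction=yates)[0]
            assert compute_chi2(worked_table, yates=yates)[0] == pytest.approx(expected)

    def test_bcpnn(self, worked_table):
        r = compute_bcpnn(worked_table)
        assert r.ic_expect == pytest.approx(1.086, abs=5e-4)
        assert r.ic_var == pytest.approx(0.2869, abs=5e-5)
        assert r.ic025 == pytest.approx(0.015, abs=5e-4)

    def test_ebgm(self, worked_table):
        r = compute_ebgm(worked_table)
        assert r.value == pytest.approx(2.500, abs=5e-4)
        assert r.low == pytest.approx(1.070, abs=5e-4)
        assert r.high == pytest.approx(5.842, abs=5e-4)


class TestSymmetricTable:
    def test_all_point_estimates_at_one(self):
        assert compute_ror(SYM).value == pytest.approx(1.0)
        assert compute_prr(SYM).value == pytest.approx(1.0)
        assert compute_ebgm(SYM).value == pytest.approx(1.0)
        assert compute_chi2(SYM)[0] == 0.0
        assert compute_bcpnn(SYM).ic_raw == pytest.approx(0.0)


class TestZeroCellPolicy:
    def test_corrected_ror(self):
        r = compute_ror(ContingencyTable(0, 10, 10, 100))
        assert r.corrected
        assert r.value == pytest.approx(0.5 * 100.5 / (10.5 * 10.5), rel=1e-12)

    def test_chi2_zero_margin_degenerate(self):
        chi2, degenerate = compute_chi2(ContingencyTable(0, 0, 5, 5))
        assert chi2 == 0.0 and degenerate

    def test_bcpnn_degenerate_still_computes_posterior(self):
        r = compute_bcpnn(ContingencyTable(0, 0, 5, 5))
        assert r.degenerate
        assert math.isfinite(r.ic_expect)
        assert r.ic_var > 0


class TestSignalFlags:
    def _flags(self, ct, crit=SignalCriteria()):
        return analyze_table(ct, crit=crit).flags

    def test_small_count_blocks_ror_prr(self):
        # a=2 with CI lower bound below 1: no frequentist signal
        flags = self._flags(ContingencyTable(2, 98, 60, 9840))
        assert not flags.ror_signal and not flags.prr_signal

    def test_strong_signal_trips_all_four(self):
        # a=60 with a very elevated reporting rate
        flags = self._flags(ContingencyTable(60, 2940, 600, 996400))
        assert flags.ror_signal and flags.prr_signal
        assert flags.bcpnn_signal and flags.ebgm_signal and flags.all_four

    def test_empty_cell_flags_nothing(self):
        flags = self._flags(ContingencyTable(0, 100, 50, 9850))
        assert not any(flags)

    def test_min_a_threshold_boundary(self):
        strong = ContingencyTable(3, 97, 30, 99870)
        assert self._flags(strong).ror_signal
        assert not self._flags(strong, SignalCriteria(min_a=4)).ror_signal


class TestAnalyzeAll:
    PC = PairCounts("pt", {"X": 10, "Y": 2, "Z": 5}, {"X": 30, "Y": 40, "Z": 5}, 30, 270)

    def test_one_row_per_target_event_sorted_by_ebgm(self):
        results = analyze_all(self.PC)
        assert [r.event for r in results] == sorted(
            (r.event for r in results),
            key=lambda e: (-next(x.ebgm for x in results if x.event == e), e),
        )
        assert {r.event for r in results} == {"X", "Y", "Z"}

    def test_events_absent_from_target_margin_excluded(self):
        pc = PairCounts("pt", {"X": 1}, {"X": 5, "W": 7}, 10, 100)
        assert {r.event for r in analyze_all(pc)} == {"X"}

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            analyze_all(PairCounts("pt", {}, {"X": 1}, 0, 10))


class TestLargeNClosure:
    """E(IC) from printed (case count, observed/expected) pairs.

    With the default joint prior count of 1, the large-N posterior
    expectation depends only on a and the observed/expected ratio.
    """

    @pytest.mark.parametrize(
        "a, ebgm, printed_ic",
        [
            (60, 92.83, 5.21),
            (3, 165.63, 1.97),
            (5, 123.02, 2.53),
            (10, 108.83, 3.33),
            (68, 131.22, 5.51),
        ],
    )
    def test_reproduces_printed_ic(self, a, ebgm, printed_ic):
        assert round(ic_expect_large_n(a, ebgm), 2) == printed_ic

    def test_limit_of_full_posterior(self):
        # scale a fixed-ratio table up; E(IC) must approach the closed form
        a, lam = 10, 4
        closed = ic_expect_large_n(a, float(lam))
        errors = []
        for s in (10, 100, 1000):
            drug_margin = event_margin = 100 * s
            n = lam * drug_margin * event_margin // a
            ct = ContingencyTable(
                a,
                drug_margin - a,
                event_margin - a,
                n - drug_margin - event_margin + a,
            )
            assert ct.a * ct.n == lam * (ct.a + ct.b) * (ct.a + ct.c)
            errors.append(abs(compute_bcpnn(ct).ic_expect - closed))
        assert errors == sorted(errors, reverse=True)  # monotone approach
        assert errors[-1] < 1e-3


cells = st.integers(min_value=1, max_value=500)


class TestAlgebraicInvariants:
    @given(cells, cells, cells, cells)
    @settings(derandomize=True, max_examples=300)
    def test_ic_raw_is_log2_ebgm(self, a, b, c, d):
        ct = ContingencyTable(a, b, c, d)
        assert compute_bcpnn(ct).ic_raw == pytest.approx(
            math.log2(compute_ebgm(ct).value), abs=1e-12
        )

    @given(cells, cells, cells, cells)
    @settings(derandomize=True, max_examples=300)
    def test_ordering_law(self, a, b, c, d):
        ct = ContingencyTable(a, b, c, d)
        ror = compute_ror(ct).value
        prr = compute_prr(ct).value
        ebgm = compute_ebgm(ct).value
        sign = a * d - b * c
        for stat in (ror, prr, ebgm):
            assert math.copysign(1, stat - 1) == math.copysign(1, sign) or sign == 0
        if sign > 0:
            assert ror >= prr >= ebgm > 1
        if sign == 0:
            assert ror == pytest.approx(prr) == pytest.approx(ebgm) == pytest.approx(1.0)

    @given(cells, cells, cells, cells)
    @settings(derandomize=True, max_examples=300)
    def test_posterior_variance_positive(self, a, b, c, d):
        r = compute_bcpnn(ContingencyTable(a, b, c, d))
        assert r.ic_var > 0
        assert r.ic025 < r.ic_expect

    @given(
        st.integers(1, 100),
        st.integers(1, 500),
        st.integers(1, 500),
        st.integers(100_000, 1_000_000),
    )
    @settings(derandomize=True, max_examples=300)
    def test_shrinkage_toward_null(self, a, b, c, d):
        # the Bayesian expectation pulls an elevated raw IC toward zero; a
        # large-n property, exercised on reporting-database-shaped tables
        # where the "other drugs, other events" cell dominates
        ct = ContingencyTable(a, b, c, d)
        r = compute_bcpnn(ct)
        if a * d > b * c:
            assert r.ic_expect < r.ic_raw


class TestOracleEquivalence:
    def test_random_tables_match_literal_transcription(self):
        rng = np.random.default_rng(42)
        hp = BcpnnHyperparameters()
        keys = ("ror", "ror_low", "ror_high", "prr", "prr_low", "prr_high",
                "chi2", "ic_expect", "ic_var", "ic025", "ebgm", "ebgm_low", "ebgm_high")
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 501, size=4))
            ct = ContingencyTable(a, b, c, d)
            expected = oracle_stats(a, b, c, d)
            got = analyze_table(ct, hp=hp)
            for key in keys:
                assert math.isclose(
                    _field(got, key), expected[key], rel_tol=1e-10, abs_tol=1e-10
                ), (key, a, b, c, d)
            if math.isnan(expected["ic_raw"]):
                assert math.isnan(got.ic_raw)
            else:
                assert math.isclose(got.ic_raw, expected["ic_raw"], rel_tol=1e-10, abs_tol=1e-10) or (
                    math.isinf(expected["ic_raw"]) and got.ic_raw == expected["ic_raw"]
                )
            assert got.corrected == expected["corrected"]


def _field(result, key):
    mapping = {
        "ror_low": result.ror_ci[0], "ror_high": result.ror_ci[1],
        "prr_low": result.prr_ci[0], "prr_high": result.prr_ci[1],
        "ebgm_low": result.ebgm_ci[0], "ebgm_high": result.ebgm_ci[1],
    }
    return mapping.get(key, getattr(result, key, None))


class TestCICoverage:
    def test_ror_ci_covers_one_under_independence(self):
        """Woolf interval coverage under row/column independence, ~95%."""
        rng = np.random.default_rng(2024)
        n, p_drug, p_event = 2000, 0.3, 0.1
        reps = 10_000
        probs = [
            p_drug * p_event,
            p_drug * (1 - p_event),
            (1 - p_drug) * p_event,
            (1 - p_drug) * (1 - p_event),
        ]
        tables = rng.multinomial(n, probs, size=reps)
        covered = 0
        for a, b, c, d in tables:
            r = compute_ror(ContingencyTable(int(a), int(b), int(c), int(d)))
            covered += r.low <= 1.0 <= r.high
        assert covered / reps == pytest.approx(0.95, abs=0.02)
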