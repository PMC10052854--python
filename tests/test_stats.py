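import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from thermovitals.io_video import SessionRecord
from thermovitals.stats import (
    chisq_2x2,
    implied_counts,
    ols,
    paired_errors,
    paired_t,
    success_table,
    table2_chisq_tests,
    validate_all,
)


def rec(true_rr=None, irt_rr=None, true_hr=None, irt_hr=None, taxa="mammal", **kw):
    return SessionRecord(
        species=kw.pop("species", "synthetic"), taxa=taxa, immobilized=False,
        true_rr=true_rr, irt_rr=irt_rr, true_hr=true_hr, irt_hr=irt_hr, **kw,
    )


class TestPairedErrors:
    def test_hand_arithmetic_oracle(self):
        rs = [rec(10, 12), rec(20, 19)]
        out = paired_errors(rs, "RR")
        assert out.mae == pytest.approx(1.5)
        assert out.mape == pytest.approx(12.5)
        assert (out.err_min, out.err_max) == (1.0, 2.0)

    def test_identical_columns_give_zero(self):
        rs = [rec(10, 10), rec(20, 20)]
        out = paired_errors(rs, "RR")
        assert out.mae == 0.0 and out.mape == 0.0

    def test_incomplete_pairs_excluded(self):
        rs = [rec(10, 12), rec(20, 19), rec(true_rr=30), rec(irt_rr=5)]
        assert paired_errors(rs, "RR").n == 2

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            paired_errors([rec(true_rr=10)], "RR")


class TestPairedT:
    def test_closed_form_oracle(self):
        # d = {1,2,3}: t = mean/sd*sqrt(3) = 2*sqrt(3)
        rs = [rec(11, 10), rec(12, 10), rec(13, 10)]
        out = paired_t(rs, "RR")
        assert out.statistic == pytest.approx(2 * np.sqrt(3))
        assert out.df == 2

    def test_antisymmetric_differences_give_zero(self):
        rs = [rec(11, 10), rec(9, 10), rec(12, 10), rec(8, 10)]
        out = paired_t(rs, "RR")
        assert out.statistic == pytest.approx(0.0)
        assert out.p_value == pytest.approx(1.0)

    def test_matches_scipy_reference(self, records):
        """Independent route: scipy's paired t on the packaged RR pairs."""
        true = [r.true_rr for r in records if r.true_rr is not None and r.irt_rr is not None]
        irt = [r.irt_rr for r in records if r.true_rr is not None and r.irt_rr is not None]
        ref = sps.ttest_rel(true, irt)
        out = paired_t(records, "RR")
        assert out.statistic == pytest.approx(ref.statistic)
        assert out.p_value == pytest.approx(ref.pvalue)

    def test_sign_convention_true_minus_irt(self):
        rs = [rec(10, 12), rec(20, 21), rec(5, 7)]  # IRT over-reads -> negative t
        assert paired_t(rs, "RR").statistic < 0

    def test_zero_variance_rejected(self):
        rs = [rec(11, 10), rec(21, 20)]
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(rs, "RR")


class TestOLS:
    def test_exact_line(self):
        rs = [rec(x, 2 * x + 1) for x in (1.0, 2.0, 3.0, 4.0)]
        out = ols(rs, "RR")
        assert out.slope == pytest.approx(2.0)
        assert out.intercept == pytest.approx(1.0)
        assert out.r_squared == pytest.approx(1.0)

    def test_residuals_sum_to_zero_and_reorder_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(5, 50, size=12)
        y = 1.1 * x + rng.normal(0, 2, size=12)
        rs = [rec(a, b) for a, b in zip(x, y)]
        out = ols(rs, "RR")
        assert abs(out.residuals.sum()) < 1e-8
        shuffled = ols(rs[::-1], "RR")
        np.testing.assert_allclose(sorted(out.residuals), sorted(shuffled.residuals))

    def test_constant_x_rejected(self):
        rs = [rec(10, 11), rec(10, 12), rec(10, 13)]
        with pytest.raises(ValueError, match="singular"):
            ols(rs, "RR")


class TestChisq2x2:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((14, 7, 22, 1), 6.200),   # thick vs thin integument, RR
            ((13, 5, 10, 16), 4.860),  # immobilized vs voluntary, HR
            ((7, 7, 29, 1), 13.974),   # low vs high video quality, RR
            ((10, 10, 10, 10), 0.0),
        ],
    )
    def test_published_tables(self, table, expected):
        out = chisq_2x2(*table)
        assert out.statistic == pytest.approx(expected, abs=5e-3)

    def test_homogeneous_table_p_one(self):
        out = chisq_2x2(10, 10, 10, 10)
        assert out.p_value == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_matches_generic_pearson_formula(self, table):
        """Oracle: scipy's r x c Pearson chi-squared (expected-count
        summation, no continuity correction) specialized to 2x2."""
        a, b, c, d = table
        ref, p, dof, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
        out = chisq_2x2(a, b, c, d)
        assert out.statistic == pytest.approx(ref)
        assert out.p_value == pytest.approx(p)
        assert out.df == dof

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_2x2(0, 0, 5, 5)


class TestSuccessTable:
    def test_taxa_grouping_matches_published_percentages(self, records):
        df = success_table(records, "taxa").set_index("group")
        assert df.loc["mammal", "n"] == 33
        assert df.loc["mammal", "rr_pct"] == pytest.approx(84.8)
        assert df.loc["bird", "rr_pct"] == pytest.approx(50.0)
        assert df.loc["reptile", "rr_pct"] == pytest.approx(100.0)
        assert df.loc["reptile", "hr_pct"] == pytest.approx(0.0)

    def test_quality_grouping_split(self, records):
        df = success_table(records, "quality").set_index("group")
        assert df.loc["low", "n"] == 14 and df.loc["high", "n"] == 30
        assert df.loc["low", "rr_pct"] == pytest.approx(50.0)
        assert df.loc["high", "rr_pct"] == pytest.approx(96.7)

    def test_single_group_all_success(self):
        rs = [rec(10, 11, species=f"s{i}") for i in range(3)]
        df = success_table(rs, "taxa")
        assert df.loc[0, "rr_pct"] == 100.0

    def test_only_validation_sessions_counted(self, records):
        df = success_table(records, "sedation")
        assert df["n"].sum() == 44


class TestTable2Implied:
    def test_implied_count_reconstruction(self):
        assert implied_counts(21, 66.7) == (14, 7)
        assert implied_counts(23, 95.7) == (22, 1)
        assert implied_counts(18, 72.2) == (13, 5)

    def test_published_chi_squared_battery(self):
        tests = table2_chisq_tests()
        assert tests["rr_by_integument"].statistic == pytest.approx(6.200, abs=5e-3)
        assert tests["hr_by_sedation"].statistic == pytest.approx(4.860, abs=5e-3)
        assert tests["rr_by_quality"].statistic == pytest.approx(13.974, abs=5e-3)
        assert tests["rr_by_sedation"].statistic == pytest.approx(1.024, abs=5e-3)
        assert tests["rr_by_fat"].statistic == pytest.approx(4.141, abs=5e-3)
        assert tests["hr_by_quality"].statistic == pytest.approx(13.424, abs=5e-3)
        assert tests["hr_by_integument"].statistic == pytest.approx(4.385, abs=5e-3)


class TestValidateAll:
    def test_headline_statistics(self, records):
        summary = validate_all(records)
        assert summary.n_validation_sessions == 44
        assert summary.rr_errors.mae == pytest.approx(1.9, abs=0.05)
        assert summary.rr_reg_all.r_squared == pytest.approx(0.96, abs=0.01)
        assert summary.hr_reg_mammal.r_squared == pytest.approx(0.9917, abs=0.01)

    def test_perfect_agreement_table(self):
        rs = [rec(float(x), float(x), float(2 * x), float(2 * x), species=f"s{x}")
              for x in (10, 20, 30, 40)]
        assert paired_errors(rs, "RR").mae == 0.0
        assert ols(rs, "HR").r_squared == pytest.approx(1.0)
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(rs, "RR")

    def test_summary_serializes_to_json(self, records):
        import json

        summary = validate_all(records)
        blob = json.loads(summary.to_json())
        assert blob["rr_errors"]["n"] == 36
        assert blob["hr_errors"]["n"] == 23
        assert "rr_by_integument" in blob["chisq_tests"]
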