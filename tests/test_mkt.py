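"""MKT family: Fisher test, alpha estimators, imputation, DFE fractions."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impmkt import (
    BandCounts,
    ContingencyTable,
    GeneClass,
    band_counts,
    classify_gene,
    d_stats,
    emkt,
    fisher_exact,
    fww_mkt,
    imp_mkt,
    imp_mkt_high,
    impute_pwd,
    run_batch,
    run_method,
    standard_mkt,
)
from impmkt.mkt import round_half_away

from conftest import make_record


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact P by exhaustive fixed-margin enumeration in
    exact rational arithmetic (independent of any library routine)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(x):
        return Fraction(
            math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1)
        )

    p_obs = table_prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return float(sum(table_prob(x) for x in range(lo, hi + 1) if table_prob(x) <= p_obs))


class TestFisherExact:
    def test_worked_example_full_table(self):
        p, flag = fisher_exact(ContingencyTable(11, 17, 15, 8))
        assert p == pytest.approx(0.093, abs=5e-4)
        assert not flag

    def test_no_association_gives_one(self):
        p, _ = fisher_exact(ContingencyTable(10, 10, 10, 10))
        assert p == pytest.approx(1.0)

    def test_zero_margin_flagged(self):
        p, flag = fisher_exact(ContingencyTable(0, 0, 5, 7))
        assert p == 1.0 and flag

    @given(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
    @settings(derandomize=True, max_examples=150)
    def test_matches_exact_enumeration_oracle(self, a, b, c, d):
        table = ContingencyTable(a, b, c, d)
        p, flag = fisher_exact(table)
        if flag:
            return
        assert p == pytest.approx(fisher_oracle(a, c, b, d), rel=1e-6)


class TestStandardMKT:
    def test_worked_example(self, worked_example):
        res = standard_mkt(worked_example)
        assert res.p_value == pytest.approx(0.093, abs=5e-4)
        assert res.alpha == pytest.approx(1 - (11 / 17) * (8 / 15), abs=1e-12)
        assert res.excluded_fraction == 0.0

    def test_equal_ratios_give_zero_alpha(self):
        rec = make_record(sfs_n=[6] + [0] * 18, sfs_s=[3] + [0] * 18, dn=10, ds=5)
        res = standard_mkt(rec)
        assert res.alpha == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kw",
        [
            {"sfs_n": [2] + [0] * 18, "sfs_s": [0] * 19},          # P_S = 0
            {"sfs_n": [2] + [0] * 18, "sfs_s": [1] + [0] * 18, "dn": 0},
            {"sfs_n": [2] + [0] * 18, "sfs_s": [1] + [0] * 18, "ds": 0},
        ],
    )
    def test_unanalyzable_margins(self, kw):
        res = standard_mkt(make_record(**kw))
        assert not res.analyzable
        assert math.isnan(res.alpha)


class TestFwwMKT:
    def test_worked_example_table_and_p(self, worked_example):
        res = fww_mkt(worked_example, 0.15)
        t = res.table
        assert (t.pn_cell, t.ps_cell, t.dn_cell, t.ds_cell) == (4, 11, 15, 8)
        assert res.p_value == pytest.approx(0.045, abs=5e-4)

    def test_worked_example_excluded_fraction(self, worked_example):
        res = fww_mkt(worked_example, 0.15)
        assert res.excluded_fraction == pytest.approx(13 / 28)

    def test_tiny_cutoff_reduces_to_standard(self, worked_example):
        res = fww_mkt(worked_example, 1 / 40)
        base = standard_mkt(worked_example)
        assert res.table == base.table
        assert res.alpha == pytest.approx(base.alpha)


class TestEMKT:
    def test_worked_example_neutral_decomposition(self, worked_example):
        res = emkt(worked_example, 0.15)
        assert res.f_neutral == pytest.approx(6 / 17)
        assert res.pneut == pytest.approx(11 * 6 / 17 + 4)
        assert res.table.pn_cell == 8
        assert res.table.ps_cell == 17

    def test_empty_synonymous_low_band_treats_low_pn_as_deleterious(self):
        rec = make_record(
            sfs_n=[5, 0, 3] + [0] * 16, sfs_s=[0, 0, 7] + [0] * 16, dn=9, ds=4
        )
        res = emkt(rec, 0.15)
        assert res.f_neutral == 0.0
        assert res.pneut == pytest.approx(3)  # only the above-cutoff P_N survives

    def test_proportional_spectra_match_standard_alpha(self):
        shape = np.array([8, 4, 2, 2, 1, 1] + [0] * 13, dtype=float)
        rec = make_record(sfs_n=2 * shape, sfs_s=shape, dn=12, ds=6)
        res = emkt(rec, 0.15)
        base = standard_mkt(rec)
        assert res.alpha == pytest.approx(base.alpha, abs=1e-12)

    def test_alternative_low_band_reading(self, worked_example):
        res = emkt(worked_example, 0.15, neutral_from_low_band=True)
        assert res.pneut == pytest.approx(7 * 6 / 17 + 4)


class TestImputePwd:
    def test_worked_example_value_and_rounding(self, worked_example):
        b = band_counts(worked_example, 0.15)
        pwd, raw, clamped = impute_pwd(b)
        assert raw == pytest.approx(7 - 4 * 6 / 11)
        assert pwd == pytest.approx(4.818, abs=5e-4)
        assert not clamped
        assert round_half_away(pwd) == 5

    def test_neutral_ratio_equality_gives_zero(self):
        pwd, raw, clamped = impute_pwd(BandCounts(6, 4, 3, 2, 0.15))
        assert raw == pytest.approx(0.0)
        assert pwd == 0.0 and not clamped

    def test_negative_imputation_clamped_to_zero(self):
        pwd, raw, clamped = impute_pwd(BandCounts(1, 8, 6, 2, 0.15))
        assert raw < 0
        assert pwd == 0.0 and clamped

    def test_undefined_ratio_raises(self):
        with pytest.raises(ValueError, match="cutoff"):
            impute_pwd(BandCounts(3, 2, 4, 0, 0.15))


class TestImpMKT:
    def test_worked_example_table_and_p(self, worked_example):
        res = imp_mkt(worked_example, 0.15)
        t = res.table
        assert (t.pn_cell, t.ps_cell, t.dn_cell, t.ds_cell) == (6, 17, 15, 8)
        assert res.p_value == pytest.approx(0.017, abs=5e-4)

    def test_worked_example_alpha_uses_unrounded_pwd(self, worked_example):
        res = imp_mkt(worked_example, 0.15)
        assert res.alpha == pytest.approx(1 - ((11 - 4.8181818) / 17) * (8 / 15), abs=1e-6)

    def test_zero_pwd_reproduces_standard_exactly(self):
        rec = make_record(
            sfs_n=[3, 0, 4, 2] + [0] * 15, sfs_s=[3, 0, 4, 2] + [0] * 15, dn=9, ds=5
        )
        res = imp_mkt(rec, 0.15)
        base = standard_mkt(rec)
        assert res.pwd == 0.0
        assert res.table == base.table
        assert res.alpha == base.alpha
        assert res.p_value == base.p_value

    def test_loses_no_more_polymorphism_than_fww(self, worked_example, rng):
        for _ in range(50):
            rec = make_record(
                sfs_n=rng.integers(0, 8, 19).astype(float),
                sfs_s=rng.integers(0, 8, 19).astype(float),
                dn=int(rng.integers(1, 20)),
                ds=int(rng.integers(1, 20)),
            )
            for cutoff in (0.15, 0.25, 0.35):
                ri, rf = imp_mkt(rec, cutoff), fww_mkt(rec, cutoff)
                if ri.analyzable and rf.analyzable:
                    assert ri.excluded_fraction <= rf.excluded_fraction + 1e-12

    def test_all_methods_coincide_when_low_band_empty(self):
        rec = make_record(
            sfs_n=[0, 0, 5, 3, 1] + [0] * 14,
            sfs_s=[0, 0, 6, 2, 2] + [0] * 14,
            dn=12,
            ds=7,
        )
        alphas = {
            m: run_method(rec, m, 0.15).alpha for m in ("mkt", "fww", "emkt", "imp")
        }
        assert len({round(a, 12) for a in alphas.values()}) == 1


class TestImpMKTHigh:
    def test_no_excess_reduces_to_standard(self):
        rec = make_record(
            sfs_n=[0, 0, 4, 4, 2] + [0] * 14,
            sfs_s=[0, 0, 4, 4, 2] + [0] * 14,
            dn=10,
            ds=10,
        )
        res = imp_mkt_high(rec, 0.15, 0.85)
        base = standard_mkt(rec)
        assert res.pwd == 0.0
        assert res.table == base.table
        assert res.alpha == pytest.approx(base.alpha)

    def test_constructed_high_frequency_excess_recovered_exactly(self):
        # mid band has equal N/S counts (ratio 1); the nonsynonymous high band
        # carries a known excess of 3 over the synonymous one
        excess = 3
        sfs_n = np.zeros(19)
        sfs_s = np.zeros(19)
        sfs_n[9] = 10          # mid band, freq 0.5
        sfs_s[9] = 10
        sfs_n[17] = 5 + excess  # high band, freq 0.9
        sfs_s[17] = 5
        rec = make_record(sfs_n=sfs_n, sfs_s=sfs_s, dn=10, ds=10)
        res = imp_mkt_high(rec, 0.15, 0.85)
        assert res.table.dn_cell == 10 + excess
        assert res.table.pn_cell == round_half_away(rec.pn - excess)
        assert res.alpha == pytest.approx(
            1 - ((rec.pn - excess) / rec.ps) * (10 / (10 + excess))
        )

    def test_no_classes_above_high_cutoff_matches_imp_with_midband_ratio(
        self, worked_example
    ):
        res_high = imp_mkt_high(worked_example, 0.15, 0.85)
        res_imp = imp_mkt(worked_example, 0.15)
        # the worked example has nothing above 0.85, so the mid band is the
        # whole above-cutoff band and the two estimators coincide
        assert res_high.pwd == pytest.approx(res_imp.pwd)
        assert res_high.alpha == pytest.approx(res_imp.alpha)

    def test_empty_mid_band_not_analyzable(self):
        rec = make_record(sfs_n=[4] + [0] * 18, sfs_s=[4] + [0] * 18, dn=5, ds=5)
        res = imp_mkt_high(rec, 0.15, 0.85)
        assert not res.analyzable


class TestDStats:
    def test_worked_example_fractions(self, worked_example):
        d = d_stats(worked_example, 0.15)
        assert d.d == pytest.approx(1 - (11 / 17) * (200 / 500), abs=1e-12)
        assert d.dw == pytest.approx((4.8181818 / 17) * 0.4, abs=1e-6)
        assert d.d0 == pytest.approx(1 - d.d - d.dw, abs=1e-12)

    def test_neutral_gene_is_all_d0(self):
        rec = make_record(
            sfs_n=[0] * 7 + [10, 5] + [0] * 10, sfs_s=[0] * 7 + [4, 2] + [0] * 10,
            dn=5, ds=3, mn=500, ms=200,
        )
        # P_N/P_S = 15/6 = m_N/m_S = 2.5 and proportional bands give P_wd = 0
        d = d_stats(rec, 0.35)
        assert d.d == pytest.approx(0.0, abs=1e-12)
        assert d.d0 == pytest.approx(1.0, abs=1e-12)

    def test_fractions_always_sum_to_one(self, rng):
        for _ in range(30):
            rec = make_record(
                sfs_n=rng.integers(0, 9, 19).astype(float),
                sfs_s=rng.integers(1, 9, 19).astype(float),
                dn=5, ds=5,
                mn=float(rng.integers(100, 900)), ms=float(rng.integers(50, 400)),
            )
            d = d_stats(rec, 0.15)
            assert d.d + d.dw + d.d0 == pytest.approx(1.0, abs=1e-12)


class TestClassification:
    def test_worked_example_imp_is_positive(self, worked_example):
        assert imp_mkt(worked_example, 0.15).classify(0.05) is GeneClass.POSITIVE

    def test_nonsignificant_and_nonanalyzable(self, worked_example):
        res = standard_mkt(worked_example)  # p = 0.093
        assert classify_gene(res, 0.05) is GeneClass.NON_SIGNIFICANT
        bad = standard_mkt(make_record())  # all-zero gene
        assert classify_gene(bad, 0.05) is GeneClass.NON_ANALYZABLE

    def test_negative_selection_label(self):
        rec = make_record(sfs_n=[30] + [0] * 18, sfs_s=[5] + [0] * 18, dn=5, ds=10)
        res = standard_mkt(rec)
        assert res.alpha < 0
        assert classify_gene(res, 0.05) is GeneClass.NEGATIVE


class TestBatch:
    def test_one_row_per_gene_per_method(self, worked_example):
        df = run_batch([worked_example], methods=("mkt", "fww", "imp"), cutoff=0.15)
        assert len(df) == 3
        imp_row = df[df.method == "imp"].iloc[0]
        assert imp_row["p_value"] == pytest.approx(0.017, abs=5e-4)
        assert imp_row["class"] == "positive"

    def test_bh_column_is_monotone_in_p(self, worked_example, rng):
        recs = [worked_example] + [
            make_record(
                gene_id=f"r{i}",
                sfs_n=rng.integers(0, 9, 19).astype(float),
                sfs_s=rng.integers(1, 9, 19).astype(float),
                dn=int(rng.integers(1, 15)),
                ds=int(rng.integers(1, 15)),
            )
            for i in range(8)
        ]
        df = run_batch(recs, methods=("mkt",), bh_correction=True)
        sub = df.dropna(subset=["p_value"]).sort_values("p_value")
        assert sub["p_bh"].is_monotonic_increasing
        assert (sub["p_bh"] >= sub["p_value"] - 1e-12).all()
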