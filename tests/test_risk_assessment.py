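"""Conservation-risk index, threshold classification and summary statistics."""

from math import inf

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pnvgap.risk_assessment import (
    CLASS_SEVERITY,
    HOEKSTRA_SCHEME,
    PAPER_SCHEME,
    RiskThresholds,
    build_risk_table,
    classify_eb_band,
    classify_risk,
    conservation_risk_index,
    crisis_pnvs,
    summary_statistics,
)


class TestCri:
    def test_direct_ratio(self):
        assert conservation_risk_index(50, 25) == 2.0

    def test_zero_influence_is_zero_for_any_protection(self):
        assert conservation_risk_index(0, 30) == 0.0
        assert conservation_risk_index(0, 0) == 0.0

    def test_unprotected_with_influence_is_infinite(self):
        assert conservation_risk_index(60, 0) == inf

    def test_out_of_range_inputs_fail(self):
        with pytest.raises(ValueError):
            conservation_risk_index(120, 10)
        with pytest.raises(ValueError):
            conservation_risk_index(50, -1)


class TestClassifyRisk:
    @pytest.mark.parametrize("hi,cri,expected", [
        (60, 12, "CR"),
        (45, 5, "EN"),
        (25, 3, "VU"),
        (10, 100, "NV"),   # fails every HI bound
        (90, 1.5, "NV"),   # fails every CRI bound
        (50, 12, "EN"),    # strict: HI must exceed 50 for CR, drops to EN
        (60, 10, "EN"),    # strict: CRI must exceed 10
    ])
    def test_default_scheme(self, hi, cri, expected):
        assert classify_risk(hi, cri, PAPER_SCHEME) == expected

    @pytest.mark.parametrize("hi,cri,expected", [
        (60, 26, "CR"),
        (60, 12, "EN"),
        (45, 5, "VU"),
        (25, 3, "VU"),
    ])
    def test_hoekstra_scheme(self, hi, cri, expected):
        assert classify_risk(hi, cri, HOEKSTRA_SCHEME) == expected

    def test_infinite_cri_classifies_by_hi_alone(self):
        assert classify_risk(60, inf) == "CR"
        assert classify_risk(15, inf) == "NV"

    def test_malformed_scheme_fails(self):
        with pytest.raises(ValueError):
            RiskThresholds("bad", (("VU", 20, 2), ("CR", 50, 10)))
        with pytest.raises(ValueError):
            RiskThresholds("bad", (("CR", -1, 10),))

    def test_monotone_and_nested_on_random_records(self, rng):
        sev = CLASS_SEVERITY
        for _ in range(1000):
            hi = rng.uniform(0, 100)
            cri = rng.uniform(0, 30)
            c = classify_risk(hi, cri)
            # raising pressure or risk never lowers the class
            assert sev[classify_risk(min(hi + 10, 100), cri)] >= sev[c]
            assert sev[classify_risk(hi, cri + 5)] >= sev[c]
            # nesting: the CR rule implies EN implies VU
            if c == "CR":
                assert hi > 40 and cri > 4
            # PA1 coverage is a subset, so CRI_pa1 >= CRI_all -> never less severe
            assert sev[classify_risk(hi, cri * 1.5)] >= sev[c]
            # the stricter global thresholds never give a more severe class
            assert sev[classify_risk(hi, cri, HOEKSTRA_SCHEME)] <= sev[c]


class TestClassOrderingProperties:
    @settings(derandomize=True, max_examples=200)
    @given(hi=st.floats(0, 100), cri=st.floats(0, 50),
           dhi=st.floats(0, 50), dcri=st.floats(0, 50))
    def test_severity_monotone_in_both_arguments(self, hi, cri, dhi, dcri):
        sev = CLASS_SEVERITY
        base = sev[classify_risk(hi, cri)]
        assert sev[classify_risk(min(hi + dhi, 100), cri)] >= base
        assert sev[classify_risk(hi, cri + dcri)] >= base

    @settings(derandomize=True, max_examples=200)
    @given(hi=st.floats(0, 100), cri=st.floats(0, 50))
    def test_global_scheme_never_more_severe(self, hi, cri):
        sev = CLASS_SEVERITY
        assert sev[classify_risk(hi, cri, HOEKSTRA_SCHEME)] <= sev[classify_risk(hi, cri)]


class TestEbBand:
    @pytest.mark.parametrize("eb,band", [(0.0, "LB"), (0.18, "LB"), (0.5, "MB"),
                                         (0.9, "MB"), (1.01, "HB"), (float("nan"), "LB")])
    def test_bias_bands(self, eb, band):
        assert classify_eb_band(eb) == band


def _tables(n=6, seed=0):
    rng = np.random.default_rng(seed)
    codes = np.arange(1, n + 1)
    cov = pd.DataFrame({
        "pnv_code": codes,
        "area_cells": rng.integers(50, 500, n),
        "gc_all_pct": rng.uniform(1, 60, n),
    })
    cov["gc_pa1_pct"] = cov["gc_all_pct"] * rng.uniform(0.2, 1.0, n)
    hi = pd.DataFrame({"pnv_code": codes, "hi_mean": rng.uniform(0, 100, n)})
    eb = pd.DataFrame({"pnv_code": codes, "eb": rng.uniform(0, 1.5, n)})
    return cov, hi, eb


class TestRiskTable:
    def test_single_record_join(self):
        cov = pd.DataFrame({"pnv_code": [1], "gc_all_pct": [10.0], "gc_pa1_pct": [5.0]})
        hi = pd.DataFrame({"pnv_code": [1], "hi_mean": [55.0]})
        tab = build_risk_table(cov, hi)
        assert tab["cri_all"].item() == pytest.approx(5.5)
        assert tab["class_all"].item() == "EN"
        assert tab["class_pa1"].item() == "CR"

    def test_classes_match_hand_applied_rules(self):
        cov, hi, eb = _tables()
        tab = build_risk_table(cov, hi, eb)
        for _, row in tab.iterrows():
            assert row["class_all"] == classify_risk(row["hi_mean"],
                                                     row["hi_mean"] / row["gc_all_pct"])

    def test_class_counts_partition_pnvs(self):
        cov, hi, eb = _tables(n=20, seed=3)
        tab = build_risk_table(cov, hi, eb)
        assert tab["class_all"].isin(list(CLASS_SEVERITY)).all()
        assert len(tab) == 20

    def test_pa1_class_at_least_as_severe(self):
        cov, hi, eb = _tables(n=30, seed=4)
        tab = build_risk_table(cov, hi, eb)
        sev = tab["class_all"].map(CLASS_SEVERITY)
        sev1 = tab["class_pa1"].map(CLASS_SEVERITY)
        assert (sev1 >= sev).all()

    def test_code_mismatch_fails_naming_codes(self):
        cov, hi, _ = _tables()
        hi2 = hi[hi.pnv_code != 3]
        with pytest.raises(ValueError, match="3"):
            build_risk_table(cov, hi2)

    def test_crisis_set_is_cr_en_plus_high_cri_vu(self):
        cov = pd.DataFrame({"pnv_code": [1, 2, 3, 4],
                            "gc_all_pct": [4.0, 10.0, 12.0, 50.0],
                            "gc_pa1_pct": [2.0, 5.0, 6.0, 25.0]})
        hi = pd.DataFrame({"pnv_code": [1, 2, 3, 4],
                           "hi_mean": [60.0, 45.0, 47.0, 30.0]})
        tab = build_risk_table(cov, hi)
        # codes: 1 -> CRI 15 CR, 2 -> CRI 4.5 EN, 3 -> CRI 3.9 VU, 4 -> CRI 0.6 NV
        assert crisis_pnvs(tab, vu_cri_floor=3.5) == [1, 2, 3]
        assert crisis_pnvs(tab, vu_cri_floor=10.0) == [1, 2]


class TestSummaryStatistics:
    def test_collinear_points_give_r2_one(self):
        cov = pd.DataFrame({"pnv_code": [1, 2, 3],
                            "gc_all_pct": [10.0, 20.0, 30.0],
                            "gc_pa1_pct": [5.0, 10.0, 15.0]})
        hi = pd.DataFrame({"pnv_code": [1, 2, 3], "hi_mean": [20.0, 40.0, 60.0]})
        rep = summary_statistics(build_risk_table(cov, hi))
        assert rep["ols_gc_all"]["r2"] == pytest.approx(1.0)

    def test_three_point_hand_ols(self):
        # points (x, y) = (0, 1), (1, 3), (2, 4): slope 1.5, intercept 7/6, R^2 = 27/28
        cov = pd.DataFrame({"pnv_code": [1, 2, 3],
                            "gc_all_pct": [1e-9, 1.0, 2.0],
                            "gc_pa1_pct": [1e-9, 1.0, 2.0]})
        hi = pd.DataFrame({"pnv_code": [1, 2, 3], "hi_mean": [1.0, 3.0, 4.0]})
        rep = summary_statistics(build_risk_table(cov, hi))
        assert rep["ols_gc_all"]["slope"] == pytest.approx(1.5, rel=1e-6)
        assert rep["ols_gc_all"]["r2"] == pytest.approx(27 / 28, rel=1e-6)

    def test_independent_hi_and_gc_give_near_zero_r2(self):
        r2s, ps = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 50
            cov = pd.DataFrame({"pnv_code": np.arange(n),
                                "gc_all_pct": rng.uniform(1, 60, n)})
            cov["gc_pa1_pct"] = cov["gc_all_pct"] * 0.5
            hi = pd.DataFrame({"pnv_code": np.arange(n), "hi_mean": rng.uniform(0, 100, n)})
            rep = summary_statistics(build_risk_table(cov, hi))
            r2s.append(rep["ols_gc_all"]["r2"])
            ps.append(rep["ols_gc_all"]["p"])
        assert np.mean(r2s) < 0.1
        # p-values roughly uniform: around half should exceed 0.4
        assert 0.2 < np.mean(np.array(ps) > 0.4) < 0.9

    def test_too_few_records_fail(self):
        cov, hi, _ = _tables(n=2)
        with pytest.raises(ValueError):
            summary_statistics(build_risk_table(cov, hi))
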