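"""Skews, identity, repeats, rank-sum test, regression, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from attcfold.attc import reverse_complement
from attcfold.stats import (
    cohort_summary,
    direct_repeats,
    linear_fit,
    pairwise_identity,
    rank_sum_test,
    skews,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestSkews:
    def test_pure_g(self):
        res = skews("GGGG")
        assert res.gc_skew == 1.0 and res.at_skew is None

    def test_balanced(self):
        res = skews("GACT")
        assert res.gc_skew == 0.0 and res.at_skew == 0.0

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_and_bounds(self, seq):
        f = skews(seq)
        r = skews(reverse_complement(seq))
        for a, b in ((f.gc_skew, r.gc_skew), (f.at_skew, r.at_skew)):
            if a is None:
                assert b is None
            else:
                assert -1.0 <= a <= 1.0
                assert math.isclose(a, -b, abs_tol=1e-12)


class TestPairwiseIdentity:
    def test_identical_is_hundred(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_disjoint_is_zero(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_symmetric(self):
        a, b = "ACGTTGCAACGT", "ACGTAGCAAGT"
        assert math.isclose(pairwise_identity(a, b),
                            pairwise_identity(b, a), abs_tol=1e-9)

    def test_hundred_iff_equal(self):
        assert pairwise_identity("ACGTA", "ACGTT") < 100.0


class TestDirectRepeats:
    def test_disjoint_alphabets_empty(self):
        assert direct_repeats("AAAA", "CCCC", 4) == []

    def test_identical_strings_full_length(self):
        hits = direct_repeats("GATTACAG", "GATTACAG", 4)
        assert hits[0].length == 8 and hits[0].start_a == 0

    def test_constructed_shared_substring(self):
        hits = direct_repeats("TTGTTAGGCTT", "CCCGTTAGGCAAA", 5)
        top = hits[0]
        assert top.sequence == "GTTAGGC"
        assert (top.start_a, top.start_b) == (2, 3)

    def test_min_len_floor(self):
        with pytest.raises(ValueError):
            direct_repeats("ACGT", "ACGT", 3)


class TestRankSum:
    def test_identical_multisets(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]).p_two_sided >= 0.99

    def test_exact_two_sided_example(self):
        res = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert res.method == "exact"
        assert math.isclose(res.p_two_sided, 0.1, abs_tol=1e-12)

    def test_all_identical_values(self):
        assert rank_sum_test([5, 5], [5, 5, 5]).p_two_sided == 1.0

    def test_exact_path_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = list(rng.permutation(np.arange(12.0))[:5])
            y = [v for v in range(12) if float(v) not in x][:5]
            res = rank_sum_test(x, [float(v) for v in y])
            ref = sps.mannwhitneyu(x, [float(v) for v in y],
                                   alternative="two-sided", method="exact")
            assert math.isclose(res.p_two_sided, ref.pvalue, abs_tol=1e-9)

    def test_approximation_close_to_exact_for_eight_vs_eight(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        res = rank_sum_test(list(x), list(y))
        assert res.method == "normal_approximation"
        exact = sps.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact").pvalue
        assert abs(res.p_two_sided - exact) < 0.005


class TestLinearFit:
    def test_exact_line(self):
        fit = linear_fit([0, 1, 2, 3], [1, 3, 5, 7])
        assert math.isclose(fit.slope, 2.0) and fit.r_squared == 1.0

    def test_constant_response(self):
        fit = linear_fit([0, 1, 2, 3], [4, 4, 4, 4])
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_closed_form_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 3.0, 3.5, 6.0, 8.0])
        fit = linear_fit(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert math.isclose(fit.slope, sxy / sxx, rel_tol=1e-12)
        assert math.isclose(fit.intercept,
                            y.mean() - fit.slope * x.mean(), rel_tol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([2, 2, 2], [1, 2, 3])


class TestCohortSummary:
    def test_threshold_proportion_is_strict(self):
        df = pd.DataFrame({
            "group": ["a"] * 4 + ["b"],
            "pfold": [0.2, 0.5, 0.05, 0.01, 0.1],
            "length": [60, 60, 120, 120, 90],
        })
        out = cohort_summary(df, "group")
        a = out[out["group"] == "a"].iloc[0]
        b = out[out["group"] == "b"].iloc[0]
        assert a["prop_pfold_above"] == 0.5
        assert b["prop_pfold_above"] == 0.0  # exactly at threshold excluded

    def test_single_site_median(self):
        df = pd.DataFrame({"group": ["a"], "pfold": [0.3], "length": [77]})
        out = cohort_summary(df, "group")
        assert out.iloc[0]["median_length"] == 77

    def test_low_band_is_closed(self):
        df = pd.DataFrame({
            "group": ["a"] * 3,
            "pfold": [1e-5, 1e-7, 1e-4],
            "length": [100] * 3,
        })
        out = cohort_summary(df, "group")
        assert math.isclose(out.iloc[0]["prop_pfold_low_band"], 2 / 3)
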