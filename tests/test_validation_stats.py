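import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stripquant import (
    PairedSeries,
    bland_altman,
    compare_methods,
    correlate,
    correlation_p,
    fisher_ci,
    minmax_scale,
    pearson_r,
    significance_stars,
    site_series_table,
)
from stripquant.datasets import field_study_correlations


class TestPearson:
    def test_perfect_linearity(self):
        a = (1.0, 2.0, 3.0, 4.0)
        assert pearson_r(PairedSeries("a", "b", a, tuple(2 * x + 1 for x in a))) == pytest.approx(1.0)
        assert pearson_r(PairedSeries("a", "b", a, tuple(-x for x in a))) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        s = PairedSeries("a", "b", (1, 2, 3, 4), (1, 3, 2, 4))
        assert pearson_r(s) == pytest.approx(0.8)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r(PairedSeries("a", "b", (1, 1, 1), (1, 2, 3)))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            PairedSeries("a", "b", (1, 2), (1, 2, 3))


class TestFisherCI:
    def test_published_field_study_brackets_reproduce(self):
        """Every printed 95% CI bracket in the published n=34 comparison
        table comes back exactly from the Fisher-z interval after
        2-decimal rounding."""
        table = field_study_correlations()
        for row in table.itertuples(index=False):
            lo, hi = fisher_ci(row.r, row.n)
            assert round(lo, 2) == pytest.approx(row.ci_low), row
            assert round(hi, 2) == pytest.approx(row.ci_high), row

    def test_zero_r_symmetric(self):
        lo, hi = fisher_ci(0.0, 34)
        assert lo == pytest.approx(-hi)

    def test_degenerate_r(self):
        with pytest.warns(UserWarning):
            assert fisher_ci(1.0, 34) == (1.0, 1.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_ci(0.5, 3)


class TestPValuesAndStars:
    def test_published_star_thresholds(self):
        # r = 0.91 at n = 34 is *** ; r = 0.46 lands between 0.001 and 0.01
        p_strong = correlation_p(0.91, 34)
        assert p_strong <= 0.001 and significance_stars(p_strong) == "***"
        p_mid = correlation_p(0.46, 34)
        assert 0.001 < p_mid <= 0.01 and significance_stars(p_mid) == "**"

    def test_zero_r_p_is_one(self):
        assert correlation_p(0.0, 34) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "p, stars", [(0.0005, "***"), (0.001, "***"), (0.005, "**"), (0.02, "*"), (0.05, "*"), (0.2, "")]
    )
    def test_star_boundaries(self, p, stars):
        assert significance_stars(p) == stars

    def test_correlate_cross_checked_against_pingouin(self):
        """Independent oracle: pingouin's Pearson r, CI and p on random data."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        res = correlate(PairedSeries("x", "y", tuple(x), tuple(y)))
        ref = pingouin.corr(x, y)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)
        lo, hi = ref["CI95"].iloc[0]
        assert res.ci_low == pytest.approx(lo, abs=5e-3)
        assert res.ci_high == pytest.approx(hi, abs=5e-3)


class TestBlandAltman:
    def test_three_pair_closed_form(self):
        # d = (-1, 0, -1): bias -2/3, sd = 1/sqrt(3)
        s = PairedSeries("a", "b", (1, 2, 3), (2, 2, 4))
        res = bland_altman(s)
        assert res.bias == pytest.approx(-2 / 3)
        assert res.sd_diff == pytest.approx(1 / math.sqrt(3))
        assert res.loa_low == pytest.approx(-2 / 3 - 1.96 / math.sqrt(3))
        assert res.loa_high == pytest.approx(-2 / 3 + 1.96 / math.sqrt(3))

    def test_identical_series(self):
        s = PairedSeries("a", "b", (1, 2, 3), (1, 2, 3))
        res = bland_altman(s)
        assert res.bias == 0 and res.sd_diff == 0 and (res.loa_low, res.loa_high) == (0, 0)

    def test_agrees_with_direct_recomputation(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(10, 3, 25)
            b = a + rng.normal(0.5, 1.0, 25)
            res = bland_altman(PairedSeries("a", "b", tuple(a), tuple(b)))
            d = a - b
            assert res.bias == pytest.approx(d.mean(), abs=1e-12)
            assert res.sd_diff == pytest.approx(d.std(ddof=1), abs=1e-12)
            assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
            assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(6)
        a = tuple(rng.normal(size=12))
        b = tuple(rng.normal(size=12))
        base = bland_altman(PairedSeries("a", "b", a, b))
        both = bland_altman(PairedSeries("a", "b", tuple(x + 5 for x in a), tuple(x + 5 for x in b)))
        assert both.bias == pytest.approx(base.bias, abs=1e-12)
        assert both.sd_diff == pytest.approx(base.sd_diff, abs=1e-12)
        one = bland_altman(PairedSeries("a", "b", tuple(x + 5 for x in a), b))
        assert one.bias == pytest.approx(base.bias + 5, abs=1e-12)

    def test_no_proportional_bias_on_constant_offset(self):
        a = tuple(float(x) for x in range(1, 13))
        b = tuple(x - 2.0 for x in a)  # difference independent of magnitude
        res = bland_altman(PairedSeries("a", "b", a, b))
        assert res.prop_bias_slope == pytest.approx(0.0, abs=1e-12)

    def test_proportional_bias_detected(self):
        a = tuple(float(x) * 1.5 for x in range(1, 20))
        b = tuple(float(x) for x in range(1, 20))
        res = bland_altman(PairedSeries("a", "b", a, b))
        assert res.prop_bias_slope > 0 and res.prop_bias_p < 0.001

    def test_multiplier_configurable(self):
        s = PairedSeries("a", "b", (1, 2, 3), (2, 2, 4))
        res = bland_altman(s, multiplier=2.0)
        assert res.loa_high - res.bias == pytest.approx(2.0 * res.sd_diff)


class TestMinMax:
    @pytest.mark.parametrize(
        "vals, expected",
        [((0, 5, 10), [0, 0.5, 1]), ((-2, 0, 2), [0, 0.5, 1])],
    )
    def test_basic(self, vals, expected):
        assert minmax_scale(vals) == pytest.approx(expected)

    def test_constant_series_warns_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            assert minmax_scale((3, 3, 3)) == [0.0, 0.0, 0.0]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30).filter(
            lambda v: max(v) > min(v)
        ),
        a=st.floats(0.1, 100),
        b=st.floats(-1e5, 1e5),
    )
    def test_invariant_to_positive_affine_rescaling(self, vals, a, b):
        scaled = [a * v + b for v in vals]
        assert minmax_scale(scaled) == pytest.approx(minmax_scale(vals), abs=1e-9)


class TestSiteSeries:
    def test_single_analyte_standardized(self):
        t = site_series_table([(1, "Fe", 0.0), (2, "Fe", 5.0), (3, "Fe", 10.0)])
        assert list(t["standardized"]) == pytest.approx([0, 0.5, 1])

    def test_cumulative_running_sum(self):
        t = site_series_table(
            [(1, "Fe", 0.0), (2, "Fe", 5.0), (3, "Fe", 10.0)], cumulative=True
        )
        assert list(t["cumulative"]) == pytest.approx([0, 0.5, 1.5])

    def test_analytes_standardized_independently(self):
        t = site_series_table(
            [(1, "A", 0.0), (2, "A", 100.0), (1, "B", 0.0), (2, "B", 1.0)]
        )
        by = t.set_index(["analyte", "site_order"])["standardized"]
        assert by[("A", 2)] == 1.0 and by[("B", 2)] == 1.0

    def test_duplicate_site_analyte_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            site_series_table([(1, "A", 0.0), (1, "A", 2.0)])


class TestCompareMethods:
    @staticmethod
    def _table(n=34, seed=0):
        rng = np.random.default_rng(seed)
        lab = rng.normal(10, 2, n)
        rows = []
        for i, v in enumerate(lab):
            rows.append((i, "Fe", "laboratory", v))
            rows.append((i, "Fe", "human_machine", v + rng.normal(0, 0.5)))
            rows.append((i, "Fe", "visual", v + rng.normal(0, 3.0)))
        return pd.DataFrame(rows, columns=["sample_id", "analyte", "method", "value"])

    def test_recovers_known_correlation_structure(self):
        rep = compare_methods(self._table())
        r = rep.set_index("method")["r"]
        assert r["human_machine"] > r["visual"]
        assert r["human_machine"] > 0.9

    def test_identical_columns_give_r_one(self):
        rows = [(i, "A", m, float(i)) for i in range(6) for m in ("laboratory", "strip")]
        rep = compare_methods(pd.DataFrame(rows, columns=["sample_id", "analyte", "method", "value"]))
        assert rep["r"].iloc[0] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        rows = [(i, "A", m, float(i) + (m == "strip")) for i in range(3) for m in ("laboratory", "strip")]
        with pytest.raises(ValueError, match=">= 4"):
            compare_methods(pd.DataFrame(rows, columns=["sample_id", "analyte", "method", "value"]))

    def test_missing_lab_method_rejected(self):
        t = self._table()
        with pytest.raises(ValueError, match="reference method"):
            compare_methods(t, lab_method="nope")

    def test_rows_sorted_by_descending_human_machine_r(self):
        t = pd.concat([self._table(seed=1), self._table(seed=2).assign(analyte="Cu")])
        rep = compare_methods(t)
        hm = rep[rep["method"] == "human_machine"]
        assert list(hm["r"]) == sorted(hm["r"], reverse=True)
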