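"""Variance stabilization, Levene tests, concordance band, cross-tissue r."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methmatch.datamodel import BetaMatrix, MatchedDataset
from methmatch.variability import (beta_transform, cross_tissue_probe_correlation,
                                   inverse_beta_transform, levene_test,
                                   mean_normalize, probe_range,
                                   variability_table, variable_loci,
                                   variance_concordance)

from conftest import make_matched


def test_mean_normalize():
    np.testing.assert_allclose(mean_normalize([0.2, 0.4, 0.6]), [-0.2, 0.0, 0.2],
                               atol=1e-12)
    np.testing.assert_allclose(mean_normalize([0.5] * 4), 0.0, atol=1e-12)
    rng = np.random.default_rng(0)
    assert abs(mean_normalize(rng.uniform(0, 1, 100)).sum()) < 1e-12


def test_probe_range_brute_force():
    assert probe_range([0.1, 0.9]) == pytest.approx(0.8)
    assert probe_range([0.3] * 5) == 0.0
    rng = np.random.default_rng(1)
    v = rng.uniform(0, 1, 40)
    brute = max(abs(a - b) for a in v for b in v)
    assert probe_range(v) == pytest.approx(brute)


class TestBetaTransform:
    def test_logit_closed_forms(self):
        assert beta_transform(0.5) == pytest.approx(0.0)
        assert beta_transform(0.8) == pytest.approx(2.0)  # log2(4)

    @pytest.mark.parametrize("mode", ["logit", "arcsine"])
    def test_round_trip_and_monotone(self, mode):
        b = np.linspace(0.001, 0.999, 200)
        t = beta_transform(b, mode=mode)
        assert np.all(np.diff(t) > 0)
        np.testing.assert_allclose(inverse_beta_transform(t, mode=mode), b, atol=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=1e-9, max_value=1 - 1e-9,
                     allow_nan=False, allow_infinity=False))
    def test_round_trip_property(self, b):
        """The logit transform is a bijection of (0, 1) onto the reals."""
        assert inverse_beta_transform(beta_transform(b)) == pytest.approx(b, abs=1e-12)

    def test_rejects_boundary_values(self):
        with pytest.raises(ValueError, match="replace"):
            beta_transform([0.0, 0.5])
        with pytest.raises(ValueError):
            beta_transform(1.0)


class TestLevene:
    def test_identical_groups_null(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        assert levene_test(g, g) == (0.0, 1.0)

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_matches_long_hand_computation(self, center):
        """W from the textbook recipe: one-way ANOVA F on absolute deviations
        from each group's center."""
        a = np.array([-1.0, 0.0, 1.0])
        b = np.array([-10.0, 0.0, 10.0])
        cfun = np.mean if center == "mean" else np.median
        za = np.abs(a - cfun(a))
        zb = np.abs(b - cfun(b))
        zbar = np.concatenate([za, zb]).mean()
        ssb = len(za) * (za.mean() - zbar) ** 2 + len(zb) * (zb.mean() - zbar) ** 2
        ssw = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
        w_expected = (ssb / 1) / (ssw / 4)
        p_expected = stats.f.sf(w_expected, 1, 4)
        stat, p = levene_test(a, b, center=center)
        assert stat == pytest.approx(w_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-12)

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert levene_test(a, b)[0] == pytest.approx(levene_test(a + 7, b)[0], rel=1e-9)

    def test_power_exceeds_half_for_threefold_variance(self):
        """At a 3-fold variance ratio and n = 25/group, the unadjusted test at
        alpha = 0.05 rejects well over half the time."""
        rng = np.random.default_rng(3)
        rejections = sum(
            levene_test(rng.normal(0, 1, 25), rng.normal(0, math.sqrt(3), 25))[1] < 0.05
            for _ in range(300)
        )
        assert rejections / 300 > 0.5


class TestVarianceConcordance:
    @pytest.mark.parametrize(
        "va,vb,expected",
        [(1.0, 1.1, "within_band"), (1.0, 1.3, "outside_band"),
         (1.0, 1.2, "within_band"), (1.0, 0.8, "within_band"),
         (1.0, 0.79, "outside_band")],
    )
    def test_band_boundaries_closed(self, va, vb, expected):
        assert variance_concordance(va, vb) == expected

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            va, vb, c = rng.uniform(0.1, 2, 3)
            assert variance_concordance(va, vb) == variance_concordance(c * va, c * vb)

    def test_zero_reference_warns_outside(self):
        with pytest.warns(UserWarning):
            assert variance_concordance(0.0, 0.1) == "outside_band"


def test_variable_loci_thresholds():
    sds = pd.Series([0.05, 0.15, 0.35], index=["a", "b", "c"])
    assert set(variable_loci(sds, 0.1)) == {"b", "c"}
    assert set(variable_loci(sds, 0.3)) == {"c"}
    assert len(variable_loci(sds, 0.1)) >= len(variable_loci(sds, 0.3))


class TestCrossTissueCorrelation:
    def test_perfect_and_inverse_correlation(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.1, 0.9, size=(3, 10))
        b = a.copy()
        b[1] = 1.0 - a[1]
        res = cross_tissue_probe_correlation(make_matched(a, b))
        assert res["cross_r"][0] == pytest.approx(1.0)
        assert res["cross_r"][1] == pytest.approx(-1.0)

    def test_null_tail_matches_analytic_expectation(self):
        """For independent tissues (n = 25), |r| > 0.5 should occur with the
        analytic two-sided tail probability of the null correlation."""
        rng = np.random.default_rng(6)
        n_probes, n = 998, 25
        a = rng.uniform(0.05, 0.95, size=(n_probes, n))
        b = rng.uniform(0.05, 0.95, size=(n_probes, n))
        res = cross_tissue_probe_correlation(make_matched(a, b))
        t = 0.5 * math.sqrt((n - 2) / (1 - 0.25))
        p_tail = 2 * stats.t.sf(t, df=n - 2)
        observed = (res["cross_r"].abs() > 0.5).mean()
        se = math.sqrt(p_tail * (1 - p_tail) / n_probes)
        assert abs(observed - p_tail) < 4 * se + 1e-3


def test_variability_table_consistency(default_run):
    table = default_run.variability_table
    assert (table["range_a"].between(0, 1)).all()
    assert (table["sd_a"] >= 0).all()
    ok = table["variance_ratio"].notna()
    np.testing.assert_allclose(
        table.loc[ok, "variance_ratio"],
        table.loc[ok, "var_t_b"] / table.loc[ok, "var_t_a"],
        rtol=1e-12,
    )
    within = table["concordance"] == "within_band"
    lo = 0.8 * table["var_t_a"]
    hi = 1.2 * table["var_t_a"]
    assert (table.loc[within, "var_t_b"].between(
        lo[within], hi[within])).all()
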