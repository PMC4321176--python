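"""Paired tests, BH adjustment, specificity classes, ICC, correlations."""

import math

import numpy as np
import pytest
from scipy import stats

from methmatch.datamodel import MatchedDataset
from methmatch.tissue import (bh_adjust, classify_specificity, global_tissue_test,
                              icc_oneway, methylation_category, paired_ttest,
                              samplewise_correlations)

from conftest import make_matched


class TestPairedTtest:
    def test_identical_pairs_null(self):
        x = np.array([0.1, 0.4, 0.9, 0.3])
        assert paired_ttest(x, x) == (0.0, 1.0)

    def test_constant_nonzero_difference(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        t, p = paired_ttest(x, x + 0.1)
        assert math.isinf(t) and t > 0
        assert 0 < p < 1e-300

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.uniform(0, 1, 25)
            y = rng.uniform(0, 1, 25)
            t, p = paired_ttest(x, y)
            ref = stats.ttest_rel(y, x)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
        assert paired_ttest(x, y) == pytest.approx(paired_ttest(x + 5, y + 5))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_ttest([0.1, 0.2], [0.2, 0.3])


def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} min(1, p_(j) m / j)."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * m / rank))
        q[i] = running
    return q


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.005, 0.5, 1.0), (0.015, 0.75, 1.0)),
            ((0.01, 0.02, 0.03), (0.03, 0.03, 0.03)),
            ((0.2, 0.2, 0.2), (0.2, 0.2, 0.2)),
        ],
    )
    def test_hand_computed(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for m in (1, 2, 5, 11, 20):
            p = rng.uniform(0, 1, m)
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)

    def test_output_dominates_input_and_monotone(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.uniform(0, 1, 50))
        q = bh_adjust(p)
        assert np.all(q >= p)
        assert np.all(np.diff(q) >= 0)


class TestSpecificityClasses:
    @pytest.mark.parametrize(
        "p,delta,expected",
        [
            (0.0005, 0.45, "highly_tissue_specific"),
            (0.0005, 0.25, "tissue_specific"),
            (0.01, 0.9, "none"),
            (0.0005, -0.45, "highly_tissue_specific"),
            (0.0005, 0.2, "none"),  # strict threshold
        ],
    )
    def test_examples(self, p, delta, expected):
        assert classify_specificity(p, delta) == expected

    def test_counts_monotone_in_delta_cutoff(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 0.002, 200)
        d = rng.uniform(-0.8, 0.8, 200)
        def count(cut):
            return sum(
                classify_specificity(pi, di, delta_threshold=cut) != "none"
                for pi, di in zip(p, d)
            )
        assert count(0.1) >= count(0.2) >= count(0.3)

    @pytest.mark.parametrize(
        "beta,expected",
        [(0.10, "hypomethylated"), (0.50, "heterogeneous"), (0.90, "hypermethylated"),
         (0.20, "heterogeneous"), (0.80, "heterogeneous")],
    )
    def test_methylation_category(self, beta, expected):
        assert methylation_category(beta) == expected


class TestICC:
    def test_perfect_subject_agreement(self):
        a = np.array([0.1, 0.5, 0.9])
        assert icc_oneway(a, a) == pytest.approx(1.0)

    def test_pure_tissue_offset(self):
        assert icc_oneway([0.2, 0.2], [0.8, 0.8]) == pytest.approx(-1.0)

    def test_undefined_when_constant(self):
        assert math.isnan(icc_oneway([0.3, 0.3], [0.3, 0.3]))

    def test_matches_anova_table_oracle(self):
        """Agreement with an explicit one-way ANOVA computed from scratch and
        with pingouin's one-way (ICC1) estimator on random 25 x 2 data."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(6)
        for _ in range(5):
            a = rng.uniform(0, 1, 25)
            b = rng.uniform(0, 1, 25)
            # long-hand ANOVA: subjects are groups with k = 2 ratings
            groups = [np.array([ai, bi]) for ai, bi in zip(a, b)]
            grand = np.mean(np.concatenate(groups))
            ssb = sum(2 * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            msb, msw = ssb / 24, ssw / 25
            expected = (msb - msw) / (msb + msw)
            assert icc_oneway(a, b) == pytest.approx(expected, rel=1e-12)

            long = pd.DataFrame({
                "subject": np.repeat(np.arange(25), 2),
                "rater": np.tile(["A", "B"], 25),
                "score": np.column_stack([a, b]).ravel(),
            })
            icc1 = pingouin.intraclass_corr(
                long, targets="subject", raters="rater", ratings="score"
            ).set_index("Type").at["ICC(1,1)", "ICC"]
            assert icc_oneway(a, b) == pytest.approx(icc1, rel=1e-6)

    def test_bounded_and_label_symmetric(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
            icc = icc_oneway(a, b)
            assert -1.0 <= icc <= 1.0
            assert icc == pytest.approx(icc_oneway(b, a), rel=1e-12)


class TestSamplewiseCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(8)
        beta = rng.uniform(0.05, 0.95, size=(30, 4))
        data = make_matched(beta, beta)
        summary = samplewise_correlations(data)
        np.testing.assert_allclose(summary.between, 1.0)

    def test_two_probe_hand_computed(self):
        # profiles over 2 probes; r computable long-hand
        a = np.array([[0.1, 0.2], [0.5, 0.8]])
        b = np.array([[0.2, 0.1], [0.6, 0.9]])
        data = make_matched(a, b)
        summary = samplewise_correlations(data)
        for j in range(2):
            x, y = a[:, j], b[:, j]
            num = ((x - x.mean()) * (y - y.mean())).sum()
            den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            assert summary.between[j] == pytest.approx(num / den, rel=1e-12)
        assert len(summary.within_a) == 1  # n(n-1)/2 pairs

    def test_lc_class_has_lowest_between_correlation(self, default_run):
        by_class = default_run.summary["correlations"]["between_by_class"]
        assert min(by_class, key=by_class.get) == "LC"


class TestGlobalTissueTest:
    def test_all_positive_differences_exact_p(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0.2, 0.4, size=(50, 25))
        data = make_matched(a, a + 0.05)
        res = global_tissue_test(data)
        # complete one-sided ranking: two-tailed exact p = 2 / 2^25
        assert res["p"] == pytest.approx(2 / 2**25, rel=1e-9)
        assert res["n_b_greater"] == 25

    def test_identical_tissues_undefined(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(0.2, 0.4, size=(50, 25))
        res = global_tissue_test(make_matched(a, a))
        assert res["defined"] is False

    def test_planted_global_offset_detected(self, default_run):
        assert default_run.global_test["p"] < 0.05
        assert default_run.global_test["n_b_greater"] > 12
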