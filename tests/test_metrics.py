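"""Agreement-statistics oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sps

from tiscout.metrics import (
    AgreementReport,
    accuracy_within,
    bland_altman,
    concordance_histogram,
    evaluate,
    lccc,
    mae_mse,
    rmar,
)


class TestAccuracyWithin:
    def test_identity_is_100(self):
        assert accuracy_within([300, 400], [300, 400]) == 100.0

    def test_one_in_one_out(self):
        assert accuracy_within([300, 400], [320, 460], threshold=50) == 50.0

    def test_boundary_counts_as_accurate(self):
        assert accuracy_within([350], [300], threshold=50) == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accuracy_within([1, 2], [1])


class TestMaeMse:
    def test_hand_arithmetic(self):
        mae, mse = mae_mse([290, 430], [300, 400])  # diffs -10, 30
        assert mae == 20.0 and mse == 500.0

    def test_identity_is_zero(self):
        assert mae_mse([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    @given(arrays(np.float64, st.integers(1, 30),
                  elements=st.floats(-1e3, 1e3)))
    @settings(max_examples=50, deadline=None)
    def test_mse_dominates_mae_squared(self, d):
        mae, mse = mae_mse(d, np.zeros_like(d))
        assert mse >= mae ** 2 - 1e-9


class TestLCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 3.0, 7.0])
        assert lccc(x, x) == pytest.approx(1.0)

    def test_constant_prediction_gives_zero(self):
        assert lccc([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # direct evaluation of Lin's formula with population moments:
        # x=[1,2,3], y=[2,3,4] -> 2*(2/3) / (2/3 + 2/3 + 1) = 4/7
        assert lccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4.0 / 7.0, rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lccc([1.0], [1.0])

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_magnitude_bounded_by_pearson(self, data):
        n = data.draw(st.integers(3, 40))
        x = np.array(data.draw(st.lists(st.floats(-100, 100), min_size=n, max_size=n)))
        y = np.array(data.draw(st.lists(st.floats(-100, 100), min_size=n, max_size=n)))
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
            return
        r = sps.pearsonr(x, y).statistic
        assert abs(lccc(x, y)) <= abs(r) + 1e-9


class TestBlandAltman:
    def test_identity_collapses(self):
        x = np.array([1.0, 2.0, 3.0])
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_constant_offset_collapses_limits(self):
        x = np.array([1.0, 2.0, 3.0])
        mean, lo, hi = bland_altman(x, x + 10)
        assert (mean, lo, hi) == (10.0, 10.0, 10.0)

    def test_mean_equals_mean_difference_exactly(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        mean, _, _ = bland_altman(x, y)
        assert mean == pytest.approx(np.mean(y) - np.mean(x), rel=1e-12)

    def test_limits_cover_about_95_percent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20_000)
        y = x + rng.normal(0.0, 5.0, size=20_000)
        _, lo, hi = bland_altman(x, y)
        d = y - x
        coverage = np.mean((d >= lo) & (d <= hi))
        assert coverage == pytest.approx(0.95, abs=0.01)


class TestRMAR:
    def test_recovers_exact_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept = rmar(x, 2 * x + 5)
        assert slope == pytest.approx(2.0, rel=1e-12)
        assert intercept == pytest.approx(5.0, rel=1e-12)

    def test_identity_gives_concordance_line(self):
        x = np.array([10.0, 20.0, 35.0])
        assert rmar(x, x) == pytest.approx((1.0, 0.0))

    def test_swap_inverts_slope(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 10, 30)
        y = 1.7 * x + rng.normal(0, 0.2, 30)
        s_xy, _ = rmar(x, y)
        s_yx, _ = rmar(y, x)
        assert s_xy == pytest.approx(1 / s_yx, rel=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        s1, _ = rmar(x, y)
        s2, _ = rmar(x, 3.0 * y)
        assert s2 == pytest.approx(3.0 * s1, rel=1e-9)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError):
            rmar([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestConcordanceHistogram:
    def test_counts_conserved(self):
        rng = np.random.default_rng(4)
        pred = rng.uniform(200, 500, 100)
        truth = rng.uniform(200, 500, 100)
        hist = concordance_histogram(pred, truth)
        assert hist.n == 100
        assert hist.bin_width == 25.0

    def test_identical_values_sit_on_diagonal(self):
        v = np.array([210.0, 260.0, 310.0])
        hist = concordance_histogram(v, v)
        assert np.trace(hist.counts) == 3

    def test_edge_value_goes_to_upper_bin(self):
        hist = concordance_histogram([50.0], [50.0], bin_width=25.0)
        # 50 sits on the edge between [25,50) and [50,75): upper bin
        assert hist.truth_edges[0] == 50.0
        assert hist.counts[0, 0] == 1

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            concordance_histogram([1.0], [1.0], bin_width=0.0)


class TestEvaluate:
    def test_perfect_agreement_row(self):
        x = np.array([250.0, 300.0, 350.0, 400.0])
        report = evaluate(x, x)
        assert report.accuracy_within_threshold == 100.0
        assert report.mae == 0.0 and report.mse == 0.0
        assert report.lccc == pytest.approx(1.0)
        assert (report.ba_mean, report.ba_lo, report.ba_hi) == (0.0, 0.0, 0.0)
        assert report.rmar_slope == pytest.approx(1.0)
        assert report.rmar_intercept == pytest.approx(0.0)
        assert report.n == 4

    def test_serialization_roundtrip(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(200, 400, 20)
        pred = truth + rng.normal(0, 20, 20)
        report = evaluate(pred, truth)
        assert AgreementReport.from_dict(report.to_dict()) == report

    def test_invariant_to_joint_reordering(self):
        rng = np.random.default_rng(6)
        truth = rng.uniform(200, 400, 30)
        pred = truth + rng.normal(0, 15, 30)
        perm = rng.permutation(30)
        a = evaluate(pred, truth).to_dict()
        b = evaluate(pred[perm], truth[perm]).to_dict()
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-9), key

    def test_report_orders_ba_limits(self):
        rng = np.random.default_rng(7)
        truth = rng.uniform(200, 400, 25)
        pred = truth + rng.normal(5, 30, 25)
        r = evaluate(pred, truth)
        assert r.ba_lo <= r.ba_mean <= r.ba_hi
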