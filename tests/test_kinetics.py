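import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gakinetics as gk
from oracles import nw_brute_force


class TestNadarayaWatson1D:
    def test_constant_response_returns_constant(self):
        x = np.array([0.1, 0.9, 2.3, 3.1])
        est = gk.nw_mean_1d(x, np.full(4, 0.7), np.linspace(0.1, 3.1, 20), 0.5)
        assert np.allclose(est.mean_v, 0.7)

    def test_symmetric_weights_average_out(self):
        est = gk.nw_mean_1d([0, 1, 2], [0, 10, 20], np.array([1.0]), 1.0)
        assert est.mean_v[0] == pytest.approx(10.0)

    def test_hand_computed_weighted_mean(self):
        # at g=0: weights 1, e^{-1/2}, e^{-2}
        est = gk.nw_mean_1d([0, 1, 2], [0, 10, 20], np.array([0.0]), 1.0)
        w = np.exp([-0.0, -0.5, -2.0])
        expected = (w @ [0, 10, 20]) / w.sum()
        assert est.mean_v[0] == pytest.approx(expected)
        assert est.mean_v[0] == pytest.approx(5.036, abs=5e-3)

    @pytest.mark.parametrize("topology", ["linear", "circular"])
    def test_matches_brute_force_double_loop(self, topology):
        rng = np.random.default_rng(42)
        for trial in range(5):
            n = rng.integers(5, 50)
            span = 360.0 if topology == "circular" else 3.0
            x = rng.uniform(0, span, n)
            v = rng.uniform(0, 1, n)
            grid = rng.uniform(0, span, 7)
            # keep every point within 5 sigma of every grid value so the
            # kernel truncation is inactive (exact-equality regime)
            sigma = span * rng.uniform(0.3, 0.6)
            est = gk.nw_mean_1d(x, v, grid, sigma, topology)
            oracle = nw_brute_force(x, v, grid, sigma, topology)
            assert np.allclose(est.mean_v, oracle, rtol=1e-12, atol=1e-12)

    def test_large_bandwidth_converges_to_global_mean(self):
        rng = np.random.default_rng(0)
        x, v = rng.uniform(0, 3, 200), rng.uniform(0, 1, 200)
        est = gk.nw_mean_1d(x, v, np.array([1.5]), 1e6)
        assert est.mean_v[0] == pytest.approx(v.mean(), rel=1e-6)

    def test_small_bandwidth_converges_to_pointwise_values(self):
        x = np.array([0.0, 1.0, 2.0])
        v = np.array([0.3, 0.6, 0.9])
        est = gk.nw_mean_1d(x, v, x, 1e-4)
        assert np.allclose(est.mean_v, v)

    def test_circular_wraps(self):
        x = np.array([5.0, 355.0])
        v = np.array([1.0, 3.0])
        est = gk.nw_mean_1d(x, v, np.array([0.0, 360.0]), 10.0, "circular")
        assert est.mean_v[0] == pytest.approx(est.mean_v[1])
        # rotation equivariance
        shift = 137.0
        est2 = gk.nw_mean_1d((x + shift) % 360, v, np.array([shift]), 10.0, "circular")
        assert est2.mean_v[0] == pytest.approx(est.mean_v[0])

    def test_empty_kernel_support_gives_nan(self):
        est = gk.nw_mean_1d([0.0], [1.0], np.array([100.0]), 1.0)
        assert np.isnan(est.mean_v[0])


class TestFundusMap:
    def test_constant_field_on_supported_cells(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(2.8, 3.2, size=(400, 2))
        fmap = gk.nw_mean_2d(pts, np.full(400, 0.15), np.linspace(2.5, 3.5, 11),
                             np.linspace(2.5, 3.5, 11), min_points=50)
        vals = fmap.mean_v[fmap.supported]
        assert len(vals) > 0 and np.allclose(vals, 0.15)

    def test_support_suppression(self):
        pts = np.tile([[3.0, 3.0]], (300, 1))
        grid = np.array([3.0, 4.0])
        fmap = gk.nw_mean_2d(pts, np.full(300, 0.2), grid, grid)
        assert fmap.supported[0, 0]  # 300 points within 250 um
        assert not fmap.supported[0, 1]  # 1 mm away: none within 250 um
        assert np.isnan(fmap.mean_v[0, 1])


class TestWeightedCounts:
    def test_single_point_single_eye(self):
        n, e = gk.weighted_counts([1.0], ["a"], np.array([1.0]), 0.125)
        assert n[0] == pytest.approx(1.0) and e[0] == pytest.approx(1.0)

    def test_two_eyes_one_point_each(self):
        n, e = gk.weighted_counts([1.0, 1.0], ["a", "b"], np.array([1.0]), 0.125)
        assert n[0] == pytest.approx(2.0) and e[0] == pytest.approx(2.0)

    def test_many_points_one_eye(self):
        n, e = gk.weighted_counts([1.0] * 100, ["a"] * 100, np.array([1.0]), 0.125)
        assert n[0] == pytest.approx(100.0) and e[0] == pytest.approx(1.0)

    def test_eye_count_bounded_by_eyes_and_points(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 3, 300)
        eyes = rng.choice(["a", "b", "c", "d"], 300)
        grid = np.linspace(0, 3, 40)
        n, e = gk.weighted_counts(x, eyes, grid, 0.125)
        assert np.all(e <= 4 + 1e-12)
        assert np.all(e <= n + 1e-12)


class TestHistogram:
    def test_density_sums_to_one(self):
        edges, dens = gk.histogram_pdf(np.array([0.002, 0.003, 0.007]))
        widths = np.diff(edges)
        assert (dens * widths).sum() == pytest.approx(1.0)
        assert dens[0] == pytest.approx(2 / (3 * 0.005))
        assert dens[1] == pytest.approx(1 / (3 * 0.005))

    def test_single_value(self):
        edges, dens = gk.histogram_pdf(np.array([0.004]))
        assert len(dens) == 1 and dens[0] == pytest.approx(1 / 0.005)

    def test_rejects_negative_or_empty(self):
        with pytest.raises(ValueError):
            gk.histogram_pdf(np.array([]))
        with pytest.raises(ValueError):
            gk.histogram_pdf(np.array([-0.1]))


class TestExponentialFit:
    def test_rate_is_reciprocal_mean(self):
        assert gk.fit_exponential(np.array([1.0, 2.0, 3.0])) == pytest.approx(0.5)
        assert gk.fit_exponential(np.array([0.2])) == pytest.approx(5.0)

    def test_mle_consistency_on_simulated_sample(self):
        rng = np.random.default_rng(7)
        v = rng.exponential(1 / 5.0, size=100_000)
        lam = gk.fit_exponential(v)
        se = 5.0 / np.sqrt(len(v))
        assert abs(lam - 5.0) < 3 * se + 0.02

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gk.fit_exponential(np.zeros(10))


class TestQQ:
    def test_exact_exponential_quantiles_on_identity_line(self):
        n, lam = 50, 2.0
        p = (np.arange(1, n + 1) - 0.5) / n
        v = -np.log(1 - p) / lam
        theo, emp = gk.qq_points(v, lam)
        assert np.allclose(theo, emp)

    def test_closed_form_small_n(self):
        theo, _ = gk.qq_points(np.array([0.1, 0.2, 0.3, 0.4]), 1.0)
        expected = -np.log([0.875, 0.625, 0.375, 0.125])
        assert np.allclose(theo, expected)

    def test_heavy_tail_rises_above_line(self):
        rng = np.random.default_rng(11)
        v = np.concatenate(
            [rng.exponential(1.0, 5000), rng.exponential(8.0, 500)]
        )
        theo, emp = gk.qq_points(v, gk.fit_exponential(v))
        k = int(0.995 * len(v))
        assert np.all(emp[k:] > theo[k:])


class TestBoxplot:
    def test_constant_bulk_flags_extreme(self):
        bs = gk.boxplot_stats(np.array([0, 0, 0, 0, 10.0]))
        assert bs.iqr == 0.0
        assert list(bs.outliers) == [10.0]

    def test_constant_data_has_no_outliers(self):
        bs = gk.boxplot_stats(np.full(20, 3.3))
        assert bs.iqr == 0.0 and len(bs.outliers) == 0
        assert bs.whisker_low == bs.whisker_high == 3.3

    def test_distant_point_is_outlier(self):
        v = np.concatenate([np.arange(1.0, 101.0), [1000.0]])
        bs = gk.boxplot_stats(v)
        assert list(bs.outliers) == [1000.0]
        assert bs.whisker_high <= 100.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=60))
    def test_outlier_rule_matches_definition(self, values):
        v = np.array(values)
        bs = gk.boxplot_stats(v)
        lo, hi = bs.q1 - 1.5 * bs.iqr, bs.q3 + 1.5 * bs.iqr
        expected = np.sort(v[(v < lo) | (v > hi)])
        assert np.array_equal(bs.outliers, expected)
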