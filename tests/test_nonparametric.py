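"""Weighted PAV monotonization and the modified Spearman-Karber estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import ternthresh as tt
from ternthresh.parametric import ttm_probabilities


def brute_force_isotonic(p, w):
    """Independent oracle: exhaustive search over all ordered partitions.

    Any weighted-least-squares monotone fit is piecewise constant with
    block values equal to block weighted means, so enumerating every
    composition of the index range into consecutive blocks (2^(n-1)
    candidates), keeping the monotone-feasible ones, and taking the
    minimum objective is an exact solution for small n.
    """
    from itertools import combinations

    p = np.asarray(p, float)
    w = np.asarray(w, float)
    n = len(p)
    best, best_obj = None, np.inf
    for k in range(n):
        for cuts in combinations(range(1, n), k):
            edges = [0, *cuts, n]
            q = np.empty(n)
            for lo, hi in zip(edges[:-1], edges[1:]):
                q[lo:hi] = np.average(p[lo:hi], weights=w[lo:hi])
            if np.all(np.diff(q) >= -1e-12):
                obj = float(np.sum(w * (q - p) ** 2))
                if obj < best_obj:
                    best, best_obj = q, obj
    return best


class TestPAV:
    def test_already_monotone_unchanged(self):
        p = np.array([0.0, 0.5, 1.0])
        np.testing.assert_allclose(tt.pav_monotonize(p, np.ones(3)), p)

    def test_pools_violating_pair(self):
        np.testing.assert_allclose(
            tt.pav_monotonize([0.2, 0.6, 0.4], np.ones(3)), [0.2, 0.5, 0.5]
        )

    def test_weighted_pooling(self):
        """(1, 0) with weights (1, 3) pools to (1*1 + 3*0)/4 = 0.25."""
        np.testing.assert_allclose(
            tt.pav_monotonize([1.0, 0.0], [1.0, 3.0]), [0.25, 0.25]
        )

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            tt.pav_monotonize([0.1, 0.2], [1.0, -1.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=5),
        st.data(),
    )
    def test_matches_brute_force_on_small_instances(self, p, data):
        w = data.draw(
            st.lists(
                st.floats(0.1, 20), min_size=len(p), max_size=len(p)
            )
        )
        got = tt.pav_monotonize(p, w)
        want = brute_force_isotonic(p, w)
        np.testing.assert_allclose(got, want, atol=1e-5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_idempotent_monotone_and_mean_preserving(self, p):
        w = np.ones(len(p))
        q = tt.pav_monotonize(p, w)
        assert np.all(np.diff(q) >= -1e-12)
        assert q.min() >= 0 and q.max() <= 1
        np.testing.assert_allclose(tt.pav_monotonize(q, w), q, atol=1e-12)
        # the overall weighted mean is preserved
        assert np.sum(w * q) == pytest.approx(np.sum(w * np.asarray(p)))

    def test_matches_sklearn_isotonic(self):
        sklearn_iso = pytest.importorskip("sklearn.isotonic")
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(15)
            w = rng.uniform(0.5, 30, 15)
            got = tt.pav_monotonize(p, w)
            want = sklearn_iso.IsotonicRegression().fit(
                np.arange(15), p, sample_weight=w
            ).predict(np.arange(15))
            np.testing.assert_allclose(got, want, atol=1e-10)


class TestSKMean:
    def test_single_jump_midpoint(self):
        """A 0->1 step between adjacent grid points d=10 and d=20 has mean 15."""
        d = np.array([0.0, 10.0, 20.0, 30.0])
        p = np.array([0.0, 0.0, 1.0, 1.0])
        assert tt.sk_mean(d, p, tt.SKConfig(-5.0, 35.0)) == pytest.approx(15.0)

    def test_gaussian_mean_recovered_within_discretization(self, exp1_grid):
        """Phi((d - 30)/50) on the +/-200 grid with +/-225 anchors -> ~30."""
        p = norm.cdf((exp1_grid - 30.0) / 50.0)
        assert tt.sk_mean(exp1_grid, p, tt.EXP1_SK) == pytest.approx(30.0, abs=2.0)

    def test_antisymmetric_function_has_zero_mean(self, exp1_grid):
        p = 1.0 / (1.0 + np.exp(-exp1_grid / 40.0))
        assert tt.sk_mean(exp1_grid, p, tt.EXP1_SK) == pytest.approx(0.0, abs=1e-9)

    def test_non_monotone_input_rejected(self):
        with pytest.raises(ValueError, match="not nondecreasing"):
            tt.sk_mean([0.0, 10.0, 20.0], [0.0, 0.5, 0.4], tt.SKConfig(-5, 25))

    def test_anchors_must_bracket_grid(self):
        with pytest.raises(ValueError, match="bracket"):
            tt.sk_mean([0.0, 10.0], [0.0, 1.0], tt.SKConfig(5.0, 25.0))
        with pytest.raises(ValueError, match="anchor_lo"):
            tt.SKConfig(10.0, -10.0)

    def test_shift_equivariance(self, exp1_grid):
        p = norm.cdf((exp1_grid - 10.0) / 60.0)
        base = tt.sk_mean(exp1_grid, p, tt.EXP1_SK)
        shifted = tt.sk_mean(
            exp1_grid + 100.0, p, tt.SKConfig(-125.0, 325.0)
        )
        assert shifted == pytest.approx(base + 100.0)


class TestSKThreshold:
    def test_half_difference_arithmetic(self):
        est = tt.SKEstimate("c", mean_R=80.0, mean_L=-40.0,
                            threshold=60.0, midpoint=20.0, anchors=(-225, 225))
        assert est.threshold == (est.mean_R - est.mean_L) / 2
        assert est.midpoint == (est.mean_R + est.mean_L) / 2

    def test_identical_functions_give_zero_threshold(self):
        counts = tt.ConditionCounts(
            "c", [-50.0, 0.0, 50.0], [2, 10, 18], [0, 0, 0], [18, 10, 2]
        )
        est = tt.sk_threshold(counts, tt.SKConfig(-100, 100))
        assert est.threshold == pytest.approx(0.0, abs=1e-12)

    def test_threshold_tracks_central_threshold_not_latency(self, exp1_grid):
        """Simulated observers with C = 50 ms and different mean latencies
        agree on the estimated threshold (the latency cancels out)."""
        rng = np.random.default_rng(42)
        ests = []
        for mu in (-60.0, 0.0, 60.0):
            p = ttm_probabilities(mu, 40.0, 50.0, 50.0, 0.5, exp1_grid)
            draws = np.array(
                [rng.multinomial(400, np.array(pi)) for pi in zip(*p)]
            )
            counts = tt.ConditionCounts(
                "c", exp1_grid, draws[:, 0], draws[:, 1], draws[:, 2]
            )
            ests.append(tt.sk_threshold(counts, tt.EXP1_SK).threshold)
        assert np.ptp(ests) < 3.0
        assert np.allclose(ests, 50.0, atol=3.0)

    def test_monotonized_functions_preserve_dominance(self, exp1_grid):
        """F_R <= F_L survives separate monotonization: with shared per-d
        weights the isotonic fit is an order-preserving operator, so the
        monotonized functions never cross (the crossing diagnostic in
        sk_threshold is a safety net only)."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.dirichlet((0.4, 0.4, 0.4), size=exp1_grid.size)
            n = rng.integers(5, 50)
            counts = tt.ConditionCounts(
                "c", exp1_grid, *(np.round(n * p.T))
            )
            keep = counts.totals > 0
            counts = tt.ConditionCounts(
                "c", exp1_grid[keep], counts.n_xy[keep],
                counts.n_si[keep], counts.n_yx[keep],
            )
            funcs = tt.empirical_functions(counts)
            w = counts.totals
            F_R = tt.pav_monotonize(funcs.F_R, w)
            F_L = tt.pav_monotonize(funcs.F_L, w)
            assert np.all(F_R <= F_L + 1e-12)

    def test_estimator_is_consistent(self, exp1_grid):
        """RMSE decreases as trials per d grow (50 -> 200 -> 800)."""
        rng = np.random.default_rng(1)
        p = ttm_probabilities(10.0, 40.0, 50.0, 50.0, 0.5, exp1_grid)
        p = np.stack(p, axis=1)
        rmse = []
        for n in (50, 200, 800):
            errs = []
            for _ in range(40):
                draws = np.array([rng.multinomial(n, pi) for pi in p])
                counts = tt.ConditionCounts(
                    "c", exp1_grid, draws[:, 0], draws[:, 1], draws[:, 2]
                )
                errs.append(tt.sk_threshold(counts, tt.EXP1_SK).threshold - 50.0)
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmse[0] > rmse[1] > rmse[2]

    def test_invariance_conclusion_robust_to_anchor_placement(self, exp1_grid):
        """The sign of the threshold difference between a C=100 and a C=25
        observer is stable for anchors perturbed +/-25 ms around +/-225."""
        rng = np.random.default_rng(3)
        counts = {}
        for label, c in (("high", 100.0), ("low", 25.0)):
            p = np.stack(
                ttm_probabilities(20.0, 40.0, c, c, 0.5, exp1_grid), axis=1
            )
            draws = np.array([rng.multinomial(400, pi) for pi in p])
            counts[label] = tt.ConditionCounts(
                label, exp1_grid, draws[:, 0], draws[:, 1], draws[:, 2]
            )
        for shift in (-20.0, 0.0, 25.0):
            cfg = tt.SKConfig(-225.0 - shift, 225.0 + shift)
            diff = (
                tt.sk_threshold(counts["high"], cfg).threshold
                - tt.sk_threshold(counts["low"], cfg).threshold
            )
            assert diff > 50.0
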