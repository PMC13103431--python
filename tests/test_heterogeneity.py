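import numpy as np
import pytest

import oracles
from npqcell.experiments import repeat_pair, spawn_seeds
from npqcell.heterogeneity import (affine_trend, centroid_trend, grid_traces,
                                   repeat_distance_matrix,
                                   variance_difference_test,
                                   variation_coefficient)
from npqcell.npqspace import ScoreSet, score_traces
from npqcell.simulate import default_population_spec, simulate_population

from conftest import MASTER_SEED


def _score_set(arr, labels=None):
    arr = np.asarray(arr, dtype=float)
    return ScoreSet(scores=arr, cell_ids=list(range(len(arr))),
                    labels=labels or ["x"] * len(arr))


class TestRepeatDistances:
    def test_identical_repeats_zero_diagonal(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(20, 3))
        res = repeat_distance_matrix(s, s)
        np.testing.assert_array_equal(res.D_ii, 0.0)

    def test_hand_computed_two_cells(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        res = repeat_distance_matrix(a, a)
        np.testing.assert_allclose(res.D, [[0, 1], [1, 0]])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 3))
        res = repeat_distance_matrix(a, b)
        np.testing.assert_allclose(res.D, oracles.brute_distance_matrix(a, b),
                                   atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            repeat_distance_matrix(np.ones((4, 3)), np.ones((5, 3)))

    def test_noise_vs_heterogeneity_contrast(self, trained):
        """With repeat jitter well below the population spread, D_ii is
        much narrower than D_ij; with no amplitude dispersion the two
        distributions have similar widths."""
        model, _ = trained
        seed = spawn_seeds(MASTER_SEED, 5)[4]
        a, b = repeat_pair(seed, population="PopQT", n_cells=150)
        sa = score_traces(a.traces, model)
        sb = score_traces(b.traces, model)
        res = repeat_distance_matrix(sa, sb)
        assert res.sd_ratio <= 0.6
        assert res.p_value < 0.01
        # dispersion-free population: same cells, spread only by noise
        spec = default_population_spec("PopQT", 150, seed=seed)
        spec = type(spec)(label=spec.label, n_cells=150,
                          amplitude_medians={"qT": 0.30},
                          amplitude_cv={"qT": 0.0},
                          noise_sigma=0.02, seed=seed)
        from npqcell.simulate import simulate_repeat_pair
        from npqcell.protocol import build_reference_protocol
        a0, b0 = simulate_repeat_pair(spec, build_reference_protocol())
        r0 = repeat_distance_matrix(score_traces(a0.traces, model),
                                    score_traces(b0.traces, model))
        assert r0.sd_ratio > 0.6


class TestVarianceTest:
    def test_identical_samples(self):
        s = np.random.default_rng(0).normal(size=100)
        stat, p = variance_difference_test(s, s)
        assert stat < 1e-20 and p > 0.99

    def test_detects_different_variances(self):
        rng = np.random.default_rng(1)
        s1 = rng.normal(0, 1, size=200)
        s2 = rng.normal(0, 3, size=200)
        _, p = variance_difference_test(s1, s2)
        assert p < 0.001

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        s1, s2 = rng.normal(size=50), rng.normal(scale=2, size=50)
        stat1, _ = variance_difference_test(s1, s2)
        stat2, _ = variance_difference_test(10 * s1, 10 * s2)
        assert np.isclose(stat1, stat2)

    def test_f_test_variant(self):
        rng = np.random.default_rng(3)
        s1 = rng.normal(0, 1, size=100)
        s2 = rng.normal(0, 2, size=100)
        stat, p = variance_difference_test(s1, s2, method="f")
        assert p < 0.01

    def test_degenerate_samples_raise(self):
        with pytest.raises(ValueError):
            variance_difference_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestVariationCoefficient:
    def test_constant_scores_zero(self):
        s = _score_set(np.tile([1.0, 2.0, 3.0], (10, 1)))
        assert variation_coefficient(s, "qT") == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        arr = np.abs(rng.normal(1, 0.2, size=(50, 3))) + 0.5
        cv1 = variation_coefficient(_score_set(arr), "qE")
        cv2 = variation_coefficient(_score_set(3.7 * arr), "qE")
        assert np.isclose(cv1, cv2)

    def test_propagates_generator_dispersion(self, trained, protocol):
        """The q̃T score CV tracks the planted 20% amplitude CV; the
        mildly concave score response compresses it slightly."""
        model, _ = trained
        for seed in (201, 202, 203):
            ts = simulate_population(
                default_population_spec("PopQT", 300, seed=seed,
                                        noise_sigma=0.005), protocol)
            s = score_traces(ts.traces, model, labels=ts.labels)
            amps = np.array([g.A_qT for g in ts.ground_truth])
            cv_amp = amps.std(ddof=1) / amps.mean()
            cv_score = variation_coefficient(s, "qT")
            assert 0.7 * cv_amp <= cv_score <= 1.1 * cv_amp

    def test_non_positive_mean_raises(self):
        s = _score_set(np.full((10, 3), -1.0))
        with pytest.raises(ValueError):
            variation_coefficient(s, "qT")


class TestGridTraces:
    def test_min_count_rule(self):
        # 4 identical points in one box get a trace, 3 in another do not
        pts = np.array([[0.1, 0.1]] * 4 + [[0.9, 0.9]] * 3)
        traces = np.ones((7, 10))
        gmap = grid_traces(pts, traces, bounds=(0, 1, 0, 1), grid_n=8,
                           min_count=3)
        occupied = [k for k, _ in gmap.mean_traces.items()]
        assert len(occupied) == 1
        assert gmap.counts.sum() == 7

    def test_empty_input(self):
        gmap = grid_traces(np.empty((0, 2)), np.empty((0, 5)))
        assert gmap.counts.sum() == 0 and not gmap.mean_traces

    def test_counts_conserved_under_permutation(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(200, 2))
        traces = rng.uniform(1, 2, size=(200, 7))
        g1 = grid_traces(pts, traces, bounds=(0, 1, 0, 1))
        perm = rng.permutation(200)
        g2 = grid_traces(pts[perm], traces[perm], bounds=(0, 1, 0, 1))
        np.testing.assert_array_equal(g1.counts, g2.counts)
        assert g1.counts.sum() == 200

    def test_mean_traces_start_at_one(self):
        rng = np.random.default_rng(6)
        pts = np.tile([[0.5, 0.5]], (10, 1))
        traces = rng.uniform(1, 3, size=(10, 12))
        gmap = grid_traces(pts, traces, bounds=(0, 1, 0, 1))
        (trace,) = gmap.mean_traces.values()
        assert np.isclose(trace[0], 1.0)


class TestAffineTrend:
    def test_exact_line(self):
        x = np.linspace(-2, 3, 40)
        fit = affine_trend(np.column_stack([x, 2 * x + 1]))
        assert np.isclose(fit.slope, 2.0)
        assert np.isclose(fit.intercept, 1.0)
        assert np.isclose(fit.r, 1.0)

    def test_isotropic_null(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(500, 2))
        fit = affine_trend(pts)
        assert abs(fit.r) < 0.15

    def test_ols_variant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = 1.5 * x + rng.normal(scale=0.1, size=200)
        fit = affine_trend(np.column_stack([x, y]), method="ols")
        assert abs(fit.slope - 1.5) < 0.05

    def test_recovers_planted_anticorrelation(self, trained, protocol):
        """WT cells drawn with anticorrelated (A_qE, A_qT) show a clear
        negative score-space correlation."""
        from npqcell.simulate import (CellParams, component_bases,
                                      simulate_trace)
        model, _ = trained
        bases = component_bases(protocol)
        rs = []
        for seed in (301, 302, 303):
            rng = np.random.default_rng(seed)
            cov = np.array([[1.0, -0.8], [-0.8, 1.0]])
            z = rng.multivariate_normal([0, 0], cov, size=200)
            traces = []
            for zE, zT in z:
                c = CellParams(A_qE=0.35 * np.exp(0.3 * zE),
                               A_qT=0.30 * np.exp(0.2 * zT),
                               noise_sigma=0.02)
                traces.append(simulate_trace(c, protocol, bases, rng))
            s = score_traces(np.stack(traces), model)
            fit = affine_trend(np.column_stack([s.axis("qT"),
                                                s.axis("qE")]))
            rs.append(fit.r)
            assert fit.r <= -0.55
        assert np.mean(rs) <= -0.6

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            affine_trend(np.ones((2, 2)))


class TestCentroidTrend:
    def test_collinear_centroids(self):
        rng = np.random.default_rng(9)
        sets = []
        for k in range(4):
            center = np.array([k * 1.0, 2 - k * 0.5])
            pts = center + 0.01 * rng.normal(size=(30, 2))
            arr = np.column_stack([pts, np.zeros(30)])
            sets.append(_score_set(arr[:, [0, 1, 2]]))
        fit = centroid_trend(sets)
        assert np.isclose(fit.slope, -0.5, atol=0.01)
        assert abs(fit.r) > 0.999

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        sets = [_score_set(rng.normal(size=(20, 3)) + k) for k in range(4)]
        f1 = centroid_trend(sets)
        f2 = centroid_trend(sets[::-1])
        assert np.isclose(f1.slope, f2.slope)
        assert np.isclose(f1.intercept, f2.intercept)

    def test_hl_activation_series_negative_slope(self, trained, protocol):
        """A progressive high-light activation series (qE median rising,
        qT median falling) traces a negative slope in the (q̃T, q̃E)
        plane."""
        from npqcell.simulate import PopulationSpec, PopulationLabel, \
            simulate_population
        model, _ = trained
        sets = []
        for k, (mE, mT) in enumerate([(0.05, 0.40), (0.15, 0.33),
                                      (0.28, 0.26), (0.38, 0.20)]):
            spec = PopulationSpec(label=PopulationLabel.WT, n_cells=150,
                                  amplitude_medians={"qE": mE, "qT": mT},
                                  amplitude_cv={"qE": 0.35, "qT": 0.2},
                                  noise_sigma=0.02, seed=400 + k)
            ts = simulate_population(spec, protocol)
            sets.append(score_traces(ts.traces, model))
        fit = centroid_trend(sets)
        assert fit.slope < 0
        assert fit.angle_to is not None

    def test_too_few_time_points_raise(self):
        with pytest.raises(ValueError):
            centroid_trend([_score_set(np.ones((5, 3)))] * 2)
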