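"""Mean-shift core: density, shift vector, mode seeking, mode merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islandshift.mean_shift import (
    Clustering,
    IsolatedPointError,
    MeanShiftConfig,
    ModeResult,
    cluster_modes,
    density_estimate,
    get_kernel,
    max_pairwise_distance,
    mean_shift_vector,
    run_mean_shift,
    shift_to_mode,
)

GAUSS = get_kernel("gaussian")
FLAT = get_kernel("flat")


def partition_sets(labels):
    """A clustering as a set of frozensets of point indices."""
    return {frozenset(np.nonzero(labels == c)[0].tolist())
            for c in np.unique(labels)}


class TestDensityEstimate:
    def test_single_point_at_zero_distance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        val = density_estimate(x, [x], GAUSS, h=2.0)
        assert val == pytest.approx(GAUSS.c_kd / 2.0**4)

    def test_flat_kernel_covers_all_points(self):
        x = np.zeros(4)
        data = np.array([[0.1, 0, 0, 0], [0, -0.3, 0, 0], [0, 0, 0.2, 0]])
        val = density_estimate(x, data, FLAT, h=1.0)
        assert val == pytest.approx(FLAT.c_kd)  # n*K(≤1)/(n*h^d)

    def test_matches_brute_force_summation(self):
        # three collinear points embedded in 4-d
        data = np.array([[t, 0, 0, 0] for t in (-1.0, 0.0, 2.5)])
        x = np.array([0.7, 0, 0, 0])
        h = 0.8
        expected = sum(
            GAUSS.c_kd * np.exp(-0.5 * np.sum(((x - xi) / h) ** 2))
            for xi in data
        ) / (len(data) * h**4)
        assert density_estimate(x, data, GAUSS, h) == pytest.approx(
            expected, abs=1e-12)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            density_estimate(np.zeros(4), np.empty((0, 4)), GAUSS, 1.0)


class TestMeanShiftVector:
    def test_zero_at_centroid_flat_kernel(self):
        data = np.array([[1, 0, 0, 0], [-1, 0, 0, 0],
                         [0, 1, 0, 0], [0, -1, 0, 0]], dtype=float)
        m = mean_shift_vector(np.zeros(4), data, FLAT, h=2.0)
        assert np.allclose(m, 0.0)

    def test_single_point_pulls_exactly(self):
        p = np.array([3.0, 1.0, -2.0, 0.5])
        x = np.array([1.0, 1.0, 1.0, 1.0])
        for kern in (GAUSS, FLAT):
            assert np.allclose(mean_shift_vector(x, [p], kern, h=10.0), p - x)

    def test_matches_weighted_mean_formula(self, rng):
        data = rng.normal(size=(10, 4))
        x = rng.normal(size=4)
        h = 1.0
        w = np.array([0.5 * np.exp(-0.5 * np.sum(((x - xi) / h) ** 2))
                      for xi in data])
        expected = (w[:, None] * data).sum(axis=0) / w.sum() - x
        assert np.allclose(mean_shift_vector(x, data, GAUSS, h), expected,
                           atol=1e-12)

    def test_isolated_point_signalled(self):
        data = np.array([[100.0, 0, 0, 0]])
        with pytest.raises(IsolatedPointError):
            mean_shift_vector(np.zeros(4), data, FLAT, h=1.0)


class TestShiftToMode:
    def test_point_already_at_mode(self):
        data = np.array([[0.0, 0, 0, 0], [2.0, 0, 0, 0]])
        x0 = np.array([1.0, 0, 0, 0])  # symmetric: zero shift
        res = shift_to_mode(x0, data, GAUSS,
                            MeanShiftConfig(bandwidth=5.0, epsilon=1e-6))
        assert res.converged and res.iterations <= 1
        assert np.allclose(res.mode, x0, atol=1e-6)

    def test_mode_stays_within_local_blob(self, rng):
        a = rng.normal(0.0, 0.1, size=(20, 4))
        b = rng.normal(50.0, 0.1, size=(20, 4))
        data = np.vstack([a, b])
        res = shift_to_mode(a[0], data, GAUSS,
                            MeanShiftConfig(bandwidth=1.0))
        assert np.linalg.norm(res.mode - a.mean(axis=0)) < 1.0

    def test_mode_matches_grid_search_argmax(self):
        # 1-d mixture embedded on the first axis: compare the converged
        # mode against a dense-grid argmax of the same KDE
        pts = np.array([0.0, 0.15, -0.2, 0.05, 4.0, 4.1])
        data = np.zeros((len(pts), 4))
        data[:, 0] = pts
        h = 0.5
        cfg = MeanShiftConfig(bandwidth=h, epsilon=1e-9, max_iterations=2000)
        res = shift_to_mode(data[0], data, GAUSS, cfg)
        grid = np.linspace(-1.0, 1.0, 4001)
        dens = [density_estimate(np.array([t, 0, 0, 0]), data, GAUSS, h)
                for t in grid]
        argmax = grid[int(np.argmax(dens))]
        assert res.converged
        assert res.mode[0] == pytest.approx(argmax, abs=1e-3)
        assert np.allclose(res.mode[1:], 0.0, atol=1e-6)

    def test_density_never_decreases_along_trajectory(self, rng):
        """Gaussian mean-shift is a monotone ascent on the estimated density."""
        data = rng.normal(size=(30, 4)) * 2.0
        cfg = MeanShiftConfig(bandwidth=1.5, epsilon=1e-8,
                              max_iterations=1000)
        for x0 in data[:10]:
            x = x0.copy()
            prev = density_estimate(x, data, GAUSS, cfg.bandwidth)
            for _ in range(cfg.max_iterations):
                shift = mean_shift_vector(x, data, GAUSS, cfg.bandwidth)
                x = x + shift
                cur = density_estimate(x, data, GAUSS, cfg.bandwidth)
                assert cur >= prev * (1 - 1e-9)
                prev = cur
                if np.linalg.norm(shift) < cfg.epsilon:
                    break

    def test_nonconvergence_flagged_not_raised(self):
        data = np.array([[0.0, 0, 0, 0], [10.0, 0, 0, 0]])
        cfg = MeanShiftConfig(bandwidth=8.0, epsilon=1e-15, max_iterations=3)
        res = shift_to_mode(data[0], data, GAUSS, cfg)
        assert not res.converged and res.iterations == 3


def _mode_results(vectors):
    return [ModeResult(start_point=v, mode=np.asarray(v, float),
                       iterations=1, converged=True) for v in vectors]


class TestClusterModes:
    def test_identical_modes_one_cluster(self):
        cl = cluster_modes(_mode_results([[1, 1, 1, 1]] * 5), merge_radius=0.1)
        assert cl.n_clusters == 1 and np.all(cl.labels == 0)

    def test_far_modes_separate_clusters(self):
        cl = cluster_modes(_mode_results([[0, 0, 0, 0], [99, 0, 0, 0]]),
                           merge_radius=1.0)
        assert cl.n_clusters == 2 and list(cl.labels) == [0, 1]

    def test_chain_merges_by_single_linkage_transitivity(self):
        r = 1.0
        chain = [[i * r / 2, 0, 0, 0] for i in range(6)]
        # each consecutive pair is r/2 < r apart, ends are 2.5r apart
        assert np.linalg.norm(np.array(chain[0]) - chain[-1]) > r
        cl = cluster_modes(_mode_results(chain), merge_radius=r)
        assert cl.n_clusters == 1

    def test_cluster_ids_follow_first_occurrence(self):
        cl = cluster_modes(
            _mode_results([[50, 0, 0, 0], [0, 0, 0, 0], [50, 0, 0, 0]]),
            merge_radius=1.0)
        assert list(cl.labels) == [0, 1, 0]


class TestRunMeanShift:
    def test_identical_points_one_cluster(self):
        data = np.ones((8, 4))
        cl = run_mean_shift(data, GAUSS, MeanShiftConfig(bandwidth=1.0))
        assert cl.n_clusters == 1

    def test_two_blobs_recovered(self, rng):
        h = 1.0
        a = rng.normal(0, 0.2, size=(20, 4))
        b = rng.normal(100 * h, 0.2, size=(20, 4))
        data = np.vstack([a, b])
        cl = run_mean_shift(data, GAUSS, MeanShiftConfig(bandwidth=h))
        assert cl.n_clusters == 2
        assert partition_sets(cl.labels) == {
            frozenset(range(20)), frozenset(range(20, 40))}

    def test_flat_kernel_global_window_one_cluster(self, rng):
        data = rng.normal(size=(15, 4))
        h = max_pairwise_distance(data) * 1.5
        cl = run_mean_shift(data, FLAT, MeanShiftConfig(bandwidth=h))
        assert cl.n_clusters == 1

    def test_bandwidth_limits(self, rng):
        data = rng.normal(size=(12, 4)) * 5
        big = run_mean_shift(data, GAUSS, MeanShiftConfig(bandwidth=1e6))
        assert big.n_clusters == 1
        tiny = run_mean_shift(data, GAUSS, MeanShiftConfig(bandwidth=1e-6))
        assert tiny.n_clusters == len(data)

    def test_permutation_invariance(self, rng):
        data = np.vstack([rng.normal(0, 0.3, size=(10, 4)),
                          rng.normal(8, 0.3, size=(10, 4))])
        perm = rng.permutation(len(data))
        cfg = MeanShiftConfig(bandwidth=1.0)
        base = run_mean_shift(data, GAUSS, cfg)
        shuf = run_mean_shift(data[perm], GAUSS, cfg)
        remapped = {frozenset(int(perm[i]) for i in grp)
                    for grp in partition_sets(shuf.labels)}
        assert partition_sets(base.labels) == remapped

    def test_cluster_mass_totals_genome_length(self, rng):
        data = rng.normal(size=(10, 4))
        masses = [50_000] * 9 + [31_000]
        cl = run_mean_shift(data, GAUSS, MeanShiftConfig(bandwidth=0.5),
                            masses=masses)
        assert cl.cluster_mass is not None
        assert int(cl.cluster_mass.sum()) == sum(masses)

    def test_agrees_with_sklearn_flat_kernel(self, rng):
        """Flat-kernel partitions match scikit-learn's MeanShift (an
        independent flat-kernel implementation) on separated blobs."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        for trial in range(5):
            k = int(rng.integers(2, 4))
            centers = rng.uniform(-50, 50, size=(k, 4))
            # enforce generous separation
            if min(np.linalg.norm(c1 - c2)
                   for i, c1 in enumerate(centers)
                   for c2 in centers[i + 1:]) < 25:
                continue
            data = np.vstack([
                c + rng.normal(0, 0.5, size=(12, 4)) for c in centers])
            h = 5.0
            mine = run_mean_shift(data, FLAT, MeanShiftConfig(bandwidth=h))
            ref = sklearn_cluster.MeanShift(bandwidth=h, bin_seeding=False)
            ref.fit(data)
            assert partition_sets(mine.labels) == partition_sets(ref.labels_)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=15)
def test_clustering_is_a_partition(seed):
    """Every point gets exactly one label; label count equals mode count."""
    rng = np.random.default_rng(seed)
    data = rng.uniform(0, 10, size=(rng.integers(3, 25), 4))
    cl = run_mean_shift(data, GAUSS, MeanShiftConfig(bandwidth=2.0))
    assert cl.labels.shape == (len(data),)
    assert set(np.unique(cl.labels)) == set(range(cl.n_clusters))
    assert len(cl.modes) == cl.n_clusters
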