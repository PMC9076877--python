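"""k-means classification, transformed divergence, and the merge loop."""

import numpy as np
import pytest

from drusemap.clustering import (
    ClassStatistics,
    ClusteringConfig,
    MultispectralStack,
    class_statistics,
    cluster_with_separability,
    kmeans_fit,
    merge_least_separable,
    transformed_divergence,
)
from drusemap.errors import ValidationError


def stats(mean, cov, n=100, cid=0):
    return ClassStatistics(
        class_id=cid,
        mean=np.asarray(mean, float),
        covariance=np.asarray(cov, float),
        pixel_count=n,
    )


def brute_force_two_means(X):
    """Exhaustive optimal 2-partition by SSE over <= 12 points."""
    n = len(X)
    best, best_sse = None, np.inf
    for code in range(1, 2**n - 1):
        labels = np.array([(code >> i) & 1 for i in range(n)])
        sse = 0.0
        for g in (0, 1):
            pts = X[labels == g]
            sse += ((pts - pts.mean(axis=0)) ** 2).sum()
        if sse < best_sse:
            best_sse, best = sse, labels
    return best


class TestKmeansFit:
    def test_two_separated_clouds_match_brute_force_optimum(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [
                rng.normal([0.2, 0.2, 0.2], 0.02, size=(6, 3)),
                rng.normal([0.8, 0.8, 0.8], 0.02, size=(6, 3)),
            ]
        )
        stack = MultispectralStack(X.reshape(3, 4, 3), np.ones((3, 4), bool))
        tm = kmeans_fit(stack, 2, config=ClusteringConfig(min_threshold=0.0))
        got = tm.labels[stack.mask]
        want = brute_force_two_means(X)
        # same partition up to label swap
        agree = np.mean(got == want)
        assert agree in (0.0, 1.0)

    def test_identical_pixels_collapse_to_single_cluster(self):
        stack = MultispectralStack(np.full((4, 4, 3), 0.5), np.ones((4, 4), bool))
        tm = kmeans_fit(stack, 2)
        assert tm.k == 1
        assert tm.classes[0].pixel_count == 16

    def test_fixed_seed_reproducible(self, two_population_stack):
        stack, _ = two_population_stack
        cfg = ClusteringConfig(seed=7)
        a = kmeans_fit(stack, 4, config=cfg)
        b = kmeans_fit(stack, 4, config=cfg)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k_out_of_range_rejected(self, two_population_stack):
        stack, _ = two_population_stack
        with pytest.raises(ValidationError):
            kmeans_fit(stack, 0)
        with pytest.raises(ValidationError):
            kmeans_fit(stack, stack.pixels.shape[0] + 1)


class TestClassStatistics:
    def test_identical_pixels_give_ridge_covariance(self):
        stack = MultispectralStack(np.full((2, 3, 3), 0.4), np.ones((2, 3), bool))
        labels = np.zeros((2, 3), dtype=int)
        (cs,) = class_statistics(stack, labels)
        np.testing.assert_allclose(cs.mean, 0.4)
        np.testing.assert_allclose(cs.covariance, 1e-6 * np.eye(3), atol=1e-12)

    def test_two_pixel_class_hand_computed(self):
        channels = np.array([[[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]])
        stack = MultispectralStack(channels, np.ones((1, 2), bool))
        (cs,) = class_statistics(stack, np.zeros((1, 2), int))
        np.testing.assert_allclose(cs.mean, [0.5, 0.5, 0.5])
        assert cs.small_sample  # 2 < 4 pixels: diagonal fallback
        np.testing.assert_allclose(np.diag(cs.covariance), 0.25 + 1e-6)

    def test_invariant_to_pixel_order(self, two_population_stack):
        stack, truth = two_population_stack
        a = class_statistics(stack, truth)
        # rebuild with rows permuted (same label<->pixel association)
        perm = np.random.default_rng(0).permutation(stack.mask.shape[0])
        stack2 = MultispectralStack(stack.channels[perm], stack.mask[perm])
        b = class_statistics(stack2, truth[perm])
        for ca, cb in zip(a, b):
            np.testing.assert_allclose(ca.mean, cb.mean)
            np.testing.assert_allclose(ca.covariance, cb.covariance, atol=1e-12)


class TestTransformedDivergence:
    def test_identical_statistics_zero(self):
        a = stats([0.1, 0.2, 0.3], np.eye(3) * 0.01)
        assert transformed_divergence(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_univariate_closed_form_embedding(self):
        # unit-variance, unit mean shift along one axis: D = 1,
        # D_T = 2 (1 - e^{-1/8}) ~= 0.23500
        a = stats([0.0, 0.0, 0.0], np.eye(3))
        b = stats([1.0, 0.0, 0.0], np.eye(3), cid=1)
        dt = transformed_divergence(a, b)
        assert dt == pytest.approx(2 * (1 - np.exp(-1 / 8)), abs=1e-9)
        assert dt == pytest.approx(0.2350, abs=5e-5)

    def test_saturates_at_two_for_huge_separation(self):
        a = stats([0.0, 0.0, 0.0], np.eye(3))
        b = stats([100.0, 0.0, 0.0], np.eye(3), cid=1)
        dt = transformed_divergence(a, b)
        assert dt <= 2.0
        assert dt >= 1.999

    def test_symmetric_and_bounded_on_random_stats(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m1, m2 = rng.normal(size=3), rng.normal(size=3)
            a1 = rng.normal(size=(3, 3))
            a2 = rng.normal(size=(3, 3))
            c1 = a1 @ a1.T + 0.01 * np.eye(3)
            c2 = a2 @ a2.T + 0.01 * np.eye(3)
            d_ab = transformed_divergence(stats(m1, c1), stats(m2, c2, cid=1))
            d_ba = transformed_divergence(stats(m2, c2, cid=1), stats(m1, c1))
            assert d_ab == pytest.approx(d_ba, rel=1e-10)
            assert 0.0 <= d_ab <= 2.0


class TestMergeSelection:
    def _theme_map_with_td(self, td_pairs, counts):
        """Build a minimal ThemeMap stand-in for merge selection."""
        from drusemap.clustering import ThemeMap

        k = len(counts)
        classes = [
            stats([float(i), 0, 0], np.eye(3) * 0.01, n=counts[i], cid=i)
            for i in range(k)
        ]
        td = np.zeros((k, k))
        for (i, j), v in td_pairs.items():
            td[i, j] = td[j, i] = v
        labels = np.zeros((1, sum(counts)), dtype=int)
        col = 0
        for i, n in enumerate(counts):
            labels[0, col : col + n] = i
            col += n
        mask = np.ones_like(labels, dtype=bool)
        return ThemeMap(labels=labels, classes=classes, mask=mask, pairwise_td=td)

    def test_lowest_td_pair_selected(self):
        tm = self._theme_map_with_td(
            {(0, 1): 0.2, (0, 2): 1.8, (1, 2): 1.9}, [10, 20, 30]
        )
        (pair, _) = merge_least_separable(tm)
        assert pair == (0, 1)

    def test_tie_breaks_to_lowest_id_pair(self):
        tm = self._theme_map_with_td(
            {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 1.9}, [10, 20, 30]
        )
        (pair, _) = merge_least_separable(tm)
        assert pair == (0, 1)

    def test_merged_centroid_is_count_weighted_mean(self):
        tm = self._theme_map_with_td({(0, 1): 0.1, (0, 2): 1.9, (1, 2): 1.8}, [10, 30, 5])
        (pair, centroids) = merge_least_separable(tm)
        m0, m1 = tm.classes[0].mean, tm.classes[1].mean
        np.testing.assert_allclose(centroids[0], (10 * m0 + 30 * m1) / 40)
        assert centroids.shape == (2, 3)

    def test_single_class_is_noop(self):
        tm = self._theme_map_with_td({}, [10])
        assert merge_least_separable(tm) is None


class TestSeparabilityLoop:
    def test_two_planted_populations_recovered(self, two_population_stack):
        stack, truth = two_population_stack
        cfg = ClusteringConfig(k_init=8, seed=0)
        tm = cluster_with_separability(stack, cfg)
        assert tm.k == 2
        got = tm.labels[stack.mask]
        want = truth[stack.mask]
        acc = max(np.mean(got == want), np.mean(got == 1 - want))
        assert acc >= 0.99

    def test_homogeneous_noise_collapses_to_k_floor(self):
        rng = np.random.default_rng(1)
        channels = 0.5 + rng.normal(0, 0.02, size=(24, 24, 3))
        stack = MultispectralStack(np.clip(channels, 0, 1), np.ones((24, 24), bool))
        tm = cluster_with_separability(stack, ClusteringConfig(k_init=8, seed=0))
        assert tm.k == tm.k_trajectory[-1] == 2
        assert tm.exit_condition == "k_floor"

    def test_default_k_init_is_16_and_honored(self):
        cfg = ClusteringConfig()
        assert cfg.k_init == 16
        rng = np.random.default_rng(2)
        channels = rng.uniform(size=(20, 20, 3))
        stack = MultispectralStack(channels, np.ones((20, 20), bool))
        tm = cluster_with_separability(stack, cfg)
        assert tm.k_trajectory[0] <= 16

    @pytest.mark.parametrize("seed", range(10))
    def test_contract_on_random_stacks(self, seed):
        """Termination bound, strictly decreasing k, and the exit condition:
        all pairs separable XOR floor reached."""
        rng = np.random.default_rng(seed)
        k_init = int(rng.integers(4, 9))
        n_blobs = int(rng.integers(1, 5))
        rows = cols = 24
        channels = 0.45 + rng.normal(0, 0.03, size=(rows, cols, 3))
        for _ in range(n_blobs):
            r0, c0 = rng.integers(4, 20, size=2)
            rad = rng.integers(2, 6)
            rr, cc = np.mgrid[0:rows, 0:cols]
            blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            channels[blob] += rng.uniform(-0.3, 0.3, size=3)
        stack = MultispectralStack(np.clip(channels, 0, 1), np.ones((rows, cols), bool))
        cfg = ClusteringConfig(k_init=k_init, seed=seed)
        tm = cluster_with_separability(stack, cfg)
        assert len(tm.k_trajectory) <= k_init - cfg.k_floor + 1
        assert all(a > b for a, b in zip(tm.k_trajectory, tm.k_trajectory[1:]))
        separable = tm.min_pairwise_td() >= cfg.td_min
        if tm.exit_condition == "separable":
            assert separable
        else:
            assert tm.k <= cfg.k_floor and not separable
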