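import numpy as np
import pytest
from sklearn.cluster import DBSCAN
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score

from tetrabin.cluster import (
    cluster, dbscan_labels, k_distance_curve, select_eps, select_minpts,
)

EXHAUSTIVE = 10**7  # candidate budget large enough to visit every leaf


@pytest.fixture(scope="module")
def blobs():
    X, y = make_blobs(
        n_samples=300, centers=[[0, 0, 0], [5, 5, 0], [0, 5, 5]],
        cluster_std=0.1, random_state=0,
    )
    return X, y


class TestKDistanceCurve:
    def test_identical_points_give_zero_curve(self):
        X = np.ones((30, 4))
        curve = k_distance_curve(X, k=3)
        assert (curve == 0).all()

    def test_matches_brute_force_oracle_under_exhaustive_search(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 5))
        approx = k_distance_curve(X, k=7, n_trees=15, seed=0, search_k=EXHAUSTIVE)
        exact = k_distance_curve(X, k=7, exact=True)
        np.testing.assert_allclose(approx, exact, atol=1e-12)

    def test_curve_is_sorted(self):
        X = np.random.default_rng(1).normal(size=(100, 3))
        curve = k_distance_curve(X, k=5)
        assert (np.diff(curve) >= 0).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            k_distance_curve(np.zeros((5, 2)), k=5)


class TestSelectEps:
    def test_piecewise_linear_jump_knee(self):
        """Slow rise 0.1->0.6 then jump to 0.9->3.0: the knee sits at the break."""
        curve = np.concatenate([np.linspace(0.1, 0.6, 900), np.linspace(0.9, 3.0, 100)])
        assert 0.6 <= select_eps(curve) <= 0.9

    def test_right_angle_knee_at_corner(self):
        curve = np.concatenate([np.full(80, 1.0), np.linspace(1.0, 9.0, 20)])
        assert select_eps(curve) == pytest.approx(1.0)

    def test_constant_curve_has_no_knee(self):
        with pytest.raises(ValueError, match="manual"):
            select_eps(np.full(50, 2.0))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            curve = np.sort(rng.gamma(2.0, 1.0, size=200)) ** 2
            if curve[-1] - curve[0] <= 0:
                continue
            base = select_eps(curve)
            for factor in (0.01, 3.7, 1000.0):
                assert select_eps(curve * factor) == pytest.approx(base * factor, rel=1e-12)


class TestDBSCAN:
    @pytest.mark.parametrize("eps,min_pts", [(0.5, 5), (1.0, 10), (2.0, 3)])
    def test_equals_reference_dbscan_exactly(self, blobs, eps, min_pts):
        """With exhaustive neighbourhood search, labels match sklearn's DBSCAN."""
        X, _ = blobs
        ours = dbscan_labels(X, eps, min_pts, search_k=EXHAUSTIVE)
        reference = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(X)
        assert (ours == reference).all()

    def test_reference_equality_with_noise_present(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.2, (80, 4)), rng.uniform(-6, 6, (40, 4))])
        ours = dbscan_labels(X, eps=0.5, min_pts=5, search_k=EXHAUSTIVE)
        reference = DBSCAN(eps=0.5, min_samples=5).fit_predict(X)
        assert (ours == reference).all()
        assert (ours >= -1).all()

    def test_exact_mode_agrees_with_index_mode(self, blobs):
        X, _ = blobs
        assert (
            dbscan_labels(X, 0.5, 5, exact=True)
            == dbscan_labels(X, 0.5, 5, search_k=EXHAUSTIVE)
        ).all()


class TestSelectMinPts:
    def test_every_grid_value_recovers_three_blobs(self, blobs):
        X, y = blobs
        for candidate in (5, 10, 15, 20, 25):
            labels = dbscan_labels(X, eps=1.0, min_pts=candidate, search_k=EXHAUSTIVE)
            assert len(set(labels[labels >= 0])) == 3
        min_pts, labels, quality = select_minpts(X, eps=1.0, search_k=EXHAUSTIVE)
        assert adjusted_rand_score(y, labels) > 0.99
        assert quality > 0.5

    def test_singleton_grid_returned_as_is(self, blobs):
        X, _ = blobs
        min_pts, _, _ = select_minpts(X, eps=1.0, grid=[10], search_k=EXHAUSTIVE)
        assert min_pts == 10

    def test_all_noise_raises(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 100, size=(50, 3))
        with pytest.raises(ValueError, match="eps"):
            select_minpts(X, eps=1e-6, search_k=EXHAUSTIVE)


class TestClusterEndToEnd:
    def test_blobs_recovered_via_adaptive_parameters(self, blobs):
        """Fully automatic Eps + MinPts selection recovers the three blobs:
        the points it clusters are grouped perfectly and almost nothing is
        discarded as noise."""
        X, y = blobs
        result = cluster(X, seed=0)
        clustered = result.labels != -1
        assert (~clustered).mean() <= 0.05
        assert adjusted_rand_score(y, result.labels) > 0.9
        assert adjusted_rand_score(y[clustered], result.labels[clustered]) > 0.99
        assert result.params.eps > 0
        assert result.params.min_pts in (5, 10, 15, 20, 25)

    def test_single_blob_needs_manual_eps_or_yields_one_cluster(self):
        """A single tight blob: one cluster, almost no noise (eps supplied:
        the silhouette guard rejects single-cluster solutions by design)."""
        rng = np.random.default_rng(5)
        X = rng.normal(0, 0.1, size=(120, 4))
        labels = dbscan_labels(X, eps=0.5, min_pts=5, search_k=EXHAUSTIVE)
        assert len(set(labels[labels >= 0])) == 1
        assert (labels == -1).mean() <= 0.05

    def test_same_seed_reproduces_labels(self, blobs):
        X, _ = blobs
        a = cluster(X, seed=3)
        b = cluster(X, seed=3)
        assert (a.labels == b.labels).all()
        assert a.params.eps == b.params.eps

    def test_noise_label_is_reserved(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.1, (60, 3)), rng.normal(8, 0.1, (60, 3)),
                       rng.uniform(-20, 20, (10, 3))])
        result = cluster(X, seed=0)
        assert set(result.labels) <= set(range(result.n_bins)) | {-1}
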