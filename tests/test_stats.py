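"""Motion matrix, PCA modes, Mann-Whitney, and discriminant analysis."""
import numpy as np
import pytest

from oracles import mann_whitney_enumeration
from velogrid.grid import GridTrajectory
from velogrid.stats import (
    build_motion_matrix,
    discriminant_classify,
    fit_pca,
    mann_whitney,
    reconstruct_mode_shape,
    subject_scores,
    unflatten,
)
from velogrid.synthetic import (
    DeformationMode,
    POSTERIOR_SUPERIOR,
    rise_hold_fall,
    simulate_cohort,
    synthetic_node_trajectories,
)


def _traj(points):
    T, N, _ = points.shape
    return GridTrajectory(points=points, valid=np.ones((T, N), bool),
                          timestamps=np.arange(T) / 30.0, n=int(np.sqrt(N)) - 1)


class TestMotionMatrix:
    def test_static_trajectory_is_all_zero(self):
        pts = np.tile(np.random.default_rng(0).normal(size=(1, 36, 3)), (5, 1, 1))
        mm = build_motion_matrix(_traj(pts))
        assert mm.data.shape == (5, 108)
        assert (mm.data == 0).all()

    def test_single_node_bump_hits_one_column(self):
        pts = np.zeros((4, 36, 3))
        pts[:, :, 0] = np.arange(36)[None, :]  # static spread
        pts[2, 7, 2] += 1.0  # node 7 moves +1 mm in z at frame 2
        mm = build_motion_matrix(_traj(pts))
        nonzero = np.argwhere(mm.data != 0)
        assert nonzero.tolist() == [[2, 7 * 3 + 2]]

    def test_flatten_round_trip(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 36, 3))
        mm = build_motion_matrix(_traj(pts), subtract_rest=False)
        for t in range(6):
            assert np.allclose(unflatten(mm.data[t]), pts[t])

    def test_never_valid_node_dropped_everywhere(self):
        pts = np.random.default_rng(2).normal(size=(5, 36, 3))
        valid = np.ones((5, 36), bool)
        valid[:, 11] = False
        traj = GridTrajectory(points=pts, valid=valid,
                              timestamps=np.arange(5) / 30.0, n=5)
        mm = build_motion_matrix(traj)
        assert mm.data.shape == (5, 105)
        assert 11 not in mm.node_index


class TestPCA:
    def test_rank_one_motion_fully_explained_by_pc1(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=108)
        v /= np.linalg.norm(v)
        amp = np.sin(np.linspace(0, np.pi, 20))
        X = np.outer(amp, v)
        mm = build_motion_matrix(_traj(X.reshape(20, 36, 3)), subtract_rest=False)
        pca = fit_pca(mm, k=3)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert abs(pca.loadings[0] @ v) >= 0.999

    def test_full_rank_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 36 * 3))
        mm = build_motion_matrix(_traj(X.reshape(10, 36, 3)), subtract_rest=False)
        pca = fit_pca(mm, k=9)
        recon = pca.mean + pca.scores @ pca.loadings
        assert np.abs(recon - X).max() < 1e-8

    def test_loadings_orthonormal_and_variance_partition(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 108))
        mm = build_motion_matrix(_traj(X.reshape(15, 36, 3)), subtract_rest=False)
        pca = fit_pca(mm, k=14)
        G = pca.loadings @ pca.loadings.T
        assert np.abs(G - np.eye(pca.k)).max() < 1e-9
        assert pca.eigenvalues.sum() == pytest.approx(pca.total_variance, rel=1e-8)
        assert (np.diff(pca.eigenvalues) <= 1e-12).all()

    def test_matches_sklearn_eigendecomposition(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 108))
        mm = build_motion_matrix(_traj(X.reshape(30, 36, 3)), subtract_rest=False)
        ours = fit_pca(mm, k=12)
        ref = SkPCA(n_components=12).fit(X)
        assert np.abs(ours.eigenvalues - ref.explained_variance_).max() < 1e-8
        cos = np.abs(np.sum(ours.loadings * ref.components_, axis=1))
        assert np.all(cos > 1 - 1e-9)

    def test_rank_deficiency_warns_and_truncates(self):
        X = np.random.default_rng(7).normal(size=(4, 108))
        mm = build_motion_matrix(_traj(X.reshape(4, 36, 3)), subtract_rest=False)
        with pytest.warns(UserWarning, match="rank deficiency"):
            pca = fit_pca(mm, k=12)
        assert pca.k == 3

    def test_paper_mode_returns_twelve_scores(self):
        traj = synthetic_node_trajectories(
            [DeformationMode(POSTERIOR_SUPERIOR, 4.7, rise_hold_fall(30))],
            frames=30, noise_sd=0.05, seed=8)
        pca = fit_pca(build_motion_matrix(traj), k=12)
        assert pca.scores.shape == (30, 12)


class TestModeShape:
    def _rank1(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=108)
        v /= np.linalg.norm(v)
        amp = np.linspace(0, 2, 12)
        X = np.outer(amp, v)
        mm = build_motion_matrix(_traj(X.reshape(12, 36, 3)), subtract_rest=False)
        return X, fit_pca(mm, k=2)

    def test_zero_score_returns_mean_configuration(self):
        _, pca = self._rank1()
        assert np.allclose(reconstruct_mode_shape(pca, 1, 0.0),
                           unflatten(pca.mean))

    def test_rank_one_frame_reconstruction(self):
        X, pca = self._rank1()
        t = 7
        shape = reconstruct_mode_shape(pca, 1, float(pca.scores[t, 0]))
        assert np.abs(shape.ravel() - X[t]).max() < 1e-8

    def test_orthonormal_loading_isometry(self):
        _, pca = self._rank1()
        for s in (0.5, -1.7, 3.0):
            d = reconstruct_mode_shape(pca, 1, s) - reconstruct_mode_shape(pca, 1, 0)
            assert np.linalg.norm(d) == pytest.approx(abs(s), rel=1e-9)

    def test_component_out_of_range(self):
        _, pca = self._rank1()
        with pytest.raises(ValueError):
            reconstruct_mode_shape(pca, 0, 1.0)


class TestMannWhitney:
    def test_spec_toy_example_exact(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.U == 0
        assert res.p_value == pytest.approx(1 / 3, rel=1e-9)
        assert res.method == "exact"

    def test_identical_samples(self):
        a = np.arange(1, 7, dtype=float)
        res = mann_whitney(a, a)
        assert res.U == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value >= 0.99

    def test_degenerate_constant_data_warns(self):
        with pytest.warns(UserWarning):
            res = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(10)
        for n1, n2 in [(2, 2), (3, 4), (5, 5), (6, 3)]:
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            res = mann_whitney(a, b)
            u_ref, p_ref = mann_whitney_enumeration(a, b)
            assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(11)
        res = mann_whitney(rng.normal(size=20), rng.normal(size=20))
        assert res.method == "asymptotic"
        assert 0 <= res.U <= 400


class TestDiscriminant:
    def test_separable_clusters_perfect_resubstitution(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 0.1, (40, 2))
        b = rng.normal(5, 0.1, (40, 2))
        X = np.vstack([a, b])
        y = np.array(["u"] * 40 + ["v"] * 40)
        res = discriminant_classify(X, y)
        assert res.accuracy_pct == 100.0

    def test_toy_set_matches_midpoint_rule(self):
        # symmetric 2-points-per-class: boundary is the midline x = 1
        X = np.array([[0, 0], [0, 1], [2, 0], [2, 1]], float)
        y = np.array(["a", "a", "b", "b"])
        res = discriminant_classify(X, y)
        probe = np.array([[0.9, 0.5], [1.1, 0.5]])
        w, b0 = res.weights, res.intercept
        assert np.sign(probe[0] @ w + b0) != np.sign(probe[1] @ w + b0)
        assert list(res.predicted) == list(y)

    def test_matches_sklearn_lda_on_balanced_data(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(0.8, 1, (50, 2))])
        y = np.array(["a"] * 50 + ["b"] * 50)
        ours = discriminant_classify(X, y)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        assert list(ours.predicted) == list(ref.predict(X))

    def test_accuracy_invariant_to_axis_rescaling(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(100, 2))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=100) > 0, "m", "f")
        a = discriminant_classify(X, y).accuracy_pct
        b = discriminant_classify(X * [17.0, 0.04], y).accuracy_pct
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            discriminant_classify(np.zeros((4, 2)), ["a"] * 4)


class TestSubjectScores:
    def test_table_shape_and_groups(self):
        cohort = simulate_cohort(n_male=2, n_female=2, frames=10, seed=14)
        table = subject_scores(cohort, k=2)
        assert set(table.columns) >= {"subject", "group", "frame", "pcs1", "pcs2"}
        assert len(table) == 4 * 10
        assert set(table["group"]) == {"M", "F"}
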