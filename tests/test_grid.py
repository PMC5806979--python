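"""Quadrangle ROI, virtual-grid construction, 3D sampling, CoG shift."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from velogrid.errors import EmptyFrameError, GridOutOfBoundsError, InvalidROIError
from velogrid.grid import (
    GridTrajectory,
    QuadrangleROI,
    build_grid_trajectory,
    cog_shift,
    cog_trajectory,
    grid_centroid,
    load_roi,
    make_virtual_grid,
    sample_grid_3d,
    save_roi,
    trajectory_from_frame,
    trajectory_to_frame,
)
from velogrid.ranging import RangeImage, RangeSequence

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)


def _plane_range_image(z=30.0, H=40, W=40, valid=None):
    u, v = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    pts = np.stack([u, v, np.full((H, W), z)], axis=-1)
    if valid is None:
        valid = np.ones((H, W), bool)
    return RangeImage(points=pts, valid=valid)


class TestVirtualGrid:
    def test_unit_square_five_by_five_has_36_nodes(self):
        grid = make_virtual_grid(QuadrangleROI(UNIT_SQUARE), n=5)
        assert grid.n_nodes == 36
        expected = np.linspace(0, 1, 6)
        assert np.allclose(np.unique(np.round(grid.flat_nodes[:, 0], 9)), expected)
        assert np.allclose(np.unique(np.round(grid.flat_nodes[:, 1], 9)), expected)

    def test_n_equals_one_returns_corners(self):
        grid = make_virtual_grid(QuadrangleROI(UNIT_SQUARE), n=1)
        assert grid.n_nodes == 4
        assert np.allclose(np.sort(grid.flat_nodes, axis=0),
                           np.sort(UNIT_SQUARE, axis=0))

    def test_skewed_quadrangle_matches_bilinear_blend(self):
        corners = np.array([[0, 0], [10, 0], [12, 8], [-2, 8]], float)
        grid = make_virtual_grid(QuadrangleROI(corners), n=2)
        tl, tr, br, bl = QuadrangleROI(corners).corners
        for i, sv in enumerate([0.0, 0.5, 1.0]):
            for j, tv in enumerate([0.0, 0.5, 1.0]):
                want = ((1 - sv) * ((1 - tv) * tl + tv * tr)
                        + sv * ((1 - tv) * bl + tv * br))
                assert np.allclose(grid.nodes[i, j], want)

    def test_corner_order_canonicalized(self):
        shuffled = UNIT_SQUARE[[2, 0, 3, 1]]
        a = make_virtual_grid(QuadrangleROI(UNIT_SQUARE), n=3)
        b = make_virtual_grid(QuadrangleROI(shuffled), n=3)
        assert np.allclose(a.nodes, b.nodes)

    def test_degenerate_roi_rejected(self):
        with pytest.raises(InvalidROIError):
            QuadrangleROI(np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float))
        with pytest.raises(InvalidROIError):
            QuadrangleROI(np.array([[0, 0], [1, 0], [0.5, 0.2], [0, 1]], float))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_nodes_translation_equivariant(self, dx, dy):
        corners = np.array([[0, 0], [10, 1], [11, 9], [-1, 8]], float)
        a = make_virtual_grid(QuadrangleROI(corners), n=4)
        b = make_virtual_grid(QuadrangleROI(corners + [dx, dy]), n=4)
        assert np.allclose(b.nodes, a.nodes + [dx, dy], atol=1e-9)


class TestSampling:
    def test_constant_plane_samples_exactly(self):
        ri = _plane_range_image(z=30.0)
        roi = QuadrangleROI(np.array([[5, 5], [30, 5], [30, 30], [5, 30]], float))
        pts, valid = sample_grid_3d(ri, make_virtual_grid(roi, n=5))
        assert valid.all()
        assert np.allclose(pts[:, 2], 30.0, atol=1e-6)

    def test_bilinear_mean_of_two_by_two(self):
        ri = _plane_range_image()
        ri.points[10, 10, 2] = 10.0
        ri.points[10, 11, 2] = 10.0
        ri.points[11, 10, 2] = 20.0
        ri.points[11, 11, 2] = 20.0
        roi = QuadrangleROI(np.array(
            [[10.5, 10.5], [20, 10.5], [20, 20], [10.5, 20]], float))
        pts, valid = sample_grid_3d(ri, make_virtual_grid(roi, n=2))
        assert valid[0]
        assert pts[0, 2] == pytest.approx(15.0)

    def test_node_invalid_with_fewer_than_two_neighbors(self):
        valid = np.ones((40, 40), bool)
        valid[10:12, 10:12] = False
        valid[10, 11] = True  # one valid neighbor only
        ri = _plane_range_image(valid=valid)
        roi = QuadrangleROI(np.array(
            [[10.5, 10.5], [20, 10.5], [20, 20], [10.5, 20]], float))
        pts, node_valid = sample_grid_3d(ri, make_virtual_grid(roi, n=2))
        assert not node_valid[0]
        assert node_valid[1:].all()

    def test_out_of_bounds_node_raises(self):
        ri = _plane_range_image()
        roi = QuadrangleROI(np.array([[5, 5], [50, 5], [50, 30], [5, 30]], float))
        with pytest.raises(GridOutOfBoundsError):
            sample_grid_3d(ri, make_virtual_grid(roi, n=2))

    def test_temporal_fill_from_nearest_valid_frame(self):
        images = []
        for k in range(3):
            valid = np.ones((40, 40), bool)
            if k == 1:
                valid[8:14, 8:14] = False  # first node invalid at frame 1
            ri = _plane_range_image(z=30.0 + k, valid=valid)
            ri.frame_index = k
            ri.timestamp = k / 30
            images.append(ri)
        roi = QuadrangleROI(np.array([[10, 10], [30, 10], [30, 30], [10, 30]], float))
        traj = build_grid_trajectory(RangeSequence(images=images),
                                     make_virtual_grid(roi, n=5))
        assert traj.valid.all()
        # filled from frame 0 (nearest valid), whose plane is z = 30
        assert traj.points[1, 0, 2] == pytest.approx(30.0)
        assert traj.points[1, -1, 2] == pytest.approx(31.0)


class TestCentroid:
    def test_identical_points(self):
        p = np.tile([1.0, 2.0, 3.0], (36, 1))
        assert np.allclose(grid_centroid(p), [1, 2, 3])

    def test_unit_cube_corners(self):
        corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                           float)
        assert np.allclose(grid_centroid(corners), [0.5, 0.5, 0.5])

    def test_matches_independent_summation(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(36, 3))
        valid = rng.random(36) > 0.3
        want = np.array([pts[valid, c].sum() / valid.sum() for c in range(3)])
        assert np.allclose(grid_centroid(pts, valid), want)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(36, 3))
        perm = rng.permutation(36)
        assert np.allclose(grid_centroid(pts), grid_centroid(pts[perm]))

    def test_empty_frame_raises(self):
        with pytest.raises(EmptyFrameError):
            grid_centroid(np.zeros((4, 3)), np.zeros(4, bool))


def _linear_trajectory(peak=3.0, frames=9):
    """Centroid moves linearly out to ``peak`` mm and back."""
    pts = np.zeros((frames, 4, 3))
    half = frames // 2
    for t in range(frames):
        a = t / half if t <= half else (frames - 1 - t) / half
        pts[t, :, 2] = a * peak
    pts[:, :, 0] = np.arange(4)[None, :]  # spread nodes out
    return GridTrajectory(points=pts, valid=np.ones((frames, 4), bool),
                          timestamps=np.arange(frames) / 30.0, n=1)


class TestCoGShift:
    def test_static_trajectory_zero(self):
        traj = _linear_trajectory(peak=0.0)
        assert cog_shift(traj) == 0.0

    def test_out_and_back_returns_peak(self):
        traj = _linear_trajectory(peak=3.0)
        assert cog_shift(traj) == pytest.approx(3.0)

    def test_rest_frame_shift_is_zero(self):
        cog = cog_trajectory(_linear_trajectory(), rest_frame=2)
        assert cog.shifts[2] == 0.0

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        traj = _linear_trajectory(peak=2.5)
        R = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        rotated = GridTrajectory(points=traj.points @ R.T, valid=traj.valid,
                                 timestamps=traj.timestamps, n=traj.n)
        assert cog_shift(rotated) == pytest.approx(cog_shift(traj))


class TestPersistence:
    def test_roi_json_round_trip(self, tmp_path):
        roi = QuadrangleROI(np.array([[5, 5], [30, 6], [31, 29], [4, 30]], float),
                            reference_frame=2)
        save_roi(roi, tmp_path / "roi.json")
        roi2 = load_roi(tmp_path / "roi.json")
        assert np.allclose(roi2.corners, roi.corners)
        assert roi2.reference_frame == 2

    def test_trajectory_csv_round_trip(self):
        rng = np.random.default_rng(6)
        traj = GridTrajectory(points=rng.normal(size=(4, 36, 3)),
                              valid=rng.random((4, 36)) > 0.1,
                              timestamps=np.arange(4) / 30.0, n=5)
        df = trajectory_to_frame(traj)
        back = trajectory_from_frame(df)
        assert np.allclose(back.points, traj.points)
        assert np.array_equal(back.valid, traj.valid)
        assert back.n == 5
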