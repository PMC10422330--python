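"""Point-cloud roughness: neighbors, plane fits, invariances, label transfer."""

import numpy as np
import pytest

from reef3d.classes import LABEL_NODATA
from reef3d.errors import ParameterError
from reef3d.roughness import (LabeledCloud, fit_plane, point_plane_distance,
                              radius_neighbors, roughness, transfer_labels)
from reef3d.synthetic import sample_point_cloud

from conftest import make_label


def grid_cloud(n=5, spacing=1.0, z=0.0):
    yy, xx = np.mgrid[0:n, 0:n]
    pts = np.column_stack([xx.ravel() * spacing, yy.ravel() * spacing,
                           np.full(n * n, z)])
    return LabeledCloud(xyz=pts)


class TestNeighbors:
    def test_isolated_point_empty(self):
        cloud = LabeledCloud(xyz=np.array([[0, 0, 0], [10, 10, 10.0]]))
        assert len(radius_neighbors(cloud, 0, 1.0)) == 0

    def test_grid_eight_neighbors(self):
        cloud = grid_cloud(5)
        center = 12                       # (2, 2) in the 5x5 grid
        nbrs = radius_neighbors(cloud, center, 1.5)
        assert len(nbrs) == 8
        assert center not in nbrs

    def test_matches_bruteforce_scan(self, rng):
        pts = rng.standard_normal((500, 3))
        cloud = LabeledCloud(xyz=pts)
        for q in (0, 123, 499):
            got = set(radius_neighbors(cloud, q, 0.5).tolist())
            d = np.linalg.norm(pts - pts[q], axis=1)
            want = set(np.nonzero((d <= 0.5) & (np.arange(500) != q))[0].tolist())
            assert got == want

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ParameterError):
            radius_neighbors(grid_cloud(3), 0, 0.0)


class TestFitPlane:
    def test_horizontal_plane(self, rng):
        pts = np.column_stack([rng.standard_normal((20, 2)), np.zeros(20)])
        fit = fit_plane(pts)
        np.testing.assert_allclose(np.abs(fit.normal), [0, 0, 1], atol=1e-12)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_z_equals_x_closed_form(self, rng):
        xy = rng.standard_normal((30, 2))
        pts = np.column_stack([xy[:, 0], xy[:, 1], xy[:, 0]])  # z = x
        fit = fit_plane(pts)
        expect = np.array([-1, 0, 1]) / np.sqrt(2)
        np.testing.assert_allclose(fit.normal, expect, atol=1e-10)

    def test_degenerate_inputs_return_none(self):
        assert fit_plane(np.zeros((2, 3))) is None
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        assert fit_plane(line) is None

    def test_residual_rotation_invariant(self, rng):
        pts = rng.standard_normal((25, 3))
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec([0.3, -0.5, 0.7]).as_matrix()
        a = fit_plane(pts)
        b = fit_plane(pts @ rot.T)
        assert a.rms_residual == pytest.approx(b.rms_residual, rel=1e-9)


class TestRoughness:
    def test_plane_cloud_zero(self, rng):
        cloud = grid_cloud(7, spacing=0.01)
        out = roughness(cloud, [0.025])
        vals = out.scalars["roughness_r25"]
        finite = np.isfinite(vals)
        assert finite.sum() > 0
        np.testing.assert_allclose(vals[finite], 0.0, atol=1e-12)

    def test_apex_above_unit_square_exact(self):
        # 8 neighbors on z=0 around the origin; query raised by 5 mm
        ring = np.array([[dx, dy, 0.0] for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                         if (dx, dy) != (0, 0)], dtype=float)
        pts = np.vstack([[0.0, 0.0, 0.005], ring])
        cloud = LabeledCloud(xyz=pts)
        out = roughness(cloud, [2.0])
        assert out.scalars["roughness_r2000"][0] == pytest.approx(0.005,
                                                                  abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        pts = rng.standard_normal((300, 3)) * 0.05
        cloud = LabeledCloud(xyz=pts)
        r = 0.03
        out = roughness(cloud, [r])
        got = out.scalars["roughness_r30"]
        for q in range(0, 300, 17):
            d = np.linalg.norm(pts - pts[q], axis=1)
            nbrs = np.nonzero((d <= r) & (np.arange(300) != q))[0]
            if len(nbrs) < 3:
                assert np.isnan(got[q])
                continue
            fit = fit_plane(pts[nbrs])
            if fit is None:
                assert np.isnan(got[q])
            else:
                assert got[q] == pytest.approx(point_plane_distance(pts[q], fit),
                                               abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        pts = rng.standard_normal((150, 3)) * 0.05
        rot = Rotation.from_rotvec([0.2, 0.4, -0.3]).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -2.0, 5.0])
        a = roughness(LabeledCloud(xyz=pts), [0.04]).scalars["roughness_r40"]
        b = roughness(LabeledCloud(xyz=moved), [0.04]).scalars["roughness_r40"]
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_uniform_scaling_linearity(self, rng):
        pts = rng.standard_normal((150, 3)) * 0.05
        a = roughness(LabeledCloud(xyz=pts), [0.04]).scalars["roughness_r40"]
        b = roughness(LabeledCloud(xyz=pts * 2.0), [0.08]).scalars["roughness_r80"]
        np.testing.assert_allclose(b, 2.0 * a, atol=1e-10)

    def test_sparse_points_get_nan(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        out = roughness(LabeledCloud(xyz=pts), [0.5])
        assert np.isnan(out.scalars["roughness_r500"]).all()


class TestTransferLabels:
    def test_cell_center_lookup(self):
        mask = make_label(np.array([[0, 1], [2, 0]]))
        x, y = mask.transform.cell_center([0, 0, 1, 1], [0, 1, 0, 1])
        cloud = LabeledCloud(xyz=np.column_stack([x, y, np.zeros(4)]))
        out = transfer_labels(cloud, mask)
        np.testing.assert_array_equal(out.class_id, [0, 1, 2, 0])

    def test_outside_extent_unset(self):
        mask = make_label(np.zeros((4, 4)))
        cloud = LabeledCloud(xyz=np.array([[-1.0, 0.0, 0.0]]))
        out = transfer_labels(cloud, mask)
        assert out.class_id[0] == LABEL_NODATA

    def test_counts_match_cells_for_grid_sampled_cloud(self, small_scene):
        cloud = sample_point_cloud(small_scene, 1.0, jitter=0.0)
        out = transfer_labels(LabeledCloud(xyz=cloud.xyz), small_scene.labels)
        labels = np.asarray(small_scene.labels.data)
        for cid in (0, 1, 2):
            assert int((out.class_id == cid).sum()) == int((labels == cid).sum())


def test_ply_roundtrip_with_scalars(tmp_path, rng):
    pts = rng.standard_normal((40, 3))
    cloud = LabeledCloud(xyz=pts, class_id=rng.integers(0, 3, 40),
                         scalars={"roughness_r20": rng.random(40)})
    for binary in (True, False):
        path = tmp_path / f"c_{binary}.ply"
        cloud.save_ply(path, binary=binary)
        back = LabeledCloud.load_ply(path)
        np.testing.assert_allclose(back.xyz, pts, atol=1e-12)
        np.testing.assert_array_equal(back.class_id, cloud.class_id)
        np.testing.assert_allclose(back.scalars["roughness_r20"],
                                   cloud.scalars["roughness_r20"], atol=1e-6)
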