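"""Slope/aspect, VRM, DSM differencing and stratified change statistics."""

import numpy as np
import pytest

from reef3d.classes import LIVE
from reef3d.errors import StatsError, TerrainError
from reef3d.raster_io import FLOAT_NODATA
from reef3d.synthetic import EpochDelta, evolve_scene
from reef3d.terrain import (change_summary, dsm_difference,
                            normals_from_slope_aspect, slope_aspect,
                            stratify_by_class, vrm)

from conftest import make_height, make_label, make_scalar


def horn_oracle(z, cell):
    """Brute-force Horn stencil over interior cells."""
    rows, cols = z.shape
    slope = np.full_like(z, np.nan)
    for i in range(1, rows - 1):
        for j in range(1, cols - 1):
            p = ((z[i - 1, j + 1] + 2 * z[i, j + 1] + z[i + 1, j + 1])
                 - (z[i - 1, j - 1] + 2 * z[i, j - 1] + z[i + 1, j - 1])) / (8 * cell)
            q = ((z[i - 1, j - 1] + 2 * z[i - 1, j] + z[i - 1, j + 1])
                 - (z[i + 1, j - 1] + 2 * z[i + 1, j] + z[i + 1, j + 1])) / (8 * cell)
            slope[i, j] = np.arctan(np.hypot(p, q))
    return slope


def vrm_oracle(dsm, window):
    """Triple-loop VRM oracle built on the slope/aspect operations."""
    s, a = slope_aspect(dsm)
    nf = normals_from_slope_aspect(s, a)
    rows, cols = dsm.shape
    half = window // 2
    out = np.full((rows, cols), FLOAT_NODATA)
    for i in range(half, rows - half):
        for j in range(half, cols - half):
            sl = (slice(i - half, i + half + 1), slice(j - half, j + half + 1))
            if not nf.valid[sl].all():
                continue
            r = np.array([nf.nx[sl].sum(), nf.ny[sl].sum(), nf.nz[sl].sum()])
            out[i, j] = 1.0 - np.linalg.norm(r) / window ** 2
    return out


class TestSlopeAspect:
    def test_constant_dsm_zero_slope(self):
        s, _ = slope_aspect(make_height(np.full((16, 16), 2.5)))
        data = np.asarray(s.data)
        assert np.all(data[data != FLOAT_NODATA] == 0.0)

    def test_unit_gradient_plane_45_degrees(self):
        yy, xx = np.mgrid[0:16, 0:16]
        dsm = make_height(xx * 0.001)        # z = x: slope 45 deg east
        s, a = slope_aspect(dsm)
        interior = np.asarray(s.data)[2:-2, 2:-2]
        np.testing.assert_allclose(interior, np.pi / 4, atol=1e-12)

    def test_matches_bruteforce_horn_stencil(self, rng):
        z = rng.standard_normal((12, 12)) * 0.01
        dsm = make_height(z)
        s, _ = slope_aspect(dsm)
        ref = horn_oracle(z, 0.001)
        got = np.asarray(s.data)
        interior = np.s_[1:-1, 1:-1]
        np.testing.assert_allclose(got[interior], ref[interior], atol=1e-12)

    def test_too_small_grid_errors(self):
        with pytest.raises(TerrainError):
            slope_aspect(make_height(np.zeros((2, 5))))

    def test_normals_unit_norm(self, rng):
        dsm = make_height(rng.standard_normal((16, 16)) * 0.01)
        s, a = slope_aspect(dsm)
        nf = normals_from_slope_aspect(s, a)
        norm = nf.nx ** 2 + nf.ny ** 2 + nf.nz ** 2
        np.testing.assert_allclose(norm[nf.valid], 1.0, atol=1e-6)
        assert np.all(nf.nz[nf.valid] > 0)

    def test_vertical_limit_normal(self):
        # slope 90 deg, aspect 0 (north) -> normal (0, 1, 0)
        s = make_scalar(np.full((4, 4), np.pi / 2))
        a = make_scalar(np.zeros((4, 4)))
        nf = normals_from_slope_aspect(s, a)
        np.testing.assert_allclose([nf.nx[0, 0], nf.ny[0, 0], nf.nz[0, 0]],
                                   [0.0, 1.0, 0.0], atol=1e-12)


class TestVrm:
    def test_flat_dsm_exactly_zero(self):
        res = vrm(make_height(np.full((64, 64), 1.0)), 21)
        v = np.asarray(res.vrm.data)
        valid = v != FLOAT_NODATA
        assert valid.sum() > 0
        assert np.abs(v[valid]).max() < 1e-12

    def test_tilted_plane_zero(self):
        yy, xx = np.mgrid[0:40, 0:40]
        res = vrm(make_height(xx * 0.0005 + yy * 0.0002), 5)
        v = np.asarray(res.vrm.data)
        assert np.abs(v[v != FLOAT_NODATA]).max() < 1e-10

    def test_matches_triple_loop_oracle(self, rng):
        dsm = make_height(rng.standard_normal((31, 31)) * 0.005)
        res = vrm(dsm, 5)
        ref = vrm_oracle(dsm, 5)
        got = np.asarray(res.vrm.data)
        both = (got != FLOAT_NODATA) & (ref != FLOAT_NODATA)
        assert np.array_equal(got != FLOAT_NODATA, ref != FLOAT_NODATA)
        np.testing.assert_allclose(got[both], ref[both], atol=1e-10)

    def test_range_and_shift_invariance(self, rng):
        z = rng.standard_normal((24, 24)) * 0.01
        a = vrm(make_height(z), 5)
        b = vrm(make_height(z + 3.7), 5)
        va, vb = np.asarray(a.vrm.data), np.asarray(b.vrm.data)
        valid = va != FLOAT_NODATA
        assert np.all((va[valid] >= 0) & (va[valid] <= 1))
        np.testing.assert_allclose(va[valid], vb[valid], atol=1e-9)

    def test_rotation_90_invariance(self, rng):
        z = rng.standard_normal((20, 20)) * 0.01
        a = np.asarray(vrm(make_height(z), 5).vrm.data)
        b = np.asarray(vrm(make_height(np.rot90(z).copy()), 5).vrm.data)
        valid = a != FLOAT_NODATA
        np.testing.assert_allclose(np.rot90(a)[np.rot90(valid)],
                                   b[np.rot90(valid)], atol=1e-9)

    def test_nodata_window_voided(self, rng):
        z = rng.standard_normal((15, 15)) * 0.01
        z[7, 7] = FLOAT_NODATA
        res = vrm(make_height(z), 3)
        v = np.asarray(res.vrm.data)
        # the 3x3 normal hole around (7,7) voids a 5x5 block of windows
        assert np.all(v[5:10, 5:10] == FLOAT_NODATA)

    def test_even_or_oversized_window_rejected(self):
        dsm = make_height(np.zeros((10, 10)))
        with pytest.raises(TerrainError):
            vrm(dsm, 4)
        with pytest.raises(TerrainError):
            vrm(dsm, 11)


class TestDifference:
    def test_self_difference_zero(self, rng):
        d = make_height(rng.standard_normal((8, 8)))
        assert np.all(np.asarray(dsm_difference(d, d).data) == 0.0)

    def test_constant_offset_in_mm(self, rng):
        z = rng.standard_normal((8, 8))
        d1 = make_height(z)
        d2 = make_height(z + 0.010)
        np.testing.assert_allclose(np.asarray(dsm_difference(d2, d1).data),
                                   10.0, atol=1e-9)

    def test_antisymmetry_and_elementwise(self, rng):
        z1 = rng.standard_normal((10, 10))
        z2 = rng.standard_normal((10, 10))
        a = np.asarray(dsm_difference(make_height(z2), make_height(z1)).data)
        b = np.asarray(dsm_difference(make_height(z1), make_height(z2)).data)
        np.testing.assert_allclose(a, -b, atol=1e-12)
        np.testing.assert_allclose(a, (z2 - z1) * 1000, atol=1e-9)

    def test_nodata_propagates(self, rng):
        z1 = rng.standard_normal((6, 6))
        z2 = z1.copy()
        z1[2, 2] = FLOAT_NODATA
        diff = dsm_difference(make_height(z2), make_height(z1))
        assert np.asarray(diff.data)[2, 2] == FLOAT_NODATA


class TestChangeSummary:
    def test_constant_field_median(self):
        row, _ = change_summary(make_scalar(np.full((10, 10), 4.2)))
        assert row["median"] == pytest.approx(4.2)
        assert row["n"] == 100

    def test_skewed_field_median_vs_mean(self):
        vals = np.array([0.0] * 9 + [100.0]).reshape(2, 5)
        row, _ = change_summary(make_scalar(vals))
        assert row["median"] == 0.0
        assert row["mean"] == pytest.approx(10.0)

    def test_histogram_truncation_leaves_stats_alone(self):
        vals = np.full((4, 4), 80.0)      # outside the +-50 mm display range
        row, (counts, edges) = change_summary(make_scalar(vals))
        assert row["median"] == 80.0       # stats untouched by truncation
        assert counts.sum() == 0           # but outside every display bin

    def test_empty_selection_errors(self):
        vals = make_scalar(np.zeros((4, 4)))
        mask = make_label(np.zeros((4, 4)))
        with pytest.raises(StatsError):
            change_summary(vals, mask=mask, class_id=LIVE)

    def test_synthetic_growth_recovered_exactly(self, small_scene):
        s2 = evolve_scene(small_scene, EpochDelta(growth_mm=10.0, seed=1))
        change = dsm_difference(s2.dsm, small_scene.dsm)
        row, _ = change_summary(change, mask=small_scene.labels, class_id=LIVE)
        assert row["median"] == pytest.approx(10.0, abs=1e-9)


class TestStratify:
    def test_single_class_mask(self, rng):
        vals = make_scalar(rng.standard_normal((8, 8)))
        mask = make_label(np.ones((8, 8)))
        table = stratify_by_class(vals, mask)
        populated = table[table.n > 0]
        assert list(populated["class"]) == [1]
        assert populated.iloc[0]["n"] == 64

    def test_per_class_median_matches_subset(self, rng):
        z = rng.standard_normal((12, 12))
        labels = rng.integers(0, 3, (12, 12))
        table = stratify_by_class(make_scalar(z), make_label(labels))
        for cid in (0, 1, 2):
            expect = np.median(z[labels == cid])
            got = table[table["class"] == cid].iloc[0]["median"]
            assert got == pytest.approx(expect)

    def test_partition_counts(self, rng):
        z = rng.standard_normal((12, 12))
        labels = rng.integers(0, 3, (12, 12))
        table = stratify_by_class(make_scalar(z), make_label(labels))
        assert table["n"].sum() == 144
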