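"""Patch extraction arithmetic, augmentation, folds and stitching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reef3d.classes import LABEL_NODATA
from reef3d.errors import ParameterError, TilingError
from reef3d.raster_io import GridTransform, Raster
from reef3d.tiling import (PatchRecord, augment_patch, extract_patches,
                           grid_origins, kfold_split, stitch_predictions)

from conftest import make_height, make_label


def make_trio(rows, cols, seed=0):
    rng = np.random.default_rng(seed)
    t = GridTransform(0.0, rows * 0.001, 0.001)
    ortho = Raster(data=rng.integers(0, 256, (rows, cols, 3), dtype=np.uint8),
                   transform=t, nodata=0.0, band_meaning="rgb")
    dsm = make_height(rng.standard_normal((rows, cols)) * 0.01, transform=t)
    labels = make_label(rng.integers(0, 3, (rows, cols)), transform=t)
    return ortho, dsm, labels


@pytest.mark.parametrize("extent,window,stride,expected", [
    ((448, 448), 448, 224, 1),
    ((896, 896), 448, 224, 9),
    ((1120, 1120), 448, 224, 16),   # floor((1120-448)/224)+1 = 4 per axis
    ((100, 70), 32, 16, 15),        # 5 x 3
])
def test_patch_count_formula(extent, window, stride, expected):
    assert len(grid_origins(extent, window, stride)) == expected


def test_extract_patches_content_and_origins():
    ortho, dsm, labels = make_trio(96, 96)
    patches = extract_patches(ortho, dsm, labels, window=64, stride=32)
    assert len(patches) == 4
    for p in patches:
        r, c = p.origin
        assert r % 32 == 0 and c % 32 == 0
        np.testing.assert_array_equal(
            p.rgb, np.asarray(ortho.data)[r:r + 64, c:c + 64])


def test_extent_smaller_than_window_errors():
    ortho, dsm, labels = make_trio(32, 32)
    with pytest.raises(TilingError):
        extract_patches(ortho, dsm, labels, window=64, stride=32)


def test_nodata_heavy_patches_dropped():
    ortho, dsm, labels = make_trio(64, 128)
    d = np.asarray(dsm.data).copy()
    d[:, 64:] = dsm.nodata          # right half entirely nodata
    dsm2 = make_height(d, transform=dsm.transform)
    patches = extract_patches(ortho, dsm2, labels, window=64, stride=64)
    assert [p.origin for p in patches] == [(0, 0)]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(rows=st.integers(16, 200), cols=st.integers(16, 200),
       window=st.integers(4, 16), stride=st.integers(1, 16))
def test_patch_count_matches_bruteforce(rows, cols, window, stride):
    if window > rows or window > cols:
        return
    got = len(grid_origins((rows, cols), window, stride))
    brute = sum(1 for r in range(0, rows, stride) if r + window <= rows) * \
        sum(1 for c in range(0, cols, stride) if c + window <= cols)
    assert got == brute


class TestAugment:
    def patch(self, seed=0):
        rng = np.random.default_rng(seed)
        return PatchRecord(rgb=rng.integers(0, 256, (16, 16, 3), dtype=np.uint8),
                           height=rng.standard_normal((16, 16)),
                           label=rng.integers(0, 3, (16, 16)).astype(np.uint8),
                           origin=(0, 0))

    def test_rotation_preserves_label_histogram(self):
        p = self.patch()
        for seed in range(8):
            q = augment_patch(p, seed)
            np.testing.assert_array_equal(np.bincount(q.label.ravel(), minlength=3),
                                          np.bincount(p.label.ravel(), minlength=3))

    def test_identical_transform_on_all_channels(self):
        # rotating the stacked channels together must equal the output
        p = self.patch()
        q = augment_patch(p, seed=3)
        for k in range(4):
            if np.array_equal(np.rot90(p.height, k), q.height):
                np.testing.assert_array_equal(np.rot90(p.rgb, k, axes=(0, 1)), q.rgb)
                np.testing.assert_array_equal(np.rot90(p.label, k), q.label)
                break
        else:
            pytest.fail("output is not a 90-degree rotation of the input")

    def test_requires_label(self):
        p = self.patch()
        p = PatchRecord(rgb=p.rgb, height=p.height, label=None, origin=(0, 0))
        with pytest.raises(ParameterError):
            augment_patch(p, 0)

    def test_translation_recrops_from_source(self):
        ortho, dsm, labels = make_trio(96, 96)
        patches = extract_patches(ortho, dsm, labels, window=32, stride=32)
        q = augment_patch(patches[4], seed=1, source=(ortho, dsm, labels))
        r, c = q.origin
        assert 0 <= r <= 64 and 0 <= c <= 64
        # content must be a rotation of the crop at the new origin
        crop = np.asarray(dsm.data)[r:r + 32, c:c + 32]
        assert any(np.array_equal(np.rot90(crop, k), q.height) for k in range(4))


class TestKFold:
    def test_partition_and_balance(self):
        folds = kfold_split(13, n_folds=5, seed=1)
        sizes = [len(folds.val_indices(f)) for f in range(5)]
        assert sum(sizes) == 13
        assert max(sizes) - min(sizes) <= 1
        all_idx = np.sort(np.concatenate([folds.val_indices(f) for f in range(5)]))
        np.testing.assert_array_equal(all_idx, np.arange(13))

    def test_determinism(self):
        a = kfold_split(20, 5, seed=7)
        b = kfold_split(20, 5, seed=7)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_too_few_patches(self):
        with pytest.raises(ParameterError):
            kfold_split(3, n_folds=5)


class TestStitch:
    def t(self, rows=8):
        return GridTransform(0.0, rows * 0.001, 0.001)

    def test_single_patch_argmax(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(4, 4)).transpose(2, 0, 1)
        r, _ = stitch_predictions([((0, 0), probs)], (4, 4), self.t(4))
        np.testing.assert_array_equal(r.data, np.argmax(probs, axis=0))

    def test_overlap_averaging_hand_case(self):
        p1 = np.array([0.6, 0.4, 0.0]).reshape(3, 1, 1)
        p2 = np.array([0.2, 0.8, 0.0]).reshape(3, 1, 1)
        r, mean = stitch_predictions([((0, 0), p1), ((0, 0), p2)], (1, 1),
                                     self.t(1))
        np.testing.assert_allclose(mean[:, 0, 0], [0.4, 0.6, 0.0])
        assert r.data[0, 0] == 1

    def test_duplicate_patch_idempotent(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(4, 4)).transpose(2, 0, 1)
        one, _ = stitch_predictions([((0, 0), probs)], (4, 4), self.t(4))
        two, _ = stitch_predictions([((0, 0), probs), ((0, 0), probs)],
                                    (4, 4), self.t(4))
        np.testing.assert_array_equal(one.data, two.data)

    def test_uncovered_cells_nodata(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(2, 2)).transpose(2, 0, 1)
        r, _ = stitch_predictions([((0, 0), probs)], (4, 4), self.t(4))
        assert np.all(np.asarray(r.data)[2:, :] == LABEL_NODATA)

    def test_empty_errors(self):
        with pytest.raises(TilingError):
            stitch_predictions([], (4, 4), self.t(4))

    def test_tile_stitch_identity_on_onehot_truth(self):
        # stitching one-hot ground-truth probabilities reproduces the truth
        ortho, dsm, labels = make_trio(96, 96, seed=5)
        patches = extract_patches(ortho, dsm, labels, window=64, stride=32)
        preds = []
        for p in patches:
            onehot = np.eye(3)[p.label].transpose(2, 0, 1)
            preds.append((p.origin, onehot))
        r, _ = stitch_predictions(preds, (96, 96), self.t(96))
        np.testing.assert_array_equal(r.data, np.asarray(labels.data))
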