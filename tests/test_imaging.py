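"""Volume handling, feature stacking, thresholding, resampling, I/O."""
import numpy as np
import pytest

import manifoldseg as ms
from manifoldseg.imaging import (BinaryLesionMask, VoxelMap, binarize,
                                 quantize_features, select_informative_axis)


class TestStackChannels:
    def test_full_mask_shape(self, tiny_volume):
        X, vmap = ms.stack_channels(tiny_volume)
        assert X.shape == (64, 4)
        assert vmap.n_rows == 64

    def test_t1post_rejected_as_input(self, tiny_volume):
        with pytest.raises(ValueError, match="ground truth"):
            ms.stack_channels(tiny_volume,
                              channel_order=("PD", "T2W", "T1post"))

    def test_zscore_normalization(self, tiny_volume):
        X, _ = ms.stack_channels(tiny_volume)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-12)

    def test_constant_channel_becomes_zeros_with_warning(self, tiny_volume):
        tiny_volume.channels["PD"][:] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            X, _ = ms.stack_channels(tiny_volume)
        np.testing.assert_array_equal(X[:, 0], 0.0)

    def test_permuted_channel_order_permutes_columns(self, tiny_volume):
        X1, _ = ms.stack_channels(tiny_volume)
        X2, _ = ms.stack_channels(
            tiny_volume, channel_order=("FLAIR", "PD", "T1pre", "T2W"))
        np.testing.assert_array_equal(X2, X1[:, [2, 0, 3, 1]])

    def test_empty_mask_rejected(self, tiny_volume):
        tiny_volume.brain_mask = np.zeros((8, 8), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            ms.stack_channels(tiny_volume)

    def test_missing_channel_named(self, tiny_volume):
        del tiny_volume.channels["FLAIR"]
        with pytest.raises(ValueError, match="FLAIR"):
            ms.stack_channels(tiny_volume)


class TestRoundTrip:
    def test_identity_embedding_reproduces_channel(self, tiny_volume):
        """stack -> embed(copy of one channel) -> image round trip."""
        X, vmap = ms.stack_channels(tiny_volume, normalize="none")
        flair = X[:, 2]
        img = ms.embedding_to_image(flair, vmap)
        np.testing.assert_allclose(img.values, tiny_volume.channels["FLAIR"])

    def test_grid_placement(self):
        vmap = VoxelMap(shape=(2, 2), flat_indices=np.arange(4))
        img = ms.embedding_to_image(np.array([1.0, 2.0, 3.0, 4.0]), vmap)
        np.testing.assert_array_equal(img.values, [[1, 2], [3, 4]])

    def test_excluded_voxel_gets_minimum(self):
        vmap = VoxelMap(shape=(2, 2), flat_indices=np.array([0, 1, 3]))
        img = ms.embedding_to_image(np.array([5.0, 2.0, 9.0]), vmap)
        assert img.values[1, 0] == 2.0  # voxel 2 excluded -> min
        assert img.excluded[1, 0]

    def test_nan_rows_excluded(self):
        vmap = VoxelMap(shape=(1, 3), flat_indices=np.arange(3))
        img = ms.embedding_to_image(np.array([1.0, np.nan, 3.0]), vmap)
        assert img.values[0, 1] == 1.0
        assert img.excluded[0, 1]

    def test_polarity_flip_anchors_bright_reference(self, rng):
        n = 1000
        ref = np.zeros(n)
        ref[:20] = 10.0       # reference-bright voxels
        y = rng.normal(size=n)
        y[:20] = -5.0         # embedded dark -> must flip
        vmap = VoxelMap(shape=(20, 50), flat_indices=np.arange(n))
        img = ms.embedding_to_image(y, vmap, polarity_reference=ref)
        assert img.polarity_flipped
        assert img.values.ravel()[:20].mean() > img.values.ravel()[20:].mean()


class TestSubtraction:
    def test_equal_channels_give_zero(self, tiny_volume):
        sub = ms.subtraction_image(tiny_volume)
        np.testing.assert_array_equal(sub, 0.0)

    def test_single_enhancing_voxel(self, tiny_volume):
        tiny_volume.channels["T1post"][3, 4] += 10.0
        sub = ms.subtraction_image(tiny_volume)
        assert sub[3, 4] == pytest.approx(10.0)
        sub[3, 4] = 0.0
        np.testing.assert_array_equal(sub, 0.0)

    def test_negative_differences_clipped(self, tiny_volume):
        tiny_volume.channels["T1post"] -= 5.0
        sub = ms.subtraction_image(tiny_volume)
        assert (sub == 0).all()

    def test_missing_channel_error(self, tiny_volume):
        del tiny_volume.channels["T1post"]
        with pytest.raises(ValueError, match="T1post"):
            ms.subtraction_image(tiny_volume)


class TestBinarize:
    def test_absolute_threshold(self):
        img = np.array([[0.0, 0.0], [10.0, 10.0]])
        mask = binarize(img, "absolute", param=5.0)
        np.testing.assert_array_equal(mask.values, [[False, False],
                                                    [True, True]])
        assert mask.threshold == 5.0

    def test_all_zero_image_empty_mask(self):
        with pytest.warns(UserWarning, match="flat"):
            mask = binarize(np.zeros((4, 4)), "otsu")
        assert mask.n_positive == 0

    def test_otsu_separates_bimodal(self, rng):
        img = np.concatenate([rng.normal(0, 1, 500),
                              rng.normal(10, 1, 500)]).reshape(50, 20)
        mask = binarize(img, "otsu")
        assert mask.n_positive == (img > 5).sum()

    def test_idempotent_rebinarization(self, rng):
        img = rng.normal(size=(16, 16))
        mask = binarize(img, "percentile", param=90.0)
        again = binarize(mask.values.astype(float), "absolute", param=0.5)
        np.testing.assert_array_equal(mask.values, again.values)

    def test_percentile(self, rng):
        img = rng.normal(size=(10, 10))
        mask = binarize(img, "percentile", param=75.0)
        assert mask.n_positive == 25

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown"):
            binarize(np.zeros((2, 2)), "magic")


class TestResample:
    def test_constant_image_stays_constant(self):
        img = np.full((256, 256), 3.0)
        for target in ((128, 128), (64, 64)):
            out = ms.resample_image(img, target)
            assert out.shape == target
            np.testing.assert_allclose(out, 3.0)

    def test_checkerboard_averages_to_half(self):
        img = np.indices((256, 256)).sum(axis=0) % 2
        out = ms.resample_image(img.astype(float), (128, 128))
        np.testing.assert_allclose(out, 0.5)

    def test_mask_majority_vote(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2, :2] = True          # full block -> True
        mask[0, 2] = True            # quarter block -> False
        out = ms.resample_mask(mask, (2, 2))
        np.testing.assert_array_equal(out, [[True, False], [False, False]])

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            ms.resample_image(np.zeros((64, 64)), (128, 128))

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            ms.resample_image(np.zeros((100, 100)), (64, 64))

    def test_volume_resample_keeps_channels_and_mask(self, tiny_volume):
        out = ms.resample_volume(tiny_volume, (4, 4))
        assert set(out.channels) == set(tiny_volume.channels)
        assert out.shape == (4, 4)
        assert out.brain_mask.shape == (4, 4)


class TestQuantize:
    def test_exact_when_few_unique_rows(self):
        X = np.repeat(np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]]),
                      [50, 30, 20], axis=0)
        codes, counts, inverse, step = quantize_features(X, max_codewords=10)
        assert step == 0.0
        assert codes.shape == (3, 2)
        np.testing.assert_array_equal(counts, [50, 30, 20])
        np.testing.assert_allclose(codes[inverse], X)

    def test_respects_budget(self, rng):
        X = rng.normal(size=(5000, 4))
        codes, counts, inverse, step = quantize_features(X, max_codewords=300)
        assert codes.shape[0] <= 300
        assert step > 0
        assert counts.sum() == 5000
        # codewords approximate their members to within the grid step
        err = np.abs(codes[inverse] - X).max()
        assert err < step

    def test_deterministic(self, rng):
        X = rng.normal(size=(2000, 3))
        a = quantize_features(X, max_codewords=100)
        b = quantize_features(X, max_codewords=100)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[2], b[2])


class TestAxisSelection:
    def test_picks_separating_component(self, rng):
        n = 500
        ref = np.zeros(n)
        ref[:10] = 1.0
        comp = rng.normal(size=(n, 3))
        comp[:10, 2] -= 8.0   # component 2 separates, negatively
        idx, sign = select_informative_axis(comp, ref)
        assert idx == 2
        assert sign == -1.0


class TestNiftiIO:
    def test_volume_roundtrip(self, tiny_volume, tmp_path):
        manifest = ms.save_volume(tiny_volume, tmp_path)
        back = ms.load_volume(manifest)
        assert set(back.channels) == set(tiny_volume.channels)
        for name in tiny_volume.channels:
            np.testing.assert_allclose(back.channels[name],
                                       tiny_volume.channels[name], rtol=1e-6)
        np.testing.assert_array_equal(back.brain_mask,
                                      tiny_volume.brain_mask)

    def test_mask_roundtrip(self, tmp_path, rng):
        from manifoldseg.imaging import load_mask, save_mask
        mask = rng.random((8, 8)) > 0.5
        save_mask(mask, tmp_path / "m.nii.gz")
        np.testing.assert_array_equal(load_mask(tmp_path / "m.nii.gz"), mask)
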