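import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvseg.preprocess import (
    AugmentParams,
    apply_window,
    augment_pair,
    downsample_inplane,
    resample_volume,
)
from mvseg.volume import Volume


def _vol(data, spacing=(1.0, 1.0, 1.0), role="intensity"):
    return Volume(np.asarray(data), spacing, role=role)


class TestResample:
    def test_slice_count_and_extent(self, rng):
        v = _vol(rng.normal(size=(10, 8, 8)).astype(np.float32), (1.24, 0.73, 0.73))
        out = resample_volume(v, (0.62, 0.73, 0.73))
        # 10 slices of 1.24 mm = 12.4 mm extent -> 20 slices of 0.62 mm
        assert out.shape == (20, 8, 8)
        assert out.spacing == (0.62, 0.73, 0.73)
        for ax in range(3):
            old_extent = v.shape[ax] * v.spacing[ax]
            new_extent = out.shape[ax] * out.spacing[ax]
            assert abs(old_extent - new_extent) <= out.spacing[ax]

    def test_identity_when_spacing_matches(self, rng):
        v = _vol(rng.normal(size=(5, 6, 7)).astype(np.float32), (1.0, 0.5, 0.5))
        out = resample_volume(v, (1.0, 0.5, 0.5))
        np.testing.assert_array_equal(out.data, v.data)

    def test_labels_stay_binary(self, rng):
        v = _vol((rng.random((12, 10, 10)) > 0.8).astype(np.uint8), role="label")
        out = resample_volume(v, (0.5, 0.7, 0.7), interp="nearest")
        assert set(np.unique(out.data)) <= {0, 1}

    def test_label_with_linear_rejected(self):
        v = _vol(np.zeros((4, 4, 4), dtype=np.uint8), role="label")
        with pytest.raises(ValueError):
            resample_volume(v, (0.5, 0.5, 0.5), interp="linear")

    def test_nonpositive_spacing_rejected(self, rng):
        v = _vol(np.zeros((4, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError):
            resample_volume(v, (1.0, 0.0, 1.0))

    def test_round_trip_error_bounded(self, rng):
        data = rng.normal(0, 100, size=(16, 16, 16)).astype(np.float32)
        smooth = _vol(data, (1.0, 1.0, 1.0))
        down = resample_volume(smooth, (2.0, 2.0, 2.0))
        back = resample_volume(down, (1.0, 1.0, 1.0))
        assert back.shape == smooth.shape
        # linear interpolation round trip: smoke bound on mean abs error
        assert np.abs(back.data - smooth.data).mean() < np.abs(data).mean()


class TestWindow:
    @pytest.mark.parametrize(
        "hu,expected",
        [(-200.0, 0.0), (600.0, 255.0), (200.0, 127.5), (-1000.0, 0.0), (1000.0, 255.0)],
    )
    def test_default_window_mapping(self, hu, expected):
        v = _vol(np.full((2, 2, 2), hu, dtype=np.float32))
        out = apply_window(v)
        np.testing.assert_allclose(out.data, expected, atol=1e-5)

    def test_bad_width_and_role(self):
        v = _vol(np.zeros((2, 2, 2), dtype=np.float32))
        with pytest.raises(ValueError):
            apply_window(v, width=0)
        with pytest.raises(ValueError):
            apply_window(
                Volume(np.zeros((2, 2, 2), np.uint8), (1, 1, 1), role="label")
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hu_lo=st.floats(-1200, 1200),
        hu_hi=st.floats(-1200, 1200),
    )
    def test_monotone_in_hu(self, hu_lo, hu_hi):
        hu_lo, hu_hi = min(hu_lo, hu_hi), max(hu_lo, hu_hi)
        v = _vol(np.array([[[hu_lo, hu_hi]]], dtype=np.float32))
        out = apply_window(v)
        assert out.data[0, 0, 0] <= out.data[0, 0, 1]


class TestDownsample:
    def test_512_to_128_with_factor_4(self):
        v = _vol(np.zeros((2, 512, 512), dtype=np.float32), (0.62, 0.73, 0.73))
        out = downsample_inplane(v, 4)
        assert out.shape == (2, 128, 128)
        np.testing.assert_allclose(out.spacing, (0.62, 2.92, 2.92))

    def test_factor_one_is_identity(self, rng):
        v = _vol(rng.normal(size=(3, 8, 8)).astype(np.float32))
        out = downsample_inplane(v, 1)
        np.testing.assert_array_equal(out.data, v.data)
        assert out.spacing == v.spacing

    def test_block_average_oracle_checkerboard(self):
        board = np.indices((1, 8, 8)).sum(axis=0) % 2
        v = _vol(board.astype(np.float32), (1.0, 1.0, 1.0))
        out = downsample_inplane(v, 2)
        # each 2x2 block of a checkerboard averages to exactly 0.5
        np.testing.assert_allclose(out.data, 0.5)
        assert out.spacing == (1.0, 2.0, 2.0)

    def test_labels_stay_binary(self, rng):
        v = _vol((rng.random((4, 16, 16)) > 0.5).astype(np.uint8), role="label")
        out = downsample_inplane(v, 4)
        assert set(np.unique(out.data)) <= {0, 1}
        assert out.shape == (4, 4, 4)

    def test_bad_factor(self):
        v = _vol(np.zeros((2, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError):
            downsample_inplane(v, 0)


class TestAugment:
    def _pair(self, rng):
        img = rng.normal(100, 30, (24, 24)).astype(np.float32)
        msk = np.zeros((24, 24), dtype=np.uint8)
        msk[8:14, 10:16] = 1
        return img, msk

    def test_degenerate_intervals_identity(self, rng):
        img, msk = self._pair(rng)
        params = AugmentParams((0, 0), (0, 0), (0, 0), (1, 1), seed=3)
        out_img, out_msk = augment_pair(img, msk, params)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_msk, msk)

    def test_same_seed_deterministic(self, rng):
        img, msk = self._pair(rng)
        params = AugmentParams(seed=7)
        a = augment_pair(img, msk, params)
        b = augment_pair(img, msk, params)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_mask_stays_binary_and_shapes_match(self, rng):
        img, msk = self._pair(rng)
        for seed in range(20):
            out_img, out_msk = augment_pair(img, msk, AugmentParams(seed=seed))
            assert out_img.shape == img.shape
            assert set(np.unique(out_msk)) <= {0, 1}

    def test_pure_rotation_matches_reference(self, rng):
        from scipy import ndimage

        img, msk = self._pair(rng)
        params = AugmentParams((10, 10), (0, 0), (0, 0), (1, 1), seed=0)
        out_img, _ = augment_pair(img, msk, params)
        ref = ndimage.rotate(
            img, -10, reshape=False, order=1, mode="constant", cval=0.0
        )
        np.testing.assert_allclose(out_img, ref, atol=1e-3)

    def test_shape_mismatch_rejected(self, rng):
        img, _ = self._pair(rng)
        with pytest.raises(ValueError):
            augment_pair(img, np.zeros((5, 5)), AugmentParams())

    def test_default_intervals_match_reference_settings(self):
        p = AugmentParams()
        assert p.rotation_deg == (-10.0, 10.0)
        assert p.shift_x_px == (-20.0, 20.0)
        assert p.shift_y_px == (-22.0, 22.0)
        assert p.zoom == (0.85, 1.15)

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            AugmentParams(rotation_deg=(5, -5))
        with pytest.raises(ValueError):
            AugmentParams(zoom=(0.0, 1.0))
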