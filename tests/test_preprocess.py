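import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivcfind.preprocess import (
    NormalizationScheme,
    PreprocessConfig,
    CTPreprocessor,
    craniocaudal_cutoff,
    normalize,
    preprocess_volume,
    resample_inplane,
    resample_slices,
    spatial_crop,
)
from ivcfind.volume_io import CTVolume, MaskVolume


def _vol(n=4, h=32, w=32, thickness=5.0, fill=0.0):
    return CTVolume(voxels=np.full((n, h, w), fill, dtype=np.float32),
                    spacing=(thickness, 1.0, 1.0))


class TestSpatialCrop:
    @pytest.mark.parametrize("extent,fraction,expected", [
        (512, 0.2, 307),   # the clinical grid: 512 -> 307
        (100, 0.2, 60),
        (256, 0.1, 204),
    ])
    def test_retained_extent(self, extent, fraction, expected):
        out = spatial_crop(_vol(h=extent, w=extent), fraction)
        assert out.voxels.shape[1:] == (expected, expected)

    def test_zero_fraction_is_identity(self, rng):
        vol = CTVolume(voxels=rng.normal(size=(3, 20, 24)).astype(np.float32),
                       spacing=(5, 1, 1))
        np.testing.assert_array_equal(spatial_crop(vol, 0.0).voxels, vol.voxels)

    def test_window_is_centered_with_trailing_remainder(self):
        vol = _vol(n=1, h=512, w=512)
        vol.voxels[0, 102, 102] = 77.0
        out = spatial_crop(vol, 0.2)
        # leading margin floor(512*0.2)=102, so (102,102) maps to (0,0)
        assert out.voxels[0, 0, 0] == 77.0

    def test_mask_and_volume_stay_aligned(self, small_phantom):
        vol, mask = small_phantom
        cv = spatial_crop(vol, 0.15)
        cm = spatial_crop(mask, 0.15)
        assert cv.voxels.shape == cm.labels.shape
        # foreground voxels still carry metal HU in the cropped volume
        assert (cv.voxels[cm.labels > 0] > 2000).all()

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            spatial_crop(_vol(), 0.5)


class TestCraniocaudalCutoff:
    @pytest.mark.parametrize("n,thickness,expected", [
        (200, 5.0, 80),    # 400 mm / 5 mm
        (50, 5.0, 50),     # scan shorter than the cutoff
        (100, 3.0, 100),   # ceil(400/3)=134 capped at 100
        (150, 3.0, 134),
    ])
    def test_kept_slice_count(self, n, thickness, expected):
        out = craniocaudal_cutoff(_vol(n=n, thickness=thickness), cutoff_mm=400.0)
        assert out.n_slices == expected

    def test_cutoff_oracle_sum_thickness(self):
        # independent oracle: keep slices whose center offset k*t is < 400
        for n, t in [(150, 3.0), (200, 5.0), (77, 7.5)]:
            expected = sum(1 for k in range(n) if k * t < 400.0)
            assert craniocaudal_cutoff(_vol(n=n, thickness=t)).n_slices == expected

    def test_keeps_cranial_end(self):
        vol = _vol(n=10, thickness=100.0)
        vol.voxels[0] = 1.0
        out = craniocaudal_cutoff(vol, cutoff_mm=400.0)
        assert out.n_slices == 4 and out.voxels[0, 0, 0] == 1.0
        flipped = CTVolume(voxels=vol.voxels[::-1].copy(), spacing=vol.spacing,
                           cranial_first=False)
        out2 = craniocaudal_cutoff(flipped, cutoff_mm=400.0)
        assert out2.n_slices == 4 and out2.voxels[-1, 0, 0] == 1.0

    def test_mask_cut_identically(self, small_phantom):
        vol, mask = small_phantom
        v, m = craniocaudal_cutoff(vol, mask, cutoff_mm=60.0)
        assert v.voxels.shape == m.labels.shape == (12, 96, 96)


class TestResampling:
    def test_inplane_to_model_grid(self):
        out = resample_inplane(_vol(h=307, w=307), (256, 256))
        assert out.voxels.shape == (4, 256, 256)
        assert out.spacing[1] == pytest.approx(307 / 256)

    def test_identity_when_shape_matches(self, rng):
        vol = CTVolume(voxels=rng.normal(size=(2, 16, 16)).astype(np.float32),
                       spacing=(5, 1, 1))
        np.testing.assert_array_equal(resample_inplane(vol, (16, 16)).voxels, vol.voxels)
        np.testing.assert_array_equal(resample_slices(vol, 2).voxels, vol.voxels)

    def test_mask_labels_closed_under_resampling(self, small_phantom):
        _, mask = small_phantom
        out = resample_inplane(mask, (64, 64))
        assert set(np.unique(out.labels)) <= {0, 1}
        out2 = resample_slices(mask, 16)
        assert set(np.unique(out2.labels)) <= {0, 1}

    def test_slice_axis_count_and_spacing(self):
        out = resample_slices(_vol(n=160, thickness=2.0), 128)
        assert out.n_slices == 128
        assert out.spacing[0] == pytest.approx(2.0 * 160 / 128)


class TestNormalize:
    def test_hard_window_endpoints_and_clipping(self):
        vol = _vol(n=1, h=2, w=3)
        vol.voxels[0] = [[1.0, 2500.0, 3000.0], [-500.0, 1250.5, 0.0]]
        out = normalize(vol, NormalizationScheme(mode="hard")).voxels[0]
        assert out[0, 0] == 0.0
        assert out[0, 1] == 1.0
        assert out[0, 2] == 1.0          # clipped above
        assert out[1, 0] == 0.0          # clipped below
        assert out[1, 1] == pytest.approx((1250.5 - 1) / (2500 - 1))

    def test_soft_uses_volume_min_max(self):
        vol = _vol(n=1, h=1, w=3)
        vol.voxels[0] = [[-100.0, 0.0, 300.0]]
        out = normalize(vol, NormalizationScheme(mode="soft")).voxels
        assert out.min() == 0.0 and out.max() == 1.0
        assert out[0, 0, 1] == pytest.approx(0.25)

    def test_soft_constant_volume_all_zero(self):
        out = normalize(_vol(fill=55.0), NormalizationScheme(mode="soft"))
        assert (out.voxels == 0).all()

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_hard_normalization_bounded_and_monotone(self, seed):
        r = np.random.default_rng(seed)
        hu = r.uniform(-1500, 4000, size=64).astype(np.float32)
        vol = CTVolume(voxels=hu.reshape(1, 8, 8), spacing=(1, 1, 1))
        out = normalize(vol, NormalizationScheme()).voxels.ravel()
        assert ((0 <= out) & (out <= 1)).all()
        order = np.argsort(hu)
        assert (np.diff(out[order]) >= -1e-7).all()


class TestFullChain:
    def test_phantom_512_reaches_model_grid(self):
        from ivcfind.phantom import PhantomSpec, generate_phantom

        vol, mask = generate_phantom(PhantomSpec(shape=(20, 512, 512), seed=3,
                                                 filter=None))
        out = preprocess_volume(vol, None, PreprocessConfig(target_n_slices=16))
        assert out.voxels.shape == (16, 256, 256)
        assert 0.0 <= out.voxels.min() and out.voxels.max() <= 1.0

    def test_transformer_pair_alignment(self, small_phantom):
        vol, mask = small_phantom
        pre = CTPreprocessor(crop_fraction=0.0, target_slice_shape=(48, 48),
                             target_n_slices=24)
        v, m = pre.fit().transform_pair(vol, mask)
        assert v.voxels.shape == m.labels.shape == (24, 48, 48)
        # metal survives hard normalization at the window ceiling; ring edges
        # are diluted by partial volume when downsampling, so check the median
        assert np.median(v.voxels[m.labels > 0]) >= 0.8

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(crop_fraction=0.6)
        with pytest.raises(ValueError):
            NormalizationScheme(hard_min_hu=10, hard_max_hu=10)
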