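"""Preprocessing chain: resampling oracles, bilateral filter, reslicing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbfseg.preprocess import (
    augment_training_set,
    correct_anisotropy,
    correct_anisotropy_labels,
    denoise_bilateral,
    normalize,
    resize_labels,
    resize_to_cube,
    reslice,
    unreslice,
)
from sbfseg.synthetic import degrade_anisotropic, generate_phantom
from sbfseg.volumes import LabelVolume, RawVolume, VoxelSpacing
from tests.conftest import small_spec

ISO = VoxelSpacing(1.0, 1.0, 1.0)


def _raw(data, spacing=ISO, normalized=False):
    return RawVolume(data=data, spacing=spacing, normalized=normalized)


class TestCorrectAnisotropy:
    def test_isotropic_identity(self):
        vol = _raw(np.arange(8, dtype=np.uint8).reshape(2, 2, 2))
        assert correct_anisotropy(vol) is vol

    def test_factor_two_duplicates_slices(self):
        data = (np.arange(5 * 8 * 8) % 256).astype(np.uint8).reshape(5, 8, 8)
        vol = _raw(data, VoxelSpacing(2.0, 1.0, 1.0))
        out = correct_anisotropy(vol)
        assert out.shape == (10, 8, 8)
        assert out.spacing.is_isotropic
        for i in range(10):
            assert np.array_equal(out.data[i], data[i // 2])

    def test_value_set_preserved(self):
        data = np.zeros((4, 4, 4), dtype=np.uint8)
        data[0, 0, 0] = 7
        data[1, 1, 1] = 255
        out = correct_anisotropy(_raw(data, VoxelSpacing(3.0, 1.0, 1.0)))
        assert set(np.unique(out.data)) <= {0, 7, 255}

    @pytest.mark.parametrize("factor", [2, 3])
    def test_degrade_then_correct_matches_index_oracle(self, factor):
        raw, _ = generate_phantom(small_spec(stage=2, seed=8, cube_side=48))
        deg = degrade_anisotropic(raw, factor)
        out = correct_anisotropy(deg)
        assert out.shape[0] == 48
        # nearest-neighbor index mapping: out[i] = degraded[floor(i/factor)]
        for i in range(out.shape[0]):
            assert np.array_equal(out.data[i], deg.data[i // factor])


class TestBilateral:
    def test_constant_volume_unchanged(self):
        vol = _raw(np.full((3, 8, 8), 77, dtype=np.uint8))
        out = denoise_bilateral(vol)
        assert np.array_equal(out.data, vol.data)

    def test_gaussian_limit(self, rng):
        """sigma_range -> inf reduces to a windowed Gaussian spatial blur."""
        img = rng.random((1, 9, 9)).astype(np.float64)
        vol = _raw(img.astype(np.float32), normalized=True)
        sigma = 1.2
        out = denoise_bilateral(vol, sigma_spatial=sigma, sigma_range=1e12)
        # independent brute-force evaluation of the limiting filter
        r = int(np.ceil(3 * sigma))
        expected = np.zeros((9, 9))
        for y in range(9):
            for x in range(9):
                num = den = 0.0
                for dy in range(-r, r + 1):
                    for dx in range(-r, r + 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < 9 and 0 <= xx < 9:
                            w = np.exp(-(dy * dy + dx * dx) / (2 * sigma**2))
                            num += w * img[0, yy, xx]
                            den += w
                expected[y, x] = num / den
        assert np.allclose(out.data[0], expected, atol=1e-6)

    def test_salt_voxel_reduced(self):
        data = np.full((1, 9, 9), 10, dtype=np.uint8)
        data[0, 4, 4] = 250
        out = denoise_bilateral(_raw(data), sigma_spatial=1.5, sigma_range=200.0)
        assert out.data[0, 4, 4] < 250

    def test_output_range_within_input_range(self, rng):
        data = rng.integers(40, 200, (4, 12, 12), dtype=np.uint8)
        out = denoise_bilateral(_raw(data))
        assert out.data.min() >= data.min()
        assert out.data.max() <= data.max()

    @pytest.mark.parametrize("kwargs", [{"sigma_spatial": 0.0},
                                        {"sigma_range": -1.0}])
    def test_nonpositive_sigma_rejected(self, kwargs):
        vol = _raw(np.zeros((2, 4, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="positive"):
            denoise_bilateral(vol, **kwargs)


class TestResize:
    def test_identity(self):
        vol = _raw(np.zeros((16, 16, 16), dtype=np.uint8))
        assert resize_to_cube(vol, 16) is vol

    def test_checkerboard_duplication(self):
        base = np.indices((4, 4, 4)).sum(axis=0) % 2
        vol = _raw((base * 255).astype(np.uint8))
        out = resize_to_cube(vol, 8)
        assert out.shape == (8, 8, 8)
        for axis_idx in np.ndindex(8, 8, 8):
            src = tuple(i // 2 for i in axis_idx)
            assert out.data[axis_idx] == vol.data[src]

    def test_labels_never_blended(self):
        data = np.zeros((5, 5, 5), dtype=np.uint8)
        data[2, 2, 2] = 4
        out = resize_labels(LabelVolume(data=data), 16)
        assert out.value_set() <= {0, 4}
        assert out.shape == (16, 16, 16)

    def test_label_anisotropy_correction_matches_raw_operator(self):
        lab = LabelVolume(data=np.arange(5 * 4 * 4, dtype=np.uint8).reshape(5, 4, 4) % 6)
        out = correct_anisotropy_labels(lab, VoxelSpacing(2.0, 1.0, 1.0))
        assert out.shape == (10, 4, 4)
        for i in range(10):
            assert np.array_equal(out.data[i], lab.data[i // 2])


class TestNormalize:
    def test_values(self):
        data = np.array([[[0, 51, 255]]], dtype=np.uint8)
        out = normalize(_raw(data))
        assert out.normalized
        assert out.data[0, 0, 0] == 0.0
        assert out.data[0, 0, 2] == 1.0
        assert abs(out.data[0, 0, 1] - 0.2) < 1e-6

    def test_double_normalize_rejected(self):
        out = normalize(_raw(np.zeros((2, 2, 2), dtype=np.uint8)))
        with pytest.raises(ValueError, match="already"):
            normalize(out)


class TestReslice:
    @pytest.mark.parametrize("axis", ["z", "y", "x"])
    def test_round_trip_bit_identical(self, axis, rng):
        data = rng.integers(0, 256, (6, 6, 6), dtype=np.uint8)
        vol = _raw(data)
        assert np.array_equal(unreslice(reslice(vol, axis)), data)

    def test_index_bookkeeping(self):
        data = np.zeros((6, 6, 6), dtype=np.uint8)
        data[1, 2, 3] = 9
        batch = reslice(_raw(data), "y")
        assert batch.slices[2, 1, 3] == 9  # section index = y coordinate
        assert not batch.slices[1].any()

    def test_shape_arithmetic(self):
        batch = reslice(_raw(np.zeros((4, 5, 6), dtype=np.uint8)), "z")
        assert len(batch) == 4
        assert batch.slices.shape == (4, 5, 6)

    def test_anisotropic_rejected(self):
        vol = _raw(np.zeros((4, 4, 4), dtype=np.uint8), VoxelSpacing(2, 1, 1))
        with pytest.raises(ValueError, match="anisotropic"):
            reslice(vol, "z")

    def test_label_volumes_resliceable(self):
        lab = LabelVolume(data=np.zeros((4, 4, 4), dtype=np.uint8))
        assert np.array_equal(unreslice(reslice(lab, "x")), lab.data)


class TestAugment:
    def test_section_counts(self):
        side = 64
        raw = _raw(np.zeros((side,) * 3, dtype=np.uint8))
        lab = LabelVolume(data=np.zeros((side,) * 3, dtype=np.uint8))
        pairs = augment_training_set([(raw, lab)])
        assert sum(len(rb) for rb, _ in pairs) == 3 * side

    def test_empty_input(self):
        assert augment_training_set([]) == []

    def test_mismatched_shapes_rejected(self):
        raw = _raw(np.zeros((16, 16, 16), dtype=np.uint8))
        lab = LabelVolume(data=np.zeros((16, 16, 17), dtype=np.uint8))
        with pytest.raises(ValueError, match="shape"):
            augment_training_set([(raw, lab)])


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16), axis=st.sampled_from(["z", "y", "x"]))
def test_reslice_is_voxel_bijection(seed, axis):
    """Every voxel appears exactly once in the batch, and comes back."""
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 256, (4, 5, 6), dtype=np.uint8)
    batch = reslice(RawVolume(data=data, spacing=ISO), axis)
    assert sorted(batch.slices.ravel()) == sorted(data.ravel())
    assert np.array_equal(unreslice(batch), data)
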