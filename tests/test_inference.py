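"""Per-axis prediction assembly, three-axis fusion, thresholding, masking."""

import numpy as np
import pytest

from hcnet.inference import (
    AxisProbabilityVolume,
    extract_brain,
    fuse_axes,
    predict_axis,
    skull_strip,
    threshold_mask,
)
from hcnet.model import HCNet, HCNetConfig
from hcnet.phantom import PhantomSpec, generate_phantom
from hcnet.volume_io import MaskVolume, Volume, normalize_intensity

TINY = HCNetConfig(cube_size=16, channel_widths=(2, 3, 4, 5, 6), seed=0)


@pytest.fixture(scope="module")
def tiny_model():
    return HCNet(TINY)


@pytest.fixture(scope="module")
def tiny_cube():
    vol, mask = generate_phantom(PhantomSpec(grid_size=16, seed=11))
    return normalize_intensity(vol), mask


class TestPredictAxis:
    def test_full_slice_coverage_and_range(self, tiny_model, tiny_cube):
        cube, _ = tiny_cube
        for axis in (0, 1, 2):
            out = predict_axis(tiny_model, cube, axis)
            assert out.probabilities.shape == (16, 16, 16)
            assert np.isfinite(out.probabilities).all()
            assert out.probabilities.min() >= 0 and out.probabilities.max() <= 1

    def test_deterministic(self, tiny_model, tiny_cube):
        cube, _ = tiny_cube
        a = predict_axis(tiny_model, cube, 0).probabilities
        b = predict_axis(tiny_model, cube, 0).probabilities
        np.testing.assert_array_equal(a, b)

    def test_forced_constant_head_gives_unit_probability(self, tiny_cube):
        """Zero head weights with a (-20, +20) bias put brain probability at 1."""
        cube, _ = tiny_cube
        model = HCNet(TINY)
        model.head.w.value[...] = 0.0
        model.head.b.value[...] = (-20.0, 20.0)
        out = predict_axis(model, cube, 1)
        np.testing.assert_array_equal(out.probabilities, 1.0)

    def test_cube_size_mismatch_rejected(self, tiny_model):
        wrong = Volume(np.zeros((32, 32, 32), dtype=np.float32), (1, 1, 1))
        with pytest.raises(ValueError, match="does not match"):
            predict_axis(tiny_model, wrong, 0)

    def test_middle_slices_written_from_block_centers(self, tiny_model, tiny_cube):
        """Batch boundary handling: assembly is independent of batch size."""
        cube, _ = tiny_cube
        a = predict_axis(tiny_model, cube, 2, batch_size=3).probabilities
        b = predict_axis(tiny_model, cube, 2, batch_size=20).probabilities
        np.testing.assert_allclose(a, b, atol=1e-6)


def _apv(arr, axis=0):
    return AxisProbabilityVolume(arr.astype(np.float32), axis)


class TestFusion:
    def test_mean_of_three_values(self):
        shape = (4, 4, 4)
        p = [_apv(np.full(shape, v), a) for a, v in enumerate((0.2, 0.4, 0.9))]
        np.testing.assert_allclose(fuse_axes(*p), 0.5, atol=1e-7)

    def test_idempotent_on_identical_maps(self, rng):
        m = rng.random((4, 4, 4), dtype=np.float32)
        fused = fuse_axes(_apv(m, 0), _apv(m, 1), _apv(m, 2))
        np.testing.assert_allclose(fused, m, atol=1e-7)

    def test_permutation_invariant(self, rng):
        maps = [_apv(rng.random((4, 4, 4), dtype=np.float32), a) for a in range(3)]
        f1 = fuse_axes(*maps)
        f2 = fuse_axes(maps[2], maps[0], maps[1])
        np.testing.assert_allclose(f1, f2, atol=1e-7)

    def test_bounded_by_min_and_max(self, rng):
        maps = [_apv(rng.random((5, 5, 5), dtype=np.float32), a) for a in range(3)]
        fused = fuse_axes(*maps)
        stack = np.stack([m.probabilities for m in maps])
        assert (fused >= stack.min(axis=0) - 1e-7).all()
        assert (fused <= stack.max(axis=0) + 1e-7).all()

    def test_majority_vote_rule(self):
        shape = (2, 2, 2)
        maps = [_apv(np.full(shape, v), a) for a, v in enumerate((0.9, 0.8, 0.1))]
        np.testing.assert_array_equal(fuse_axes(*maps, rule="vote"), 1.0)

    def test_shape_mismatch_rejected(self, rng):
        a = _apv(rng.random((4, 4, 4)), 0)
        b = _apv(rng.random((5, 5, 5)), 1)
        with pytest.raises(ValueError, match="shape"):
            fuse_axes(a, b, a)


class TestThreshold:
    def test_above_threshold_all_ones(self):
        assert (threshold_mask(np.full((3, 3, 3), 0.6), 0.5) == 1).all()

    def test_tie_counts_as_brain(self):
        assert threshold_mask(np.array([[[0.5]]]), 0.5)[0, 0, 0] == 1

    def test_threshold_one_on_lesser_values(self):
        assert (threshold_mask(np.full((2, 2, 2), 0.999), 1.0) == 0).all()

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            threshold_mask(np.zeros((2, 2, 2)), 1.5)


class TestExtractBrain:
    def test_all_ones_mask_is_identity(self, rng):
        v = Volume(rng.random((4, 4, 4), dtype=np.float32), (1, 1, 1))
        m = MaskVolume(np.ones((4, 4, 4), np.uint8), (1, 1, 1))
        np.testing.assert_array_equal(extract_brain(v, m).voxels, v.voxels)

    def test_all_zeros_mask_zeroes_volume(self, rng):
        v = Volume(rng.random((4, 4, 4), dtype=np.float32) + 1, (1, 1, 1))
        m = MaskVolume(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
        assert (extract_brain(v, m).voxels == 0).all()

    def test_support_equals_mask(self, rng):
        v = Volume(rng.random((5, 5, 5), dtype=np.float32) + 0.5, (1, 1, 1))
        m = MaskVolume((rng.random((5, 5, 5)) > 0.5).astype(np.uint8), (1, 1, 1))
        out = extract_brain(v, m)
        np.testing.assert_array_equal(out.voxels != 0, m.voxels.astype(bool))

    def test_shape_mismatch(self, rng):
        v = Volume(rng.random((4, 4, 4)), (1, 1, 1))
        m = MaskVolume(np.zeros((5, 5, 5), np.uint8), (1, 1, 1))
        with pytest.raises(ValueError, match="shapes differ"):
            extract_brain(v, m)


class TestSkullStrip:
    def test_end_to_end_native_geometry(self, tiny_model):
        """Anisotropic native volume in, binary native-space mask out."""
        vol, _ = generate_phantom(
            PhantomSpec(grid_size=16, spacing=(0.6, 1.2, 0.6), seed=3)
        )
        native = Volume(vol.voxels[:, :12, :], (0.6, 1.2, 0.6))  # non-cubic grid
        result = skull_strip(native, tiny_model)
        assert result.mask_native.shape == native.shape
        assert set(np.unique(result.mask_native.voxels)) <= {0, 1}
        assert result.fused_probabilities.shape == (16, 16, 16)
        np.testing.assert_array_equal(
            result.mask_cube.voxels,
            threshold_mask(result.fused_probabilities, result.threshold),
        )
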