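import numpy as np
import pytest

from perinet.bounding import (
    OPTION_SHAPES,
    extract_2ds,
    extract_sfb,
    extract_svb,
    normalize01,
    resample_isotropic,
    resize,
    run_option,
    split_lesions,
)
from perinet.dce_data import SubtractiveStack

from conftest import make_series
from perinet.dce_data import make_stack


def stack_from_mask(mask, spacing=(1.0, 1.0, 1.0), values=None, label=0):
    mask = np.asarray(mask) > 0
    if values is None:
        values = np.random.default_rng(0).random(mask.shape).astype(np.float32)
    channels = np.stack([values * (i + 1) for i in range(4)], axis=0)
    return SubtractiveStack("S", channels, (1, 2, 3, 4), spacing, mask, label)


def brute_force_components(mask):
    """Flood-fill connected components under 26-connectivity (oracle)."""
    mask = np.asarray(mask) > 0
    seen = np.zeros_like(mask)
    comps = []
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask & ~seen)):
        if seen[start]:
            continue
        comp = np.zeros_like(mask)
        frontier = [start]
        while frontier:
            v = frontier.pop()
            if seen[v] or not mask[v]:
                continue
            seen[v] = True
            comp[v] = True
            for o in offsets:
                w = tuple(np.add(v, o))
                if all(0 <= w[a] < mask.shape[a] for a in range(3)) and mask[w]:
                    frontier.append(w)
        comps.append(comp)
    return comps


class TestSplitLesions:
    def test_single_solid_lesion(self, unifocal_series):
        lesions = split_lesions(unifocal_series.mask)
        assert len(lesions.components) == 1

    def test_two_disjoint_lesions_larger_first(self):
        mask = np.zeros((20, 20, 10), dtype=bool)
        mask[2:5, 2:5, 2:5] = True  # 27 voxels
        mask[10:16, 10:16, 3:7] = True  # 144 voxels
        lesions = split_lesions(mask)
        assert len(lesions.components) == 2
        counts = [c.sum() for c in lesions.components]
        assert counts == sorted(counts, reverse=True)

    def test_corner_touching_cubes_are_one_component(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        mask[5:8, 5:8, 5:8] = True  # touches only at voxel corner (5,5,5)/(4,4,4)
        lesions = split_lesions(mask)
        assert len(lesions.components) == 1

    def test_matches_brute_force_flood_fill(self):
        rng = np.random.default_rng(7)
        mask = rng.random((12, 12, 8)) > 0.8
        if not mask.any():
            mask[0, 0, 0] = True
        lesions = split_lesions(mask)
        oracle = brute_force_components(mask)
        assert len(lesions.components) == len(oracle)
        union = np.zeros_like(mask)
        for c in lesions.components:
            union |= c
        assert np.array_equal(union, mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_lesions(np.zeros((5, 5, 5)))


class TestFixedBox:
    def test_centered_crop_coordinates(self):
        # centroid (100,100,40) in a 256x256x100 grid -> x,y in [20,180), z in [0,80)
        mask = np.zeros((256, 256, 100), dtype=bool)
        mask[100, 100, 40] = True
        vol = np.zeros((256, 256, 100), dtype=np.float32)
        vol[20:180, 20:180, 0:80] = 7.0  # exactly the expected crop region
        stack = stack_from_mask(mask, values=vol)
        channels, _ = extract_sfb(stack)
        assert channels.shape == (4, 160, 160, 80)
        assert np.all(channels[0] == 7.0)

    def test_border_centroid_zero_padded(self):
        mask = np.zeros((64, 64, 32), dtype=bool)
        mask[2, 2, 2] = True
        stack = stack_from_mask(mask, values=np.ones((64, 64, 32), dtype=np.float32))
        channels, _ = extract_sfb(stack)
        assert channels.shape == (4, 160, 160, 80)
        assert channels[0, 0, 0, 0] == 0.0  # padded corner
        assert channels.max() > 0

    def test_oversized_tumor_warns(self):
        mask = np.ones((200, 30, 30), dtype=bool)
        stack = stack_from_mask(mask)
        with pytest.warns(UserWarning, match="exceeds"):
            extract_sfb(stack)


class TestVariableBox:
    def test_cube_side_is_max_extent(self):
        mask = np.zeros((60, 60, 40), dtype=bool)
        mask[10:40, 15:35, 20:30] = True  # extents 30, 20, 10
        stack = stack_from_mask(mask)
        channels, cmask = extract_svb(stack, mask)
        assert channels.shape == (4, 30, 30, 30)
        assert cmask.sum() == mask.sum()

    def test_single_voxel_gives_unit_cube(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[4, 5, 6] = True
        channels, cmask = extract_svb(stack_from_mask(mask), mask)
        assert channels.shape == (4, 1, 1, 1)
        assert cmask.all()

    def test_union_box_contains_both_lesions_and_gap(self):
        mask = np.zeros((60, 30, 20), dtype=bool)
        mask[5:10, 5:10, 5:10] = True
        mask[40:46, 10:22, 8:14] = True  # union bbox extents (41, 17, 9)
        marker = np.zeros(mask.shape, dtype=np.float32)
        marker[20, 10, 9] = 5.0  # tissue between the lesions
        stack = stack_from_mask(mask, values=marker)
        channels, cmask = extract_svb(stack, mask)
        assert channels.shape == (4, 41, 41, 41)
        assert cmask.sum() == mask.sum()
        assert (channels[0] == 5.0).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_crop_contains_mask_and_side_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((30, 25, 20), dtype=bool)
        n = rng.integers(1, 40)
        idx = (
            rng.integers(0, 30, n),
            rng.integers(0, 25, n),
            rng.integers(0, 20, n),
        )
        mask[idx] = True
        coords = np.nonzero(mask)
        side_oracle = max(int(c.max() - c.min() + 1) for c in coords)
        channels, cmask = extract_svb(stack_from_mask(mask), mask)
        assert channels.shape[1:] == (side_oracle,) * 3
        assert cmask.sum() == mask.sum()  # nothing cropped away


class TestIsotropicResampling:
    def test_isotropic_input_is_identity(self, unifocal_stack):
        out = resample_isotropic(unifocal_stack)
        assert out.channels.shape == unifocal_stack.channels.shape
        np.testing.assert_array_equal(out.channels, unifocal_stack.channels)

    def test_axis_length_formula(self):
        mask = np.zeros((10, 10, 60), dtype=bool)
        mask[4:6, 4:6, 25:35] = True
        stack = stack_from_mask(mask, spacing=(0.7, 0.7, 2.4))
        out = resample_isotropic(stack)
        assert out.channels.shape[3] == round(60 * 2.4 / 0.7)  # 206
        assert out.spacing == (0.7, 0.7, 0.7)
        assert out.mask.any()

    def test_constant_volume_stays_constant(self):
        mask = np.zeros((8, 8, 12), dtype=bool)
        mask[3:5, 3:5, 5:7] = True
        vals = np.full((8, 8, 12), 3.5, dtype=np.float32)
        stack = stack_from_mask(mask, spacing=(1.0, 1.0, 2.0), values=vals)
        out = resample_isotropic(stack)
        np.testing.assert_allclose(out.channels[0], 3.5, atol=1e-5)

    def test_nonpositive_spacing_rejected(self, unifocal_stack):
        stack = unifocal_stack
        object.__setattr__(stack, "spacing", (1.0, 0.0, 1.0))
        with pytest.raises(ValueError, match="spacing"):
            resample_isotropic(stack)


class TestSliceExtraction:
    def test_slice_count_matches_lesion_span(self):
        mask = np.zeros((30, 30, 30), dtype=bool)
        mask[8:22, 8:22, 5:21] = True  # z slices 5..20 inclusive -> 16
        stack = stack_from_mask(mask, spacing=(0.7, 0.7, 2.4))
        slices = extract_2ds(stack)
        assert len(slices) == 16

    def test_single_slice_lesion(self):
        mask = np.zeros((20, 20, 10), dtype=bool)
        mask[5:9, 5:9, 4] = True
        stack = stack_from_mask(mask, spacing=(1.0, 1.0, 3.0))
        slices = extract_2ds(stack)
        assert len(slices) == 1

    def test_gap_slices_excluded(self):
        mask = np.zeros((40, 40, 24), dtype=bool)
        mask[10:20, 10:20, 4:7] = True
        mask[10:20, 10:20, 11:14] = True  # 4-slice lesion-free gap at z=7..10
        stack = stack_from_mask(mask, spacing=(0.7, 0.7, 2.4))
        slices = extract_2ds(stack)
        # per-slice mask-sum oracle on the SVB crop
        _, cmask = extract_svb(stack, mask)
        expected = int((cmask.sum(axis=(0, 1)) > 0).sum())
        assert len(slices) == expected
        assert expected == 6

    def test_slicing_axis_is_coarsest_with_tie_toward_last(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[4:8, 4:8, 4:8] = True
        # values vary along x only, so x-slices are constant images
        vals = np.broadcast_to(
            np.arange(12, dtype=np.float32)[:, None, None], (12, 12, 12)
        ).copy()
        sx = extract_2ds(stack_from_mask(mask, spacing=(3.0, 1.0, 1.0), values=vals))
        assert len(sx) == 4
        for _, img in sx:
            assert np.ptp(img[0]) == 0.0  # sliced along the coarse x axis
        # equal spacing: tie breaks toward z; slices then vary along x
        st = extract_2ds(stack_from_mask(mask, spacing=(1.0, 1.0, 1.0), values=vals))
        assert len(st) == 4
        assert all(np.ptp(img[0]) > 0 for _, img in st)


class TestResizeNormalize:
    def test_resize_identity(self):
        data = np.random.default_rng(0).random((4, 64, 64, 64)).astype(np.float32)
        out = resize(data, (64, 64, 64))
        np.testing.assert_array_equal(out, data)

    def test_resize_constant(self):
        data = np.full((4, 10, 12, 8), 2.0, dtype=np.float32)
        out = resize(data, (64, 64, 64))
        np.testing.assert_allclose(out, 2.0, atol=1e-5)

    def test_downscale_preserves_linear_ramp(self):
        x = np.linspace(0, 1, 64, dtype=np.float32)
        ramp = np.broadcast_to(x[:, None, None], (64, 64, 64))
        data = np.stack([ramp] * 4).astype(np.float32)
        out = resize(data, (32, 32, 32))
        profile = out[0, :, 16, 16]
        diffs = np.diff(profile[1:-1])  # interior: constant slope
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-4)

    def test_normalize_range_and_constant(self):
        data = np.arange(-4.0, 5.0, dtype=np.float32).reshape(1, 9, 1, 1)
        data = np.concatenate([data] * 4, axis=0)
        out = normalize01(data)
        assert out.min() == 0.0 and out.max() == 1.0
        assert np.all(normalize01(np.full((4, 3, 3, 3), 9.0)) == 0.0)

    def test_normalize_affine_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.random((4, 6, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(
            normalize01(v), normalize01(1.7 * v + 3.0), atol=1e-5
        )


class TestRunOption:
    def test_unifocal_slvb_equals_svb(self, unifocal_stack):
        svb = run_option(unifocal_stack, "svb")
        slvb = run_option(unifocal_stack, "slvb")
        assert len(svb) == len(slvb) == 1
        np.testing.assert_allclose(svb[0].data, slvb[0].data, atol=1e-6)

    def test_multi_lesion_slvb_sample_count(self):
        series = make_series(
            grid=(40, 40, 24),
            lesion_centers=((8, 8, 6), (20, 20, 12), (32, 32, 18)),
            lesion_radii=((2, 2, 2),) * 3,
            label=1,
        )
        samples = run_option(make_stack(series), "slvb")
        assert len(samples) == 3
        assert {s.lesion_id for s in samples} == {1, 2, 3}

    def test_sfb_shape(self, unifocal_stack):
        samples = run_option(unifocal_stack, "sfb")
        assert samples[0].data.shape == (4, 160, 160, 80)

    def test_sib_equals_svb_when_isotropic(self, unifocal_stack):
        svb = run_option(unifocal_stack, "svb")[0]
        sib = run_option(unifocal_stack, "sib")[0]
        np.testing.assert_allclose(svb.data, sib.data, atol=1e-6)

    @pytest.mark.parametrize("option", sorted(OPTION_SHAPES))
    def test_canonical_shapes_and_unit_range(self, bifocal_stack, option):
        for s in run_option(bifocal_stack, option):
            assert s.data.shape == OPTION_SHAPES[option]
            assert 0.0 <= s.data.min() and s.data.max() <= 1.0

    def test_unknown_option_rejected(self, unifocal_stack):
        with pytest.raises(ValueError, match="unknown bounding option"):
            run_option(unifocal_stack, "box")
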