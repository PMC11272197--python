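"""Segmentation pipeline: normalization, torso, fat, SAT/VAT split, edits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adiposeg.errors import (
    ConfigurationError,
    DegenerateInputError,
    DomainError,
    EditError,
    EmptySliceError,
)
from adiposeg.phantom import SpineParams, generate_phantom
from adiposeg.segmentation import (
    EditOp,
    EditScript,
    SegmentationParams,
    apply_edits,
    extract_torso,
    normalize_stack,
    segment_fat,
    segment_stack,
    split_sat_vat,
)
from adiposeg.types import ImageStack, MaskStack, dice

from conftest import small_phantom_spec


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_constant_slice_is_degenerate(self):
        stack = ImageStack(np.full((2, 16, 16), 7.0), (1.0, 1.0), 10.0)
        with pytest.raises(DegenerateInputError, match="slice 1"):
            normalize_stack(stack, SegmentationParams())

    def test_idempotent(self, noisy_phantom):
        stack, _ = noisy_phantom
        params = SegmentationParams()
        once = normalize_stack(stack, params)
        twice = normalize_stack(once, params)
        assert np.max(np.abs(twice.voxels - once.voxels)) < 1e-6

    def test_bias_flattening_reduces_within_class_cv(self):
        spec = small_phantom_spec(seed=21, noise_sigma=0.0, bias_field_amplitude=0.3)
        stack, truth = generate_phantom(spec)
        norm = normalize_stack(stack, SegmentationParams())
        fat = truth.sat_mask.labels | truth.vat_mask.labels

        def cv(img):
            v = img[fat]
            return v.std() / v.mean()

        assert cv(norm.voxels) < cv(stack.voxels)

    def test_off_mode_returns_copy(self, noisy_phantom):
        stack, _ = noisy_phantom
        out = normalize_stack(stack, SegmentationParams(normalization="off"))
        assert np.array_equal(out.voxels, stack.voxels)


# ---------------------------------------------------------------------------
# torso extraction
# ---------------------------------------------------------------------------

class TestTorso:
    def test_all_air_slice_raises_empty_slice(self):
        stack = ImageStack(np.full((1, 32, 32), 5.0), (1.0, 1.0), 10.0)
        params = SegmentationParams(
            air_threshold_mode="fixed", fixed_air_threshold=10.0, normalization="off"
        )
        with pytest.raises(EmptySliceError, match="slice 1"):
            extract_torso(stack, params)

    def test_noiseless_phantom_torso_dice(self, noiseless_phantom):
        stack, truth = noiseless_phantom
        params = SegmentationParams()
        norm = normalize_stack(stack, params)
        torso = extract_torso(norm, params)
        assert dice(torso, truth.torso_mask) >= 0.99

    def test_torso_has_no_holes_and_one_component(self, noisy_phantom):
        from scipy import ndimage
        from skimage import measure

        stack, _ = noisy_phantom
        params = SegmentationParams()
        torso = extract_torso(normalize_stack(stack, params), params)
        for z in range(torso.n_slices):
            sl = torso.labels[z]
            assert np.array_equal(ndimage.binary_fill_holes(sl), sl)
            assert measure.label(sl, connectivity=2).max() == 1


# ---------------------------------------------------------------------------
# fat segmentation
# ---------------------------------------------------------------------------

class TestFat:
    def test_ring_only_phantom_recovers_sat_ring(self):
        from adiposeg.phantom import BlobParams

        spec = small_phantom_spec(
            seed=31, noise_sigma=0.05, bias_field_amplitude=0.0,
            vat_blob_params=BlobParams(count=0),
        )
        stack, truth = generate_phantom(spec)
        params = SegmentationParams()
        norm = normalize_stack(stack, params)
        torso = extract_torso(norm, params)
        fat = segment_fat(norm, torso, params)
        assert dice(fat, truth.sat_mask) >= 0.95

    def test_threshold_above_max_gives_empty_mask(self, noisy_phantom):
        stack, _ = noisy_phantom
        params = SegmentationParams()
        norm = normalize_stack(stack, params)
        torso = extract_torso(norm, params)
        high = SegmentationParams(fat_threshold_mode="fixed", fixed_fat_threshold=2.0)
        fat = segment_fat(norm, torso, high)
        assert fat.voxel_count() == 0

    def test_fat_is_subset_of_torso_over_seeds(self):
        for seed in range(5):
            stack, _ = generate_phantom(small_phantom_spec(seed=seed))
            params = SegmentationParams()
            norm = normalize_stack(stack, params)
            torso = extract_torso(norm, params)
            fat = segment_fat(norm, torso, params)
            assert fat.is_subset_of(torso)

    def test_fixed_threshold_monotonicity(self, noisy_phantom):
        stack, _ = noisy_phantom
        params = SegmentationParams()
        norm = normalize_stack(stack, params)
        torso = extract_torso(norm, params)
        counts = []
        for thr in (0.3, 0.5, 0.7, 0.9):
            p = SegmentationParams(fat_threshold_mode="fixed", fixed_fat_threshold=thr)
            counts.append(segment_fat(norm, torso, p).voxel_count())
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# SAT/VAT split
# ---------------------------------------------------------------------------

class TestSplit:
    def test_noiseless_phantom_sat_vat_dice(self, noiseless_phantom):
        stack, truth = noiseless_phantom
        result = segment_stack(stack)
        assert dice(result.sat, truth.sat_mask) >= 0.95
        assert dice(result.vat, truth.vat_mask) >= 0.95

    def test_empty_fat_gives_empty_compartments(self):
        nz, nr, nc = 2, 32, 32
        torso = np.zeros((nz, nr, nc), bool)
        torso[:, 4:28, 4:28] = True
        fat = np.zeros_like(torso)
        result = split_sat_vat(MaskStack(fat), MaskStack(torso), SegmentationParams())
        assert result.sat.voxel_count() == 0
        assert result.vat.voxel_count() == 0
        assert result.nonvat.voxel_count() == 0

    def test_fat_outside_torso_is_precondition_error(self):
        torso = np.zeros((1, 16, 16), bool)
        torso[:, 4:12, 4:12] = True
        fat = np.zeros_like(torso)
        fat[:, 0:3, 0:3] = True
        with pytest.raises(DomainError, match="subset"):
            split_sat_vat(MaskStack(fat), MaskStack(torso), SegmentationParams())

    def test_isolated_interior_fat_yields_no_sat_with_warning(self):
        torso = np.zeros((1, 48, 48), bool)
        torso[:, 2:46, 2:46] = True
        fat = np.zeros_like(torso)
        fat[:, 20:28, 20:28] = True  # far from the torso boundary band
        result = split_sat_vat(MaskStack(fat), MaskStack(torso), SegmentationParams())
        assert result.sat.voxel_count() == 0
        assert result.vat.voxel_count() == fat.sum()
        warnings = [e for e in result.log if e.get("warnings")]
        assert any("no SAT" in w for e in warnings for w in e["warnings"])

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_of_fat_mask_on_phantoms(self, seed):
        stack, _ = generate_phantom(small_phantom_spec(seed=seed))
        params = SegmentationParams()
        norm = normalize_stack(stack, params)
        torso = extract_torso(norm, params)
        fat = segment_fat(norm, torso, params)
        result = split_sat_vat(fat, torso, params, pixel_spacing_mm=stack.pixel_spacing_mm)
        assert np.array_equal(result.sat.labels | result.vat.labels, fat.labels)
        assert result.sat.is_disjoint_from(result.vat)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_partition_property_on_random_masks(self, seed):
        """SAT u VAT = fat and SAT n VAT = {} for arbitrary mask shapes."""
        rng = np.random.default_rng(seed)
        from scipy import ndimage

        blur = ndimage.gaussian_filter(rng.random((1, 40, 40)), 3)
        torso = blur > np.quantile(blur, 0.4)
        torso[:, [0, -1], :] = False
        torso[:, :, [0, -1]] = False
        fat = torso & (rng.random(torso.shape) < 0.5)
        result = split_sat_vat(MaskStack(fat), MaskStack(torso), SegmentationParams())
        assert np.array_equal(result.sat.labels | result.vat.labels, fat)
        assert result.sat.is_disjoint_from(result.vat)

    def test_determinism_identical_results(self, noisy_phantom):
        stack, _ = noisy_phantom
        a = segment_stack(stack)
        b = segment_stack(stack)
        assert np.array_equal(a.sat.labels, b.sat.labels)
        assert np.array_equal(a.vat.labels, b.vat.labels)
        assert np.array_equal(a.nonvat.labels, b.nonvat.labels)

    def test_rotation_equivariance_90_degrees(self):
        stack, _ = generate_phantom(small_phantom_spec(seed=33))
        rot = ImageStack(
            np.rot90(stack.voxels, k=1, axes=(1, 2)).copy(),
            stack.pixel_spacing_mm,
            stack.slice_thickness_mm,
        )
        a = segment_stack(stack)
        b = segment_stack(rot)
        for name in ("sat", "vat", "torso"):
            expected = np.rot90(getattr(a, name).labels, k=1, axes=(1, 2))
            assert np.array_equal(expected, getattr(b, name).labels), name

    def test_stage_log_is_complete_and_unique(self, noisy_phantom):
        stack, _ = noisy_phantom
        result = segment_stack(stack)
        stages = [e["stage"] for e in result.log]
        assert len(stages) == len(set(stages))
        for stage in ("normalize", "torso", "fat", "erode", "assign", "nonvat"):
            assert stage in stages


# ---------------------------------------------------------------------------
# scripted edits
# ---------------------------------------------------------------------------

class TestEdits:
    def test_empty_script_is_identity(self, handmade_result):
        out = apply_edits(handmade_result, EditScript())
        assert np.array_equal(out.sat.labels, handmade_result.sat.labels)
        assert np.array_equal(out.vat.labels, handmade_result.vat.labels)

    def test_add_then_remove_restores_masks(self, handmade_result):
        region = [(15.0, 25.0), (15.0, 33.0), (19.0, 33.0), (19.0, 25.0)]
        script = EditScript(
            [
                EditOp(slice_index=2, compartment="SAT", action="add", polygon=region),
                EditOp(slice_index=2, compartment="SAT", action="remove", polygon=region),
            ]
        )
        out = apply_edits(handmade_result, script)
        assert np.array_equal(out.sat.labels, handmade_result.sat.labels)
        assert np.array_equal(out.vat.labels, handmade_result.vat.labels)
        assert np.array_equal(out.nonvat.labels, handmade_result.nonvat.labels)

    def test_add_steals_voxels_from_other_compartment(self, handmade_result):
        region = [(19.0, 19.0), (19.0, 27.0), (27.0, 27.0), (27.0, 19.0)]
        script = EditScript([EditOp(2, "SAT", "add", polygon=region)])
        out = apply_edits(handmade_result, script)
        assert out.sat.is_disjoint_from(out.vat)
        assert out.vat.voxel_count() < handmade_result.vat.voxel_count()

    def test_reassign_moves_between_sat_and_vat(self, handmade_result):
        region = [(19.0, 19.0), (19.0, 27.0), (27.0, 27.0), (27.0, 19.0)]
        script = EditScript([EditOp(2, "SAT", "reassign", polygon=region)])
        out = apply_edits(handmade_result, script)
        moved = handmade_result.vat.labels[1] & ~out.vat.labels[1]
        assert moved.sum() > 0
        assert np.all(out.sat.labels[1][moved])
        total = handmade_result.sat.voxel_count() + handmade_result.vat.voxel_count()
        assert out.sat.voxel_count() + out.vat.voxel_count() == total

    def test_spinal_fat_removal_mirrors_manual_cleanup(self):
        spec = small_phantom_spec(
            seed=41, spine_params=SpineParams(body_radius_mm=8, fat_radius_mm=5)
        )
        stack, truth = generate_phantom(spec)
        result = segment_stack(stack)
        ops = []
        for z in range(stack.n_slices):
            region = truth.spine_fat_mask.labels[z]
            if region.any():
                ops.append(EditOp(z + 1, "SAT", "remove", mask=region))
                ops.append(EditOp(z + 1, "VAT", "remove", mask=region))
        edited = apply_edits(result, EditScript(ops))
        assert not np.any(edited.sat.labels & truth.spine_fat_mask.labels)
        assert not np.any(edited.vat.labels & truth.spine_fat_mask.labels)

    def test_polygon_outside_grid_names_offending_edit(self, handmade_result):
        script = EditScript(
            [
                EditOp(1, "SAT", "add", polygon=[(0.0, 0.0), (0.0, 5.0), (5.0, 5.0)]),
                EditOp(1, "VAT", "add", polygon=[(0.0, 0.0), (0.0, 99.0), (99.0, 99.0)]),
            ]
        )
        with pytest.raises(EditError, match="edit 1"):
            apply_edits(handmade_result, script)

    def test_self_intersecting_polygon_rejected(self, handmade_result):
        bowtie = [(5.0, 5.0), (10.0, 10.0), (5.0, 10.0), (10.0, 5.0)]
        script = EditScript([EditOp(1, "SAT", "add", polygon=bowtie)])
        with pytest.raises(EditError, match="self-intersecting"):
            apply_edits(handmade_result, script)

    def test_slice_out_of_range_rejected(self, handmade_result):
        script = EditScript([EditOp(99, "SAT", "remove", polygon=[(1, 1), (1, 2), (2, 2)])])
        with pytest.raises(EditError, match="slice index"):
            apply_edits(handmade_result, script)


class TestParams:
    def test_invalid_radii_rejected(self):
        with pytest.raises(ConfigurationError):
            SegmentationParams(erosion_radius_vox=0)

    def test_fixed_mode_requires_threshold(self):
        with pytest.raises(ConfigurationError):
            SegmentationParams(fat_threshold_mode="fixed")
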