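"""SUVR, ROI features, cube tiling and clinical standardisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epifuse.io_manifest import ClinicalVector, ValidationError, Volume3D
from epifuse.preprocess import (
    CohortStats,
    CoverageError,
    ParcellationAtlas,
    ReferenceError_,
    compute_roi_matrix,
    compute_suvr,
    extract_cubes,
    normalize_pet_suvr,
    standardize_clinical,
)


def toy_atlas():
    """2x2x2 grid: region 1 front half, cerebellar region 2 back half."""
    labels = np.zeros((2, 2, 2), dtype=np.int32)
    labels[0] = 1
    labels[1] = 2
    return ParcellationAtlas(labels=labels, region_ids=(1, 2), cerebellar_ids=(2,))


class TestSuvr:
    def test_constant_pet_gives_unit_suvr(self, atlas):
        pet = Volume3D(np.full(atlas.labels.shape, 3.7, dtype=np.float32))
        prof = compute_suvr(pet, atlas)
        for v in prof.values.values():
            assert v == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_toy_ratio(self):
        atlas = toy_atlas()
        pet = np.zeros((2, 2, 2), dtype=np.float32)
        pet[0] = 4.0  # region 1
        pet[1] = 2.0  # cerebellar reference
        prof = compute_suvr(Volume3D(pet), atlas)
        assert prof.values[1] == pytest.approx(2.0, abs=1e-12)
        assert prof.values[2] == pytest.approx(1.0, abs=1e-12)
        assert prof.reference_mean == pytest.approx(2.0)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        atlas = toy_atlas()
        rng = np.random.default_rng(0)
        base = rng.uniform(0.5, 2.0, (2, 2, 2)).astype(np.float64)
        p1 = compute_suvr(Volume3D(base), atlas)
        p2 = compute_suvr(Volume3D(base * scale), atlas)
        for rid in p1.values:
            assert p2.values[rid] == pytest.approx(p1.values[rid], rel=1e-9)

    def test_cerebellar_self_suvr_is_one(self, atlas, rng):
        pet = Volume3D(rng.uniform(0.5, 2.0, atlas.labels.shape))
        prof = compute_suvr(pet, atlas)
        ref_ids = atlas.cerebellar_ids
        # reference recomputed from its own regional means must be 1
        ref_mask = atlas.cerebellar_mask()
        assert float(pet.data[ref_mask].mean()) / prof.reference_mean == pytest.approx(1.0)
        for rid in ref_ids:
            assert prof.values[rid] == pytest.approx(1.0, abs=1e-6)

    def test_zero_reference_rejected(self):
        atlas = toy_atlas()
        pet = np.zeros((2, 2, 2))
        with pytest.raises(ReferenceError_):
            compute_suvr(Volume3D(pet), atlas)

    def test_empty_region_named(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        labels[0] = 1
        labels[1] = 2
        atlas = ParcellationAtlas(labels=labels, region_ids=(1, 2, 7), cerebellar_ids=(2,))
        with pytest.raises(CoverageError, match="7"):
            compute_suvr(Volume3D(np.ones((2, 2, 2))), atlas)

    def test_voxelwise_normalisation_matches_profile(self, atlas, rng):
        pet = Volume3D(rng.uniform(0.5, 2.0, atlas.labels.shape))
        norm = normalize_pet_suvr(pet, atlas)
        prof = compute_suvr(pet, atlas)
        rid = atlas.region_ids[0]
        mask = atlas.region_mask(rid)
        assert float(norm.data[mask].mean()) == pytest.approx(prof.values[rid], rel=1e-5)


class TestRoiMatrix:
    def test_r2_length_one(self):
        atlas = toy_atlas()
        pet = np.ones((2, 2, 2))
        pet[0] = 2.0
        fv = compute_roi_matrix(Volume3D(pet), atlas)
        assert fv.entries.shape == (1,)
        assert fv.entries[0] == pytest.approx(np.log(2.0))

    def test_r90_length_4005(self):
        from epifuse.preprocess import SUVRProfile

        labels = np.zeros((48, 48, 48), dtype=np.int32)
        # build a 90-region atlas by slicing voxels into 90 runs
        flat = labels.reshape(-1)
        bounds = np.linspace(0, flat.size, 91).astype(int)
        for r in range(90):
            flat[bounds[r] : bounds[r + 1]] = r + 1
        atlas = ParcellationAtlas(
            labels=flat.reshape(48, 48, 48), region_ids=tuple(range(1, 91)),
            cerebellar_ids=(90,),
        )
        prof = SUVRProfile(values={r: 1.0 + 0.01 * r for r in range(1, 91)}, reference_mean=1.0)
        fv = compute_roi_matrix(prof, atlas)
        assert fv.entries.shape == (90 * 89 // 2,) == (4005,)

    def test_identical_values_give_unit_ratios(self):
        atlas = toy_atlas()
        fv = compute_roi_matrix(Volume3D(np.full((2, 2, 2), 5.0)), atlas)
        np.testing.assert_allclose(np.exp(fv.entries), 1.0)

    def test_degenerate_region_count(self):
        labels = np.ones((2, 2, 2), dtype=np.int32)
        atlas = ParcellationAtlas(labels=labels, region_ids=(1,), cerebellar_ids=(1,))
        with pytest.raises(ValidationError, match=">= 2"):
            compute_roi_matrix(Volume3D(np.ones((2, 2, 2))), atlas)


class TestCubes:
    def test_single_cube_identity(self, rng):
        data = rng.random((48, 48, 48)).astype(np.float32)
        cs = extract_cubes(Volume3D(data))
        assert len(cs) == 1
        assert tuple(cs.origins[0]) == (0, 0, 0)
        np.testing.assert_array_equal(cs.cubes[0], data)

    def test_two_cube_volume(self, rng):
        data = rng.random((96, 48, 48)).astype(np.float32)
        cs = extract_cubes(Volume3D(data))
        assert len(cs) == 2
        assert [tuple(o) for o in cs.origins] == [(0, 0, 0), (48, 0, 0)]

    def test_padding_arithmetic(self, rng):
        data = rng.random((50, 48, 48)).astype(np.float32)
        cs = extract_cubes(Volume3D(data), pad_value=0.0)
        assert len(cs) == 2
        second = cs.cubes[1]
        # planes 2..47 of the second cube lie beyond the volume: padding
        assert np.all(second[2:] == 0.0)
        assert np.any(second[:2] != 0.0)

    @settings(max_examples=20, deadline=None)
    @given(
        nx=st.integers(1, 100), ny=st.integers(1, 60), nz=st.integers(1, 60),
    )
    def test_tiling_conserves_voxel_sum(self, nx, ny, nz):
        rng = np.random.default_rng(nx * 7919 + ny * 131 + nz)
        data = rng.random((nx, ny, nz))
        cs = extract_cubes(data, size=48, pad_value=0.0)
        assert cs.cubes.sum() == pytest.approx(data.sum(), rel=1e-6)
        # each voxel covered exactly once: counts add up
        assert len(cs) * 48 ** 3 >= data.size

    def test_every_cube_exactly_sized(self, rng):
        cs = extract_cubes(rng.random((50, 30, 7)), size=48)
        assert cs.cubes.shape[1:] == (48, 48, 48)


class TestClinicalStandardisation:
    def _cohort(self, ages, edus):
        return [ClinicalVector(0, 0, a, 0, e) for a, e in zip(ages, edus)]

    def test_zero_variance_fallback(self):
        stats = CohortStats.fit(self._cohort([40, 40, 40], [10, 12, 14]))
        v = standardize_clinical(ClinicalVector(1, 0, 40, 1, 12), stats)
        assert v[2] == 0.0  # age term centred, not divided

    def test_vector_at_training_means(self):
        stats = CohortStats.fit(self._cohort([30, 50], [10, 14]))
        v = standardize_clinical(ClinicalVector(1, 1, 40, 0, 12), stats)
        np.testing.assert_allclose(v, [1, 1, 0, 0, 0], atol=1e-12)
        assert v.shape == (5,)

    def test_pet_flag_appended_last(self):
        stats = CohortStats.fit(self._cohort([30, 50], [10, 14]))
        clin = ClinicalVector(1, 1, 40, 0, 12, pet_positive=1)
        v = standardize_clinical(clin, stats)
        assert v.shape == (6,)
        assert v[-1] == 1.0

    def test_z_scoring_uses_training_stats(self):
        stats = CohortStats.fit(self._cohort([20, 40], [8, 16]))
        v = standardize_clinical(ClinicalVector(0, 0, 40, 1, 8), stats)
        assert v[2] == pytest.approx((40 - 30) / 10)
        assert v[4] == pytest.approx((8 - 12) / 4)
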