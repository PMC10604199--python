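"""Phantom generator: determinism, mirror geometry, planted effects."""

import numpy as np
import pytest

from epifuse.io_manifest import ValidationError
from epifuse.preprocess import compute_suvr
from epifuse.synthetic_fixtures import (
    PhantomAtlas,
    PhantomSpec,
    ProvenanceError,
    generate_cohort,
    generate_records,
    ground_truth,
    make_atlas,
)

DIMS = (48, 48, 48)


class TestAtlas:
    def test_requested_regions_all_nonempty(self):
        atlas = make_atlas((96, 96, 96), R=4, seed=0)
        for rid in atlas.region_ids:
            assert (atlas.labels == rid).sum() > 0
        assert atlas.n_regions == 4

    def test_hippocampi_are_exact_mirrors(self, atlas):
        left = atlas.labels == PhantomAtlas.HIPPO_LEFT
        right = atlas.labels == PhantomAtlas.HIPPO_RIGHT
        np.testing.assert_array_equal(left[::-1], right)

    def test_deterministic_regeneration(self):
        a = make_atlas(DIMS, R=5, seed=3)
        b = make_atlas(DIMS, R=5, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValidationError, match="R >= 3"):
            make_atlas(DIMS, R=2)


class TestCohort:
    def test_regeneration_is_bit_identical(self, atlas):
        spec = PhantomSpec(dims=DIMS, n_ep=2, n_hc=2, seed=9)
        r1, t1 = generate_records(spec, atlas)
        r2, t2 = generate_records(spec, atlas)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.mri.data, b.mri.data)
            np.testing.assert_array_equal(a.pet.data, b.pet.data)
            assert a.clinical == b.clinical
        assert t1.equals(t2)

    def test_controls_are_symmetric_up_to_noise(self, small_cohort, atlas):
        records, truth = small_cohort
        hc = next(r for r in records if r.label == 0)
        asym = hc.pet.data - hc.pet.data[::-1]
        # residual asymmetry is pure noise: zero-mean, sd ~ sqrt(2)*noise_sd*scale
        assert abs(float(asym.mean())) < 0.01
        ep = next(r for r in records if r.label == 1)
        ep_asym = ep.pet.data - ep.pet.data[::-1]
        hippo = (atlas.labels == 1) | (atlas.labels == 2)
        # within the bilateral target structure the deficit dominates the noise
        assert np.abs(ep_asym[hippo]).mean() > 3 * np.abs(asym[hippo]).mean()

    def test_planted_suvr_deficit_matches_fraction(self, small_cohort, atlas):
        records, truth = small_cohort
        for rec, (_, t) in zip(records, truth.iterrows()):
            prof = compute_suvr(rec.pet, atlas)
            left, right = prof.values[1], prof.values[2]
            if t["label"] == 0:
                assert left / right == pytest.approx(1.0, abs=0.05)
            else:
                affected, contra = (left, right) if t["lateralization"] == "left" else (right, left)
                assert affected / contra == pytest.approx(1 - t["hypometab_frac"], abs=0.05)

    def test_mri_atrophy_brightens_and_shrinks(self, small_cohort, atlas):
        records, truth = small_cohort
        ep = next(r for r in records if r.label == 1)
        t = truth.set_index("subject_id").loc[ep.subject_id]
        rid = 1 if t["lateralization"] == "left" else 2
        mask = atlas.labels == rid
        hc = next(r for r in records if r.label == 0)
        # mean intensity over the full structure drops (shell became tissue),
        # but the maximum inside rises (densification)
        assert ep.mri.data[mask].max() > hc.mri.data[mask].max()
        inner_mean_ep = np.sort(ep.mri.data[mask])[-50:].mean()
        inner_mean_hc = np.sort(hc.mri.data[mask])[-50:].mean()
        assert inner_mean_ep > inner_mean_hc

    def test_symptom_rates_differ_by_class(self, atlas):
        spec = PhantomSpec(dims=DIMS, n_ep=40, n_hc=40, seed=21)
        records, _ = generate_records(spec, atlas)
        ep_rate = np.mean([r.clinical.symptom_fear for r in records if r.label == 1])
        hc_rate = np.mean([r.clinical.symptom_fear for r in records if r.label == 0])
        assert ep_rate > 0.6 and hc_rate < 0.3


class TestGroundTruth:
    def test_row_counts_and_zero_hc_effects(self, disk_cohort):
        _, manifest, truth = disk_cohort
        assert len(truth) == len(manifest) == 6
        hc = truth[truth["label"] == 0]
        assert (hc["atrophy_frac"] == 0).all() and (hc["hypometab_frac"] == 0).all()

    def test_truth_labels_match_manifest(self, disk_cohort):
        out, manifest, _ = disk_cohort
        truth = ground_truth(manifest)
        assert truth["label"].tolist() == manifest.table["label"].tolist()
        assert truth["subject_id"].tolist() == manifest.table["subject_id"].astype(str).tolist()

    def test_foreign_cohort_rejected(self, tmp_path):
        from epifuse.io_manifest import CohortManifest
        import pandas as pd
        from epifuse.io_manifest import MANIFEST_COLUMNS

        df = pd.DataFrame([{c: 0 for c in MANIFEST_COLUMNS}])
        df["subject_id"] = "x"
        m = CohortManifest(table=df, root=tmp_path)
        with pytest.raises(ProvenanceError):
            ground_truth(m)

    def test_disk_round_trip_preserves_volumes(self, disk_cohort, atlas):
        out, manifest, _ = disk_cohort
        from epifuse.io_manifest import load_subject

        spec = PhantomSpec(dims=DIMS, n_ep=3, n_hc=3, seed=5)
        records, _ = generate_records(spec, atlas)
        for rec, row in zip(records, manifest):
            loaded = load_subject(row, root=out)
            np.testing.assert_array_equal(loaded.mri.data, rec.mri.data)
            np.testing.assert_array_equal(loaded.pet.data, rec.pet.data)


def test_invalid_spec_fields_rejected():
    with pytest.raises(ValidationError):
        PhantomSpec(atrophy_frac=1.0)
    with pytest.raises(ValidationError):
        PhantomSpec(lateralization="up")
    with pytest.raises(ValidationError):
        PhantomSpec(n_ep=0)
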