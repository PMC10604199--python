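"""Synthetic multi-modal brain-phantom cohorts.

Generates, entirely in code, the kind of data the pipeline consumes:
a procedural ellipsoidal "brain" parcellation with exactly mirrored
bilateral hippocampal structures and a cerebellar reference region,
plus per-subject MRI-like and PET-like volumes.  Patient (EP) subjects
carry the canonical mesial-temporal-sclerosis signature — a shrunken,
denser (brighter) hippocampus in the MRI channel and a unilaterally
hypometabolic hippocampus in the PET channel — while control (HC)
subjects are bilaterally symmetric up to noise.  Symptom flags are
drawn at class-specific rates and ages/education are sampled from one
shared distribution so the classes stay demographically matched.

Each PET volume also receives a random global tracer-scale factor, so
the cerebellar SUVR normalisation is doing real work downstream.

Everything is driven by a single integer seed: the same spec and seed
reproduce bit-identical volumes, manifests and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_manifest import (
    ClinicalVector,
    CohortManifest,
    MANIFEST_COLUMNS,
    SubjectRecord,
    ValidationError,
    Volume3D,
    save_manifest,
    write_volume,
)
from .preprocess import ParcellationAtlas

TRUTH_FILENAME = "ground_truth.csv"
TRUTH_COLUMNS = ["subject_id", "label", "lateralization", "atrophy_frac", "hypometab_frac"]


class ProvenanceError(ValidationError):
    """A cohort was not produced by this generator."""


class GeometryError(ValidationError):
    """Requested phantom structures do not fit the volume."""


@dataclass
class PhantomSpec:
    """Cohort-level dials of the phantom generator.

    Defaults emulate the published study conditions: 15 patients and 15
    matched controls, a unilateral ~30% metabolic deficit and ~30%
    hippocampal volume loss in patients, and symptom flags far more
    frequent in patients than controls.
    """

    dims: tuple[int, int, int] = (96, 96, 96)
    n_ep: int = 15
    n_hc: int = 15
    atrophy_frac: float = 0.3
    hypometab_frac: float = 0.3
    lateralization: str = "random"  # left | right | random
    symptom_prob_ep: float = 0.8
    symptom_prob_hc: float = 0.1
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("atrophy_frac", "hypometab_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        for name in ("symptom_prob_ep", "symptom_prob_hc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.lateralization not in ("left", "right", "random"):
            raise ValidationError(f"unknown lateralization {self.lateralization!r}")
        if self.n_ep < 1 or self.n_hc < 1:
            raise ValidationError("need at least one subject per class")
        if min(self.dims) < 48:
            import warnings

            warnings.warn("phantom dims below 48 voxels; cubes will be mostly padding")


@dataclass
class PhantomAtlas(ParcellationAtlas):
    """Procedural parcellation with known structure geometry.

    Region ids: 1 = left hippocampus, 2 = right hippocampus,
    3 = cerebellar reference, 4.. = filler parcels.  The right
    hippocampus is the exact voxel mirror of the left about the
    midplane of axis 0.
    """

    dims: tuple[int, int, int] = (96, 96, 96)
    hippo_center_left: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hippo_radii: tuple[float, float, float] = (0.0, 0.0, 0.0)
    brain_intensity: float = 1.0
    seed: int = 0

    HIPPO_LEFT, HIPPO_RIGHT, CEREBELLUM = 1, 2, 3


def _ellipsoid_mask(dims, center, radii) -> np.ndarray:
    grids = np.ogrid[[slice(0, n) for n in dims]]
    acc = np.zeros(dims, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def make_atlas(
    dims: tuple[int, int, int] = (96, 96, 96),
    R: int = 8,
    seed: int = 0,
) -> PhantomAtlas:
    """Build the phantom parcellation (deterministic for fixed arguments).

    Needs R >= 3: left target, right target and the cerebellar
    reference; remaining parcels fill the rest of the brain mask in
    axis-2 slabs of equal voxel count.
    """
    if R < 3:
        raise ValidationError(f"need R >= 3 regions, got {R}")
    dims = tuple(int(d) for d in dims)
    nx, ny, nz = dims
    cx = (nx - 1) / 2.0  # mirror plane of axis 0
    brain = _ellipsoid_mask(dims, ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2),
                            (0.46 * nx, 0.46 * ny, 0.46 * nz))
    hippo_center = (cx - 0.22 * nx, 0.55 * ny, 0.45 * nz)
    hippo_radii = (0.085 * nx, 0.085 * ny, 0.085 * nz)
    hippo_left = _ellipsoid_mask(dims, hippo_center, hippo_radii)
    hippo_right = hippo_left[::-1]  # exact mirror about the midplane
    cereb = _ellipsoid_mask(dims, ((nx - 1) / 2, 0.80 * ny, 0.18 * nz),
                            (0.18 * nx, 0.13 * ny, 0.11 * nz))
    cereb &= ~(hippo_left | hippo_right)
    for name, mask in (("brain", brain), ("left hippocampus", hippo_left),
                       ("cerebellum", cereb)):
        if not mask.any():
            raise GeometryError(f"{name} structure does not fit dims {dims}")
    labels = np.zeros(dims, dtype=np.int32)
    filler = brain & ~(hippo_left | hippo_right | cereb)
    # equal-count slabs along axis 2 (deterministic; seed kept for API stability)
    fz = np.nonzero(filler)
    order = np.lexsort((fz[0], fz[1], fz[2]))
    voxel_idx = tuple(a[order] for a in fz)
    n_filler_regions = R - 3
    if n_filler_regions > 0:
        if len(order) < n_filler_regions:
            raise GeometryError(f"not enough brain voxels for {n_filler_regions} filler parcels")
        bounds = np.linspace(0, len(order), n_filler_regions + 1).astype(int)
        for j in range(n_filler_regions):
            sel = tuple(a[bounds[j] : bounds[j + 1]] for a in voxel_idx)
            labels[sel] = 4 + j
    labels[cereb] = PhantomAtlas.CEREBELLUM
    labels[hippo_left] = PhantomAtlas.HIPPO_LEFT
    labels[hippo_right] = PhantomAtlas.HIPPO_RIGHT
    region_ids = tuple(range(1, R + 1)) if n_filler_regions > 0 else (1, 2, 3)
    return PhantomAtlas(
        labels=labels,
        region_ids=region_ids,
        cerebellar_ids=(PhantomAtlas.CEREBELLUM,),
        dims=dims,
        hippo_center_left=hippo_center,
        hippo_radii=hippo_radii,
        seed=seed,
    )


# ---------------------------------------------------------------- volumes


TISSUE_MRI = 1.0
HIPPO_MRI = 1.2
UPTAKE_PET = 1.0


def _subject_volumes(
    atlas: PhantomAtlas,
    spec: PhantomSpec,
    is_ep: bool,
    side: str | None,
    rng: np.random.Generator,
) -> tuple[Volume3D, Volume3D]:
    dims = atlas.dims
    nx = dims[0]
    brain = atlas.labels > 0
    hippo_l = atlas.labels == PhantomAtlas.HIPPO_LEFT
    hippo_r = atlas.labels == PhantomAtlas.HIPPO_RIGHT

    mri = np.zeros(dims, dtype=np.float64)
    mri[brain] = TISSUE_MRI
    mri[hippo_l | hippo_r] = HIPPO_MRI

    pet = np.zeros(dims, dtype=np.float64)
    pet[brain] = UPTAKE_PET

    if is_ep:
        assert side in ("left", "right")
        # shrunken, denser hippocampus: keep (1 - atrophy) of the volume,
        # raise intensity inside, return the shed shell to plain tissue
        shrink = (1.0 - spec.atrophy_frac) ** (1.0 / 3.0)
        small_left = _ellipsoid_mask(
            dims, atlas.hippo_center_left, tuple(r * shrink for r in atlas.hippo_radii)
        )
        small = small_left if side == "left" else small_left[::-1]
        full = hippo_l if side == "left" else hippo_r
        mri[full] = TISSUE_MRI
        mri[small] = HIPPO_MRI * (1.0 + spec.atrophy_frac)
        # unilateral hypometabolism over the full structure
        pet[full] *= 1.0 - spec.hypometab_frac

    # per-subject tracer scale: what SUVR normalisation must undo
    pet *= float(np.exp(rng.normal(0.0, 0.2)))
    if spec.noise_sd > 0:
        mri = mri + rng.normal(0.0, spec.noise_sd, dims)
        pet = pet + rng.normal(0.0, spec.noise_sd, dims)
    pet = np.clip(pet, 0.0, None)
    return (
        Volume3D(mri.astype(np.float32)),
        Volume3D(pet.astype(np.float32)),
    )


def _sample_clinical(rng: np.random.Generator, is_ep: bool, spec: PhantomSpec) -> ClinicalVector:
    p = spec.symptom_prob_ep if is_ep else spec.symptom_prob_hc
    return ClinicalVector(
        symptom_abdominal=int(rng.random() < p),
        symptom_fear=int(rng.random() < p),
        age=float(np.clip(rng.normal(30.0, 8.0), 1.0, None)),  # one shared distribution
        sex=int(rng.random() < 0.5),
        education=float(np.clip(rng.normal(12.0, 3.0), 0.0, None)),
    )


def generate_records(
    spec: PhantomSpec, atlas: PhantomAtlas
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """In-memory cohort: subject records plus the ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    records, truth_rows = [], []
    plan = [(True, i) for i in range(spec.n_ep)] + [(False, i) for i in range(spec.n_hc)]
    for is_ep, i in plan:
        sid = f"{'ep' if is_ep else 'hc'}{i:03d}"
        if is_ep:
            if spec.lateralization == "random":
                side = "left" if rng.random() < 0.5 else "right"
            else:
                side = spec.lateralization
        else:
            side = None
        mri, pet = _subject_volumes(atlas, spec, is_ep, side, rng)
        clinical = _sample_clinical(rng, is_ep, spec)
        records.append(
            SubjectRecord(subject_id=sid, label=int(is_ep), mri=mri, pet=pet, clinical=clinical)
        )
        truth_rows.append(
            {
                "subject_id": sid,
                "label": int(is_ep),
                "lateralization": side or "none",
                "atrophy_frac": spec.atrophy_frac if is_ep else 0.0,
                "hypometab_frac": spec.hypometab_frac if is_ep else 0.0,
            }
        )
    return records, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def generate_cohort(
    spec: PhantomSpec, atlas: PhantomAtlas, out_dir: str | Path
) -> tuple[CohortManifest, pd.DataFrame]:
    """Write a full cohort to disk: NIfTI volumes, manifest CSV, atlas
    NIfTI and ground-truth CSV.  Returns the loaded-back manifest and
    the truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_records(spec, atlas)
    rows = []
    for rec in records:
        mri_path = f"{rec.subject_id}_mri.nii.gz"
        pet_path = f"{rec.subject_id}_pet.nii.gz"
        write_volume(rec.mri, out_dir / mri_path)
        write_volume(rec.pet, out_dir / pet_path)
        c = rec.clinical
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "mri_path": mri_path,
                "pet_path": pet_path,
                "symptom_abdominal": c.symptom_abdominal,
                "symptom_fear": c.symptom_fear,
                "age": c.age,
                "sex": c.sex,
                "education": c.education,
            }
        )
    manifest = CohortManifest(table=pd.DataFrame(rows, columns=MANIFEST_COLUMNS), root=out_dir)
    save_manifest(manifest, out_dir / "manifest.csv")
    truth.to_csv(out_dir / TRUTH_FILENAME, index=False)
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4)),
        str(out_dir / "atlas.nii.gz"),
    )
    return manifest, truth


def ground_truth(cohort: CohortManifest) -> pd.DataFrame:
    """The planted per-subject truth for a cohort this module generated.

    Raises ``ProvenanceError`` if no ground-truth table accompanies the
    manifest or its subjects do not match row-for-row.
    """
    truth_path = Path(cohort.root) / TRUTH_FILENAME
    if not truth_path.exists():
        raise ProvenanceError(
            f"no {TRUTH_FILENAME} beside the manifest; cohort was not generated here"
        )
    truth = pd.read_csv(truth_path)
    ids_m = cohort.table["subject_id"].astype(str).tolist()
    ids_t = truth["subject_id"].astype(str).tolist()
    if ids_m != ids_t:
        raise ProvenanceError("ground-truth subjects do not match the manifest")
    return truth
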