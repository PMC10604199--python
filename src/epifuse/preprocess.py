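"""SUVR normalisation, ROI features, cube partitioning, clinical scaling.

The PET standardisation follows the cerebellar-reference convention:
for each parcellation region i the standardized uptake value ratio is

    SUVR_i = mean SUV over region i / mean SUV over the cerebellar
             reference voxels

which removes global inter-subject tracer-dose and scanner scale.  The
reference region's own SUVR is identically 1, and every SUVR is
invariant under a global positive rescaling of the PET image — both are
enforced as tests.

Volumes feeding the 3D network are partitioned into non-overlapping
48x48x48 cubes; volumes whose dimensions are not multiples of the
stride are zero-padded on the high side of each axis so every voxel is
covered exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_manifest import ClinicalVector, SubjectRecord, ValidationError, Volume3D

log = logging.getLogger(__name__)

CUBE_SIZE = 48  # edge length of network input blocks, voxels


class ReferenceError_(ValidationError):
    """Cerebellar reference mean is non-positive."""


class CoverageError(ValidationError):
    """A declared atlas region has no voxels."""


# ---------------------------------------------------------------- atlas


@dataclass
class ParcellationAtlas:
    """Integer-labelled parcellation on the subject grid.

    ``labels`` uses 0 for background; every nonzero voxel must carry a
    label in ``region_ids`` (1..R for an AAL-style 90-region scheme).
    ``cerebellar_ids`` designates the reference regions for SUVR.
    """

    labels: np.ndarray
    region_ids: tuple[int, ...]
    cerebellar_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("atlas labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("atlas labels must be integers")
        self.region_ids = tuple(sorted(int(r) for r in self.region_ids))
        self.cerebellar_ids = tuple(sorted(int(r) for r in self.cerebellar_ids))
        if not self.cerebellar_ids:
            raise ValidationError("cerebellar reference set must be nonempty")
        if not set(self.cerebellar_ids) <= set(self.region_ids):
            raise ValidationError("cerebellar_ids must be a subset of region_ids")
        if 0 in self.region_ids:
            raise ValidationError("region id 0 is reserved for background")
        present = set(np.unique(self.labels)) - {0}
        stray = present - set(self.region_ids)
        if stray:
            raise ValidationError(f"voxels labelled outside region_ids: {sorted(stray)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def cerebellar_mask(self) -> np.ndarray:
        return np.isin(self.labels, self.cerebellar_ids)


@dataclass
class SUVRProfile:
    """Regional SUVR values plus the cerebellar reference mean."""

    values: dict[int, float]
    reference_mean: float

    def as_array(self, region_ids: tuple[int, ...] | None = None) -> np.ndarray:
        ids = region_ids if region_ids is not None else tuple(sorted(self.values))
        return np.array([self.values[i] for i in ids], dtype=float)


def regional_means(vol: Volume3D, atlas: ParcellationAtlas) -> dict[int, float]:
    """Arithmetic mean intensity per atlas region (the SUV convention)."""
    if vol.shape != atlas.labels.shape:
        raise ValidationError(
            f"volume shape {vol.shape} != atlas shape {atlas.labels.shape}"
        )
    data = vol.data
    out: dict[int, float] = {}
    for rid in atlas.region_ids:
        mask = atlas.labels == rid
        n = int(mask.sum())
        if n == 0:
            raise CoverageError(f"atlas region {rid} has no voxels")
        out[rid] = float(data[mask].mean(dtype=np.float64))
    return out


def compute_suvr(pet: Volume3D, atlas: ParcellationAtlas) -> SUVRProfile:
    """Cerebellar-reference SUVR for every atlas region.

    The reference mean is taken over the union of the cerebellar
    regions' voxels; it must be strictly positive.
    """
    means = regional_means(pet, atlas)
    ref_mask = atlas.cerebellar_mask()
    ref_mean = float(pet.data[ref_mask].mean(dtype=np.float64))
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise ReferenceError_(
            f"cerebellar reference mean must be > 0, got {ref_mean}"
        )
    values = {rid: m / ref_mean for rid, m in means.items()}
    return SUVRProfile(values=values, reference_mean=ref_mean)


def normalize_pet_suvr(pet: Volume3D, atlas: ParcellationAtlas) -> Volume3D:
    """Voxelwise SUVR image: PET divided by the cerebellar reference mean."""
    ref_mask = atlas.cerebellar_mask()
    ref_mean = float(pet.data[ref_mask].mean(dtype=np.float64))
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise ReferenceError_(
            f"cerebellar reference mean must be > 0, got {ref_mean}"
        )
    return Volume3D(
        data=(pet.data / ref_mean).astype(np.float32),
        spacing=pet.spacing,
        axis_order=pet.axis_order,
    )


# ---------------------------------------------------------------- ROI features


@dataclass
class ROIFeatureVector:
    """Strict upper triangle of an RxR region-pair matrix, row-major."""

    entries: np.ndarray
    R: int

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        expected = self.R * (self.R - 1) // 2
        if self.entries.shape != (expected,):
            raise ValidationError(
                f"expected {expected} upper-triangle entries for R={self.R}, "
                f"got shape {self.entries.shape}"
            )


def compute_roi_matrix(
    profile_or_volume: SUVRProfile | Volume3D,
    atlas: ParcellationAtlas,
) -> ROIFeatureVector:
    """Pairwise regional feature vector from the parcellation.

    The region-pair matrix is the log-ratio M[i, j] = log(v_i / v_j) of
    regional values (SUVR for a profile, mean intensity for a raw
    volume), which is antisymmetric, so only the strict upper triangle
    carries information and is returned in row-major order.
    """
    if atlas.n_regions < 2:
        raise ValidationError(f"need R >= 2 regions, got {atlas.n_regions}")
    if isinstance(profile_or_volume, SUVRProfile):
        vals = profile_or_volume.as_array(atlas.region_ids)
    else:
        means = regional_means(profile_or_volume, atlas)
        vals = np.array([means[i] for i in atlas.region_ids], dtype=float)
    if np.any(vals <= 0):
        raise ValidationError("log-ratio ROI matrix requires positive regional values")
    logv = np.log(vals)
    M = logv[:, None] - logv[None, :]
    iu = np.triu_indices(atlas.n_regions, k=1)
    return ROIFeatureVector(entries=M[iu], R=atlas.n_regions)


# ---------------------------------------------------------------- cubes


@dataclass
class CubeSet:
    """Non-overlapping tiling of a (padded) volume into fixed-size cubes."""

    cubes: np.ndarray  # (n, size, size, size)
    origins: np.ndarray  # (n, 3) voxel coordinates of each minimum corner
    size: int
    stride: int
    pad_value: float
    source_shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.cubes)


def extract_cubes(
    vol: Volume3D | np.ndarray,
    size: int = CUBE_SIZE,
    stride: int | None = None,
    pad_value: float = 0.0,
) -> CubeSet:
    """Partition a volume into ``size``-cubes on a ``stride`` grid.

    The volume is padded with ``pad_value`` on the high side of each
    axis up to the next multiple of the stride, so at stride == size
    the cubes tile the padded volume with every voxel covered exactly
    once.  Cubes are enumerated in lexicographic origin order.
    """
    if size < 1:
        raise ValidationError(f"cube size must be >= 1, got {size}")
    stride = size if stride is None else stride
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol)
    shape = data.shape
    # pad so every stride-grid cube of `size` fits entirely
    padded_dims = []
    for n in shape:
        n_steps = max(1, -(-(n - size) // stride) + 1) if n > size else 1
        padded_dims.append(max((n_steps - 1) * stride + size, n))
    pads = [(0, pd - n) for pd, n in zip(padded_dims, shape)]
    padded = np.pad(data, pads, constant_values=pad_value)
    grids = [range(0, pd - size + 1, stride) for pd in padded_dims]
    origins, cubes = [], []
    for i in grids[0]:
        for j in grids[1]:
            for k in grids[2]:
                origins.append((i, j, k))
                cubes.append(padded[i : i + size, j : j + size, k : k + size])
    return CubeSet(
        cubes=np.stack(cubes),  # dtype preserved: tiling must conserve exactly
        origins=np.asarray(origins, dtype=int),
        size=size,
        stride=stride,
        pad_value=pad_value,
        source_shape=shape,
    )


# ---------------------------------------------------------------- clinical


@dataclass
class CohortStats:
    """Training-fold means/sds for the continuous clinical covariates.

    Fit on training subjects only; applying the same statistics to a
    held-out fold is what keeps cross-validation leak-free.
    """

    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float

    @classmethod
    def fit(cls, clinicals: list[ClinicalVector]) -> "CohortStats":
        if not clinicals:
            raise ValidationError("cannot fit cohort statistics on an empty set")
        ages = np.array([c.age for c in clinicals], dtype=float)
        edus = np.array([c.education for c in clinicals], dtype=float)
        return cls(
            age_mean=float(ages.mean()),
            age_sd=float(ages.std(ddof=0)),
            education_mean=float(edus.mean()),
            education_sd=float(edus.std(ddof=0)),
        )


def _zscore(x: float, mean: float, sd: float, name: str) -> float:
    if sd == 0.0:
        log.warning("zero variance in %s; centering only", name)
        return x - mean
    return (x - mean) / sd


def standardize_clinical(v: ClinicalVector, stats: CohortStats) -> np.ndarray:
    """Fixed-length numeric clinical vector.

    Binary fields pass through; age and education are z-scored with the
    training-fold statistics (centering only when the fold variance is
    zero).  Order: (abdominal flag, fear flag, age, sex, education) and,
    when the PET asymmetry flag is present, it is appended last.
    """
    out = [
        float(v.symptom_abdominal),
        float(v.symptom_fear),
        _zscore(v.age, stats.age_mean, stats.age_sd, "age"),
        float(v.sex),
        _zscore(v.education, stats.education_mean, stats.education_sd, "education"),
    ]
    if v.pet_positive is not None:
        out.append(float(v.pet_positive))
    return np.asarray(out, dtype=np.float32)


def subject_cubes(
    subject: SubjectRecord,
    atlas: ParcellationAtlas | None = None,
    suvr_normalize: bool = True,
    size: int = CUBE_SIZE,
) -> tuple[CubeSet, CubeSet]:
    """(MRI cubes, PET cubes) for the image channels; PET optionally SUVR-scaled."""
    pet = subject.pet
    if suvr_normalize and atlas is not None:
        pet = normalize_pet_suvr(pet, atlas)
    return extract_cubes(subject.mri, size=size), extract_cubes(pet, size=size)
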