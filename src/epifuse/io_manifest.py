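"""Volume, manifest and report I/O.

Handles the three formats the pipeline touches — NIfTI volumes, CSV/TSV
cohort manifests and JSON metric reports — and enforces the cohort
integrity contracts: co-registered MRI/PET pairs, unique subject ids,
binary labels, finite voxel data.

Volumes are reoriented to closest-canonical (RAS) order at load, so the
first array axis is always the anatomical left–right axis.  The
bilateral asymmetry stage relies on this: the midsagittal plane is then
simply the midpoint of axis 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
import pandas as pd

EP, HC = 1, 0  # epilepsy patient / healthy control label convention

MANIFEST_COLUMNS = [
    "subject_id",
    "label",
    "mri_path",
    "pet_path",
    "symptom_abdominal",
    "symptom_fear",
    "age",
    "sex",
    "education",
]


class ValidationError(ValueError):
    """An input violates a documented data contract."""


class CoregistrationError(ValidationError):
    """MRI and PET grids of one subject do not match."""


# ---------------------------------------------------------------- types


@dataclass
class Volume3D:
    """A 3D scalar grid with voxel spacing (mm) and orientation tag.

    ``axis_order`` names the anatomical direction of each array axis
    (e.g. ``"RAS"``); axis 0 is the left–right axis after canonical
    loading.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_order: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume must be 3D, got {self.data.ndim}D shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValidationError(f"all dimensions must be >= 1, got {self.data.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite voxels (NaN or Inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ClinicalVector:
    """Typical-symptom flags plus demographic covariates for one subject.

    ``pet_positive`` stays ``None`` until the PET asymmetry stage has
    produced a subject-level flag.
    """

    symptom_abdominal: int
    symptom_fear: int
    age: float
    sex: int
    education: float
    pet_positive: int | None = None

    def __post_init__(self) -> None:
        for name in ("symptom_abdominal", "symptom_fear", "sex"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(f"{name} must be 0 or 1, got {v!r}")
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.education < 0:
            raise ValidationError(f"education must be >= 0, got {self.education}")
        if self.pet_positive is not None and self.pet_positive not in (0, 1):
            raise ValidationError(f"pet_positive must be 0/1 or None, got {self.pet_positive!r}")

    def with_pet_flag(self, flag: int) -> "ClinicalVector":
        return replace(self, pet_positive=int(flag))


@dataclass
class SubjectRecord:
    """One subject: co-registered volumes, clinical vector and label."""

    subject_id: str
    label: int
    mri: Volume3D
    pet: Volume3D
    clinical: ClinicalVector

    def __post_init__(self) -> None:
        if self.label not in (EP, HC):
            raise ValidationError(f"label must be 0 (HC) or 1 (EP), got {self.label!r}")
        if self.mri.shape != self.pet.shape:
            raise CoregistrationError(
                f"subject {self.subject_id}: MRI shape {self.mri.shape} != "
                f"PET shape {self.pet.shape}"
            )
        if self.mri.spacing != self.pet.spacing:
            raise CoregistrationError(
                f"subject {self.subject_id}: MRI spacing {self.mri.spacing} != "
                f"PET spacing {self.pet.spacing}"
            )


@dataclass
class CohortManifest:
    """Tabular index of a cohort; one row per subject."""

    table: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"manifest missing required columns: {missing}")
        ids = self.table["subject_id"].astype(str)
        dupes = sorted(ids[ids.duplicated()].unique())
        if dupes:
            raise ValidationError(f"duplicate subject_id values: {dupes}")
        bad = set(self.table["label"].unique()) - {0, 1}
        if bad:
            raise ValidationError(f"labels must be 0/1, found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterator[pd.Series]:
        for _, row in self.table.iterrows():
            yield row

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy(dtype=int)


# ---------------------------------------------------------------- volumes


def load_volume(path: str | Path) -> Volume3D:
    """Load a NIfTI volume, reoriented to canonical (RAS) axis order.

    Raises ``FileNotFoundError`` for a missing path and
    ``ValidationError`` for non-3D or non-finite images.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data=data, spacing=spacing, axis_order="RAS")


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write a volume as NIfTI with a diagonal (RAS) affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine), str(path))
    return path


# ---------------------------------------------------------------- manifest


def _read_table(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def load_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest (CSV, or TSV by sniffing)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return CohortManifest(table=_read_table(path), root=path.parent)


def save_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.table.to_csv(path, index=False)
    return path


def clinical_from_row(row: pd.Series) -> ClinicalVector:
    kwargs = dict(
        symptom_abdominal=int(row["symptom_abdominal"]),
        symptom_fear=int(row["symptom_fear"]),
        age=float(row["age"]),
        sex=int(row["sex"]),
        education=float(row["education"]),
    )
    if "pet_positive" in row.index and not (
        row["pet_positive"] is None or (isinstance(row["pet_positive"], float) and math.isnan(row["pet_positive"]))
    ):
        kwargs["pet_positive"] = int(row["pet_positive"])
    return ClinicalVector(**kwargs)


def load_subject(row: pd.Series, root: str | Path = ".") -> SubjectRecord:
    """Materialise one manifest row into a full ``SubjectRecord``.

    Relative volume paths are resolved against ``root`` (the manifest's
    directory).  A co-registration mismatch raises
    ``CoregistrationError`` naming both shapes.
    """
    root = Path(root)

    def _resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else root / p

    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        label=int(row["label"]),
        mri=load_volume(_resolve(row["mri_path"])),
        pet=load_volume(_resolve(row["pet_path"])),
        clinical=clinical_from_row(row),
    )


def load_cohort(manifest: CohortManifest) -> list[SubjectRecord]:
    return [load_subject(row, root=manifest.root) for row in manifest]


# ---------------------------------------------------------------- reports


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def save_json(obj: dict, path: str | Path) -> Path:
    """Write a metrics/report dict as JSON; NaN becomes null."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
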