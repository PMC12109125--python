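"""Reading and writing the formats the pipeline touches.

Volumes and masks travel as NIfTI-1 (via nibabel); clinical tables and
dataset manifests as CSV (via pandas).  Every volume is reoriented at load
to one fixed anatomical frame so that downstream code can rely on axis 0
being the axial (through-plane) direction.  Masks are *never* resampled:
a grid mismatch with the reference volume is an error, because the method
assumes co-registered, spatially coherent sequences.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Sequence",
    "MaskLabel",
    "Volume",
    "SegmentationMask",
    "ClinicalRecord",
    "ClinicalSchema",
    "DatasetManifest",
    "ManifestRow",
    "IngestionError",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_clinical_table",
    "write_clinical_table",
    "read_manifest",
    "write_manifest",
]


class Sequence(str, enum.Enum):
    T2WI_FS = "T2WI_FS"
    DWI = "DWI"


class MaskLabel(str, enum.Enum):
    TUMOR = "TUMOR"
    PROSTATE = "PROSTATE"
    ORGAN_EXCLUSION = "ORGAN_EXCLUSION"


class IngestionError(ValueError):
    """Raised when a file cannot be ingested; message carries path + reason."""


class GridMismatchError(IngestionError):
    """Mask and reference volume do not share shape/spacing."""


@dataclass
class Volume:
    """One 3-D MRI sequence: voxel grid (axial, row, column) + spacing in mm."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    sequence: Sequence
    patient_id: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise IngestionError(f"volume grid must be rank 3, got {self.grid.ndim}")
        if not np.all(np.isfinite(self.grid)):
            raise IngestionError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise IngestionError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self):
        return self.grid.shape


@dataclass
class SegmentationMask:
    """Binary mask on the same grid as its paired volume."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    label: MaskLabel
    empty: bool = field(init=False)

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise IngestionError(f"mask grid must be rank 3, got {g.ndim}")
        self.grid = (g > 0).astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.empty = not bool(self.grid.any())

    @property
    def shape(self):
        return self.grid.shape


@dataclass
class ClinicalRecord:
    patient_id: str
    numeric: dict[str, float]
    categorical: dict[str, int]
    bcr_label: int

    def __post_init__(self):
        if self.bcr_label not in (0, 1):
            raise IngestionError(
                f"patient {self.patient_id}: bcr_label must be 0/1, got {self.bcr_label}"
            )


@dataclass
class ClinicalSchema:
    """Declares which clinical columns are numeric and, for categoricals,
    the ordered category codes (1-based ordinal integers)."""

    numeric_fields: list[str]
    categorical_fields: dict[str, list[int]]  # field -> allowed ordered codes
    label_field: str = "bcr_label"
    id_field: str = "patient_id"

    @property
    def fields(self) -> list[str]:
        return self.numeric_fields + list(self.categorical_fields)

    @property
    def dim(self) -> int:
        return len(self.fields)


def default_schema() -> ClinicalSchema:
    """Preoperative covariates: age and PSA as numerics; grading/stage/risk
    systems as ordinal categoricals."""
    return ClinicalSchema(
        numeric_fields=["age", "psa"],
        categorical_fields={
            "gleason_sum": [1, 2, 3],      # <7, =7, >7
            "isup_grade": [1, 2, 3, 4, 5],
            "clinical_stage": [1, 2],      # cT2x, cT3x
            "capra": [1, 2],               # <6, >=6
        },
    )


@dataclass
class ManifestRow:
    patient_id: str
    path_t2: str
    path_dwi: str
    path_tumor_mask: str
    path_prostate_mask: str
    path_exclusion_mask: str | None = None
    split: str = ""


@dataclass
class DatasetManifest:
    rows: list[ManifestRow]
    clinical_path: str = ""

    def __post_init__(self):
        ids = [r.patient_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IngestionError(f"duplicate patient_ids in manifest: {dupes}")

    def __len__(self):
        return len(self.rows)

    def validate_files(self):
        for r in self.rows:
            paths = [r.path_t2, r.path_dwi, r.path_tumor_mask, r.path_prostate_mask]
            if r.path_exclusion_mask:
                paths.append(r.path_exclusion_mask)
            for p in paths:
                if not Path(p).exists():
                    raise IngestionError(f"manifest references missing file: {p}")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _canonical_grid(img) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Reorient to RAS and put the axial (superior-inferior) axis first."""
    can = nib.as_closest_canonical(img)
    data = np.asarray(can.dataobj)
    zooms = can.header.get_zooms()[:3]
    # canonical RAS stores (x, y, z); move z (axial) to axis 0
    grid = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return grid, spacing


def read_volume(path, sequence: Sequence, patient_id: str = "") -> Volume:
    path = Path(path)
    if not path.exists():
        raise IngestionError(f"{path}: file not found")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise IngestionError(f"{path}: not a readable NIfTI file ({exc})") from exc
    if len(img.shape) != 3:
        raise IngestionError(f"{path}: non-3D image with shape {img.shape}")
    affine = img.affine
    if affine is None or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise IngestionError(f"{path}: degenerate affine")
    grid, spacing = _canonical_grid(img)
    return Volume(grid=grid, spacing=spacing, sequence=Sequence(sequence),
                  patient_id=patient_id)


def write_volume(vol: Volume, path) -> Path:
    """Write in the canonical frame so a read-back grid is bit-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.transpose(np.asarray(vol.grid), (2, 1, 0))
    sa, sr, sc = vol.spacing
    affine = np.diag([sc, sr, sa, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_mask(path, label: MaskLabel, reference: Volume) -> SegmentationMask:
    path = Path(path)
    if not path.exists():
        raise IngestionError(f"{path}: file not found")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise IngestionError(f"{path}: non-3D mask with shape {img.shape}")
    grid, spacing = _canonical_grid(img)
    if grid.shape != reference.shape:
        raise GridMismatchError(
            f"{path}: mask shape {grid.shape} != reference shape {reference.shape}"
        )
    if not np.allclose(spacing, reference.spacing, rtol=1e-4, atol=1e-4):
        raise GridMismatchError(
            f"{path}: mask spacing {spacing} != reference spacing {reference.spacing}"
        )
    return SegmentationMask(grid=grid, spacing=reference.spacing, label=MaskLabel(label))


def write_mask(mask: SegmentationMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.transpose(mask.grid.astype(np.uint8), (2, 1, 0))
    sa, sr, sc = mask.spacing
    affine = np.diag([sc, sr, sa, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


# ---------------------------------------------------------------------------
# clinical CSV


def read_clinical_table(path, schema: ClinicalSchema) -> list[ClinicalRecord]:
    path = Path(path)
    if not path.exists():
        raise IngestionError(f"{path}: file not found")
    df = pd.read_csv(path)
    required = [schema.id_field, *schema.fields, schema.label_field]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise IngestionError(f"{path}: missing columns {missing_cols}")
    if df[schema.id_field].duplicated().any():
        dupes = df.loc[df[schema.id_field].duplicated(), schema.id_field].tolist()
        raise IngestionError(f"{path}: duplicate patient_id(s) {dupes}")
    records = []
    for idx, row in df.iterrows():
        for col in required:
            if pd.isna(row[col]):
                raise IngestionError(f"{path}: missing value at row {idx}, column '{col}'")
        cat = {}
        for fname, codes in schema.categorical_fields.items():
            code = int(row[fname])
            if code not in codes:
                raise IngestionError(
                    f"{path}: row {idx}, column '{fname}': unknown category {code} "
                    f"(allowed {codes})"
                )
            cat[fname] = code
        records.append(
            ClinicalRecord(
                patient_id=str(row[schema.id_field]),
                numeric={f: float(row[f]) for f in schema.numeric_fields},
                categorical=cat,
                bcr_label=int(row[schema.label_field]),
            )
        )
    return records


def write_clinical_table(records: list[ClinicalRecord], schema: ClinicalSchema, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        row = {schema.id_field: r.patient_id}
        row.update({f: r.numeric[f] for f in schema.numeric_fields})
        row.update({f: r.categorical[f] for f in schema.categorical_fields})
        row[schema.label_field] = r.bcr_label
        rows.append(row)
    cols = [schema.id_field, *schema.fields, schema.label_field]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# manifest CSV


_MANIFEST_COLS = [
    "patient_id", "path_t2", "path_dwi", "path_tumor_mask",
    "path_prostate_mask", "path_exclusion_mask", "split",
]


def write_manifest(manifest: DatasetManifest, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in manifest.rows:
        rows.append({
            "patient_id": r.patient_id, "path_t2": r.path_t2, "path_dwi": r.path_dwi,
            "path_tumor_mask": r.path_tumor_mask, "path_prostate_mask": r.path_prostate_mask,
            "path_exclusion_mask": r.path_exclusion_mask or "", "split": r.split,
        })
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, index=False)
    return path


def read_manifest(path) -> DatasetManifest:
    path = Path(path)
    if not path.exists():
        raise IngestionError(f"{path}: file not found")
    df = pd.read_csv(path, dtype=str).fillna("")
    rows = [
        ManifestRow(
            patient_id=r["patient_id"], path_t2=r["path_t2"], path_dwi=r["path_dwi"],
            path_tumor_mask=r["path_tumor_mask"], path_prostate_mask=r["path_prostate_mask"],
            path_exclusion_mask=r["path_exclusion_mask"] or None, split=r["split"],
        )
        for _, r in df.iterrows()
    ]
    return DatasetManifest(rows=rows)
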