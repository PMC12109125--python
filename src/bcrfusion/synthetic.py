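"""Dual-sequence prostate phantoms with planted, region-specific signal.

Each phantom is an ellipsoidal "prostate" containing a spherical "tumor" on
an anisotropic grid, rendered into two channels with the contrast polarity
of the real sequences: on the T2-like channel the gland is bright and the
tumor hypointense; on the DWI-like channel the tumor is hyperintense.
Label-dependent effects are planted *per region* so that each analysis
region carries its own, independently tunable signal:

* tumor (ITR): the DWI tumor intensity is shifted by ``label * tumor_dwi_shift``;
* 5 mm peritumoral shell (PTR): extra zero-mean texture noise with standard
  deviation ``label * ptr_texture_gain * noise_sd``;
* periprostatic shell (PPR): a radial intensity ramp decaying from the
  prostate surface, scaled by ``label * ppr_gradient_gain * noise_sd``;
* clinical covariates: numerics drawn from label-shifted Gaussians and
  ordinal categoricals from label-tilted multinomials, controlled by
  ``clinical_shift``.

With every effect size at zero the two classes are identical in law, which
gives a null cohort for separability checks.  Positive prevalence defaults
to 0.2, matching a cohort in which roughly one patient in five recurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_data import (
    ClinicalRecord,
    ClinicalSchema,
    DatasetManifest,
    ManifestRow,
    MaskLabel,
    SegmentationMask,
    Sequence,
    Volume,
    default_schema,
    write_clinical_table,
    write_manifest,
    write_mask,
    write_volume,
)

__all__ = [
    "PhantomParams",
    "PhantomPatient",
    "SyntheticCohort",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
]


@dataclass
class PhantomParams:
    """Generation settings; the defaults are the package's study conditions."""

    n_patients: int = 120
    prevalence: float = 0.2
    grid_shape: tuple[int, int, int] = (20, 64, 64)
    spacing: tuple[float, float, float] = (3.5, 0.6, 0.6)
    prostate_semiaxis_mm: tuple[float, float] = (9.0, 13.0)  # sampled per axis
    tumor_radius_mm: tuple[float, float] = (4.0, 7.0)
    tumor_dwi_shift: float = 10.0
    ptr_texture_gain: float = 1.5
    ppr_gradient_gain: float = 1.5
    clinical_shift: float = 1.0
    noise_sd: float = 2.0
    margin_mm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.prevalence <= 1.0):
            raise ValueError(f"prevalence must be in (0, 1], got {self.prevalence}")
        if self.tumor_radius_mm[1] >= self.prostate_semiaxis_mm[0]:
            raise ValueError(
                "largest tumor radius must be smaller than the smallest prostate "
                f"semi-axis ({self.tumor_radius_mm[1]} >= {self.prostate_semiaxis_mm[0]})"
            )
        extent = [n * s for n, s in zip(self.grid_shape, self.spacing)]
        if min(extent) < 2 * (self.prostate_semiaxis_mm[1] + self.margin_mm):
            raise ValueError(
                f"grid extent {extent} mm too small for a prostate of semi-axis "
                f"{self.prostate_semiaxis_mm[1]} mm plus a {self.margin_mm} mm shell"
            )


@dataclass
class PhantomPatient:
    patient_id: str
    t2: Volume
    dwi: Volume
    tumor: SegmentationMask
    prostate: SegmentationMask
    exclusion: SegmentationMask
    clinical: ClinicalRecord
    label: int


@dataclass
class SyntheticCohort:
    patients: list[PhantomPatient]
    params: PhantomParams
    schema: ClinicalSchema = field(default_factory=default_schema)
    single_class_warning: bool = False

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patients], dtype=int)

    def __len__(self):
        return len(self.patients)


def _physical_coords(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _tilted_multinomial(base: np.ndarray, tilt: float, rng) -> int:
    """Sample an ordinal code 1..K from base probabilities tilted toward
    higher codes by ``tilt`` (log-linear in the code)."""
    k = len(base)
    codes = np.arange(1, k + 1)
    w = base * np.exp(tilt * (codes - (k + 1) / 2.0))
    w /= w.sum()
    return int(rng.choice(codes, p=w))


_CAT_BASE = {
    "gleason_sum": np.array([0.20, 0.38, 0.42]),
    "isup_grade": np.array([0.18, 0.24, 0.14, 0.20, 0.24]),
    "clinical_stage": np.array([0.82, 0.18]),
    "capra": np.array([0.46, 0.54]),
}


def _sample_clinical(params: PhantomParams, label: int, rng,
                     patient_id: str) -> ClinicalRecord:
    shift = params.clinical_shift * label
    age = float(rng.normal(70.0 + 3.0 * shift, 6.0))
    psa = float(max(0.1, rng.normal(10.0 + 4.0 * shift, 4.0)))
    cat = {
        name: _tilted_multinomial(base, 0.5 * shift, rng)
        for name, base in _CAT_BASE.items()
    }
    return ClinicalRecord(patient_id=patient_id, numeric={"age": age, "psa": psa},
                          categorical=cat, bcr_label=label)


def generate_phantom(params: PhantomParams, label: int,
                     rng: np.random.Generator, patient_id: str = "P0"
                     ) -> PhantomPatient:
    """Render one dual-sequence phantom with its masks and clinical row."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0/1, got {label}")
    shape, spacing = params.grid_shape, params.spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    za, ya, xa = _physical_coords(shape, spacing)

    # prostate: random ellipsoid near the grid center
    semi = rng.uniform(*params.prostate_semiaxis_mm, size=3)
    center = extent / 2.0 + rng.uniform(-2.0, 2.0, size=3)
    u = np.sqrt(((za - center[0]) / semi[0]) ** 2
                + ((ya - center[1]) / semi[1]) ** 2
                + ((xa - center[2]) / semi[2]) ** 2)
    prostate = u <= 1.0

    # tumor: random ball strictly inside the prostate
    radius = rng.uniform(*params.tumor_radius_mm)
    max_u = 1.0 - radius / semi.min()
    if max_u <= 0:
        raise ValueError("tumor cannot fit inside the sampled prostate")
    for _ in range(100):
        offs = rng.uniform(-1.0, 1.0, size=3) * semi * max_u
        if np.sqrt(((offs / semi) ** 2).sum()) <= max_u:
            break
    else:  # pragma: no cover - rejection loop virtually always succeeds
        offs = np.zeros(3)
    tcen = center + offs
    dist_t = np.sqrt((za - tcen[0]) ** 2 + (ya - tcen[1]) ** 2 + (xa - tcen[2]) ** 2)
    tumor = dist_t <= radius

    # adjacent organ (e.g. rectum): ellipsoid posterior to the gland,
    # clipped so it never overlaps the prostate
    ocen = center + np.array([0.0, semi[1] + 6.0, 0.0])
    osemi = np.array([8.0, 7.0, 9.0])
    organ = (((za - ocen[0]) / osemi[0]) ** 2 + ((ya - ocen[1]) / osemi[1]) ** 2
             + ((xa - ocen[2]) / osemi[2]) ** 2) <= 1.0
    organ &= ~prostate

    # base contrast
    t2 = np.full(shape, 10.0)
    dwi = np.full(shape, 10.0)
    t2[prostate] += 15.0
    dwi[prostate] += 5.0
    t2[tumor] -= 8.0
    dwi[tumor] += 12.0 + label * params.tumor_dwi_shift

    # peritumoral texture (inside prostate, within margin_mm of the tumor)
    shell_t = (dist_t <= radius + params.margin_mm) & ~tumor & prostate
    n_shell = int(shell_t.sum())
    if n_shell and params.ptr_texture_gain > 0:
        sd = label * params.ptr_texture_gain * params.noise_sd
        if sd > 0:
            tex = rng.normal(0.0, sd, size=n_shell)
            t2[shell_t] += tex
            dwi[shell_t] += rng.normal(0.0, sd, size=n_shell)

    # periprostatic radial ramp, decaying over margin_mm outside the gland
    d_out = (u - 1.0) * semi.min()  # approx physical distance outside surface
    shell_p = (~prostate) & (d_out <= params.margin_mm) & (d_out >= 0)
    ramp = np.zeros(shape)
    ramp[shell_p] = 1.0 - d_out[shell_p] / params.margin_mm
    amp = label * params.ppr_gradient_gain * params.noise_sd
    t2 += amp * ramp
    dwi += amp * ramp

    # acquisition noise
    t2 += rng.normal(0.0, params.noise_sd, size=shape)
    dwi += rng.normal(0.0, params.noise_sd, size=shape)

    clinical = _sample_clinical(params, label, rng, patient_id)
    return PhantomPatient(
        patient_id=patient_id,
        t2=Volume(t2, spacing, Sequence.T2WI_FS, patient_id),
        dwi=Volume(dwi, spacing, Sequence.DWI, patient_id),
        tumor=SegmentationMask(tumor.astype(np.uint8), spacing, MaskLabel.TUMOR),
        prostate=SegmentationMask(prostate.astype(np.uint8), spacing, MaskLabel.PROSTATE),
        exclusion=SegmentationMask(organ.astype(np.uint8), spacing, MaskLabel.ORGAN_EXCLUSION),
        clinical=clinical,
        label=label,
    )


def generate_cohort(params: PhantomParams) -> SyntheticCohort:
    """Generate a cohort with Bernoulli(prevalence) labels and one
    independent random substream per patient."""
    if params.n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_patients + 1)
    label_rng = np.random.default_rng(children[0])
    labels = (label_rng.random(params.n_patients) < params.prevalence).astype(int)
    patients = []
    for i in range(params.n_patients):
        rng = np.random.default_rng(children[i + 1])
        pid = f"P{i:04d}"
        patients.append(generate_phantom(params, int(labels[i]), rng, pid))
    single = len(set(labels.tolist())) < 2
    if single:
        warnings.warn("synthetic cohort contains a single class", stacklevel=2)
    return SyntheticCohort(patients=patients, params=params,
                           single_class_warning=single)


def write_cohort(cohort: SyntheticCohort, directory) -> DatasetManifest:
    """Persist the cohort as NIfTI volumes/masks + clinical and manifest CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        pdir = directory / p.patient_id
        paths = {
            "t2": write_volume(p.t2, pdir / "t2.nii.gz"),
            "dwi": write_volume(p.dwi, pdir / "dwi.nii.gz"),
            "tumor": write_mask(p.tumor, pdir / "tumor_mask.nii.gz"),
            "prostate": write_mask(p.prostate, pdir / "prostate_mask.nii.gz"),
            "exclusion": write_mask(p.exclusion, pdir / "exclusion_mask.nii.gz"),
        }
        rows.append(ManifestRow(
            patient_id=p.patient_id,
            path_t2=str(paths["t2"]), path_dwi=str(paths["dwi"]),
            path_tumor_mask=str(paths["tumor"]),
            path_prostate_mask=str(paths["prostate"]),
            path_exclusion_mask=str(paths["exclusion"]),
        ))
    clin_path = directory / "clinical.csv"
    write_clinical_table([p.clinical for p in cohort.patients], cohort.schema, clin_path)
    manifest = DatasetManifest(rows=rows, clinical_path=str(clin_path))
    write_manifest(manifest, directory / "manifest.csv")
    return manifest
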