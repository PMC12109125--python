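"""End-to-end plumbing: volumes + masks + clinical rows -> model-ready
samples, and the multi-model experiment harness (single-region models,
the combined multi-region model, the clinical baseline and the integrated
model, evaluated under repeated stratified CV)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import compare_models
from .io_data import (
    ClinicalRecord,
    ClinicalSchema,
    DatasetManifest,
    MaskLabel,
    Sequence,
    default_schema,
    read_clinical_table,
    read_mask,
    read_volume,
)
from .model import ModelConfig, PatientInput
from .preprocessing import (
    AugmentParams,
    SlicePair,
    encode_clinical,
    extract_slices,
    fit_clinical_stats,
    zscore_normalize,
)
from .roi import build_regions
from .synthetic import SyntheticCohort
from .training import TrainConfig, repeated_stratified_kfold, train_model

__all__ = [
    "PatientSample",
    "prepare_patient",
    "prepare_cohort",
    "load_manifest_samples",
    "VARIANTS",
    "run_variant_cv",
    "run_comparison",
]

log = logging.getLogger("bcrfusion")


@dataclass
class PatientSample:
    """Preprocessed imaging for one patient plus the raw clinical record
    (encoding to [0,1] happens later, with training-split statistics)."""

    patient_id: str
    slices: dict[str, list[SlicePair]]
    record: ClinicalRecord | None = None


def prepare_patient(t2, dwi, tumor, prostate, exclusion=None,
                    regions=("ITR", "PTR", "PPR"), margin_mm: float = 5.0,
                    n_slices: int = 8, input_size: int = 64,
                    record: ClinicalRecord | None = None) -> PatientSample:
    """Normalise, build the region masks and extract per-region slice stacks."""
    t2n = zscore_normalize(t2)
    dwin = zscore_normalize(dwi)
    region_set = build_regions(tumor, prostate, exclusion, margin_mm)
    slices = {}
    for r in regions:
        mask = region_set[r]
        if mask.empty:
            # a region can be empty (e.g. zero margin); feed all-padding stack
            size = (input_size, input_size, 2)
            slices[r] = [SlicePair(np.zeros(size, dtype=np.float32), k, r, True)
                         for k in range(n_slices)]
        else:
            slices[r] = extract_slices(t2n, dwin, mask, n_slices, input_size, region=r)
    return PatientSample(patient_id=t2.patient_id, slices=slices, record=record)


def prepare_cohort(cohort: SyntheticCohort, regions=("ITR", "PTR", "PPR"),
                   margin_mm: float = 5.0, n_slices: int = 8,
                   input_size: int = 64) -> tuple[list[PatientSample], np.ndarray]:
    samples = [
        prepare_patient(p.t2, p.dwi, p.tumor, p.prostate, p.exclusion,
                        regions, margin_mm, n_slices, input_size, record=p.clinical)
        for p in cohort.patients
    ]
    return samples, cohort.labels


def load_manifest_samples(manifest: DatasetManifest, clinical_path,
                          schema: ClinicalSchema | None = None,
                          regions=("ITR", "PTR", "PPR"), margin_mm: float = 5.0,
                          n_slices: int = 8, input_size: int = 64
                          ) -> tuple[list[PatientSample], np.ndarray]:
    """Read a manifest's volumes/masks/clinical rows into samples."""
    schema = schema or default_schema()
    records = {r.patient_id: r for r in read_clinical_table(clinical_path, schema)}
    samples, labels = [], []
    for row in manifest.rows:
        if row.patient_id not in records:
            raise ValueError(f"patient {row.patient_id} missing from clinical table")
        t2 = read_volume(row.path_t2, Sequence.T2WI_FS, row.patient_id)
        dwi = read_volume(row.path_dwi, Sequence.DWI, row.patient_id)
        tumor = read_mask(row.path_tumor_mask, MaskLabel.TUMOR, t2)
        prostate = read_mask(row.path_prostate_mask, MaskLabel.PROSTATE, t2)
        excl = (read_mask(row.path_exclusion_mask, MaskLabel.ORGAN_EXCLUSION, t2)
                if row.path_exclusion_mask else None)
        rec = records[row.patient_id]
        samples.append(prepare_patient(t2, dwi, tumor, prostate, excl, regions,
                                       margin_mm, n_slices, input_size, record=rec))
        labels.append(rec.bcr_label)
    return samples, np.array(labels, dtype=int)


# ---------------------------------------------------------------------------
# the model-variant study

# variant name -> (regions, use_clinical); the clinical-only baseline is
# handled separately (it has no imaging branch)
VARIANTS: dict[str, tuple[tuple[str, ...], bool]] = {
    "itr": (("ITR",), False),
    "ptr": (("PTR",), False),
    "ppr": (("PPR",), False),
    "combined": (("ITR", "PTR", "PPR"), False),
    "integrated": (("ITR", "PTR", "PPR"), True),
}


def _encode_fold(samples: list[PatientSample], train_ids, schema: ClinicalSchema,
                 use_clinical: bool) -> list[PatientInput]:
    """Build PatientInputs; clinical min-max statistics come from the fold's
    training portion only."""
    stats = None
    if use_clinical:
        stats = fit_clinical_stats([samples[i].record for i in train_ids], schema)
    inputs = []
    for s in samples:
        clin = encode_clinical(s.record, schema, stats) if use_clinical else None
        inputs.append(PatientInput(patient_id=s.patient_id, slices=s.slices,
                                   clinical=clin))
    return inputs


def run_variant_cv(samples: list[PatientSample], labels, variant: str,
                   model_cfg: ModelConfig, train_cfg: TrainConfig,
                   schema: ClinicalSchema | None = None,
                   augment_params: AugmentParams | None = None,
                   plan=None) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Train one model variant across the fold plan; returns the fold-wise
    validation predictions [(fold_key, val_ids, probs), ...]."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant '{variant}' (choose from {list(VARIANTS)})")
    regions, use_clin = VARIANTS[variant]
    schema = schema or default_schema()
    cfg = ModelConfig.from_dict({**model_cfg.to_dict(),
                                 "regions": regions, "use_clinical": use_clin})
    labels = np.asarray(labels, dtype=int)
    if plan is None:
        plan = repeated_stratified_kfold(labels, train_cfg.k, train_cfg.repeats,
                                         train_cfg.seed)
    preds = []
    for rep, fold, tr, va in plan:
        inputs = _encode_fold(samples, tr, schema, use_clin)
        fold_cfg = TrainConfig(**{**train_cfg.__dict__,
                                  "seed": train_cfg.seed + 1000 * rep + fold})
        model, hist = train_model(inputs, labels, tr, va, cfg, fold_cfg,
                                  augment_params)
        from .training import _predict_probs
        probs = _predict_probs(model, inputs, va)
        log.info("variant=%s repeat=%d fold=%d best_epoch=%s val_auc=%.3f",
                 variant, rep, fold, hist.attrs.get("best_epoch"),
                 hist["val_auc"].max())
        preds.append((f"r{rep}f{fold}", va, probs))
    return preds


def run_clinical_cv(samples: list[PatientSample], labels,
                    train_cfg: TrainConfig, schema: ClinicalSchema | None = None,
                    plan=None, seed_offset: int = 0
                    ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Repeated-CV predictions of the clinical-only MLP baseline."""
    from .estimator import ClinicalOnlyClassifier

    schema = schema or default_schema()
    labels = np.asarray(labels, dtype=int)
    if plan is None:
        plan = repeated_stratified_kfold(labels, train_cfg.k, train_cfg.repeats,
                                         train_cfg.seed)
    records = [s.record for s in samples]
    preds = []
    for rep, fold, tr, va in plan:
        clf = ClinicalOnlyClassifier(
            schema=schema, lr0=1e-3, max_epochs=train_cfg.max_epochs,
            patience=train_cfg.patience, seed=train_cfg.seed + seed_offset
            + 1000 * rep + fold)
        clf.fit([records[i] for i in tr], labels[tr])
        probs = clf.predict_proba([records[i] for i in va])[:, 1]
        preds.append((f"r{rep}f{fold}", va, probs))
    return preds


def run_comparison(samples, labels, variants: list[str], model_cfg: ModelConfig,
                   train_cfg: TrainConfig, schema: ClinicalSchema | None = None,
                   augment_params: AugmentParams | None = None,
                   include_clinical: bool = False, out_dir=None):
    """Run several variants on a shared fold plan and compare them."""
    labels = np.asarray(labels, dtype=int)
    plan = repeated_stratified_kfold(labels, train_cfg.k, train_cfg.repeats,
                                     train_cfg.seed)
    model_preds = {}
    for v in variants:
        model_preds[v] = run_variant_cv(samples, labels, v, model_cfg, train_cfg,
                                        schema, augment_params, plan)
    if include_clinical:
        model_preds["clinical"] = run_clinical_cv(samples, labels, train_cfg,
                                                  schema, plan)
    reports, comparisons, table = compare_models(labels, model_preds)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, preds in model_preds.items():
            rows = []
            for key, ids, probs in preds:
                for i, p in zip(np.asarray(ids), np.asarray(probs)):
                    rows.append({"fold": key, "patient_index": int(i),
                                 "label": int(labels[i]), "prob": float(p)})
            pd.DataFrame(rows).to_csv(out_dir / f"predictions_{name}.csv", index=False)
        table.to_csv(out_dir / "metrics_table.csv", index=False)
        (out_dir / "metrics_table.txt").write_text(table.to_string(index=False) + "\n")
        comp_rows = [{"model_a": c.model_a, "model_b": c.model_b,
                      "auc_a": c.auc_a, "auc_b": c.auc_b, "z": c.delong_z,
                      "p": c.delong_p, "band": c.band} for c in comparisons]
        pd.DataFrame(comp_rows).to_csv(out_dir / "delong_comparisons.csv", index=False)
        summary = {name: {m: list(rep[m]) for m in rep.metrics}
                   for name, rep in reports.items()}
        (out_dir / "reports.json").write_text(json.dumps(summary, indent=2))
    return reports, comparisons, table, model_preds
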