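# bcrfusion

Multi-region, multi-sequence prostate MRI + clinical fusion for predicting
biochemical recurrence (BCR) after radical prostatectomy.

## The problem

After surgery for localized prostate cancer, 20–40% of patients relapse
biochemically (two consecutive PSA measurements ≥ 0.2 ng/mL). Predicting
that risk *preoperatively* from routine imaging would let clinicians plan
adjuvant treatment and follow-up intensity without invasive sampling.
Tumor-centric models ignore the tumor microenvironment; this package
implements a classifier that reads three anatomical regions — intratumoral
(ITR), peritumoral (PTR: a 5 mm shell around the tumor clipped to the
prostate) and periprostatic (PPR: a 5 mm shell outside the gland, adjacent
organs excluded) — on two co-registered sequences (T2WI-FS and DWI),
optionally fused with clinical covariates (age, PSA, Gleason/ISUP grade,
stage, CAPRA).

## The model

Per axial position of a patient:

1. a shared dual-channel residual CNN encodes each region's masked slice
   pair I ∈ ℝ^(W×H×2) into f_image ∈ ℝ^(W_I×H_I×C_I);
2. region maps are concatenated along channels (ITR, PTR, PPR) and a
   learned axial-position embedding AS ∈ ℝ^(W_I×H_I) is added, broadcast
   across channels;
3. the clinical vector (numerics min–max scaled to [0,1], ordinal codes for
   categoricals) is linearly mapped and each value replicated over the
   plane, then concatenated → C_total = 3·C_I + D_emb channels;
4. the fused map is read as S = W_I·H_I tokens, projected to the
   transformer hidden size, combined with positional embeddings, passed
   through a transformer encoder stack (4 layers, 8 heads, 256-dim by
   default), mean-pooled, and mapped by an FC layer to a slice score r_i;
5. the patient's score vector R = (r_1 … r_N) goes through a final
   FC + sigmoid → recurrence probability ŷ, trained with binary
   cross-entropy.

Training follows AdamW (lr 1e-4, cosine annealing to 0), batch 16, early
stopping on validation AUC (patience 10), augmentation (rotation, flips,
brightness/contrast) on training slices only, and stratified 5-fold CV
repeated 20 times with 95% percentile CIs. Evaluation provides
sensitivity/specificity/accuracy/F1 at a threshold, tie-aware AUC, and
DeLong tests between correlated ROC curves.

Everything runs on a small NumPy autodiff core inside the package
(`bcrfusion.nn`) — no GPU or deep-learning framework required — and a
synthetic phantom generator plants region-specific, label-dependent signal
so the whole pipeline is exercisable without patient data.

## Worked example

Generate a 60-phantom cohort with planted intratumoral signal, train the
single-region ITR model under 3-fold CV at desk scale (~1 minute on one
CPU), and summarise:

```python
import numpy as np
from bcrfusion.config import desk_config
from bcrfusion.evaluation import roc_auc
from bcrfusion.pipeline import prepare_cohort, run_variant_cv
from bcrfusion.synthetic import generate_cohort
from bcrfusion.training import repeated_stratified_kfold

cfg = desk_config(seed=0, n_patients=60)
cohort = generate_cohort(cfg.phantom)
samples, labels = prepare_cohort(cohort)
plan = repeated_stratified_kfold(labels, k=3, repeats=1, seed=0)
preds = run_variant_cv(samples, labels, "itr", cfg.model, cfg.train, plan=plan)
ids = np.concatenate([p[1] for p in preds])
probs = np.concatenate([p[2] for p in preds])
print(f"patients: {len(labels)}  positives: {labels.sum()}")
print(f"pooled held-out AUC (ITR model): {roc_auc(labels[ids], probs):.3f}")
```

which prints

```
patients: 60  positives: 10
pooled held-out AUC (ITR model): 0.810
```

The phantom tumors carry a DWI intensity shift of five noise standard
deviations for recurrence-positive patients, so even 15 epochs on 40
training patients per fold recover the planted signal well above chance
(AUC 0.81 here; ≈ 0.98 at the 120-patient study size used by the
verification script); with all effect sizes set to zero the same pipeline
yields chance-level AUC.

The same experiment is available from the shell:

```bash
bcrfusion run --seed 0 --out runs/demo            # desk config, all variants
bcrfusion simulate --seed 0 --out runs/sim        # phantoms as NIfTI + CSV
bcrfusion build-rois --manifest runs/sim/data/manifest.csv --out runs/rois
bcrfusion compare --pred-dir runs/demo --out runs/cmp
```

## Layout

| path | contents |
|---|---|
| `src/bcrfusion/io_data.py` | NIfTI/CSV ingestion, grids, schemas |
| `src/bcrfusion/synthetic.py` | phantom cohort generator |
| `src/bcrfusion/roi.py` | mm-exact dilation, ITR/PTR/PPR, Dice |
| `src/bcrfusion/preprocessing.py` | z-score, slice stacks, clinical encoding, augmentation |
| `src/bcrfusion/nn/` | NumPy autodiff core, layers, AdamW |
| `src/bcrfusion/model.py` | the fusion network and its pieces |
| `src/bcrfusion/estimator.py` | sklearn-style classifiers |
| `src/bcrfusion/training.py` | splits, repeated CV, cosine schedule, training loop |
| `src/bcrfusion/evaluation.py` | metrics, AUC, DeLong, CV summaries |
| `src/bcrfusion/pipeline.py` / `cli.py` | orchestration and the `bcrfusion` CLI |

See `docs/methods.md` for the full methodological account.
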