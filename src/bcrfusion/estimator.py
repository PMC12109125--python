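"""Scikit-learn-style estimators wrapping the fusion network.

``RecurrenceClassifier`` consumes :class:`~bcrfusion.pipeline.PatientSample`
objects (per-region slice stacks + raw clinical record) and exposes the
usual ``fit`` / ``predict_proba`` / ``predict`` surface, so it composes with
sklearn model selection.  Clinical min–max statistics are fitted on the
training data seen by ``fit`` only; validation-time values outside the
training range are clipped.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .io_data import ClinicalRecord, ClinicalSchema, default_schema
from .model import ClinicalMLP, FusionNet, ModelConfig, PatientInput
from .nn import Tensor
from .preprocessing import AugmentParams, encode_clinical, fit_clinical_stats
from .training import TrainConfig, stratified_split, train_model

__all__ = ["RecurrenceClassifier", "ClinicalOnlyClassifier"]


class RecurrenceClassifier(BaseEstimator, ClassifierMixin):
    """Multi-region multi-sequence CNN–transformer recurrence classifier.

    Parameters mirror the model and training configuration; fitted state
    lives in trailing-underscore attributes (``model_``, ``history_``,
    ``clinical_stats_``).
    """

    def __init__(self, backbone: str = "tiny", input_size: int = 64,
                 n_slices: int = 8, regions: tuple = ("ITR", "PTR", "PPR"),
                 use_clinical: bool = False, d_emb: int = 16,
                 transformer_layers: int = 4, transformer_heads: int = 8,
                 model_dim: int = 256, ffn_dim: int | None = None,
                 dropout: float = 0.1, freeze_prefix: int = 2,
                 lr0: float = 1e-4, batch_size: int = 16, max_epochs: int = 300,
                 patience: int = 10, weight_decay: float = 0.01,
                 val_fraction: float = 0.2, augment: bool = True,
                 pos_weight: float | None = None, schema: ClinicalSchema | None = None,
                 seed: int = 0):
        self.backbone = backbone
        self.input_size = input_size
        self.n_slices = n_slices
        self.regions = regions
        self.use_clinical = use_clinical
        self.d_emb = d_emb
        self.transformer_layers = transformer_layers
        self.transformer_heads = transformer_heads
        self.model_dim = model_dim
        self.ffn_dim = ffn_dim
        self.dropout = dropout
        self.freeze_prefix = freeze_prefix
        self.lr0 = lr0
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.weight_decay = weight_decay
        self.val_fraction = val_fraction
        self.augment = augment
        self.pos_weight = pos_weight
        self.schema = schema
        self.seed = seed

    # -- config assembly ----------------------------------------------------

    def _model_config(self, d_cli: int) -> ModelConfig:
        return ModelConfig(
            backbone=self.backbone, input_size=self.input_size,
            n_slices=self.n_slices, regions=tuple(self.regions),
            use_clinical=self.use_clinical, d_cli=d_cli, d_emb=self.d_emb,
            transformer_layers=self.transformer_layers,
            transformer_heads=self.transformer_heads, model_dim=self.model_dim,
            ffn_dim=self.ffn_dim, dropout=self.dropout,
            freeze_prefix=self.freeze_prefix)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lr0=self.lr0, batch_size=self.batch_size, max_epochs=self.max_epochs,
            patience=self.patience, weight_decay=self.weight_decay,
            pos_weight=self.pos_weight, seed=self.seed)

    def _validate_X(self, X):
        for x in X:
            for r in self.regions:
                if r.upper() not in x.slices:
                    raise ValueError(
                        f"patient {x.patient_id}: missing slices for region {r}")
            if self.use_clinical and x.record is None:
                raise ValueError(
                    f"patient {x.patient_id}: clinical record required")

    def _encode(self, X, stats) -> list[PatientInput]:
        schema = self.schema or default_schema()
        inputs = []
        for x in X:
            clin = (encode_clinical(x.record, schema, stats)
                    if self.use_clinical else None)
            inputs.append(PatientInput(patient_id=x.patient_id, slices=x.slices,
                                       clinical=clin))
        return inputs

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on patient samples; if no explicit validation set is supplied,
        a stratified split of the training data monitors early stopping."""
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError(f"{len(X)} samples but {len(y)} labels")
        self._validate_X(X)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("fit requires both classes")
        schema = self.schema or default_schema()

        if X_val is None:
            tr_ids, va_ids = stratified_split(y, 1.0 - self.val_fraction,
                                              seed=self.seed)
            X_all, y_all = list(X), y
        else:
            tr_ids = np.arange(len(X))
            va_ids = np.arange(len(X), len(X) + len(X_val))
            X_all = list(X) + list(X_val)
            y_all = np.concatenate([y, np.asarray(y_val, dtype=int)])

        self.clinical_stats_ = (
            fit_clinical_stats([X_all[i].record for i in tr_ids], schema)
            if self.use_clinical else None)
        inputs = self._encode(X_all, self.clinical_stats_)
        cfg = self._model_config(schema.dim)
        aug = AugmentParams() if self.augment else AugmentParams(
            rotation_deg=0.0, flip_prob=0.0, brightness_range=(0.0, 0.0),
            contrast_range=(1.0, 1.0))
        self.model_, self.history_ = train_model(
            inputs, y_all, tr_ids, va_ids, cfg, self._train_config(), aug)
        self.config_ = cfg
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        self._validate_X(X)
        inputs = self._encode(X, getattr(self, "clinical_stats_", None))
        from .training import _predict_probs
        p1 = _predict_probs(self.model_, inputs, np.arange(len(inputs)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


class ClinicalOnlyClassifier(BaseEstimator, ClassifierMixin):
    """Clinical-covariate baseline: min–max encoding + a 2-layer perceptron
    (D_cli → 16 → 1, sigmoid), trained with AdamW, cosine schedule and
    validation-AUC early stopping."""

    def __init__(self, schema: ClinicalSchema | None = None, hidden: int = 16,
                 lr0: float = 1e-3, max_epochs: int = 200, patience: int = 10,
                 weight_decay: float = 0.01, val_fraction: float = 0.2,
                 seed: int = 0):
        self.schema = schema
        self.hidden = hidden
        self.lr0 = lr0
        self.max_epochs = max_epochs
        self.patience = patience
        self.weight_decay = weight_decay
        self.val_fraction = val_fraction
        self.seed = seed

    def _encode(self, records: list[ClinicalRecord], stats) -> np.ndarray:
        schema = self.schema or default_schema()
        return np.stack([encode_clinical(r, schema, stats).values
                         for r in records]).astype(np.float32)

    def fit(self, X, y):
        from sklearn.metrics import roc_auc_score

        from .training import cosine_lr

        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("fit requires both classes")
        schema = self.schema or default_schema()
        tr, va = stratified_split(y, 1.0 - self.val_fraction, seed=self.seed)
        self.stats_ = fit_clinical_stats([X[i] for i in tr], schema)
        feats = self._encode(list(X), self.stats_)
        model = ClinicalMLP(schema.dim, seed=self.seed, hidden=self.hidden)
        opt = nn.AdamW(model.parameters(), lr=self.lr0,
                       weight_decay=self.weight_decay)
        rng = np.random.default_rng(self.seed)
        best, best_state, stall = -np.inf, None, 0
        for epoch in range(1, self.max_epochs + 1):
            opt.lr = cosine_lr(epoch - 1, self.max_epochs, self.lr0)
            model.train()
            order = rng.permutation(tr)
            probs = model(Tensor(feats[order]))
            from .model import bce_loss
            loss = bce_loss(probs, y[order].astype(np.float32))
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.eval()
            with nn.no_grad():
                pv = model(Tensor(feats[va])).data
            auc = (roc_auc_score(y[va], pv)
                   if len(np.unique(y[va])) == 2 else float("nan"))
            if np.isfinite(auc) and auc > best:
                best, best_state, stall = auc, model.state_dict(), 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_state is not None:
            model.load_state_dict(best_state)
        self.model_ = model
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        feats = self._encode(list(X), self.stats_)
        self.model_.eval()
        with nn.no_grad():
            p1 = self.model_(Tensor(feats)).data
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
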