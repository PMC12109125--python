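"""Optimisation and resampling protocol.

Stratified 80/20 splitting with largest-remainder allocation, stratified
k-fold cross-validation repeated R times, AdamW with an epoch-granular
cosine-annealed learning rate, per-epoch validation-AUC early stopping with
best-epoch weight restoration, and training-time augmentation wired to the
training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

from . import nn
from .model import FusionNet, ModelConfig, PatientInput, bce_loss
from .nn import Tensor
from .preprocessing import AugmentParams, augment

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "stratified_split",
    "repeated_stratified_kfold",
    "cosine_lr",
    "train_model",
]


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 300
    patience: int = 10
    weight_decay: float = 0.01
    k: int = 5
    repeats: int = 20
    train_fraction: float = 0.8
    pos_weight: float | None = None  # optional positive-class loss weight
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.patience >= self.max_epochs:
            raise ValueError(
                f"patience ({self.patience}) must be smaller than max_epochs "
                f"({self.max_epochs})"
            )


@dataclass
class FoldPlan:
    """All (repeat, fold) train/validation index pairs of a repeated CV."""

    entries: list[tuple[int, int, np.ndarray, np.ndarray]] = field(default_factory=list)
    k: int = 5
    repeats: int = 1

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_json(self, path) -> None:
        import json
        payload = [{"repeat": int(r), "fold": int(f),
                    "train": np.asarray(tr).tolist(),
                    "validation": np.asarray(va).tolist()}
                   for r, f, tr, va in self.entries]
        with open(path, "w") as fh:
            json.dump({"k": self.k, "repeats": self.repeats, "folds": payload}, fh)

    @classmethod
    def from_json(cls, path) -> "FoldPlan":
        import json
        with open(path) as fh:
            d = json.load(fh)
        entries = [(e["repeat"], e["fold"], np.asarray(e["train"]),
                    np.asarray(e["validation"])) for e in d["folds"]]
        return cls(entries=entries, k=d["k"], repeats=d["repeats"])


def stratified_split(labels, train_fraction: float = 0.8, seed: int = 0,
                     allow_adjust: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation partition with largest-remainder counts.

    The total training size is round(train_fraction * N); per-class training
    counts are the class quotas floored, with leftover slots given to the
    classes with the largest fractional remainders.  Assignment within a
    class is a seeded uniform draw.  If a class would vanish from either
    side, an error is raised unless ``allow_adjust`` moves one sample back.
    """
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present for a stratified split")
    if counts.min() < 2:
        raise ValueError(f"smallest stratum has {counts.min()} member(s); need >= 2")
    n_train = int(np.floor(train_fraction * n + 0.5))
    quotas = train_fraction * counts
    base = np.floor(quotas).astype(int)
    rem = quotas - base
    short = n_train - base.sum()
    order = np.argsort(-rem, kind="stable")
    take = base.copy()
    for i in range(int(short)):
        take[order[i % len(classes)]] += 1
    for ci, c in enumerate(classes):
        if take[ci] >= counts[ci]:
            if allow_adjust:
                take[ci] = counts[ci] - 1
            else:
                raise ValueError(
                    f"class {c} would have no validation samples "
                    f"(train quota {take[ci]} of {counts[ci]}); "
                    "reduce train_fraction or set allow_adjust"
                )
        if take[ci] == 0:
            if allow_adjust:
                take[ci] = 1
            else:
                raise ValueError(f"class {c} would have no training samples")
    rng = np.random.default_rng(seed)
    train_ids, val_ids = [], []
    for ci, c in enumerate(classes):
        members = np.where(labels == c)[0]
        perm = rng.permutation(members)
        train_ids.extend(perm[: take[ci]])
        val_ids.extend(perm[take[ci]:])
    return np.sort(np.array(train_ids)), np.sort(np.array(val_ids))


def repeated_stratified_kfold(labels, k: int = 5, repeats: int = 20,
                              seed: int = 0) -> FoldPlan:
    """Stratified k-fold CV repeated ``repeats`` times with fresh shuffles."""
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot form {k} folds"
        )
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    entries = []
    for i, (tr, va) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        entries.append((i // k, i % k, tr, va))
    return FoldPlan(entries=entries, k=k, repeats=repeats)


def cosine_lr(step: int, total_steps: int, lr0: float) -> float:
    """lr = lr0 · ½(1 + cos(π·step/total_steps)); lr0 at 0, 0 at the end."""
    if step < 0 or step > total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * step / total_steps))


def _weighted_bce(probs: Tensor, y: np.ndarray, pos_weight: float) -> Tensor:
    p = probs.clip(1e-7, 1.0 - 1e-7)
    yw = y * pos_weight
    terms = Tensor(yw) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -terms.sum() * (1.0 / (yw.sum() + (1 - y).sum()))


def _batch_arrays(inputs: list[PatientInput], ids, regions, augment_fn=None):
    xs, pads, clins = [], [], []
    for i in ids:
        x, pad = inputs[i].stack(regions, augment_fn)
        xs.append(x)
        pads.append(pad)
        if inputs[i].clinical is not None:
            clins.append(inputs[i].clinical.values)
    x = np.stack(xs).astype(np.float32)
    pad = np.stack(pads)
    clin = np.stack(clins).astype(np.float32) if clins else None
    return x, pad, clin


def _predict_probs(model: FusionNet, inputs, ids, batch_size=32) -> np.ndarray:
    model.eval()
    out = []
    with nn.no_grad():
        for s in range(0, len(ids), batch_size):
            chunk = ids[s: s + batch_size]
            x, pad, clin = _batch_arrays(inputs, chunk, model.cfg.regions)
            ct = Tensor(clin) if (model.cfg.use_clinical and clin is not None) else None
            out.append(model(Tensor(x), pad, ct).data)
    return np.concatenate(out)


def _safe_auc(y, p) -> float:
    from sklearn.metrics import roc_auc_score
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, p))


def train_model(inputs: list[PatientInput], labels, train_ids, val_ids,
                model_cfg: ModelConfig, train_cfg: TrainConfig,
                augment_params: AugmentParams | None = None,
                ) -> tuple[FusionNet, pd.DataFrame]:
    """Train the fusion network on the given split.

    Returns the model restored to its best-validation-AUC weights and a
    per-epoch history (epoch, train_loss, val_auc, lr).  Ties in the
    validation metric count as non-improvement; training halts once the
    metric has not improved for ``patience`` consecutive epochs.
    """
    labels = np.asarray(labels).astype(int)
    train_ids = np.asarray(train_ids)
    val_ids = np.asarray(val_ids)
    if np.intersect1d(train_ids, val_ids).size:
        raise ValueError("train and validation splits overlap")
    if len(np.unique(labels[train_ids])) < 2:
        raise ValueError("training split contains a single class")

    rng = np.random.default_rng(train_cfg.seed)
    model = FusionNet(model_cfg, seed=train_cfg.seed)
    opt = nn.AdamW(model.parameters(), lr=train_cfg.lr0,
                   weight_decay=train_cfg.weight_decay)
    aug = augment_params if augment_params is not None else AugmentParams()
    augment_fn = (lambda sp: augment(sp, rng, aug))

    best_auc = -np.inf
    best_state = None
    best_epoch = 0
    stall = 0
    history = []
    for epoch in range(1, train_cfg.max_epochs + 1):
        lr = cosine_lr(epoch - 1, train_cfg.max_epochs, train_cfg.lr0)
        opt.lr = lr
        model.train()
        order = rng.permutation(train_ids)
        losses = []
        for s in range(0, len(order), train_cfg.batch_size):
            batch = order[s: s + train_cfg.batch_size]
            x, pad, clin = _batch_arrays(inputs, batch, model_cfg.regions, augment_fn)
            ct = Tensor(clin) if (model_cfg.use_clinical and clin is not None) else None
            probs = model(Tensor(x), pad, ct)
            y = labels[batch].astype(np.float32)
            if train_cfg.pos_weight:
                loss = _weighted_bce(probs, y, train_cfg.pos_weight)
            else:
                loss = bce_loss(probs, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_probs = _predict_probs(model, inputs, val_ids)
        val_auc = _safe_auc(labels[val_ids], val_probs)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_auc": val_auc, "lr": lr})
        if np.isfinite(val_auc) and val_auc > best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= train_cfg.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return model, hist
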