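"""Classification metrics, ROC analysis, CV summaries and model comparison.

Threshold metrics are the standard confusion-table quantities
(sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, F1).  AUC is the
tie-aware Mann–Whitney probability that a positive outscores a negative.
Repeated-CV results are summarised as the mean with a 95% percentile
interval over fold-repeat estimates.  Correlated ROC curves are compared
with the DeLong test via placement values (structural components).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ConfusionMetrics",
    "MetricsReport",
    "ComparisonResult",
    "confusion_metrics",
    "roc_auc",
    "roc_points",
    "youden_threshold",
    "delong_test",
    "delong_variance",
    "summarize_cv",
    "compare_models",
    "significance_band",
]

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "f1", "auc")


@dataclass
class ConfusionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float  # NaN when no positives
    specificity: float  # NaN when no negatives
    accuracy: float
    f1: float
    sensitivity_defined: bool = True
    specificity_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "accuracy": self.accuracy, "f1": self.f1}


@dataclass
class MetricsReport:
    """(mean, ci_low, ci_high) per metric over fold-repeat estimates."""

    metrics: dict[str, tuple[float, float, float]]
    n_estimates: int

    def __getitem__(self, name: str):
        return self.metrics[name]


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    auc_a: float
    auc_b: float
    delong_z: float
    delong_p: float
    band: str = field(init=False)

    def __post_init__(self):
        if not (0.0 < self.delong_p <= 1.0):
            raise ValueError(f"p-value out of range: {self.delong_p}")
        self.band = significance_band(self.delong_p)


def significance_band(p: float) -> str:
    if p >= 0.05:
        return "ns"
    return "0.01<p<0.05" if p > 0.01 else "p<0.01"


def confusion_metrics(labels, probs, threshold: float = 0.5) -> ConfusionMetrics:
    """Threshold the probabilities (>= threshold is positive) and evaluate
    the confusion-table metrics; undefined ratios are flagged, not zeroed."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"labels {y.shape} and probs {p.shape} differ in length")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    npos, nneg = tp + fn, tn + fp
    sens = tp / npos if npos else float("nan")
    spec = tn / nneg if nneg else float("nan")
    acc = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    return ConfusionMetrics(tp=tp, tn=tn, fp=fp, fn=fn, sensitivity=sens,
                            specificity=spec, accuracy=acc, f1=f1,
                            sensitivity_defined=npos > 0,
                            specificity_defined=nneg > 0)


def roc_auc(labels, scores) -> float:
    """Tie-aware AUC: P(score⁺ > score⁻) + ½ P(score⁺ = score⁻)."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_points(labels, scores) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold), exportable as CSV."""
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int),
                              np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def youden_threshold(labels, scores) -> float:
    """Operating point maximising sensitivity + specificity − 1 (choose on
    training folds only)."""
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), scores)
    return float(thr[np.argmax(tpr - fpr)])


# ---------------------------------------------------------------------------
# DeLong test


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _placements(pos: np.ndarray, neg: np.ndarray):
    """Placement values (structural components) and the AUC for one model."""
    m, n = len(pos), len(neg)
    z = np.concatenate([pos, neg])
    t = _midrank(z)
    tp = _midrank(pos)
    tn = _midrank(neg)
    v01 = (t[:m] - tp) / n              # per-positive components
    v10 = 1.0 - (t[m:] - tn) / m        # per-negative components
    auc = t[:m].sum() / (m * n) - (m + 1.0) / (2.0 * n)
    return v01, v10, auc


def delong_variance(labels, scores_a, scores_b):
    """AUCs, the variance of their difference and its covariance pieces."""
    y = np.asarray(labels).astype(int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (y.shape == a.shape == b.shape):
        raise ValueError("labels and both score vectors must share length")
    if len(np.unique(y)) < 2:
        raise ValueError("DeLong test requires both classes")
    pos, neg = y == 1, y == 0
    m, n = int(pos.sum()), int(neg.sum())
    v01 = np.empty((2, m))
    v10 = np.empty((2, n))
    aucs = np.empty(2)
    for r, s in enumerate((a, b)):
        v01[r], v10[r], aucs[r] = _placements(s[pos], s[neg])
    s01 = np.cov(v01) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(v10) if n > 1 else np.zeros((2, 2))
    var = (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / m \
        + (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n
    return aucs[0], aucs[1], float(var)


def delong_test(labels, scores_a, scores_b) -> tuple[float, float]:
    """Two-sided DeLong comparison of two correlated AUCs -> (z, p)."""
    auc_a, auc_b, var = delong_variance(labels, scores_a, scores_b)
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        raise FloatingPointError(
            f"zero DeLong variance with unequal AUCs ({auc_a} vs {auc_b})"
        )
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(max(p, np.finfo(float).tiny), 1.0))


# ---------------------------------------------------------------------------
# repeated-CV summaries and the model-comparison harness


def summarize_cv(values, metric_names=METRIC_NAMES) -> MetricsReport:
    """Mean and 95% percentile CI over fold-repeat estimates.

    ``values`` is either a mapping metric -> sequence of estimates or a
    DataFrame with one column per metric.
    """
    if isinstance(values, pd.DataFrame):
        values = {c: values[c].to_numpy() for c in values.columns}
    out = {}
    n = None
    for name, vals in values.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError(f"metric '{name}': need >= 2 estimates, got {len(vals)}")
        n = len(vals) if n is None else n
        lo, hi = np.percentile(vals, [2.5, 97.5], method="linear")
        out[name] = (float(vals.mean()), float(lo), float(hi))
    return MetricsReport(metrics=out, n_estimates=n or 0)


def _fold_metric_frame(labels, fold_preds, threshold: float) -> pd.DataFrame:
    rows = []
    for _key, ids, probs in fold_preds:
        y = np.asarray(labels)[np.asarray(ids)]
        cm = confusion_metrics(y, probs, threshold)
        row = cm.as_dict()
        row["auc"] = roc_auc(y, probs) if len(np.unique(y)) == 2 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(labels, model_preds: dict[str, list], threshold: float = 0.5,
                   reference: str | None = None
                   ) -> tuple[dict[str, MetricsReport], list[ComparisonResult], pd.DataFrame]:
    """Per-model CV summaries plus pairwise DeLong comparisons.

    ``model_preds`` maps a model name to its fold-wise validation
    predictions, a list of ``(fold_key, patient_ids, probs)``.  All models
    must be evaluated on the same patients fold for fold.  The DeLong
    comparison pools each model's first-repeat out-of-fold predictions so
    that every patient contributes exactly once.
    """
    names = list(model_preds)
    ref_folds = [(tuple(np.asarray(ids).tolist())) for _k, ids, _p in model_preds[names[0]]]
    for name in names[1:]:
        folds = [(tuple(np.asarray(ids).tolist())) for _k, ids, _p in model_preds[name]]
        if folds != ref_folds:
            raise ValueError(f"model '{name}' evaluated on different patients/folds")
    reports = {
        name: summarize_cv(_fold_metric_frame(labels, preds, threshold))
        for name, preds in model_preds.items()
    }

    def pooled(name):
        ids_all, probs_all = [], []
        seen = set()
        for _key, ids, probs in model_preds[name]:
            ids = np.asarray(ids)
            if any(i in seen for i in ids.tolist()):
                break  # start of the next repeat
            seen.update(ids.tolist())
            ids_all.append(ids)
            probs_all.append(np.asarray(probs))
        ids_all = np.concatenate(ids_all)
        order = np.argsort(ids_all)
        return ids_all[order], np.concatenate(probs_all)[order]

    comparisons = []
    ref_names = [reference] if reference else names
    done = set()
    for a in ref_names:
        for b in names:
            if a == b or (b, a) in done:
                continue
            done.add((a, b))
            ids_a, pa = pooled(a)
            ids_b, pb = pooled(b)
            y = np.asarray(labels)[ids_a]
            z, p = delong_test(y, pa, pb)
            comparisons.append(ComparisonResult(
                model_a=a, model_b=b,
                auc_a=roc_auc(y, pa), auc_b=roc_auc(np.asarray(labels)[ids_b], pb),
                delong_z=z, delong_p=p))

    abbrev = {"sensitivity": "SENS", "specificity": "SPEC", "accuracy": "ACC",
              "f1": "F1", "auc": "AUC"}
    rows = []
    for name in names:
        rep = reports[name]
        row = {"model": name}
        for m in METRIC_NAMES:
            mean, lo, hi = rep[m]
            row[abbrev[m]] = f"{mean:.3f} ({lo:.3f}-{hi:.3f})"
        rows.append(row)
    table = pd.DataFrame(rows, columns=["model"] + [abbrev[m] for m in METRIC_NAMES])
    return reports, comparisons, table
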