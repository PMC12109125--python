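"""Metrics, ROC/AUC, DeLong test and CV summaries against oracles."""

import numpy as np
import pytest

from bcrfusion.evaluation import (
    compare_models,
    confusion_metrics,
    delong_test,
    delong_variance,
    roc_auc,
    significance_band,
    summarize_cv,
    youden_threshold,
)

rng = np.random.default_rng(31)


def brute_force_auc(y, s):
    pos, neg = s[y == 1], s[y == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * ties) / (len(pos) * len(neg))


# -- confusion metrics ------------------------------------------------------

def test_confusion_metrics_worked_example():
    # TP=3, FP=1, TN=5, FN=1
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    p = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.2, 0.3, 0.1, 0.4, 0.9])
    m = confusion_metrics(y, p, 0.5)
    assert (m.tp, m.fp, m.tn, m.fn) == (3, 1, 5, 1)
    assert m.sensitivity == pytest.approx(0.75)
    assert m.specificity == pytest.approx(5 / 6)
    assert m.accuracy == pytest.approx(0.8)
    assert m.f1 == pytest.approx(0.75)


def test_confusion_metrics_perfect_and_degenerate():
    y = np.array([1, 0, 1, 0])
    m = confusion_metrics(y, np.array([0.9, 0.1, 0.8, 0.2]))
    assert (m.sensitivity, m.specificity, m.accuracy, m.f1) == (1, 1, 1, 1)
    m = confusion_metrics(np.zeros(4, dtype=int), np.array([0.1, 0.2, 0.9, 0.1]))
    assert not m.sensitivity_defined and np.isnan(m.sensitivity)
    assert m.specificity_defined and m.specificity == pytest.approx(0.75)


def test_confusion_accuracy_identity_on_random_tables():
    for seed in range(30):
        r = np.random.default_rng(seed)
        y = r.integers(0, 2, size=50)
        p = r.random(50)
        m = confusion_metrics(y, p, 0.5)
        npos, nneg = (y == 1).sum(), (y == 0).sum()
        if npos and nneg:
            assert m.accuracy == pytest.approx(
                (m.sensitivity * npos + m.specificity * nneg) / 50)


# -- AUC --------------------------------------------------------------------

def test_roc_auc_edge_cases():
    y = np.array([1, 1, 0, 0])
    assert roc_auc(y, np.array([0.9, 0.8, 0.2, 0.1])) == 1.0
    assert roc_auc(y, np.array([0.5, 0.5, 0.5, 0.5])) == 0.5
    assert roc_auc(np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.7, 0.1])) == 0.75
    with pytest.raises(ValueError):
        roc_auc(np.ones(4), np.ones(4))


def test_roc_auc_matches_all_pairs_oracle_on_200_instances():
    for seed in range(200):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 60))
        y = r.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = np.round(r.random(n), 1)  # coarse grid -> frequent ties
        assert abs(roc_auc(y, s) - brute_force_auc(y, s)) < 1e-12


def test_roc_auc_complement_symmetry():
    for seed in range(20):
        r = np.random.default_rng(seed)
        y = r.integers(0, 2, size=30)
        y[:2] = [0, 1]
        s = np.round(r.random(30), 1)
        assert roc_auc(y, s) + roc_auc(y, -s) == pytest.approx(1.0, abs=1e-12)


def test_youden_threshold_separates_separable_scores():
    y = np.array([0, 0, 0, 1, 1, 1])
    s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
    t = youden_threshold(y, s)
    assert 0.3 < t <= 0.7


# -- DeLong -----------------------------------------------------------------

def test_delong_self_comparison_and_antisymmetry():
    y = (rng.random(80) < 0.4).astype(int)
    a = rng.standard_normal(80) + y
    b = 0.5 * a + rng.standard_normal(80)
    z, p = delong_test(y, a, a)
    assert z == 0.0 and p == 1.0
    z_ab, p_ab = delong_test(y, a, b)
    z_ba, p_ba = delong_test(y, b, a)
    assert z_ab == pytest.approx(-z_ba)
    assert p_ab == pytest.approx(p_ba)


def test_delong_z_matches_direct_placement_covariance():
    """Direct O(n^2) placement-value computation on small instances."""
    for seed in range(10):
        r = np.random.default_rng(seed)
        n = int(r.integers(20, 51))
        y = r.integers(0, 2, size=n)
        y[:4] = [0, 0, 1, 1]
        a = r.standard_normal(n) + 0.7 * y
        b = r.standard_normal(n) + 0.4 * y
        pos, neg = np.where(y == 1)[0], np.where(y == 0)[0]
        m, nn_ = len(pos), len(neg)

        def placements(s):
            v01 = np.array([((s[i] > s[neg]).sum() + 0.5 * (s[i] == s[neg]).sum()) / nn_
                            for i in pos])
            v10 = np.array([((pos.size and (s[pos] > s[j]).sum())
                             + 0.5 * (s[pos] == s[j]).sum()) / m for j in neg])
            return v01, 1.0 - v10

        va01, va10 = placements(a)
        vb01, vb10 = placements(b)
        auc_a, auc_b = va01.mean(), vb01.mean()
        s01 = np.cov(np.stack([va01, vb01]))
        s10 = np.cov(np.stack([1.0 - va10, 1.0 - vb10]))
        var = (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / m \
            + (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / nn_
        z_direct = (auc_a - auc_b) / np.sqrt(var)
        z, _ = delong_test(y, a, b)
        assert z == pytest.approx(z_direct, abs=1e-8)


def test_delong_variance_close_to_bootstrap():
    r = np.random.default_rng(4)
    n = 200
    y = (r.random(n) < 0.4).astype(int)
    base = r.standard_normal(n) + 0.8 * y
    a = base + 0.5 * r.standard_normal(n)
    b = 0.7 * base + 0.6 * r.standard_normal(n)
    _, _, var = delong_variance(y, a, b)
    boot = []
    for _ in range(1000):
        idx = r.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        boot.append(roc_auc(y[idx], a[idx]) - roc_auc(y[idx], b[idx]))
    bv = np.var(boot)
    assert abs(var - bv) / bv < 0.15


def test_significance_bands():
    assert significance_band(0.5) == "ns"
    assert significance_band(0.03) == "0.01<p<0.05"
    assert significance_band(0.001) == "p<0.01"


# -- CV summaries -----------------------------------------------------------

def test_summarize_cv_degenerate_and_percentiles():
    rep = summarize_cv({"auc": [0.7] * 10})
    assert rep["auc"] == (0.7, 0.7, 0.7)
    vals = np.arange(1, 101) / 100.0
    rep = summarize_cv({"auc": vals})
    lo, hi = np.percentile(vals, [2.5, 97.5], method="linear")
    assert rep["auc"] == (pytest.approx(vals.mean()), pytest.approx(lo),
                          pytest.approx(hi))
    shuffled = vals.copy()
    np.random.default_rng(0).shuffle(shuffled)
    assert summarize_cv({"auc": shuffled})["auc"][0] == pytest.approx(vals.mean())
    with pytest.raises(ValueError):
        summarize_cv({"auc": [0.5]})


# -- comparison harness -----------------------------------------------------

def _fake_preds(labels, quality, seed, folds=3):
    r = np.random.default_rng(seed)
    n = len(labels)
    ids = np.arange(n)
    out = []
    for f in range(folds):
        va = ids[f::folds]
        probs = np.clip(0.5 + quality * (labels[va] - 0.5)
                        + 0.2 * r.standard_normal(len(va)), 0, 1)
        out.append((f"r0f{f}", va, probs))
    return out


def test_compare_models_self_comparison_and_table_schema():
    labels = (np.random.default_rng(1).random(60) < 0.4).astype(int)
    preds = _fake_preds(labels, 0.8, seed=2)
    reports, comps, table = compare_models(labels, {"a": preds, "b": preds})
    assert len(comps) == 1
    assert comps[0].delong_z == 0.0 and comps[0].delong_p == 1.0
    assert list(table.columns) == ["model", "SENS", "SPEC", "ACC", "F1", "AUC"]
    assert table["model"].tolist() == ["a", "b"]
    for name in ("a", "b"):
        mean, lo, hi = reports[name]["auc"]
        assert lo <= mean <= hi


def test_compare_models_rejects_mismatched_folds():
    labels = (np.random.default_rng(1).random(60) < 0.4).astype(int)
    preds_a = _fake_preds(labels, 0.8, seed=2)
    preds_b = _fake_preds(labels, 0.8, seed=2, folds=2)
    with pytest.raises(ValueError, match="different patients"):
        compare_models(labels, {"a": preds_a, "b": preds_b})


def test_roc_points_trace_the_curve():
    from bcrfusion.evaluation import roc_points
    y = np.array([0, 0, 1, 1])
    s = np.array([0.1, 0.4, 0.35, 0.8])
    df = roc_points(y, s)
    assert {"fpr", "tpr", "threshold"} == set(df.columns)
    assert df["fpr"].iloc[0] == 0.0 and df["tpr"].iloc[-1] == 1.0
    assert (df["fpr"].diff().dropna() >= 0).all()
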