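"""ROC/DeLong statistics, operating points, calibration, DCA, confusion."""

import numpy as np
import pytest
from scipy import stats

from perirad import (auc_delong, calibration_curve, confusion_metrics,
                     crossvalidate, decision_curve, delong_test,
                     operating_point)
from oracles import brute_auc


# -- AUC --------------------------------------------------------------------

def test_auc_equals_pair_counting_100_seeds():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 31))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        scores = np.round(rng.random(n), 2)  # duplicates exercise ties
        assert auc_delong(scores, labels).auc == brute_auc(scores, labels)


def test_auc_ci_and_variance():
    rng = np.random.default_rng(1)
    labels = np.repeat([0, 1], 50)
    scores = labels * 1.0 + rng.normal(0, 0.8, 100)
    r = auc_delong(scores, labels, cohort="training")
    assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1
    assert r.variance > 0
    assert r.cohort == "training"
    half = 1.96 * np.sqrt(r.variance)
    assert r.ci_high - r.ci_low == pytest.approx(
        min(1, r.auc + half) - max(0, r.auc - half), abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(ValueError, match="both classes"):
        auc_delong([0.2, 0.8], [1, 1])


# -- DeLong test ------------------------------------------------------------

def test_delong_identical_scores():
    labels = np.repeat([0, 1], 15)
    scores = np.linspace(0, 1, 30)
    z, p = delong_test(scores, scores, labels)
    assert z == 0.0 and p == 1.0


def test_delong_detects_clear_difference():
    rng = np.random.default_rng(2)
    labels = np.repeat([0, 1], 100)
    good = labels + rng.normal(0, 0.3, 200)
    bad = rng.normal(0, 1, 200)
    z, p = delong_test(good, bad, labels)
    assert p < 1e-4 and z > 0


def test_delong_paired_reduces_to_unpaired_when_independent():
    # with zero covariance the paired variance equals the sum of variances
    rng = np.random.default_rng(3)
    labels = np.repeat([0, 1], 40)
    a = labels + rng.normal(0, 1, 80)
    b = labels + rng.normal(0, 1, 80)
    z_p, _ = delong_test(a, b, labels, paired=True)
    z_u, _ = delong_test(a, b, labels, labels_b=labels, paired=False)
    # same AUC difference, variances differ only by the (small) covariance
    assert np.sign(z_p) == np.sign(z_u)
    assert abs(z_p - z_u) < 1.0


def test_delong_type_i_error_calibrated():
    # two equally-uninformative paired scores: p < 0.05 should occur ~5%
    hits = 0
    n_rep = 500
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1], 30)
        latent = rng.normal(0, 1, 60)
        a = latent + rng.normal(0, 1, 60)
        b = latent + rng.normal(0, 1, 60)
        _, p = delong_test(a, b, labels)
        hits += p < 0.05
    assert 0.03 < hits / n_rep < 0.07


def test_delong_unpaired_requires_labels():
    with pytest.raises(ValueError, match="unpaired"):
        delong_test([0.1, 0.9], [0.2, 0.8], [0, 1], paired=False)


# -- operating point --------------------------------------------------------

def test_operating_point_youden():
    scores = np.array([0.1, 0.2, 0.3, 0.6, 0.7, 0.9])
    labels = np.array([0, 0, 0, 1, 1, 1])
    sens, spec, thr = operating_point(scores, labels)
    assert sens == 1.0 and spec == 1.0
    assert 0.3 < thr <= 0.6


def test_operating_point_tie_breaks_to_highest_threshold():
    scores = np.array([0.2, 0.4, 0.6, 0.8])
    labels = np.array([0, 1, 0, 1])
    sens, spec, thr = operating_point(scores, labels)
    # J = 0.5 at thresholds 0.4 and 0.8; tie resolves to 0.8
    assert thr == 0.8
    assert sens == 0.5 and spec == 1.0


def test_frozen_threshold_reused():
    scores = np.array([0.1, 0.4, 0.6, 0.9])
    labels = np.array([0, 0, 1, 1])
    r = auc_delong(scores, labels, threshold=0.5)
    assert r.threshold == 0.5
    assert r.sensitivity == 1.0 and r.specificity == 1.0


# -- calibration ------------------------------------------------------------

def test_calibration_well_calibrated_probs():
    rng = np.random.default_rng(4)
    probs = rng.uniform(0.05, 0.95, 4000)
    labels = (rng.random(4000) < probs).astype(int)
    pts, slope, intercept = calibration_curve(probs, labels)
    assert slope == pytest.approx(1.0, abs=0.15)
    assert intercept == pytest.approx(0.0, abs=0.2)
    assert (pts["n"] >= 2).all()
    assert np.abs(pts["mean_predicted"] - pts["observed"]).max() < 0.1


def test_calibration_validation():
    with pytest.raises(ValueError, match="probabilities"):
        calibration_curve([0.5, 1.2], [0, 1])


# -- decision curves --------------------------------------------------------

def test_dca_treat_all_closed_form():
    labels = np.array([1] * 3 + [0] * 7)  # prevalence 0.3
    probs = np.full(10, 0.99)
    dc = decision_curve(probs, labels, thresholds=np.array([0.1]))
    assert dc.treat_all[0] == pytest.approx(0.3 - 0.7 / 9)
    assert dc.treat_all[0] == pytest.approx(0.22222222, abs=1e-6)
    # predicting everyone positive reproduces treat-all
    assert dc.net_benefit[0] == pytest.approx(dc.treat_all[0])
    assert dc.treat_none[0] == 0.0


def test_dca_never_beats_perfect_classifier():
    rng = np.random.default_rng(5)
    labels = (rng.random(200) < 0.3).astype(int)
    probs = np.clip(labels * 0.7 + rng.random(200) * 0.3, 0, 1)
    dc = decision_curve(probs, labels)
    prevalence = labels.mean()
    assert (dc.net_benefit <= prevalence + 1e-12).all()
    assert np.isfinite(dc.net_benefit).all()
    df = dc.to_frame()
    assert list(df.columns) == ["threshold", "model", "treat_all", "treat_none"]
    assert len(df) == 99


def test_dca_threshold_bounds():
    with pytest.raises(ValueError, match="thresholds"):
        decision_curve([0.5], [1], thresholds=np.array([0.0, 0.5]))


# -- confusion metrics ------------------------------------------------------

def test_confusion_perfect():
    r = confusion_metrics(["A", "B", "C"], ["A", "B", "C"])
    assert r.accuracy == 1.0 and r.f1 == 1.0


def test_confusion_three_class_worked_example():
    truth = ["A", "A", "B", "B", "C", "C"]
    pred = ["A", "B", "B", "B", "C", "A"]
    r = confusion_metrics(pred, truth)
    assert r.accuracy == pytest.approx(4 / 6)
    # per-class F1: A 1/2, B 4/5, C 2/3; equal support -> weighted mean 59/90
    assert r.f1 == pytest.approx(59 / 90)
    assert r.matrix.to_numpy().sum() == 6
    assert np.trace(r.matrix.to_numpy()) == 4


def test_confusion_unseen_predicted_class_column():
    r = confusion_metrics(["A", "D"], ["A", "B"])
    assert "D" in r.matrix.columns
    assert "D" not in r.matrix.index
    assert r.matrix.loc["B", "D"] == 1


# -- cross-validation -------------------------------------------------------

class _Dummy:
    def fit(self, X, y):
        self.mean_ = X[y == 1].mean() if (y == 1).any() else 0.0
        return self

    def predict_proba(self, X):
        d = np.abs(X.sum(axis=1))
        p = 1 / (1 + np.exp(-(X.sum(axis=1))))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (X.sum(axis=1) > 0).astype(int)


def test_crossvalidate_stratified_and_deterministic():
    rng = np.random.default_rng(6)
    X = rng.normal(0, 1, (40, 3))
    y = np.repeat([0, 1], 20)
    X[y == 1] += 1.5
    a = crossvalidate(_Dummy, X, y, k=5, seed=1)
    b = crossvalidate(_Dummy, X, y, k=5, seed=1)
    assert a.equals(b)
    assert len(a) == 5
    assert a["auc"].mean() > 0.7


def test_crossvalidate_loo_boundary_and_k_validation():
    X = np.random.default_rng(7).normal(0, 1, (8, 2))
    y = np.array([0, 1] * 4)
    out = crossvalidate(_Dummy, X, y, k=8, metric="accuracy")
    assert len(out) == 8 and (out["n_test"] == 1).all()
    with pytest.raises(ValueError, match="smaller k"):
        crossvalidate(_Dummy, X, y, k=5)
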