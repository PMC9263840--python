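"""ROC/AUC statistics, DeLong comparisons, calibration, decision curves,
and ternary confusion metrics.

AUC is the Mann-Whitney estimator (ties get half credit); its variance uses
the DeLong structural components in the midrank formulation, giving the
usual normal-approximation 95% CI and the paired/unpaired DeLong tests.
Operating points maximize Youden's J on the cohort the ROC was built from;
when evaluating test cohorts the training threshold is frozen and reused.
Decision-curve net benefit is NB(t) = TP/n - FP/n * t/(1-t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold


# ---------------------------------------------------------------------------
# DeLong machinery


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """(AUC, V10 placements of positives, V01 placements of negatives)."""
    labels = np.asarray(labels).astype(int)
    pos = np.asarray(scores, dtype=np.float64)[labels == 1]
    neg = np.asarray(scores, dtype=np.float64)[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_s = np.concatenate([pos, neg])
    r_all = _midranks(all_s)
    r_pos = _midranks(pos)
    r_neg = _midranks(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n            # placement of each positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m      # placement of each negative
    return float(auc), v10, v01


@dataclass(frozen=True)
class RocResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    threshold: float
    cohort: str = ""

    def to_dict(self) -> dict:
        return {"auc": self.auc, "variance": self.variance,
                "ci": [self.ci_low, self.ci_high],
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "threshold": self.threshold, "cohort": self.cohort}


def auc_delong(scores, labels, cohort: str = "",
               threshold: float | None = None) -> RocResult:
    """AUC with DeLong variance and 95% CI, plus a Youden operating point.

    If ``threshold`` is given (frozen from training), sensitivity and
    specificity are evaluated there instead of re-optimizing.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.96 * np.sqrt(max(var, 0.0))
    if threshold is None:
        sens, spec, threshold = operating_point(scores, labels)
    else:
        sens, spec = _sens_spec_at(scores, labels, threshold)
    return RocResult(auc=auc, variance=float(var),
                     ci_low=float(np.clip(auc - half, 0, 1)),
                     ci_high=float(np.clip(auc + half, 0, 1)),
                     sensitivity=sens, specificity=spec,
                     threshold=float(threshold), cohort=cohort)


def delong_test(scores_a, scores_b, labels_a, labels_b=None,
                paired: bool = True) -> tuple[float, float]:
    """Two-sided DeLong comparison of two AUCs; returns (Z, p).

    Paired mode requires both score vectors on the same cases (covariance
    term included); unpaired mode compares independent cohorts and reduces
    to the zero-covariance formula.
    """
    if paired:
        if labels_b is not None and not np.array_equal(labels_a, labels_b):
            raise ValueError("paired comparison needs identical labels")
        auc_a, v10a, v01a = _delong_components(scores_a, labels_a)
        auc_b, v10b, v01b = _delong_components(scores_b, labels_a)
        m, n = v10a.size, v01a.size
        var_a = np.var(v10a, ddof=1) / m + np.var(v01a, ddof=1) / n
        var_b = np.var(v10b, ddof=1) / m + np.var(v01b, ddof=1) / n
        cov = (np.cov(v10a, v10b, ddof=1)[0, 1] / m
               + np.cov(v01a, v01b, ddof=1)[0, 1] / n)
        var = var_a + var_b - 2 * cov
    else:
        if labels_b is None:
            raise ValueError("unpaired comparison needs labels for both cohorts")
        ra = auc_delong(scores_a, labels_a)
        rb = auc_delong(scores_b, labels_b)
        auc_a, auc_b = ra.auc, rb.auc
        var = ra.variance + rb.variance
    if var <= 0:
        if auc_a == auc_b:
            return 0.0, 1.0
        raise ValueError("degenerate variance in DeLong test")
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Operating point


def _sens_spec_at(scores, labels, threshold) -> tuple[float, float]:
    scores = np.asarray(scores)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    pos = labels == 1
    sens = float(pred[pos].mean()) if pos.any() else 0.0
    spec = float((~pred[~pos]).mean()) if (~pos).any() else 0.0
    return sens, spec


def operating_point(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J over all observed score cuts.

    Returns (sensitivity, specificity, threshold); ties resolve to the
    highest threshold (most specific among equal-J cuts).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    cuts = np.unique(scores)
    cand = np.concatenate([cuts, [cuts[-1] + 1.0]])  # include predict-none
    best = (-np.inf, 0.0, 0.0, 0.0)
    for t in cand:
        sens, spec = _sens_spec_at(scores, labels, t)
        j = sens + spec - 1.0
        if j > best[0] or (j == best[0] and t > best[3]):
            best = (j, sens, spec, t)
    return best[1], best[2], float(best[3])


# ---------------------------------------------------------------------------
# Calibration


def calibration_curve(probs, labels, bins: int = 10
                      ) -> tuple[pd.DataFrame, float, float]:
    """Quantile-binned reliability points plus logistic recalibration.

    Returns (points DataFrame [mean_predicted, observed, n], slope,
    intercept) where slope/intercept come from regressing the outcome on
    logit(p); a perfectly calibrated model has slope 1, intercept 0.
    Bins with fewer than 2 cases are merged into their left neighbor.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, bins + 1)))
    idx = np.clip(np.searchsorted(edges, probs, side="right") - 1,
                  0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() == 0:
            continue
        if sel.sum() < 2 and rows:
            prev = rows[-1]
            ntot = prev["n"] + sel.sum()
            prev["mean_predicted"] = (prev["mean_predicted"] * prev["n"]
                                      + probs[sel].sum()) / ntot
            prev["observed"] = (prev["observed"] * prev["n"]
                                + labels[sel].sum()) / ntot
            prev["n"] = ntot
            continue
        rows.append({"mean_predicted": float(probs[sel].mean()),
                     "observed": float(labels[sel].mean()),
                     "n": int(sel.sum())})
    pts = pd.DataFrame(rows)
    eps = 1e-6
    lp = np.log(np.clip(probs, eps, 1 - eps) / np.clip(1 - probs, eps, 1 - eps))
    import statsmodels.api as sm
    try:
        fit = sm.GLM(labels, sm.add_constant(lp),
                     family=sm.families.Binomial()).fit()
        intercept, slope = float(fit.params[0]), float(fit.params[1])
    except Exception:
        intercept, slope = 0.0, 1.0
    return pts, slope, intercept


# ---------------------------------------------------------------------------
# Decision curves


@dataclass(frozen=True)
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.treat_none is None:
            object.__setattr__(self, "treat_none",
                               np.zeros_like(self.thresholds))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "model": self.net_benefit,
                             "treat_all": self.treat_all,
                             "treat_none": self.treat_none})


def decision_curve(probs, labels,
                   thresholds: np.ndarray | None = None) -> DecisionCurve:
    """Net benefit across threshold probabilities (default grid 0.01..0.99)."""
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.min() <= 0 or thresholds.max() >= 1:
        raise ValueError("thresholds must lie in (0, 1)")
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n = labels.size
    prev = labels.mean()
    odds = thresholds / (1.0 - thresholds)
    nb = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = probs >= t
        tp = (pred & (labels == 1)).sum()
        fp = (pred & (labels == 0)).sum()
        nb[i] = tp / n - fp / n * odds[i]
    treat_all = prev - (1.0 - prev) * odds
    return DecisionCurve(thresholds=thresholds, net_benefit=nb,
                         treat_all=treat_all)


# ---------------------------------------------------------------------------
# Confusion metrics


@dataclass(frozen=True)
class ConfusionReport:
    matrix: pd.DataFrame      # rows = truth, columns = predicted
    accuracy: float
    f1: float
    f1_average: str = "weighted"

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.to_dict(), "accuracy": self.accuracy,
                "f1": self.f1, "f1_average": self.f1_average}


def confusion_metrics(predicted, labels, average: str = "weighted"
                      ) -> ConfusionReport:
    """K x K confusion matrix with accuracy and (weighted by default) F1."""
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    unseen = sorted(set(predicted.tolist()) - set(classes))
    all_classes = classes + unseen
    mat = pd.DataFrame(0, index=classes, columns=all_classes)
    for t, p in zip(labels, predicted):
        mat.loc[t, p] += 1
    acc = float(np.trace(mat.loc[classes, classes].to_numpy()) / labels.size)
    f1 = float(f1_score(labels, predicted, average=average, zero_division=0))
    return ConfusionReport(matrix=mat, accuracy=acc, f1=f1, f1_average=average)


# ---------------------------------------------------------------------------
# Cross-validation


def crossvalidate(model_factory, X, y, k: int = 10, seed: int = 0,
                  metric: str = "auc") -> pd.DataFrame:
    """Stratified k-fold metrics for a model factory.

    ``model_factory()`` must return an unfitted estimator with fit /
    predict_proba (binary AUC) or fit / predict (accuracy).  Returns the
    per-fold table; summarize with mean/std.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if k == len(y):  # leave-one-out boundary: stratification is vacuous
        from sklearn.model_selection import KFold
        skf = KFold(n_splits=k)
    elif k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count "
                         f"({counts.min()}); use a smaller k")
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        est = model_factory()
        est.fit(X[tr], y[tr])
        if metric == "auc":
            p = est.predict_proba(X[te])[:, 1]
            val = auc_delong(p, y[te]).auc
        elif metric == "accuracy":
            val = float((est.predict(X[te]) == y[te]).mean())
        else:
            raise ValueError(f"unknown metric {metric!r}")
        rows.append({"fold": fold, metric: val, "n_test": len(te)})
    return pd.DataFrame(rows)
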