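"""Three-stage feature-selection cascade.

1.  ICC reproducibility filter: a feature survives only if both the
    inter-reader ICC (reader 1 session 1 vs reader 2) and the intra-reader
    ICC (reader 1 session 1 vs session 2) exceed 0.75, computed on the
    re-segmented subset.  ICC form is ICC(2,1): two-way random effects,
    absolute agreement, single measurement.
2.  Max-abs normalization: each column is divided by its training-cohort
    maximum absolute value, so training values lie in [-1, 1]; test values
    reuse the frozen scales and may exceed that interval.
3.  Univariate top-20% ANOVA-F screen (K = floor(0.2 * m); 1,089 candidates
    keep 217), then an embedded L1-penalized linear SVM (squared hinge):
    features with any nonzero coefficient are retained, majority-voted
    across refit seeds for stability.

The retained sets are strictly nested across stages and recorded in a
SelectionTrace.  All statistics except ICC are computed on training rows
only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

ICC_THRESHOLD = 0.75
F_FRACTION = 0.20


@dataclass
class SelectionTrace:
    """Per-stage record of the cascade: retained names and statistics."""

    stages: list[str] = field(default_factory=list)
    retained: dict[str, list[str]] = field(default_factory=dict)
    stats: dict[str, pd.DataFrame] = field(default_factory=dict)

    def record(self, stage: str, names: list[str],
               stats: pd.DataFrame | None = None) -> None:
        if self.stages:
            prev = set(self.retained[self.stages[-1]])
            if not set(names) <= prev:
                raise ValueError(f"stage {stage!r} retained features not "
                                 "nested within the previous stage")
        self.stages.append(stage)
        self.retained[stage] = list(names)
        if stats is not None:
            self.stats[stage] = stats

    def counts(self) -> dict[str, int]:
        return {s: len(self.retained[s]) for s in self.stages}

    def retained_percentage(self, n_input: int, stage: str) -> float:
        return round(100.0 * len(self.retained[stage]) / n_input, 1)

    def to_dict(self) -> dict:
        return {"stages": self.stages,
                "retained": {s: self.retained[s] for s in self.stages},
                "counts": self.counts()}


def compute_icc(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is cases x raters (>= 3 cases, 2+ raters), evaluated from
    the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    r = np.asarray(ratings, dtype=np.float64)
    if r.ndim != 2 or r.shape[0] < 3 or r.shape[1] < 2:
        raise ValueError("need >= 3 cases and >= 2 ratings per case")
    n, k = r.shape
    grand = r.mean()
    row_m = r.mean(axis=1)
    col_m = r.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sse = ((r - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-15 or msr < 1e-15 and mse < 1e-15:
        warnings.warn("zero between-subject variance: ICC set to 0", stacklevel=2)
        return 0.0
    return float((msr - mse) / denom)


def reproducibility_filter(f_r1s1: pd.DataFrame, f_r1s2: pd.DataFrame,
                           f_r2: pd.DataFrame,
                           threshold: float = ICC_THRESHOLD
                           ) -> tuple[list[str], pd.DataFrame]:
    """Features with inter- and intra-reader ICC above the threshold.

    The three matrices are the re-segmented subset's feature tables
    (reader 1 session 1/2, reader 2), sharing index and columns.  The same
    retained set is applied to intratumoral and peritumoral matrices
    downstream.
    """
    for other in (f_r1s2, f_r2):
        if list(other.columns) != list(f_r1s1.columns):
            raise ValueError("feature matrices have mismatched columns")
        if len(other) != len(f_r1s1):
            raise ValueError("feature matrices have mismatched cases")
    rows = []
    retained = []
    for col in f_r1s1.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inter = compute_icc(np.column_stack([f_r1s1[col], f_r2[col]]))
            intra = compute_icc(np.column_stack([f_r1s1[col], f_r1s2[col]]))
        rows.append({"feature": col, "icc_inter": inter, "icc_intra": intra})
        if inter > threshold and intra > threshold:
            retained.append(col)
    return retained, pd.DataFrame(rows).set_index("feature")


@dataclass(frozen=True)
class MaxAbsScales:
    scales: pd.Series

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.scales.index] / self.scales


def maxabs_fit(train: pd.DataFrame) -> MaxAbsScales:
    """Frozen per-column max-abs scales from the training cohort.

    All-zero columns carry no information at any scale; they are dropped
    with a warning.
    """
    scales = train.abs().max(axis=0)
    zero = scales[scales == 0].index.tolist()
    if zero:
        warnings.warn(f"dropping {len(zero)} all-zero columns before "
                      "max-abs normalization", stacklevel=2)
        logger.warning("all-zero columns dropped: %s", zero[:10])
        scales = scales[scales > 0]
    return MaxAbsScales(scales=scales)


def maxabs_normalize(train: pd.DataFrame, apply_to: pd.DataFrame | None = None
                     ) -> tuple[pd.DataFrame, MaxAbsScales]:
    """Normalize ``apply_to`` (default: the training matrix itself) by
    training max-abs scales."""
    scaler = maxabs_fit(train)
    target = train if apply_to is None else apply_to
    return scaler.apply(target), scaler


def anova_f_select(X: pd.DataFrame, y: np.ndarray,
                   fraction: float = F_FRACTION
                   ) -> tuple[list[str], pd.Series]:
    """Keep the floor(fraction * m) features with largest one-way ANOVA F.

    Ties break by column order; 1,089 candidates at fraction 0.20 keep 217.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError(f"class {classes[counts.argmin()]!r} has fewer than 2 cases")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_vals, _ = f_classif(X.to_numpy(), y)
    f_vals = np.nan_to_num(f_vals, nan=0.0)
    k = int(np.floor(fraction * X.shape[1]))
    k = max(k, 1)
    # stable sort descending; ties keep original column order
    order = np.argsort(-f_vals, kind="stable")[:k]
    keep = sorted(order.tolist())
    names = [X.columns[i] for i in keep]
    return names, pd.Series(f_vals, index=X.columns, name="F")


def l1svm_select(X: pd.DataFrame, y: np.ndarray, C: float = 1.0,
                 n_seeds: int = 10, tol: float = 1e-4,
                 max_iter: int = 5000) -> tuple[list[str], pd.Series]:
    """Embedded selection by an L1-penalized linear SVM (squared hinge).

    The model is refit across ``n_seeds`` seeds and a feature is retained
    if it carries a nonzero coefficient in the majority of refits (ternary
    labels: one-vs-rest, any class counts).  Returns the retained names and
    the mean absolute coefficient per feature.
    """
    y = np.asarray(y)
    votes = np.zeros(X.shape[1])
    coef_acc = np.zeros(X.shape[1])
    for s in range(n_seeds):
        clf = LinearSVC(penalty="l1", loss="squared_hinge", dual=False, C=C,
                        tol=tol, max_iter=max_iter, random_state=s,
                        class_weight="balanced")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X.to_numpy(), y)
        coefs = np.abs(np.atleast_2d(clf.coef_)).max(axis=0)
        votes += coefs > 1e-10
        coef_acc += coefs
    mask = votes > n_seeds / 2.0
    if not mask.any():
        raise ValueError(
            f"L1-SVM at C={C} zeroed every feature; increase C")
    names = [c for c, m in zip(X.columns, mask) if m]
    logger.info("L1-SVM retained %d/%d features (C=%g, tol=%g)",
                len(names), X.shape[1], C, tol)
    return names, pd.Series(coef_acc / n_seeds, index=X.columns, name="mean_abs_coef")


def run_selection_cascade(train: pd.DataFrame, y: np.ndarray,
                          icc_retained: list[str] | None = None,
                          fraction: float = F_FRACTION, C: float = 1.0,
                          n_seeds: int = 10) -> tuple[list[str], SelectionTrace,
                                                      MaxAbsScales]:
    """ICC filter (precomputed names) -> max-abs -> F top-20% -> L1-SVM."""
    trace = SelectionTrace()
    cols = [c for c in train.columns if icc_retained is None or c in set(icc_retained)]
    trace.record("icc", cols)
    Xn, scaler = maxabs_normalize(train[cols])
    trace.record("maxabs", list(Xn.columns))
    f_names, f_stats = anova_f_select(Xn, y, fraction)
    trace.record("f-top20", f_names, f_stats.to_frame())
    l1_names, l1_stats = l1svm_select(Xn[f_names], y, C=C, n_seeds=n_seeds)
    trace.record("l1svm", l1_names, l1_stats.to_frame())
    return l1_names, trace, scaler
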