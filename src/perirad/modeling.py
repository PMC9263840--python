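"""Subtype classification models and the statsmodels-style fitting surface.

Five model families per task:

* IRM   — SVM on selected intratumoral radiomics features
* PRM   — SVM on one peritumoral ring's selected features; the optimal ring
          is chosen by AUC (binary tasks) or accuracy (ternary)
* CIPRM — logistic model on the intratumoral + optimal peritumoral Rad-scores
* CM    — logistic model on the screened clinical-radiological predictors
* CCRM  — logistic model on both Rad-scores and the clinical predictors

The Rad-score is the SVM's calibrated positive-class probability (per-class
probability vector for the ternary task).  Tasks: 1 HR-positive vs others,
2 HER2-enriched vs others, 3 TNBC vs others, 4 three-way.

``SubtypeClassificationModel`` bundles the data and configuration;
``fit()`` runs selection and fitting on the training cohort only and
returns a ``SubtypeClassificationResults`` carrying the fitted families,
ring choice, evaluation metrics and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .evaluation import RocResult, auc_delong, confusion_metrics
from .selection import SelectionTrace, run_selection_cascade

logger = logging.getLogger(__name__)

SUBTYPES = ("HR-positive", "HER2-enriched", "TNBC")
MODEL_KINDS = ("IRM", "PRM", "CIPRM", "CM", "CCRM")


@dataclass(frozen=True)
class TaskSpec:
    """One classification task; id 4 is the ternary task."""

    id: int

    def __post_init__(self):
        if self.id not in (1, 2, 3, 4):
            raise ValueError(f"task id must be 1..4, got {self.id}")

    @property
    def is_ternary(self) -> bool:
        return self.id == 4

    @property
    def positive_class(self) -> str | None:
        return {1: "HR-positive", 2: "HER2-enriched", 3: "TNBC"}.get(self.id)

    def encode(self, subtype_labels) -> np.ndarray:
        labels = np.asarray(subtype_labels)
        if self.is_ternary:
            return labels
        return (labels == self.positive_class).astype(int)


# ---------------------------------------------------------------------------
# Cohort splitting


def split_cohort(table: pd.DataFrame, ratio: float = 0.7, seed: int = 0,
                 stratify_column: str = "subtype"
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified training/internal-test split with floor(ratio * n) training rows.

    Per-stratum sizes are floored, then the remainder is distributed by
    largest fractional part so the training total is exactly floor(ratio*n)
    (327 cases at 7:3 give 228/99).
    """
    if len(table) < 10:
        raise ValueError("need at least 10 cases to split")
    n_train = int(np.floor(ratio * len(table)))
    rng = np.random.default_rng(seed)
    groups = list(table.groupby(stratify_column, sort=True))
    quotas = {}
    fracs = []
    for name, g in groups:
        exact = ratio * len(g)
        quotas[name] = int(np.floor(exact))
        fracs.append((exact - np.floor(exact), name))
    short = n_train - sum(quotas.values())
    for _, name in sorted(fracs, reverse=True)[:short]:
        quotas[name] += 1
    train_idx = []
    for name, g in groups:
        if quotas[name] == 0 or quotas[name] == len(g):
            raise ValueError(f"stratum {name!r} would leave an empty split")
        picked = rng.choice(len(g), size=quotas[name], replace=False)
        train_idx.extend(g.index[picked].tolist())
    train = table.loc[sorted(train_idx)]
    test = table.drop(index=train_idx).sort_index()
    return train, test


# ---------------------------------------------------------------------------
# Clinical screening


NUMERIC_COVARIATES = ("age", "tumor_size")
CATEGORICAL_ORDER = {
    "bpe": ["minimal", "mild", "moderate", "marked"],
    "fgt": ["dense", "non-dense"],
    "margin": ["clear", "blurry"],
    "aln_short_diameter": ["<=5mm", ">5mm"],
    "firmness": ["soft", "hard"],
    "mobility": ["pushable", "non-pushable"],
    "menopause": ["pre", "post"],
}


def _design_column(series: pd.Series, name: str) -> pd.Series:
    if name in NUMERIC_COVARIATES:
        return series.astype(float)
    order = CATEGORICAL_ORDER[name]
    codes = series.map({c: i for i, c in enumerate(order)})
    if codes.isna().any():
        raise ValueError(f"unknown category in covariate {name!r}")
    return codes.astype(float)


@dataclass
class ClinicalScreenResult:
    """Univariate p-values plus multivariate ORs of the surviving predictors."""

    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    predictors: list[str]
    ridge_fallback: bool = False


def screen_clinical_predictors(clinical: pd.DataFrame, task: TaskSpec,
                               alpha: float = 0.05) -> ClinicalScreenResult:
    """Univariate screen then multivariate logistic (multinomial for task 4).

    Numeric covariates use a two-sample t-test (binary) or one-way ANOVA
    (ternary); categorical ones a chi-square test.  Survivors enter the
    multivariate model; those significant there are the independent
    predictors, reported with odds ratios and 95% CIs.
    """
    y = task.encode(clinical["subtype"].to_numpy())
    covs = list(NUMERIC_COVARIATES) + list(CATEGORICAL_ORDER)
    uni_rows = []
    survivors = []
    for cov in covs:
        col = clinical[cov]
        if cov in NUMERIC_COVARIATES:
            groups = [col[y == lv].astype(float) for lv in np.unique(y)]
            stat, p = stats.f_oneway(*groups) if len(groups) > 2 \
                else stats.ttest_ind(*groups)
        else:
            ct = pd.crosstab(col, y)
            if ct.shape[0] < 2:
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = stats.chi2_contingency(ct)
        uni_rows.append({"covariate": cov, "stat": float(stat), "p": float(p)})
        if p < alpha:
            survivors.append(cov)
    uni = pd.DataFrame(uni_rows).set_index("covariate")
    if not survivors:
        return ClinicalScreenResult(univariate=uni,
                                    multivariate=pd.DataFrame(),
                                    predictors=[])
    X = pd.DataFrame({c: _design_column(clinical[c], c) for c in survivors})
    mv, ridge = _multivariate_logistic(X, y, task.is_ternary)
    # the ridge fallback yields no Wald p-values; keep the univariate
    # survivors as the predictor set in that case
    predictors = survivors if ridge or "p" not in mv \
        else mv.index[mv["p"] < alpha].tolist()
    return ClinicalScreenResult(univariate=uni, multivariate=mv,
                                predictors=predictors, ridge_fallback=ridge)


def _multivariate_logistic(X: pd.DataFrame, y: np.ndarray, ternary: bool
                           ) -> tuple[pd.DataFrame, bool]:
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MNLogit(pd.Categorical(y).codes, Xc) if ternary \
                else sm.Logit(y, Xc)
            fit = model.fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("logistic fit did not converge")
        params = np.atleast_2d(fit.params.T if ternary else fit.params)
        ses = np.atleast_2d(fit.bse.T if ternary else fit.bse)
        pvals = np.atleast_2d(fit.pvalues.T if ternary else fit.pvalues)
        if not (np.isfinite(params).all() and np.isfinite(ses).all()
                and np.isfinite(pvals).all()):
            raise RuntimeError("degenerate covariance (quasi-separation)")
        rows = []
        for j, name in enumerate(Xc.columns):
            if name == "const":
                continue
            b = float(np.abs(params[:, j]).max())
            k = int(np.abs(params[:, j]).argmax())
            se = float(ses[k, j])
            rows.append({"covariate": name, "beta": float(params[k, j]),
                         "or": float(np.exp(params[k, j])),
                         "or_ci_low": float(np.exp(params[k, j] - 1.96 * se)),
                         "or_ci_high": float(np.exp(params[k, j] + 1.96 * se)),
                         "p": float(pvals[:, j].min())})
        return pd.DataFrame(rows).set_index("covariate"), False
    except Exception as exc:
        logger.warning("multivariate logistic failed (%s); weak-ridge fallback",
                       exc)
        lr = LogisticRegression(C=10.0, max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lr.fit(X.to_numpy(), y)
        coefs = np.abs(np.atleast_2d(lr.coef_)).max(axis=0)
        signed = np.atleast_2d(lr.coef_)[np.abs(np.atleast_2d(lr.coef_)).max(axis=1).argmax()]
        rows = [{"covariate": c, "beta": float(signed[j]),
                 "or": float(np.exp(signed[j])), "or_ci_low": np.nan,
                 "or_ci_high": np.nan, "p": np.nan}
                for j, c in enumerate(X.columns)]
        return pd.DataFrame(rows).set_index("covariate"), True


# ---------------------------------------------------------------------------
# Radiomics SVM models


@dataclass
class FittedModel:
    """A fitted family member with its Rad-score contract.

    ``rad_score`` maps a feature frame (columns = ``feature_names``) to the
    calibrated positive-class probability (binary) or the class-probability
    matrix (ternary); all scores lie in [0, 1].
    """

    kind: str
    task: TaskSpec
    feature_names: list[str]
    estimator: object
    ring_distance: float | None = None
    trace: SelectionTrace | None = None
    scaler: object = None

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        needs_ring = self.kind in ("PRM",)
        if needs_ring and self.ring_distance is None:
            raise ValueError(f"{self.kind} requires a ring distance")

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        Xs = X[self.feature_names]
        if self.scaler is not None:
            Xs = self.scaler.apply(X)[self.feature_names]
        return np.asarray(Xs, dtype=float)

    def rad_score(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.estimator.predict_proba(self._design(X))
        if self.task.is_ternary:
            return proba
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._design(X))


def fit_task_model(X: pd.DataFrame, y: np.ndarray, task: TaskSpec,
                   kind: str, ring_distance: float | None = None,
                   kernel: str = "rbf", C: float = 1.0, seed: int = 0,
                   trace: SelectionTrace | None = None,
                   scaler=None) -> FittedModel:
    """SVM with probability calibration on the training rows only.

    Class weights are inverse to class frequency; the kernel width uses the
    inverse-variance ``gamma='scale'`` convention.  Ternary labels are
    handled one-vs-rest inside the probability calibration.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    est = SVC(kernel=kernel, C=C, gamma="scale", probability=True,
              class_weight="balanced", random_state=seed)
    est.fit(np.asarray(X, dtype=float), y)
    return FittedModel(kind=kind, task=task, feature_names=list(X.columns),
                       estimator=est, ring_distance=ring_distance,
                       trace=trace, scaler=scaler)


def select_optimal_ring(candidate_metrics: dict[float, float],
                        task: TaskSpec) -> float:
    """Ring with the best validation metric (AUC binary, accuracy ternary);
    ties resolve to the smallest distance."""
    if len(candidate_metrics) < 2:
        raise ValueError("need at least two candidate rings")
    best = max(candidate_metrics.values())
    return min(d for d, v in candidate_metrics.items() if v == best)


# ---------------------------------------------------------------------------
# Combined logistic models


@dataclass
class CombinedModel:
    """Logistic (multinomial for the ternary task) on Rad-scores and/or
    clinical predictors, with coefficients exposed for the nomogram."""

    kind: str
    task: TaskSpec
    feature_names: list[str]
    intercept: np.ndarray            # (n_classes-1,) or (1,)
    coef: np.ndarray                 # (n_classes-1, p) or (1, p)
    classes: list
    dropped_collinear: list[str] = field(default_factory=list)
    ridge_fallback: bool = False
    train_prevalence: float | np.ndarray = 0.5

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Z = np.asarray(X[self.feature_names], dtype=float) if self.feature_names \
            else np.zeros((len(X), 0))
        return self.intercept[None, :] + Z @ self.coef.T

    def rad_score(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(X)
        if self.task.is_ternary:
            full = np.hstack([np.zeros((len(eta), 1)), eta])
            e = np.exp(full - full.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)
        return 1.0 / (1.0 + np.exp(-eta[:, 0]))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = self.rad_score(X)
        if self.task.is_ternary:
            return np.asarray(self.classes)[p.argmax(axis=1)]
        return (p >= 0.5).astype(int)


def _drop_collinear(X: pd.DataFrame, tol: float = 0.999) -> tuple[pd.DataFrame, list[str]]:
    dropped = []
    keep: list[str] = []
    for c in X.columns:
        col = X[c].to_numpy(dtype=float)
        if np.std(col) == 0:
            dropped.append(c)
            continue
        redundant = False
        for k in keep:
            r = np.corrcoef(col, X[k].to_numpy(dtype=float))[0, 1]
            if abs(r) > tol:
                redundant = True
                break
        (dropped if redundant else keep).append(c)
    if dropped:
        logger.warning("collinearity guard dropped predictors: %s", dropped)
    return X[keep], dropped


def fit_combined(inputs: pd.DataFrame, y: np.ndarray, task: TaskSpec,
                 kind: str) -> CombinedModel:
    """Fit CIPRM (two Rad-scores), CM (clinical only) or CCRM (both).

    Collinear or constant inputs are dropped with a log entry; perfect
    separation falls back to a weak ridge fit, flagged on the result.  An
    empty predictor set degenerates to an intercept-only model predicting
    the training prevalence.
    """
    if kind not in ("CIPRM", "CM", "CCRM"):
        raise ValueError(f"fit_combined handles CIPRM/CM/CCRM, got {kind!r}")
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    X, dropped = _drop_collinear(inputs)
    prevalence = (np.array([(y == c).mean() for c in classes])
                  if task.is_ternary else float((y == 1).mean()))
    if X.shape[1] == 0:
        if task.is_ternary:
            p = np.asarray(prevalence)
            intercept = np.log(p[1:] / p[0])
        else:
            pv = float(prevalence)
            intercept = np.array([np.log(pv / (1 - pv))])
        return CombinedModel(kind=kind, task=task, feature_names=[],
                             intercept=intercept,
                             coef=np.zeros((intercept.size, 0)),
                             classes=classes, dropped_collinear=dropped,
                             train_prevalence=prevalence)
    ridge = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xc = sm.add_constant(X.astype(float), has_constant="add")
            if task.is_ternary:
                codes = np.searchsorted(classes, y)
                fit = sm.MNLogit(codes, Xc).fit(disp=0, maxiter=300)
                params = fit.params.to_numpy()  # (p+1, K-1)
                intercept = params[0, :]
                coef = params[1:, :].T
            else:
                fit = sm.Logit(y, Xc).fit(disp=0, maxiter=300)
                intercept = np.array([fit.params["const"]])
                coef = fit.params.drop("const").to_numpy()[None, :]
        if not np.all(np.isfinite(intercept)) or not np.all(np.isfinite(coef)) \
                or np.abs(coef).max() > 50:
            raise RuntimeError("separation suspected (diverging coefficients)")
    except Exception as exc:
        logger.warning("%s logistic failed (%s); weak-ridge fallback", kind, exc)
        ridge = True
        lr = LogisticRegression(C=10.0, max_iter=5000)
        lr.fit(X.to_numpy(dtype=float), y)
        if task.is_ternary:
            # convert softmax parameters to baseline-reference form
            intercept = lr.intercept_[1:] - lr.intercept_[0]
            coef = lr.coef_[1:, :] - lr.coef_[0:1, :]
        else:
            intercept = lr.intercept_.copy()
            coef = lr.coef_.copy()
    return CombinedModel(kind=kind, task=task, feature_names=list(X.columns),
                         intercept=np.asarray(intercept, dtype=float),
                         coef=np.asarray(coef, dtype=float), classes=classes,
                         dropped_collinear=dropped, ridge_fallback=ridge,
                         train_prevalence=prevalence)


# ---------------------------------------------------------------------------
# Nomogram


@dataclass(frozen=True)
class NomogramSpec:
    """Points-based rendering of a binary logistic model.

    Each predictor maps its value to 0..100 points; the predictor with the
    largest |beta| x observed range spans exactly 0-100.  Total points map
    back to probability through the reconstructed linear predictor, so the
    round trip reproduces the model probability exactly.
    """

    predictors: list[str]
    betas: dict[str, float]
    refs: dict[str, float]          # value contributing 0 points
    scale: float                    # |beta| * range of the dominant predictor
    intercept_eff: float            # model intercept + sum(beta * ref)

    def points(self, row: dict[str, float]) -> dict[str, float]:
        out = {}
        for name in self.predictors:
            b = self.betas[name]
            out[name] = 100.0 * abs(b) * (row[name] - self.refs[name]) \
                * (1 if b > 0 else -1) / self.scale
        return out

    def total_points(self, row: dict[str, float]) -> float:
        return float(sum(self.points(row).values()))

    def probability(self, total_points: float) -> float:
        eta = self.intercept_eff + self.scale * total_points / 100.0
        return float(1.0 / (1.0 + np.exp(-eta)))


def build_nomogram(model: CombinedModel, train_inputs: pd.DataFrame) -> NomogramSpec:
    """Nomogram of a fitted binary logistic combined model.

    Reference values are the observed minimum (positive coefficient) or
    maximum (negative), so per-predictor points are non-negative.
    """
    if model.task.is_ternary:
        raise ValueError("nomograms are defined for binary tasks only")
    betas = {n: float(b) for n, b in zip(model.feature_names, model.coef[0])}
    if not betas or all(b == 0 for b in betas.values()):
        raise ValueError("cannot build a nomogram from a zero-coefficient model")
    refs, scales = {}, {}
    for name, b in betas.items():
        lo = float(train_inputs[name].min())
        hi = float(train_inputs[name].max())
        refs[name] = lo if b > 0 else hi
        scales[name] = abs(b) * (hi - lo)
    scale = max(scales.values())
    intercept_eff = float(model.intercept[0]
                          + sum(betas[n] * refs[n] for n in betas))
    return NomogramSpec(predictors=list(betas), betas=betas, refs=refs,
                        scale=scale, intercept_eff=intercept_eff)
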