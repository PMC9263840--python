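"""The fitting surface: one model object per task, statsmodels-style.

``SubtypeClassificationModel`` takes the intratumoral feature matrix, the
per-ring peritumoral matrices, the clinical table, the subtype labels and
cohort tags; ``fit()`` runs the per-task selection cascade and fits the
five families (IRM, PRM per ring with optimal-ring choice, CIPRM, CM,
CCRM) on training rows only, returning a ``SubtypeClassificationResults``
with per-cohort evaluation and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (ConfusionReport, RocResult, auc_delong,
                         confusion_metrics)
from .modeling import (CombinedModel, FittedModel, NomogramSpec, TaskSpec,
                       build_nomogram, fit_combined, fit_task_model,
                       screen_clinical_predictors, select_optimal_ring)
from .selection import run_selection_cascade

logger = logging.getLogger(__name__)

COHORT_TAGS = ("training", "internal-test", "external-test")


@dataclass(frozen=True)
class ModelConfig:
    """Classifier and selection settings shared by the five families."""

    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    l1_C: float = 1.0
    l1_seeds: int = 10
    f_fraction: float = 0.20
    ring_cv_folds: int = 5
    clinical_alpha: float = 0.05


class SubtypeClassificationModel:
    """Five-family subtype classifier for one task.

    Parameters
    ----------
    intratumoral, rings
        Cases x features matrices (index = case id); ``rings`` maps ring
        distance (mm) to the matrix of that ring's features.
    clinical
        Per-case clinical covariates including a ``subtype`` column.
    cohort
        Per-case tag from {training, internal-test, external-test}; all
        fitting statistics use training rows only.
    icc_retained
        Feature names surviving the reproducibility filter (applied to
        intratumoral and ring matrices alike), or None to skip the stage.
    """

    def __init__(self, intratumoral: pd.DataFrame, rings: dict[float, pd.DataFrame],
                 clinical: pd.DataFrame, cohort: pd.Series, task: TaskSpec,
                 icc_retained: list[str] | None = None,
                 config: ModelConfig = ModelConfig()):
        idx = intratumoral.index
        for d, m in rings.items():
            if not m.index.equals(idx):
                raise ValueError(f"ring {d} mm matrix index mismatch")
        if not clinical.index.equals(idx) or not cohort.index.equals(idx):
            raise ValueError("clinical/cohort index mismatch")
        bad = set(cohort.unique()) - set(COHORT_TAGS)
        if bad:
            raise ValueError(f"unknown cohort tags {bad}")
        self.intratumoral = intratumoral
        self.rings = dict(sorted(rings.items()))
        self.clinical = clinical
        self.cohort = cohort
        self.task = task
        self.icc_retained = icc_retained
        self.config = config
        self.y = pd.Series(task.encode(clinical["subtype"].to_numpy()), index=idx)

    # -- helpers ----------------------------------------------------------
    @property
    def train_mask(self) -> pd.Series:
        return self.cohort == "training"

    def _fit_radiomics(self, X: pd.DataFrame, kind: str, seed: int,
                       ring: float | None = None):
        tr = self.train_mask
        selected, trace, scaler = run_selection_cascade(
            X.loc[tr], self.y.loc[tr].to_numpy(),
            icc_retained=self.icc_retained,
            fraction=self.config.f_fraction, C=self.config.l1_C,
            n_seeds=self.config.l1_seeds)
        Xn = scaler.apply(X)[selected]
        model = fit_task_model(Xn.loc[tr], self.y.loc[tr].to_numpy(),
                               self.task, kind, ring_distance=ring,
                               kernel=self.config.svm_kernel,
                               C=self.config.svm_C, seed=seed, trace=trace)
        model.scaler = scaler
        scores = self._scores_all(model, X)
        return model, scores

    def _scores_all(self, model: FittedModel, X: pd.DataFrame):
        sel = model.feature_names
        Xn = model.scaler.apply(X)[sel] if model.scaler is not None else X[sel]
        proba = model.estimator.predict_proba(np.asarray(Xn, dtype=float))
        if self.task.is_ternary:
            return pd.DataFrame(proba, index=X.index,
                                columns=[str(c) for c in model.estimator.classes_])
        pos = list(model.estimator.classes_).index(1)
        return pd.Series(proba[:, pos], index=X.index)

    def _ring_metric(self, model: FittedModel, X: pd.DataFrame,
                     scores, seed: int) -> float:
        """Training cross-validated AUC (binary) or accuracy (ternary) for
        ring selection; falls back to the apparent training metric when the
        smallest class cannot support the fold count."""
        tr = self.train_mask
        y_tr = self.y.loc[tr].to_numpy()
        k = self.config.ring_cv_folds
        _, counts = np.unique(y_tr, return_counts=True)
        sel = model.feature_names
        Xn = model.scaler.apply(X)[sel].loc[tr].to_numpy(dtype=float)
        if counts.min() >= k:
            from sklearn.model_selection import StratifiedKFold
            from sklearn.svm import SVC
            aucs = []
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            for tr_i, te_i in skf.split(Xn, y_tr):
                est = SVC(kernel=self.config.svm_kernel, C=self.config.svm_C,
                          gamma="scale", probability=True,
                          class_weight="balanced", random_state=seed)
                est.fit(Xn[tr_i], y_tr[tr_i])
                if self.task.is_ternary:
                    aucs.append(float((est.predict(Xn[te_i]) == y_tr[te_i]).mean()))
                else:
                    pos = list(est.classes_).index(1)
                    p = est.predict_proba(Xn[te_i])[:, pos]
                    if np.unique(y_tr[te_i]).size < 2:
                        continue
                    aucs.append(auc_delong(p, y_tr[te_i]).auc)
            if aucs:
                return float(np.mean(aucs))
        logger.info("ring selection falls back to apparent training metric")
        if self.task.is_ternary:
            return float((model.predict(X.loc[tr]) == y_tr).mean())
        return auc_delong(np.asarray(scores.loc[tr]), y_tr).auc

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int = 0) -> "SubtypeClassificationResults":
        tr = self.train_mask
        y_tr = self.y.loc[tr].to_numpy()

        irm, irm_scores = self._fit_radiomics(self.intratumoral, "IRM", seed)
        prm_candidates: dict[float, FittedModel] = {}
        prm_scores_all: dict[float, object] = {}
        ring_metrics: dict[float, float] = {}
        for d, X in self.rings.items():
            m, s = self._fit_radiomics(X, "PRM", seed, ring=d)
            prm_candidates[d] = m
            prm_scores_all[d] = s
            ring_metrics[d] = self._ring_metric(m, X, s, seed)
        optimal_ring = select_optimal_ring(ring_metrics, self.task)
        prm = prm_candidates[optimal_ring]
        prm_scores = prm_scores_all[optimal_ring]

        rad_inputs = self._rad_input_frame(irm_scores, prm_scores)
        screen = screen_clinical_predictors(
            self.clinical.loc[tr], self.task, alpha=self.config.clinical_alpha)
        clin_inputs = self._clinical_design(screen.predictors)

        ciprm = fit_combined(rad_inputs.loc[tr], y_tr, self.task, "CIPRM")
        cm = fit_combined(clin_inputs.loc[tr], y_tr, self.task, "CM")
        ccrm_inputs = pd.concat([rad_inputs, clin_inputs], axis=1)
        ccrm = fit_combined(ccrm_inputs.loc[tr], y_tr, self.task, "CCRM")

        nomogram = None
        if not self.task.is_ternary:
            try:
                nomogram = build_nomogram(ccrm, ccrm_inputs.loc[tr])
            except ValueError as exc:
                logger.warning("no nomogram: %s", exc)

        res = SubtypeClassificationResults(
            model=self, seed=seed, irm=irm, prm=prm,
            prm_candidates=prm_candidates, ring_metrics=ring_metrics,
            optimal_ring=optimal_ring, ciprm=ciprm, cm=cm, ccrm=ccrm,
            clinical_screen=screen, nomogram=nomogram,
            scores={"IRM": irm_scores, "PRM": prm_scores,
                    "CIPRM": self._combined_scores(ciprm, rad_inputs),
                    "CM": self._combined_scores(cm, clin_inputs),
                    "CCRM": self._combined_scores(ccrm, ccrm_inputs)})
        res._evaluate()
        return res

    def _rad_input_frame(self, irm_scores, prm_scores) -> pd.DataFrame:
        if self.task.is_ternary:
            cols = {}
            for cls in irm_scores.columns:
                cols[f"radscore_intra_{cls}"] = irm_scores[cls]
            for cls in prm_scores.columns:
                cols[f"radscore_peri_{cls}"] = prm_scores[cls]
            return pd.DataFrame(cols)
        return pd.DataFrame({"radscore_intra": irm_scores,
                             "radscore_peri": prm_scores})

    def _clinical_design(self, predictors: list[str]) -> pd.DataFrame:
        from .modeling import _design_column
        return pd.DataFrame({p: _design_column(self.clinical[p], p)
                             for p in predictors},
                            index=self.clinical.index)

    def _combined_scores(self, model: CombinedModel, inputs: pd.DataFrame):
        p = model.rad_score(inputs)
        if self.task.is_ternary:
            return pd.DataFrame(p, index=inputs.index,
                                columns=[str(c) for c in model.classes])
        return pd.Series(p, index=inputs.index)


@dataclass
class SubtypeClassificationResults:
    """Fitted families, ring choice, per-cohort evaluation, and summaries."""

    model: SubtypeClassificationModel
    seed: int
    irm: FittedModel
    prm: FittedModel
    prm_candidates: dict[float, FittedModel]
    ring_metrics: dict[float, float]
    optimal_ring: float
    ciprm: CombinedModel
    cm: CombinedModel
    ccrm: CombinedModel
    clinical_screen: object
    nomogram: NomogramSpec | None
    scores: dict[str, object]
    evaluation: dict[str, dict[str, object]] = field(default_factory=dict)

    def _evaluate(self) -> None:
        m = self.model
        thresholds: dict[str, float] = {}
        for kind, sc in self.scores.items():
            self.evaluation[kind] = {}
            for tag in COHORT_TAGS:
                rows = m.cohort == tag
                if rows.sum() == 0:
                    continue
                y = m.y.loc[rows].to_numpy()
                if m.task.is_ternary:
                    probs = sc.loc[rows].to_numpy()
                    classes = list(sc.columns)
                    pred = np.asarray(classes)[probs.argmax(axis=1)]
                    self.evaluation[kind][tag] = confusion_metrics(pred, y)
                else:
                    s = sc.loc[rows].to_numpy()
                    if np.unique(y).size < 2:
                        continue
                    if tag == "training":
                        r = auc_delong(s, y, cohort=tag)
                        thresholds[kind] = r.threshold
                    else:
                        r = auc_delong(s, y, cohort=tag,
                                       threshold=thresholds.get(kind))
                    self.evaluation[kind][tag] = r

    # -- reporting --------------------------------------------------------
    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for kind, per_tag in self.evaluation.items():
            for tag, r in per_tag.items():
                if isinstance(r, RocResult):
                    rows.append({"model": kind, "cohort": tag, "auc": r.auc,
                                 "ci_low": r.ci_low, "ci_high": r.ci_high,
                                 "sensitivity": r.sensitivity,
                                 "specificity": r.specificity})
                else:
                    rows.append({"model": kind, "cohort": tag,
                                 "accuracy": r.accuracy, "f1": r.f1})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [f"Subtype classification task {m.task.id}"
                 + ("" if m.task.is_ternary
                    else f" ({m.task.positive_class} vs others)"),
                 f"seed: {self.seed}",
                 f"optimal peritumoral ring: {self.optimal_ring:g} mm "
                 f"(candidates: "
                 + ", ".join(f"{d:g} mm={v:.3f}" for d, v in
                             sorted(self.ring_metrics.items())) + ")",
                 f"clinical predictors: "
                 + (", ".join(self.clinical_screen.predictors) or "(none)"),
                 ""]
        df = self.metrics_frame()
        lines.append(df.to_string(index=False,
                                  float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        out = {
            "task": self.model.task.id,
            "seed": self.seed,
            "optimal_ring_mm": self.optimal_ring,
            "ring_metrics": {f"{d:g}": v for d, v in self.ring_metrics.items()},
            "clinical_predictors": list(self.clinical_screen.predictors),
            "selection_counts": {
                "IRM": self.irm.trace.counts() if self.irm.trace else {},
                "PRM": self.prm.trace.counts() if self.prm.trace else {},
            },
            "metrics": {},
        }
        for kind, per_tag in self.evaluation.items():
            out["metrics"][kind] = {}
            for tag, r in per_tag.items():
                if isinstance(r, RocResult):
                    out["metrics"][kind][tag] = {
                        "auc": round(r.auc, 6),
                        "ci": [round(r.ci_low, 6), round(r.ci_high, 6)],
                        "sensitivity": round(r.sensitivity, 6),
                        "specificity": round(r.specificity, 6)}
                else:
                    out["metrics"][kind][tag] = {
                        "accuracy": round(r.accuracy, 6),
                        "f1": round(r.f1, 6)}
        return out
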