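"""Task encoding, cohort splitting, clinical screening, model families,
ring selection, combined logistic models, nomograms."""

import numpy as np
import pandas as pd
import pytest

from perirad import (TaskSpec, build_nomogram, fit_combined, fit_task_model,
                     screen_clinical_predictors, select_optimal_ring,
                     split_cohort)
from perirad.modeling import SUBTYPES


# -- tasks ------------------------------------------------------------------

def test_taskspec_encoding():
    labels = np.array(["HR-positive", "TNBC", "HER2-enriched", "HR-positive"])
    assert np.array_equal(TaskSpec(1).encode(labels), [1, 0, 0, 1])
    assert np.array_equal(TaskSpec(2).encode(labels), [0, 0, 1, 0])
    assert np.array_equal(TaskSpec(3).encode(labels), [0, 1, 0, 0])
    assert np.array_equal(TaskSpec(4).encode(labels), labels)
    assert TaskSpec(4).is_ternary and not TaskSpec(1).is_ternary
    with pytest.raises(ValueError):
        TaskSpec(5)


# -- splitting --------------------------------------------------------------

def _cohort(n_by_class):
    rows = []
    i = 0
    for cls, n in zip(SUBTYPES, n_by_class):
        for _ in range(n):
            rows.append({"case_id": f"c{i:04d}", "subtype": cls})
            i += 1
    return pd.DataFrame(rows)


def test_split_327_gives_228_99():
    # modeled cohort: 227 / 46 / 54 by subtype
    table = _cohort((227, 46, 54))
    train, test = split_cohort(table, ratio=0.7, seed=0)
    assert len(train) == 228 and len(test) == 99
    assert set(train["case_id"]).isdisjoint(test["case_id"])


def test_split_stratification_within_one_case():
    table = _cohort((70, 20, 10))
    train, _ = split_cohort(table, ratio=0.7, seed=1)
    for cls, n in zip(SUBTYPES, (70, 20, 10)):
        got = (train["subtype"] == cls).sum()
        assert abs(got - 0.7 * n) <= 1.0, cls


def test_split_deterministic_and_validated():
    table = _cohort((30, 10, 10))
    a, _ = split_cohort(table, seed=5)
    b, _ = split_cohort(table, seed=5)
    assert a.equals(b)
    c, _ = split_cohort(table, seed=6)
    assert not a.equals(c)
    with pytest.raises(ValueError, match="at least 10"):
        split_cohort(table.head(5))
    with pytest.raises(ValueError, match="empty split"):
        split_cohort(_cohort((48, 1, 1)))


# -- clinical screening -----------------------------------------------------

def _clinical(n=120, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    subtype = rng.choice(SUBTYPES, size=n, p=[0.5, 0.25, 0.25])
    pos = subtype == "TNBC"
    aln = np.where(
        rng.random(n) < np.where(pos & informative, 0.85, 0.2), ">5mm", "<=5mm")
    return pd.DataFrame({
        "subtype": subtype,
        "age": rng.normal(50, 9, n),
        "tumor_size": np.where(pos & informative, 25, 15) + rng.normal(0, 2, n),
        "bpe": rng.choice(["minimal", "mild", "moderate", "marked"], n),
        "fgt": rng.choice(["dense", "non-dense"], n),
        "margin": rng.choice(["clear", "blurry"], n),
        "aln_short_diameter": aln,
        "firmness": rng.choice(["soft", "hard"], n),
        "mobility": rng.choice(["pushable", "non-pushable"], n),
        "menopause": rng.choice(["pre", "post"], n),
    })


def test_clinical_screen_finds_planted_predictors():
    res = screen_clinical_predictors(_clinical(), TaskSpec(3))
    assert {"tumor_size", "aln_short_diameter"} <= set(res.predictors)
    assert res.univariate.loc["tumor_size", "p"] < 0.05
    assert not res.ridge_fallback or True  # fallback allowed but flagged
    if not res.multivariate.empty:
        ors = res.multivariate.loc[res.predictors, "or"]
        assert (ors > 0).all()


def test_clinical_screen_no_signal():
    res = screen_clinical_predictors(_clinical(informative=False, seed=3),
                                     TaskSpec(1), alpha=0.001)
    assert res.predictors == []
    assert res.multivariate.empty


def test_clinical_screen_ternary_runs():
    res = screen_clinical_predictors(_clinical(seed=4), TaskSpec(4))
    assert "tumor_size" in res.predictors


# -- SVM family -------------------------------------------------------------

def _xy(n=60, seed=0, ternary=False):
    rng = np.random.default_rng(seed)
    if ternary:
        y = np.array(SUBTYPES)[rng.integers(0, 3, n)]
        shift = {s: i * 2.0 for i, s in enumerate(SUBTYPES)}
        X = pd.DataFrame({"f1": [shift[c] for c in y] + rng.normal(0, 0.5, n),
                          "f2": rng.normal(0, 1, n)})
    else:
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"f1": y * 2.0 + rng.normal(0, 0.5, n),
                          "f2": rng.normal(0, 1, n)})
    return X, y


def test_fit_task_model_scores_in_unit_interval():
    X, y = _xy()
    m = fit_task_model(X, y, TaskSpec(1), "IRM")
    s = m.rad_score(X)
    assert s.shape == (60,)
    assert (0 <= s).all() and (s <= 1).all()
    # scores separate the classes
    assert s[y == 1].mean() > s[y == 0].mean() + 0.3


def test_fit_task_model_ternary_probability_matrix():
    X, y = _xy(ternary=True, seed=1)
    m = fit_task_model(X, y, TaskSpec(4), "IRM")
    p = m.rad_score(X)
    assert p.shape == (60, 3)
    assert np.allclose(p.sum(axis=1), 1.0)
    assert (m.predict(X) == y).mean() > 0.8


def test_fit_task_model_validation():
    X, y = _xy()
    with pytest.raises(ValueError, match="single class"):
        fit_task_model(X, np.zeros(60), TaskSpec(1), "IRM")
    with pytest.raises(ValueError, match="ring distance"):
        fit_task_model(X, y, TaskSpec(1), "PRM")
    with pytest.raises(ValueError, match="unknown model kind"):
        fit_task_model(X, y, TaskSpec(1), "XYZ")


# -- ring selection ---------------------------------------------------------

def test_select_optimal_ring_worked_examples():
    t1 = {2: 0.681, 4: 0.725, 6: 0.794, 8: 0.751}
    t2 = {2: 0.642, 4: 0.744, 6: 0.728, 8: 0.784}
    assert select_optimal_ring(t1, TaskSpec(1)) == 6
    assert select_optimal_ring(t2, TaskSpec(2)) == 8


def test_select_optimal_ring_tie_and_validation():
    assert select_optimal_ring({2: 0.8, 4: 0.8, 6: 0.7}, TaskSpec(1)) == 2
    with pytest.raises(ValueError, match="two candidate"):
        select_optimal_ring({2: 0.8}, TaskSpec(1))


# -- combined logistic models -----------------------------------------------

def test_fit_combined_recovers_logistic_coefficients():
    rng = np.random.default_rng(2)
    n = 4000
    X = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
    eta = -0.5 + 1.2 * X["a"] - 0.8 * X["b"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    m = fit_combined(X, y, TaskSpec(1), "CIPRM")
    assert not m.ridge_fallback
    assert m.coef[0, 0] == pytest.approx(1.2, abs=0.15)
    assert m.coef[0, 1] == pytest.approx(-0.8, abs=0.15)
    assert m.intercept[0] == pytest.approx(-0.5, abs=0.15)
    p = m.rad_score(X)
    assert ((0 < p) & (p < 1)).all()
    assert np.array_equal(m.predict(X), (p >= 0.5).astype(int))


def test_fit_combined_drops_collinear_and_constant():
    rng = np.random.default_rng(3)
    n = 200
    a = rng.normal(0, 1, n)
    X = pd.DataFrame({"a": a, "dup": a * 2.0 + 1e-9,
                      "const": np.ones(n)})
    y = (rng.random(n) < 1 / (1 + np.exp(-a))).astype(int)
    m = fit_combined(X, y, TaskSpec(1), "CCRM")
    assert set(m.dropped_collinear) == {"dup", "const"}
    assert m.feature_names == ["a"]


def test_fit_combined_intercept_only_degenerate():
    X = pd.DataFrame({"const": np.ones(40)})
    y = np.array([1] * 10 + [0] * 30)
    m = fit_combined(X, y, TaskSpec(1), "CM")
    assert m.feature_names == []
    p = m.rad_score(pd.DataFrame({"const": np.ones(5)}))
    assert np.allclose(p, 0.25)


def test_fit_combined_separation_falls_back_to_ridge():
    X = pd.DataFrame({"a": np.linspace(-1, 1, 40)})
    y = (X["a"] > 0).astype(int).to_numpy()
    m = fit_combined(X, y, TaskSpec(1), "CIPRM")
    assert m.ridge_fallback
    assert np.isfinite(m.coef).all()


def test_fit_combined_ternary():
    rng = np.random.default_rng(4)
    n = 900
    y = np.array(SUBTYPES)[rng.integers(0, 3, n)]
    shift = {s: i * 1.5 for i, s in enumerate(SUBTYPES)}
    X = pd.DataFrame({"s": [shift[c] for c in y] + rng.normal(0, 0.7, n)})
    m = fit_combined(X, y, TaskSpec(4), "CCRM")
    p = m.rad_score(X)
    assert p.shape == (n, 3)
    assert np.allclose(p.sum(axis=1), 1.0)
    assert (m.predict(X) == y).mean() > 0.6


# -- nomogram ---------------------------------------------------------------

def test_nomogram_round_trip_exact():
    rng = np.random.default_rng(5)
    n = 300
    X = pd.DataFrame({"rad": rng.random(n), "size": rng.normal(18, 4, n)})
    eta = -3.0 + 4.0 * X["rad"] + 0.1 * X["size"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    m = fit_combined(X, y, TaskSpec(1), "CCRM")
    nom = build_nomogram(m, X)
    # dominant predictor spans exactly 0..100 points over its range
    spans = {name: abs(nom.betas[name]) * (X[name].max() - X[name].min())
             for name in nom.predictors}
    dom = max(spans, key=spans.get)
    hi_row = {name: (X[name].max() if nom.betas[name] > 0 else X[name].min())
              for name in nom.predictors}
    assert nom.points(hi_row)[dom] == pytest.approx(100.0)
    lo_row = {name: nom.refs[name] for name in nom.predictors}
    assert nom.total_points(lo_row) == pytest.approx(0.0)
    # per-predictor points are non-negative over the observed range
    for i in range(20):
        row = {name: float(X[name].iloc[i]) for name in nom.predictors}
        assert all(v >= -1e-9 for v in nom.points(row).values())
        # round trip reproduces the model probability exactly
        p_model = m.rad_score(X.iloc[[i]])[0]
        assert nom.probability(nom.total_points(row)) == pytest.approx(
            p_model, abs=1e-12)


def test_nomogram_rejects_ternary_and_zero_coef():
    rng = np.random.default_rng(6)
    X = pd.DataFrame({"a": rng.normal(0, 1, 60)})
    y3 = np.array(SUBTYPES)[rng.integers(0, 3, 60)]
    m3 = fit_combined(X, y3, TaskSpec(4), "CCRM")
    with pytest.raises(ValueError, match="binary"):
        build_nomogram(m3, X)
    y = np.array([1] * 20 + [0] * 40)
    m0 = fit_combined(pd.DataFrame(index=range(60)), y, TaskSpec(1), "CM")
    with pytest.raises(ValueError, match="zero-coefficient"):
        build_nomogram(m0, pd.DataFrame(index=range(60)))
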