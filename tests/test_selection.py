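"""Selection cascade: ICC, max-abs scaling, ANOVA-F screen, L1-SVM."""

import numpy as np
import pandas as pd
import pytest

from perirad import (SelectionTrace, anova_f_select, compute_icc,
                     l1svm_select, maxabs_normalize, reproducibility_filter,
                     run_selection_cascade)
from perirad.selection import maxabs_fit


# -- ICC --------------------------------------------------------------------

def test_icc_worked_example_12_over_26():
    # MSR=4.5, MSC=6, MSE=0.5 -> ICC(2,1) = 12/26
    val = compute_icc(np.array([[1, 2], [2, 4], [3, 6]], dtype=float))
    assert val == pytest.approx(12 / 26)


def test_icc_perfect_agreement():
    r = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0], [2.0, 2.0]])
    assert compute_icc(r) == pytest.approx(1.0)


def test_icc_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(0)
    for trial in range(5):
        subj = rng.normal(0, 2, size=12)
        rater = rng.normal(0, 0.5, size=3)
        r = subj[:, None] + rater[None, :] + rng.normal(0, 1, (12, 3))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 3),
            "raters": np.tile(np.arange(3), 12),
            "ratings": r.ravel()})
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="ratings")
        # pingouin labels ICC(2,1) as "ICC2" (older) or "ICC(A,1)" (newer)
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])]
        icc2 = float(row["ICC"].iloc[0])
        assert compute_icc(r) == pytest.approx(icc2, abs=1e-8)


def test_icc_validation_and_degenerate():
    with pytest.raises(ValueError):
        compute_icc(np.array([[1.0, 2.0], [3.0, 4.0]]))  # < 3 cases
    with pytest.raises(ValueError):
        compute_icc(np.array([1.0, 2.0, 3.0]))
    with pytest.warns(UserWarning, match="ICC set to 0"):
        assert compute_icc(np.full((4, 2), 3.0)) == 0.0


def test_reproducibility_filter():
    rng = np.random.default_rng(1)
    n = 20
    base = rng.normal(0, 1, (n, 3))
    stable = pd.DataFrame(base + rng.normal(0, 0.05, (n, 3)),
                          columns=["a", "b", "c"])
    r1s1 = pd.DataFrame(base, columns=["a", "b", "c"])
    r1s1["noisy"] = rng.normal(0, 1, n)
    r1s2 = stable.copy()
    r1s2["noisy"] = rng.normal(0, 1, n)
    r2 = pd.DataFrame(base + rng.normal(0, 0.05, (n, 3)),
                      columns=["a", "b", "c"])
    r2["noisy"] = rng.normal(0, 1, n)
    retained, stats = reproducibility_filter(r1s1, r1s2, r2)
    assert retained == ["a", "b", "c"]
    assert set(stats.index) == {"a", "b", "c", "noisy"}
    assert (stats.loc[["a", "b", "c"], ["icc_inter", "icc_intra"]] > 0.75).all().all()
    with pytest.raises(ValueError, match="columns"):
        reproducibility_filter(r1s1, r1s2[["a", "b", "c"]], r2)


# -- max-abs ----------------------------------------------------------------

def test_maxabs_training_range_and_frozen_scales():
    rng = np.random.default_rng(2)
    train = pd.DataFrame(rng.normal(0, 5, (30, 4)), columns=list("abcd"))
    test = pd.DataFrame(rng.normal(0, 20, (10, 4)), columns=list("abcd"))
    Xn, scaler = maxabs_normalize(train)
    assert Xn.abs().max().max() <= 1.0 + 1e-12
    # frozen scales: test values may leave [-1, 1]
    Tn = scaler.apply(test)
    assert np.allclose(Tn.to_numpy(), test.to_numpy() / train.abs().max().to_numpy())
    assert Tn.abs().max().max() > 1.0


def test_maxabs_drops_zero_columns_with_warning():
    train = pd.DataFrame({"ok": [1.0, -2.0, 3.0], "zero": [0.0, 0.0, 0.0]})
    with pytest.warns(UserWarning, match="all-zero"):
        scaler = maxabs_fit(train)
    assert list(scaler.scales.index) == ["ok"]


# -- ANOVA-F ----------------------------------------------------------------

def test_anova_f_floor_and_discrimination():
    rng = np.random.default_rng(3)
    y = np.repeat([0, 1], 20)
    X = pd.DataFrame(rng.normal(0, 1, (40, 10)),
                     columns=[f"f{i}" for i in range(10)])
    X["sig"] = y + rng.normal(0, 0.1, 40)
    names, fvals = anova_f_select(X, y, fraction=0.2)
    assert len(names) == 2  # floor(0.2 * 11)
    assert "sig" in names
    assert fvals["sig"] == fvals.max()


def test_anova_f_1089_keeps_217_with_column_order_ties():
    rng = np.random.default_rng(4)
    y = np.repeat([0, 1, 2], 4)
    X = pd.DataFrame(np.tile(rng.normal(0, 1, (12, 1)), (1, 1089)),
                     columns=[f"c{i:04d}" for i in range(1089)])
    names, _ = anova_f_select(X, y, fraction=0.20)
    assert len(names) == 217
    # all-tied F values: stable sort keeps the first 217 columns
    assert names == [f"c{i:04d}" for i in range(217)]


def test_anova_f_validation():
    X = pd.DataFrame(np.random.default_rng(5).normal(size=(6, 3)))
    with pytest.raises(ValueError, match="fraction"):
        anova_f_select(X, np.array([0, 0, 0, 1, 1, 1]), fraction=0.0)
    with pytest.raises(ValueError, match="two classes"):
        anova_f_select(X, np.zeros(6), 0.2)
    with pytest.raises(ValueError, match="fewer than 2"):
        anova_f_select(X, np.array([0, 0, 0, 0, 0, 1]), 0.2)


# -- L1-SVM -----------------------------------------------------------------

def _l1_data(seed=6, n=60, informative=3, noise=12):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    cols = {}
    for i in range(informative):
        cols[f"sig{i}"] = y * 2.0 + rng.normal(0, 0.3, n)
    for i in range(noise):
        cols[f"noise{i}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols), y


def test_l1svm_selects_informative_features():
    X, y = _l1_data()
    names, coefs = l1svm_select(X, y, C=0.5)
    assert any(n.startswith("sig") for n in names)
    sig_mean = coefs[[c for c in X if c.startswith("sig")]].mean()
    noise_mean = coefs[[c for c in X if c.startswith("noise")]].mean()
    assert sig_mean > 5 * noise_mean


def test_l1svm_deterministic_and_empty_error():
    X, y = _l1_data(7)
    a, _ = l1svm_select(X, y, C=0.5)
    b, _ = l1svm_select(X, y, C=0.5)
    assert a == b
    with pytest.raises(ValueError, match="increase C"):
        l1svm_select(X, y, C=1e-6)


# -- trace + cascade --------------------------------------------------------

def test_selection_trace_enforces_nesting():
    t = SelectionTrace()
    t.record("icc", ["a", "b", "c"])
    t.record("f", ["a", "c"])
    with pytest.raises(ValueError, match="nested"):
        t.record("l1", ["a", "d"])
    assert t.counts() == {"icc": 3, "f": 2}
    assert t.retained_percentage(4, "f") == 50.0


def test_cascade_nesting_and_scaler():
    X, y = _l1_data(8, n=80, informative=4, noise=16)
    selected, trace, scaler = run_selection_cascade(
        X, y, icc_retained=list(X.columns)[:-2], fraction=0.5, C=0.5)
    assert trace.stages == ["icc", "maxabs", "f-top20", "l1svm"]
    sets = [set(trace.retained[s]) for s in trace.stages]
    assert sets[0] >= sets[1] >= sets[2] >= sets[3]
    assert set(selected) == sets[-1]
    assert set(scaler.scales.index) == sets[1]
    # retained-percentage bookkeeping to one decimal
    assert trace.retained_percentage(1316, "icc") == round(
        100 * len(sets[0]) / 1316, 1)
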