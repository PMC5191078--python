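"""Weak classifiers: decision rules and exactness of the LCE search."""

import numpy as np
import pandas as pd
import pytest

from grapeboost.weak import (
    WeakModel,
    decision_value,
    train_lce_line,
    train_lce_threshold,
    weak_classify,
    weighted_error,
)


def make_df(**columns):
    return pd.DataFrame(columns)


# -- decision rules ---------------------------------------------------


@pytest.mark.parametrize(
    "model, sample, expected",
    [
        (WeakModel("threshold_above", ("H",), (0.57,)), {"H": 0.57}, 0.0),
        (WeakModel("threshold_below", ("bstar",), (0.31,)), {"bstar": 0.20}, 0.11),
        # two-channel line with the B/R coefficients of the reference fit
        (
            WeakModel("line", ("B", "R"), (10.0, -6.16, -1.3)),
            {"B": 0.5, "R": 0.3},
            10 * 0.5 - 6.16 * 0.3 - 1.3,
        ),
    ],
)
def test_decision_value_hand_cases(model, sample, expected):
    assert decision_value(model, sample) == pytest.approx(expected, abs=1e-12)


def test_boundary_margin_classifies_as_grape():
    model = WeakModel("threshold_above", ("H",), (0.57,))
    assert weak_classify(model, {"H": 0.57}) == 1  # margin 0 -> +1
    assert weak_classify(model, {"H": 0.37}) == -1
    assert weak_classify(model, {"H": 0.77}) == 1


def test_classification_flips_exactly_at_zero_margin(rng):
    model = WeakModel("line", ("B", "R"), (1.0, -1.0, 0.05))
    df = make_df(B=rng.random(50), R=rng.random(50))
    margins = model.decision_values(df)
    labels = model.classify(df)
    assert np.array_equal(labels == 1, margins >= 0)


def test_missing_feature_error_names_the_component():
    model = WeakModel("threshold_above", ("Cb",), (0.5,))
    with pytest.raises(KeyError, match="Cb"):
        weak_classify(model, {"H": 0.3})


# -- threshold training -----------------------------------------------


def test_separable_case_zero_error_midpoint_threshold():
    df = make_df(H=[0.2, 0.3, 0.7, 0.8], label=[-1, -1, 1, 1])
    model, err = train_lce_threshold(df, None, "H", "threshold_above")
    assert err == 0.0
    assert model.params[0] == pytest.approx(0.5)  # widest-gap midpoint


def test_nonseparable_case_best_error_is_one_quarter():
    df = make_df(H=[0.2, 0.3, 0.7, 0.8], label=[-1, 1, -1, 1])
    _, err = train_lce_threshold(df, None, "H", "threshold_above")
    assert err == pytest.approx(0.25)


def test_concentrated_weights_flip_the_optimum():
    # uniform optimum sacrifices the low grape outlier (threshold ~0.7,
    # error 1/4, by enumeration); weight 0.97 on that outlier forces the
    # threshold below it (error 0.02)
    df = make_df(H=[0.2, 0.4, 0.6, 0.8], label=[1, -1, -1, 1])
    uniform_model, uerr = train_lce_threshold(df, None, "H", "threshold_above")
    assert uerr == pytest.approx(0.25)
    w = np.array([0.97, 0.01, 0.01, 0.01])
    weighted_model, werr = train_lce_threshold(df, w, "H", "threshold_above")
    assert weighted_model.params[0] < 0.2 < 0.6 < uniform_model.params[0]
    assert werr == pytest.approx(0.02)


def test_threshold_below_mirrors_above():
    df = make_df(bstar=[0.1, 0.2, 0.6, 0.7], label=[1, 1, -1, -1])
    model, err = train_lce_threshold(df, None, "bstar", "threshold_below")
    assert err == 0.0
    assert 0.2 < model.params[0] <= 0.6
    assert weak_classify(model, {"bstar": 0.15}) == 1


def test_single_class_input_is_rejected():
    df = make_df(H=[0.2, 0.4], label=[1, 1])
    with pytest.raises(ValueError):
        train_lce_threshold(df, None, "H", "threshold_above")


def _brute_force_best_error(values, labels, weights, kind):
    """Oracle: evaluate the weighted error at every sample value +- eps."""
    weights = weights / weights.sum()
    cands = np.concatenate(
        [values - 1e-9, values + 1e-9, [values.min() - 1.0, values.max() + 1.0]]
    )
    best = np.inf
    for th in cands:
        if kind == "threshold_above":
            pred = np.where(values >= th, 1, -1)
        else:
            pred = np.where(th - values >= 0, 1, -1)
        best = min(best, weights[pred != labels].sum())
    return best


@pytest.mark.parametrize("kind", ["threshold_above", "threshold_below"])
def test_threshold_search_is_exactly_optimal(kind, rng):
    for _ in range(100):
        n = int(rng.integers(2, 51))
        values = rng.random(n).round(2)  # duplicates likely
        labels = rng.choice([-1, 1], size=n)
        if len(set(labels)) < 2:
            labels[0] = -labels[1] if n > 1 else 1
        weights = rng.random(n) + 1e-3
        df = make_df(H=values, label=labels)
        _, err = train_lce_threshold(df, weights, "H", kind)
        oracle = _brute_force_best_error(values, labels, weights, kind)
        assert err == pytest.approx(oracle, abs=1e-12)


def test_trained_error_never_worse_than_constant_classifier(rng):
    for _ in range(30):
        n = int(rng.integers(2, 40))
        labels = rng.choice([-1, 1], size=n)
        if len(set(labels)) < 2:
            labels[0] = -labels[1]
        weights = rng.random(n) + 1e-3
        df = make_df(Cb=rng.random(n), label=labels)
        _, err = train_lce_threshold(df, weights, "Cb", "threshold_above")
        w = weights / weights.sum()
        assert err <= min(w[labels == 1].sum(), w[labels == -1].sum()) + 1e-12


# -- line training ----------------------------------------------------


def test_line_separates_diagonally_separable_clusters():
    # grape strictly below the B = R diagonal, background strictly above;
    # neither single channel separates
    df = make_df(
        B=[0.2, 0.5, 0.8, 0.1, 0.4, 0.7],
        R=[0.1, 0.4, 0.7, 0.2, 0.5, 0.8],
        label=[-1, -1, -1, 1, 1, 1],
    )
    line_model, line_err = train_lce_line(df, None, ("B", "R"))
    assert line_err == 0.0
    assert np.array_equal(line_model.classify(df), df["label"].to_numpy())
    for comp in ("B", "R"):
        _, err = train_lce_threshold(df, None, comp, "threshold_above")
        assert err > 0.0


def test_line_uniform_weights_equal_explicit_equal_weights():
    df = make_df(B=[0.2, 0.8, 0.3, 0.9], R=[0.7, 0.2, 0.8, 0.1], label=[1, -1, 1, -1])
    m1, e1 = train_lce_line(df, None, ("B", "R"))
    m2, e2 = train_lce_line(df, np.full(4, 0.25), ("B", "R"))
    assert m1 == m2 and e1 == e2


def test_weighted_error_matches_direct_count():
    df = make_df(H=[0.2, 0.8, 0.6], label=[-1, 1, -1])
    model = WeakModel("threshold_above", ("H",), (0.5,))
    # misclassifies only the third sample
    assert weighted_error(model, df) == pytest.approx(1 / 3)
    assert weighted_error(model, df, np.array([0.5, 0.25, 0.25])) == pytest.approx(0.25)


def test_weak_model_json_dict_roundtrip():
    model = WeakModel("line", ("B", "R"), (10.0, -6.16, -1.3))
    assert WeakModel.from_dict(model.to_dict()) == model
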