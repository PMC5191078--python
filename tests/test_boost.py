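"""The boosting loop: weight algebra, stopping rules, model persistence."""

import json

import numpy as np
import pandas as pd
import pytest

from grapeboost.boost import (
    BoostConfig,
    GrapeBoost,
    StrongClassifier,
    alpha_from_error,
    init_weights,
    load_model,
    save_model,
    strong_classify,
    train,
    update_weights,
    weighted_error,
)
from grapeboost.synth import generate_samples
from grapeboost.weak import WeakModel, train_lce_line, train_lce_threshold


# -- weight algebra ---------------------------------------------------


def test_init_weights_uniform_and_normalized():
    assert np.array_equal(init_weights(4), [0.25, 0.25, 0.25, 0.25])
    assert np.array_equal(init_weights(1), [1.0])
    with pytest.raises(ValueError):
        init_weights(0)


@pytest.mark.parametrize(
    "eps, expected",
    [
        (0.119, 1.001),  # pins the natural-log reading of the weight rule
        (0.225, 0.618),
        (0.044, 1.539),
    ],
)
def test_alpha_from_error_three_decimals(eps, expected):
    assert round(alpha_from_error(eps), 3) == expected


def test_alpha_rejects_errors_at_or_above_half():
    for eps in (0.5, 0.7, -0.1):
        with pytest.raises(ValueError):
            alpha_from_error(eps)


def test_alpha_zero_error_is_capped_by_sample_count():
    capped = alpha_from_error(0.0, n_samples=100)
    assert capped == pytest.approx(0.5 * np.log(199.0))
    with pytest.raises(ValueError):
        alpha_from_error(0.0)


def test_update_weights_hand_case():
    # two equal-weight samples, one misclassified, alpha = 0.5*ln(3):
    # factors 3^{-1/2} and 3^{+1/2} renormalize to (0.25, 0.75)
    df = pd.DataFrame({"H": [0.6, 0.4], "label": [1, 1]})
    model = WeakModel("threshold_above", ("H",), (0.5,))
    new = update_weights(np.array([0.5, 0.5]), model, df, 0.5 * np.log(3.0))
    assert np.allclose(new, [0.25, 0.75], atol=1e-12)
    assert new.sum() == pytest.approx(1.0, abs=1e-12)


def test_update_weights_misclassified_gain_relative_weight(rng):
    df = pd.DataFrame({"H": rng.random(20), "label": rng.choice([-1, 1], 20)})
    model = WeakModel("threshold_above", ("H",), (0.5,))
    w0 = init_weights(20)
    w1 = update_weights(w0, model, df, 0.8)
    wrong = np.asarray(model.classify(df)) != df["label"].to_numpy()
    if wrong.any() and (~wrong).any():
        assert w1[wrong].min() > w1[~wrong].max()
    assert w1.sum() == pytest.approx(1.0, abs=1e-12)


def test_weighted_error_extremes():
    df = pd.DataFrame({"H": [0.8, 0.2], "label": [1, -1]})
    good = WeakModel("threshold_above", ("H",), (0.5,))
    bad = WeakModel("threshold_below", ("H",), (0.5,))
    assert weighted_error(good, df, init_weights(2)) == 0.0
    assert weighted_error(bad, df, init_weights(2)) == 1.0


# -- strong classifier combination ------------------------------------


def _vote_clf(alphas):
    # four disjoint single-component stumps so votes can be set freely
    comps = ["H", "Cb", "bstar", "R"]
    rounds = []
    for comp, alpha in zip(comps, alphas):
        kind = "threshold_below" if comp == "bstar" else "threshold_above"
        rounds.append((WeakModel(kind, (comp,), (0.5,)), alpha))
    return StrongClassifier(rounds=rounds)


def test_strong_classifier_weighted_vote_arithmetic():
    clf = _vote_clf([1.537, 1.001, 0.620, 0.331])
    # votes (+1, +1, -1, -1): 1.537 + 1.001 - 0.620 - 0.331 = +1.587 > 0
    sample = {"H": 0.9, "Cb": 0.9, "bstar": 0.9, "R": 0.2}
    assert float(clf.decision_values(sample)) == pytest.approx(1.587)
    assert strong_classify(clf, sample) == 1
    # all votes -1
    assert strong_classify(clf, {"H": 0.1, "Cb": 0.1, "bstar": 0.9, "R": 0.1}) == -1


def test_exact_zero_score_classifies_as_background():
    clf = StrongClassifier(
        rounds=[
            (WeakModel("threshold_above", ("H",), (0.5,)), 0.7),
            (WeakModel("threshold_below", ("H",), (0.5,)), 0.7),
        ]
    )
    # H = 0.5 sits on both boundaries: votes +1 and +1 ... pick H values
    # giving opposite votes with equal weight: score exactly 0
    assert float(clf.decision_values({"H": 0.4})) == pytest.approx(0.0)
    assert strong_classify(clf, {"H": 0.4}) == -1


# -- training loop ----------------------------------------------------


def test_separable_data_trains_in_one_round():
    df = pd.DataFrame({"H": [0.1, 0.2, 0.8, 0.9], "label": [-1, -1, 1, 1]})
    pool = (("threshold_above", ("H",)), ("threshold_below", ("H",)))
    clf, trace = train(df, BoostConfig(max_rounds=4, target_error=0.05, pool=pool))
    assert len(clf.rounds) == 1
    assert trace.training_errors[-1] == 0.0
    assert trace.stop_reason == "target training error reached"


def test_interval_data_needs_three_rounds_to_reach_zero():
    # +1 on an interior interval: no single threshold separates, but a
    # weighted vote of above/below stumps does
    df = pd.DataFrame({"H": [0.1, 0.4, 0.5, 0.6, 0.9], "label": [-1, 1, 1, 1, -1]})
    pool = (("threshold_above", ("H",)), ("threshold_below", ("H",)))
    clf, trace = train(
        df,
        BoostConfig(max_rounds=8, target_error=0.01, pool=pool, without_replacement=False),
    )
    assert trace.training_errors[-1] == 0.0
    assert all(r.error > 0.0 for r in trace.rounds)
    assert len(clf.rounds) >= 3


def test_hopeless_data_raises_no_learner_better_than_chance():
    # identical feature values with balanced labels: every stump is at 0.5
    df = pd.DataFrame({"H": [0.5, 0.5, 0.5, 0.5], "label": [1, 1, -1, -1]})
    pool = (("threshold_above", ("H",)),)
    with pytest.raises(ValueError, match="chance"):
        train(df, BoostConfig(max_rounds=3, pool=pool))


def test_fixture_training_invariants(train_samples, fitted):
    trace = fitted.trace
    labels = train_samples["label"].to_numpy()
    # each family used at most once, >= 1 round retained
    assert 1 <= len(trace.rounds) <= 4
    for r in trace.rounds:
        assert r.error < 0.5
        assert r.alpha > 0
        assert r.weights_after.sum() == pytest.approx(1.0, abs=1e-12)
    # classical AdaBoost training-error bound
    eps = fitted.errors_
    bound = np.prod(2 * np.sqrt(eps * (1 - eps)))
    assert fitted.training_error_ <= bound + 1e-12
    # the ensemble beats every uniformly-trained weak family
    strong_acc = 1.0 - fitted.training_error_
    for kind, comps in fitted.config.pool:
        if kind == "line":
            model, err = train_lce_line(train_samples, None, comps)
        else:
            model, err = train_lce_threshold(train_samples, None, comps[0], kind)
        weak_acc = float(np.mean(np.asarray(model.classify(train_samples)) == labels))
        assert strong_acc >= weak_acc - 1e-12


def test_training_is_deterministic(train_samples):
    r1 = GrapeBoost(train_samples).fit()
    r2 = GrapeBoost(train_samples).fit()
    assert r1.classifier.rounds == r2.classifier.rounds
    assert np.array_equal(r1.errors_, r2.errors_)
    assert r1.trace.training_errors == r2.trace.training_errors


def test_first_round_recovers_a_threshold_inside_the_class_gap():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        grape = 0.75 + 0.08 * rng.random(60)  # in [0.75, 0.83]
        bg = 0.20 + 0.35 * rng.random(120)  # in [0.20, 0.55]
        df = pd.DataFrame(
            {"H": np.concatenate([grape, bg]), "label": [1] * 60 + [-1] * 120}
        )
        clf, _ = train(df, BoostConfig(max_rounds=1, pool=(("threshold_above", ("H",)),)))
        th = clf.rounds[0][0].params[0]
        hits += bg.max() < th <= grape.min()
    assert hits >= 19


def test_frozen_pool_weights_fixed_models_without_refitting(train_samples):
    frozen = [
        WeakModel("threshold_above", ("H",), (0.66,)),
        WeakModel("threshold_below", ("bstar",), (0.47,)),
    ]
    res = GrapeBoost(train_samples).fit(max_rounds=2, frozen_pool=frozen)
    trained = [m for m, _ in res.classifier.rounds]
    assert set(trained) <= set(frozen)  # parameters untouched


# -- results object and persistence -----------------------------------


def test_results_summary_lists_every_round(fitted):
    text = fitted.summary()
    assert "eps_t" in text and "alpha_t" in text
    for t in range(len(fitted.classifier.rounds)):
        assert f"h{t + 1}(x)" in text


def test_model_json_roundtrip_preserves_alphas(tmp_path, fitted):
    path = tmp_path / "model.json"
    fitted.save(path)
    loaded = load_model(path)
    assert loaded.rounds == fitted.classifier.rounds  # full precision


def test_truncated_model_file_raises_parse_error(tmp_path, fitted):
    path = tmp_path / "model.json"
    fitted.save(path)
    path.write_text(path.read_text()[:40])
    with pytest.raises(ValueError, match="model"):
        load_model(path)


def test_save_model_metadata_passthrough(tmp_path):
    clf = StrongClassifier(rounds=[(WeakModel("threshold_above", ("H",), (0.6,)), 1.0)])
    path = tmp_path / "m.json"
    save_model(clf, path, metadata={"seed": 7})
    payload = json.loads(path.read_text())
    assert payload["metadata"]["seed"] == 7
    assert load_model(path).rounds == clf.rounds
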