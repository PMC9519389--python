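"""Split plans, metrics, MLP training, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nlrmotifs.errors import InputError, ModelError
from nlrmotifs.predict import (
    Hyperparams,
    MetricsReport,
    MotifStartClassifier,
    evaluate,
    load_model,
    make_split,
    predict_residue_probabilities,
    save_model,
    train_predictor,
)


def test_make_split_sizes_and_determinism():
    plan = make_split(10, seed=3)
    assert sorted(len(g) for g in plan.groups) == [2, 2, 2, 2, 2]
    plan13 = make_split(13, seed=3)
    assert sorted(len(g) for g in plan13.groups) == [2, 2, 3, 3, 3]
    again = make_split(13, seed=3)
    assert all(
        np.array_equal(a, b) for a, b in zip(plan13.groups, again.groups)
    )
    all_idx = np.sort(np.concatenate(plan13.groups))
    assert np.array_equal(all_idx, np.arange(13))
    with pytest.raises(InputError):
        make_split(4, seed=0)


@settings(max_examples=200, derandomize=True)
@given(
    tp=st.integers(0, 500), fp=st.integers(0, 500),
    tn=st.integers(0, 500), fn=st.integers(0, 500),
)
def test_metric_identities(tp, fp, tn, fn):
    """G^2 = precision * recall and the F1 harmonic-mean identity."""
    r = MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn)
    assert abs(r.g ** 2 - r.precision * r.recall) < 1e-12
    if r.precision + r.recall > 0:
        expected_f1 = 2 * r.precision * r.recall / (r.precision + r.recall)
        assert abs(r.f1 - expected_f1) < 1e-12
    if tp + fp > 0:
        assert abs(r.precision - tp / (tp + fp)) < 1e-12
    if tn + fp > 0:
        assert abs(r.specificity - tn / (tn + fp)) < 1e-12


def test_evaluate_worked_confusion_example():
    """TP=8, FP=2, FN=2, TN=88 -> precision=recall=F1=G=0.8, spec~0.9778."""
    probs = np.zeros(100)
    starts = list(range(10))
    probs[:8] = 0.9  # eight true starts found
    probs[20:22] = 0.9  # two false alarms
    r = evaluate(probs, starts, threshold=0.5)
    assert (r.tp, r.fp, r.fn, r.tn) == (8, 2, 2, 88)
    assert r.precision == pytest.approx(0.8)
    assert r.recall == pytest.approx(0.8)
    assert r.f1 == pytest.approx(0.8)
    assert r.g == pytest.approx(0.8)
    assert r.specificity == pytest.approx(88 / 90, abs=1e-4)


def test_evaluate_perfect_and_degenerate_cases():
    probs = np.zeros(50)
    probs[7] = 0.99
    perfect = evaluate(probs, [7])
    assert (perfect.precision, perfect.recall, perfect.f1, perfect.g) == (1, 1, 1, 1)
    silent = evaluate(np.zeros(50), [7])
    assert silent.precision == 0.0
    assert silent.recall == 0.0
    assert "no-predicted-positives" in silent.degenerate


def test_evaluate_position_tolerance():
    probs = np.zeros(30)
    probs[10] = 0.9
    assert evaluate(probs, [11], tolerance=0).tp == 0
    r = evaluate(probs, [11], tolerance=1)
    assert (r.tp, r.fn, r.fp) == (1, 0, 0)


def test_threshold_monotonicity():
    rng = np.random.default_rng(7)
    probs = rng.random(300)
    starts = rng.choice(300, 20, replace=False).tolist()
    prev_recall = 1.1
    for thr in np.linspace(0.05, 0.95, 10):
        r = evaluate(probs, starts, threshold=thr)
        assert r.recall <= prev_recall + 1e-12
        prev_recall = r.recall
    # separable ordering: all true starts score above every negative,
    # so precision is non-decreasing in the threshold as well
    sep = np.full(100, 0.2)
    sep[:10] = 0.9
    prev_precision = 0.0
    for thr in (0.1, 0.5, 0.85):
        r = evaluate(sep, list(range(10)), threshold=thr)
        assert r.precision >= prev_precision - 1e-12
        prev_precision = r.precision


def _toy_windows(definition, n=400, seed=0):
    """Linearly separable window set at the motif's true dimensionality."""
    rng = np.random.default_rng(seed)
    dim = 40 * (definition.length + 10)
    X = rng.standard_normal((n, dim)).astype(np.float32)
    y = np.zeros(n, dtype=int)
    pos = rng.choice(n, n // 4, replace=False)
    y[pos] = 1
    X[pos, :30] += 4.0
    return X, y


def test_separable_toy_reaches_perfect_f1(by_name):
    d = by_name["GLPL"]
    X, y = _toy_windows(d, n=400)
    hp = Hyperparams(seed=0, max_epochs=120)
    plan = make_split(len(X), seed=1)
    model, cv_reports, test_report = train_predictor(X, y, d, hp, plan)
    assert len(cv_reports) == 4
    assert test_report.f1 == 1.0


def test_shuffled_labels_give_chance_level_f1(by_name):
    d = by_name["GLPL"]
    rng = np.random.default_rng(5)
    X, y = _toy_windows(d, n=400, seed=5)
    y = rng.permutation(y)  # destroy any feature-label association
    hp = Hyperparams(seed=0, max_epochs=60)
    plan = make_split(len(X), seed=1)
    try:
        _, _, test_report = train_predictor(X, y, d, hp, plan, cv=False)
    except InputError:
        pytest.skip("single-class split group after shuffling")
    assert test_report.f1 <= 0.6  # prevalence 0.25 plus sampling noise


def test_training_is_deterministic(by_name):
    d = by_name["GLPL"]
    X, y = _toy_windows(d, n=300, seed=2)
    hp = Hyperparams(seed=11, max_epochs=30)
    plan = make_split(len(X), seed=1)
    m1, _, _ = train_predictor(X, y, d, hp, plan, cv=False)
    m2, _, _ = train_predictor(X, y, d, hp, plan, cv=False)
    w1 = np.concatenate([c.ravel() for c in m1.estimator.mlp_.coefs_])
    w2 = np.concatenate([c.ravel() for c in m2.estimator.mlp_.coefs_])
    assert np.array_equal(w1, w2)


def test_single_class_group_is_rejected(by_name):
    d = by_name["GLPL"]
    X, y = _toy_windows(d, n=100, seed=3)
    plan = make_split(len(X), seed=1)
    y_bad = y.copy()
    y_bad[plan.groups[2]] = 0
    with pytest.raises(InputError, match="group 3"):
        train_predictor(X, y_bad, d, Hyperparams(), plan)


def test_dimension_mismatch_is_rejected(by_name):
    d = by_name["GLPL"]
    X, y = _toy_windows(d, n=100, seed=4)
    with pytest.raises(ModelError, match="dimension"):
        train_predictor(X[:, :100], y, d, Hyperparams(), make_split(100, 1))


def test_model_round_trip_and_registry_override_check(by_name, tmp_path):
    from nlrmotifs.profiles import ProfileFeatures
    from nlrmotifs.registry import default_registry, get_definition

    d = by_name["GLPL"]
    X, y = _toy_windows(d, n=200, seed=6)
    hp = Hyperparams(seed=0, max_epochs=30)
    model, _, _ = train_predictor(X, y, d, hp, make_split(200, 1), cv=False)
    path = tmp_path / "glpl.model.joblib"
    save_model(model, path)
    back = load_model(path)
    rng = np.random.default_rng(0)
    feats = ProfileFeatures(
        "t", rng.random((40, 2, 20)).astype(np.float32), np.ones(40, dtype=bool)
    )
    p1 = predict_residue_probabilities(model, feats, d)
    p2 = predict_residue_probabilities(back, feats, d)
    assert np.array_equal(p1, p2)
    assert len(p1) == 40
    assert p1.min() >= 0 and p1.max() <= 1

    corrupted = tmp_path / "corrupt.joblib"
    corrupted.write_bytes(b"not a model")
    with pytest.raises(ModelError):
        load_model(corrupted)

    longer = default_registry({"GLPL": {"length": 6, "consensus": None}})
    with pytest.raises(ModelError, match="length"):
        predict_residue_probabilities(back, feats, get_definition("GLPL", longer))


def test_short_sequence_still_scores_every_residue(by_name):
    from nlrmotifs.profiles import ProfileFeatures

    d = by_name["GLPL"]
    X, y = _toy_windows(d, n=200, seed=8)
    model, _, _ = train_predictor(
        X, y, d, Hyperparams(seed=0, max_epochs=20), make_split(200, 1), cv=False
    )
    rng = np.random.default_rng(1)
    feats = ProfileFeatures(
        "tiny", rng.random((2, 2, 20)).astype(np.float32), np.ones(2, dtype=bool)
    )
    probs = predict_residue_probabilities(model, feats, d)
    assert probs.shape == (2,)
    assert np.all((probs >= 0) & (probs <= 1))
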