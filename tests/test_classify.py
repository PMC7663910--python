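"""Window classifiers: separability, determinism, kNN oracle, phase dispatch."""

import numpy as np
import pytest

from tugseg import (
    ClassifierConfig,
    LabelSequence,
    SimulationConfig,
    WindowSpec,
    predict,
    preprocess_trial,
    simulate_trial,
    train,
    window_features,
    window_labels,
)
from tugseg.classify import TECHNIQUES
from tugseg.features import WindowFeatureSet, feature_names


def _fake_feature_set(matrix, phase="preop"):
    n = matrix.shape[0]
    spec = WindowSpec(128)
    return WindowFeatureSet(
        matrix=matrix,
        names=[f"f{i}" for i in range(matrix.shape[1])],
        spans=[(i * 64, i * 64 + 128) for i in range(n)],
        spec=spec,
        fs=128.0,
        meta={"phase": phase},
    )


def _wlabels(labels):
    return LabelSequence(labels, level="window", window_size=128, hop=64)


def _separable_data(rng, n=40):
    X = np.vstack([
        rng.normal(0.0, 0.3, size=(n, 5)),
        rng.normal(5.0, 0.3, size=(n, 5)),
    ])
    y = ["sitting"] * n + ["walking_out"] * n
    return _fake_feature_set(X), _wlabels(y)


@pytest.mark.parametrize("technique", TECHNIQUES)
def test_separable_classes_resubstitution_perfect(technique):
    rng = np.random.default_rng(1)
    feats, labels = _separable_data(rng)
    cfg = ClassifierConfig(technique=technique, mode="single", seed=0)
    model = train([feats], [labels], cfg)
    assert predict(model, feats).labels == labels.labels


@pytest.mark.parametrize("technique", ["svm_linear", "cart", "adaboost"])
def test_same_seed_same_predictions(technique):
    rng = np.random.default_rng(2)
    X = rng.normal(size=(120, 10))
    y = [["sitting", "walking_out", "turning"][i % 3] for i in range(120)]
    feats, labels = _fake_feature_set(X), _wlabels(y)
    cfg = ClassifierConfig(technique=technique, mode="single", seed=5)
    preds = [predict(train([feats], [labels], cfg), feats).labels for _ in range(2)]
    assert preds[0] == preds[1]


def test_knn_matches_brute_force_distance_scan():
    """k=9 prediction equals the majority label of the 9 nearest training
    rows found by exhaustive standardized-distance search."""
    rng = np.random.default_rng(3)
    Xtr = rng.normal(size=(60, 6))
    ytr = [["sitting", "walking_out"][i % 2] for i in range(60)]
    probe = rng.normal(size=(5, 6))
    cfg = ClassifierConfig(technique="knn", mode="single", knn_k=9)
    model = train([_fake_feature_set(Xtr)], [_wlabels(ytr)], cfg)
    got = predict(model, _fake_feature_set(probe)).labels

    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    Ztr = (Xtr - mu) / sd
    for row, pred in zip((probe - mu) / sd, got):
        d = np.sqrt(((Ztr - row) ** 2).sum(axis=1))
        nearest = np.argsort(d, kind="stable")[:9]
        votes = [ytr[i] for i in nearest]
        majority = max(set(votes), key=votes.count)
        assert pred == majority


def test_multi_mode_trains_per_phase_and_dispatches():
    rng = np.random.default_rng(4)
    feats_a, labels_a = _separable_data(rng)
    feats_b, labels_b = _separable_data(rng)
    feats_b.meta["phase"] = "postop"
    cfg = ClassifierConfig(technique="cart", mode="multi", seed=0)
    model = train([feats_a, feats_b], [labels_a, labels_b], cfg)
    assert set(model.models) == {"preop", "postop"}
    with pytest.raises(KeyError, match="postop_2wk"):
        predict(model, feats_a, phase="postop_2wk")


def test_missing_class_warns_and_is_recorded():
    rng = np.random.default_rng(5)
    feats, labels = _separable_data(rng)
    cfg = ClassifierConfig(technique="cart", mode="single")
    with pytest.warns(UserWarning, match="absent"):
        model = train([feats], [labels], cfg)
    assert "turning" in model.manifest["missing_classes"]


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        ClassifierConfig(technique="random_forest")
    with pytest.raises(ValueError):
        ClassifierConfig(mode="ensemble")
    assert ClassifierConfig(technique="svm").technique == "svm_linear"
    assert ClassifierConfig(technique="nb").technique == "naive_bayes"


def test_clean_simulated_trials_classified_well_above_chance():
    """Every technique beats 1/7 chance comfortably on clean signals;
    the linear SVM and AdaBoost exceed 0.85 window accuracy."""
    spec = WindowSpec(128)
    feats, labels = [], []
    for seed in range(6):  # alternating distances, as in the protocol
        rec, gt = simulate_trial(
            SimulationConfig(seed=seed, distance_m=5 if seed % 2 else 10)
        )
        feats.append(window_features(preprocess_trial(rec), spec))
        labels.append(window_labels(gt, spec, length=len(rec)))
    held_out = []
    for seed in (100, 101, 102):
        rec, gt = simulate_trial(SimulationConfig(seed=seed))
        held_out.append(
            (window_features(preprocess_trial(rec), spec),
             window_labels(gt, spec, length=len(rec)).labels)
        )

    def accuracy(technique):
        cfg = ClassifierConfig(technique=technique, mode="single", seed=0)
        model = train(feats, labels, cfg)
        accs = [
            np.mean([p == t for p, t in zip(predict(model, f).labels, lab)])
            for f, lab in held_out
        ]
        return np.mean(accs)

    for technique in TECHNIQUES:
        acc = accuracy(technique)
        assert acc > 3 / 7, technique
    assert accuracy("svm_linear") > 0.85
    assert accuracy("adaboost") > 0.85
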