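"""Window classifiers: five techniques, per-phase or pooled training.

Five supervised techniques identify the semantic subtask of each
feature window: a linear-kernel SVM, k-nearest neighbours (k = 9),
Gaussian naive Bayes, a CART decision tree, and AdaBoost over
depth-1 decision trees.  Two training regimes are supported:

* ``multi``  — one classifier per perioperative recovery phase, so each
  model only ever sees the movement characteristics of its phase;
* ``single`` — one pooled classifier over all phases.

Features are standardized (zero mean, unit variance per column) with a
scaler fitted on the training data only; the linear SVM and kNN are
scale-sensitive, so the same convention is applied to every technique.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_model import SEMANTIC_LABELS, LabelSequence, check_labels
from .features import WindowFeatureSet

TECHNIQUES = ("svm_linear", "knn", "naive_bayes", "cart", "adaboost")

#: CLI-friendly aliases.
TECHNIQUE_ALIASES = {
    "svm": "svm_linear",
    "nb": "naive_bayes",
    "dt": "cart",
}


@dataclass
class ClassifierConfig:
    """Technique choice plus the hyperparameters left open by the method.

    Defaults: SVM C = 1.0 (linear kernel), kNN k = 9, AdaBoost with 100
    rounds of depth-1 trees, Gaussian naive Bayes, CART with no depth
    cap.  ``mode`` selects per-phase ('multi') or pooled ('single')
    training.  ``seed`` drives every stochastic learner.
    """

    technique: str = "svm_linear"
    mode: str = "multi"
    seed: int = 0
    svm_c: float = 1.0
    knn_k: int = 9
    adaboost_rounds: int = 100
    adaboost_depth: int = 1
    class_weight: str | None = None  # optional "balanced"

    def __post_init__(self) -> None:
        self.technique = TECHNIQUE_ALIASES.get(self.technique, self.technique)
        if self.technique not in TECHNIQUES:
            raise ValueError(f"technique must be one of {TECHNIQUES}")
        if self.mode not in ("multi", "single"):
            raise ValueError("mode must be 'multi' or 'single'")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def _make_estimator(cfg: ClassifierConfig):
    if cfg.technique == "svm_linear":
        return SVC(kernel="linear", C=cfg.svm_c, class_weight=cfg.class_weight,
                   random_state=cfg.seed)
    if cfg.technique == "knn":
        return KNeighborsClassifier(n_neighbors=cfg.knn_k)
    if cfg.technique == "naive_bayes":
        return GaussianNB()
    if cfg.technique == "cart":
        return DecisionTreeClassifier(random_state=cfg.seed,
                                      class_weight=cfg.class_weight)
    if cfg.technique == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=cfg.adaboost_depth),
            n_estimators=cfg.adaboost_rounds,
            random_state=cfg.seed,
        )
    raise AssertionError(cfg.technique)


def _make_pipeline(cfg: ClassifierConfig) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", _make_estimator(cfg))])


@dataclass
class TrainedModel:
    """Fitted classifier(s) with scaler and a training manifest.

    In multi mode ``models`` maps phase name to a fitted pipeline; in
    single mode it holds one entry under the key ``'pooled'``.
    """

    config: ClassifierConfig
    models: dict[str, Pipeline]
    manifest: dict = field(default_factory=dict)

    def pipeline_for(self, phase: str | None) -> Pipeline:
        if self.config.mode == "single":
            return self.models["pooled"]
        if phase not in self.models:
            raise KeyError(
                f"no classifier trained for phase {phase!r}; "
                f"available: {sorted(self.models)}"
            )
        return self.models[phase]


def _gather(features: list[WindowFeatureSet], labels: list[LabelSequence]):
    X = np.vstack([f.matrix for f in features])
    y = np.concatenate([np.asarray(seq.labels, dtype=object) for seq in labels])
    phases = np.concatenate(
        [np.repeat(f.meta.get("phase"), f.n_windows) for f in features]
    )
    if len(X) != len(y):
        raise ValueError("feature rows and window labels disagree in length")
    return X, y, phases


def train(
    features: list[WindowFeatureSet],
    labels: list[LabelSequence],
    cfg: ClassifierConfig,
) -> TrainedModel:
    """Fit the configured technique on per-trial features and window labels.

    Emits a warning for any semantic class absent from the training
    data; the class counts per fitted model land in the manifest.
    """
    for seq in labels:
        check_labels(seq.labels, SEMANTIC_LABELS)
    X, y, phases = _gather(features, labels)

    missing = set(SEMANTIC_LABELS) - set(y)
    if missing:
        warnings.warn(f"classes absent from training data: {sorted(missing)}")

    models: dict[str, Pipeline] = {}
    counts: dict[str, dict[str, int]] = {}
    if cfg.mode == "single":
        groups = {"pooled": np.ones(len(y), dtype=bool)}
    else:
        groups = {ph: phases == ph for ph in dict.fromkeys(phases)}
    for key, mask in groups.items():
        pipe = _make_pipeline(cfg)
        pipe.fit(X[mask], y[mask])
        models[str(key)] = pipe
        uniq, cts = np.unique(y[mask], return_counts=True)
        counts[str(key)] = dict(zip(uniq.tolist(), cts.tolist()))
    manifest = {
        "technique": cfg.technique,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "class_counts": counts,
        "n_windows": int(len(y)),
        "missing_classes": sorted(missing),
    }
    return TrainedModel(config=cfg, models=models, manifest=manifest)


def predict(model: TrainedModel, features: WindowFeatureSet,
            phase: str | None = None) -> LabelSequence:
    """Predict one semantic label per window of one trial.

    In multi mode the trial's phase (argument, or ``meta['phase']``)
    selects the phase-specific classifier.
    """
    phase = phase if phase is not None else features.meta.get("phase")
    pipe = model.pipeline_for(phase)
    pred = pipe.predict(features.matrix)
    return LabelSequence(
        [str(p) for p in pred],
        level="window",
        window_size=features.spec.size,
        hop=features.spec.hop,
        meta={"phase": phase, "technique": model.config.technique},
    )
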