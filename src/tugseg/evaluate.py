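"""Sample-level stream metrics and trial-level cross-validation.

The segmented output is scored against ground truth sample by sample,
over the eight final classes, as one-vs-rest confusion counts on the
continuous stream.  Per class, sensitivity = TP/(TP+FN) and precision =
TP/(TP+FP); the headline figure is the *average accuracy*, the mean
over classes of the one-vs-rest accuracy (TP+TN)/(TP+FP+TN+FN).

Model quality is estimated by p-fold cross-validation (p = 5 by
default) partitioned at the trial level: every trial lands in exactly
one test fold, the full pipeline (features, classifier, knowledge-based
postprocessing) runs per fold, and confusion counts are pooled across
test folds before metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import ClassifierConfig, predict, train
from .data_model import (
    OUTPUT_LABELS,
    SEMANTIC_LABELS,
    LabelSequence,
    SegmentList,
    TrialRecording,
    output_sample_labels,
)
from .features import WindowSpec, window_features, window_labels
from .postprocess import postprocess, to_segments
from .preprocess import preprocess_trial


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/TN/FN tallies on the sample stream."""

    classes: tuple[str, ...]
    tp: dict[str, int]
    fp: dict[str, int]
    tn: dict[str, int]
    fn: dict[str, int]

    @classmethod
    def zeros(cls, classes: Sequence[str] = OUTPUT_LABELS) -> "ConfusionCounts":
        z = lambda: {c: 0 for c in classes}
        return cls(tuple(classes), z(), z(), z(), z())

    def add(self, other: "ConfusionCounts") -> None:
        for c in self.classes:
            self.tp[c] += other.tp[c]
            self.fp[c] += other.fp[c]
            self.tn[c] += other.tn[c]
            self.fn[c] += other.fn[c]

    def total(self, c: str) -> int:
        return self.tp[c] + self.fp[c] + self.tn[c] + self.fn[c]


def confusion(
    pred: SegmentList | Sequence[str],
    gt: Sequence[str],
    classes: Sequence[str] = OUTPUT_LABELS,
) -> ConfusionCounts:
    """One-vs-rest confusion counts comparing prediction to ground truth.

    ``pred`` may be a segment list (expanded to per-sample labels) or a
    per-sample label sequence of the same length as ``gt``.
    """
    if isinstance(pred, SegmentList):
        pred_labels = pred.to_sample_labels()
    elif isinstance(pred, LabelSequence):
        pred_labels = list(pred.labels)
    else:
        pred_labels = list(pred)
    gt_labels = list(gt.labels) if isinstance(gt, LabelSequence) else list(gt)
    if len(pred_labels) != len(gt_labels):
        raise ValueError(
            f"stream lengths differ: pred {len(pred_labels)} vs gt {len(gt_labels)}"
        )
    p = np.asarray(pred_labels, dtype=object)
    g = np.asarray(gt_labels, dtype=object)
    counts = ConfusionCounts.zeros(classes)
    n = len(g)
    for c in counts.classes:
        pp = p == c
        gg = g == c
        tp = int(np.sum(pp & gg))
        fp = int(np.sum(pp & ~gg))
        fn = int(np.sum(~pp & gg))
        counts.tp[c] = tp
        counts.fp[c] = fp
        counts.fn[c] = fn
        counts.tn[c] = n - tp - fp - fn
    return counts


@dataclass
class EvaluationReport:
    """Per-class sensitivity/precision/accuracy and their mean accuracy.

    A metric with an empty denominator (e.g. sensitivity of a class
    absent from the ground truth) is reported as ``None``, never NaN.
    """

    per_class: dict[str, dict[str, float | None]]
    overall_accuracy: float
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
            "manifest": self.manifest,
        }


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(counts: ConfusionCounts, manifest: dict | None = None) -> EvaluationReport:
    """Sensitivity, precision and accuracy per class; mean accuracy overall."""
    per_class: dict[str, dict[str, float | None]] = {}
    accs: list[float] = []
    for c in counts.classes:
        tp, fp, tn, fn = counts.tp[c], counts.fp[c], counts.tn[c], counts.fn[c]
        acc = _ratio(tp + tn, tp + fp + tn + fn)
        per_class[c] = {
            "sensitivity": _ratio(tp, tp + fn),
            "precision": _ratio(tp, tp + fp),
            "accuracy": acc,
            "support": tp + fn,
        }
        if acc is not None:
            accs.append(acc)
    overall = float(np.mean(accs)) if accs else 0.0
    return EvaluationReport(
        per_class=per_class,
        overall_accuracy=overall,
        manifest=manifest or {},
    )


def make_folds(n_trials: int, p: int, seed: int) -> list[np.ndarray]:
    """Seeded random trial-level partition into p folds of near-equal size."""
    if n_trials < p:
        raise ValueError(f"need at least {p} trials for {p}-fold CV, got {n_trials}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    return [np.sort(chunk) for chunk in np.array_split(perm, p)]


def segment_trial(
    recording: TrialRecording,
    model,
    spec: WindowSpec,
    filter_width: int = 5,
) -> tuple[SegmentList, LabelSequence, LabelSequence]:
    """Run the full pipeline on one trial.

    Returns (final segments, inferred window labels, raw window labels).
    """
    prepped = preprocess_trial(recording, width=filter_width)
    feats = window_features(prepped, spec)
    raw = predict(model, feats)
    segments, inferred = postprocess(raw, spec, len(recording), fs=recording.fs)
    return segments, inferred, raw


def cross_validate(
    trials: list[tuple[TrialRecording, LabelSequence]],
    cfg: ClassifierConfig,
    spec: WindowSpec = WindowSpec(128),
    p: int = 5,
    seed: int = 0,
    filter_width: int = 5,
) -> EvaluationReport:
    """p-fold CV of the full pipeline with sample-level pooled metrics.

    Trials are partitioned at random (uniformly, without stratification);
    per fold, classifiers are trained on the training trials only
    (scaler included) and every test trial is segmented end to end.
    Confusion counts are pooled over all test folds before metrics are
    computed.  The manifest additionally reports the *raw* classifier's
    sample-level metrics over the seven semantic classes — the same
    stream scored without knowledge-based postprocessing — and per-phase
    average accuracy of the full pipeline.
    """
    folds = make_folds(len(trials), p, seed)
    pre = [preprocess_trial(rec, width=filter_width) for rec, _ in trials]
    feats = [window_features(t, spec) for t in pre]
    wlabels = [window_labels(gt, spec, length=len(rec)) for rec, gt in trials]

    pooled = ConfusionCounts.zeros(OUTPUT_LABELS)
    raw_pooled = ConfusionCounts.zeros(SEMANTIC_LABELS)
    phase_counts: dict[str, ConfusionCounts] = {}
    fold_manifest = []
    for k, test_idx in enumerate(folds):
        test = set(int(i) for i in test_idx)
        train_idx = [i for i in range(len(trials)) if i not in test]
        model = train(
            [feats[i] for i in train_idx],
            [wlabels[i] for i in train_idx],
            cfg,
        )
        for i in sorted(test):
            rec, gt = trials[i]
            raw = predict(model, feats[i])
            segments, inferred = postprocess(raw, spec, len(rec), fs=rec.fs)
            gt8 = output_sample_labels(gt.labels)
            pooled_i = confusion(segments, gt8, OUTPUT_LABELS)
            pooled.add(pooled_i)
            phase = rec.meta.get("phase", "unknown")
            phase_counts.setdefault(phase, ConfusionCounts.zeros(OUTPUT_LABELS)).add(pooled_i)
            raw_segments = to_segments(raw, spec, len(rec), fs=rec.fs)
            raw_pooled.add(confusion(raw_segments, gt.labels, SEMANTIC_LABELS))
        fold_manifest.append({"fold": k, "test_trials": sorted(test)})

    raw_report = metrics(raw_pooled)
    manifest = {
        "technique": cfg.technique,
        "mode": cfg.mode,
        "window_size": spec.size,
        "p": p,
        "seed": seed,
        "n_trials": len(trials),
        "folds": fold_manifest,
        "raw_overall_accuracy": raw_report.overall_accuracy,
        "raw_per_class": raw_report.per_class,
        "per_phase_overall_accuracy": {
            ph: metrics(c).overall_accuracy for ph, c in sorted(phase_counts.items())
        },
    }
    return metrics(pooled, manifest=manifest)
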