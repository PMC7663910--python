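"""Train a window classifier and segment a held-out trial end to end.

Fits a linear SVM on a small single-phase cohort, then runs the full
pipeline (preprocess, features, classify, knowledge-based postprocess)
on an unseen trial.  The raw run count shows classifier fragmentation;
the final segment list shows postprocessing collapsing it to the eight
canonical subtasks.
"""

from tugseg import (
    ClassifierConfig,
    SimulationConfig,
    WindowSpec,
    preprocess_trial,
    segment_trial,
    simulate_trial,
    train,
    window_features,
    window_labels,
)

spec = WindowSpec(128)
feats, labels = [], []
for seed in range(6):
    rec, gt = simulate_trial(SimulationConfig(seed=seed, distance_m=5 if seed % 2 else 10))
    feats.append(window_features(preprocess_trial(rec), spec))
    labels.append(window_labels(gt, spec, length=len(rec)))
model = train(feats, labels, ClassifierConfig(technique="svm_linear", mode="single", seed=0))

rec, gt = simulate_trial(SimulationConfig(seed=500))
segments, inferred, raw = segment_trial(rec, model, spec)

print(f"raw classifier output: {len(raw.runs())} runs over {len(raw)} windows")
print(f"after postprocessing:  {len(segments)} segments")
print(f"{'segment':<16}{'duration (s)':>13}")
for cls, s, e in segments.segments:
    print(f"{cls:<16}{(e - s) / rec.fs:>13.2f}")
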