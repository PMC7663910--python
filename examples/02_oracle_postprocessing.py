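"""Postprocess ground-truth window labels: the knowledge-based stage alone.

Derives majority-vote window labels (W = 128 samples, 50% overlap) from
a simulated trial's ground truth and runs fragmentation modification,
subtask inference and segment extraction.  On clean input the output is
exactly the eight canonical subtasks; the printed boundary error shows
the residual window-quantization effect (at most about one window).
"""

from tugseg import SimulationConfig, WindowSpec, postprocess, simulate_trial, window_labels

cfg = SimulationConfig(seed=7)
recording, ground_truth = simulate_trial(cfg)
spec = WindowSpec(128)

labels = window_labels(ground_truth, spec, length=len(recording))
segments, inferred = postprocess(labels, spec, len(recording), fs=recording.fs)

gt_runs = ground_truth.runs()
print(f"{len(segments)} segments from {len(labels)} windows")
print(f"{'segment':<16}{'start (s)':>10}{'end (s)':>9}{'boundary err (ms)':>19}")
for (cls, s, e), (_, gs, ge) in zip(segments.segments, gt_runs):
    err_ms = abs(s - gs) / recording.fs * 1000
    print(f"{cls:<16}{s / recording.fs:>10.2f}{e / recording.fs:>9.2f}{err_ms:>19.0f}")
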