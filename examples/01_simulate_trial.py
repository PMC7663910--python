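"""Simulate one synthetic TUG trial and inspect its ground truth.

Generates a 5-m preoperative trial at 128 Hz and prints the subtask run
structure: each row is one protocol phase with its start time and
duration.  The durations are the values the generator actually drew
(sitting ~5 s, chair transfers ~1 s, walking = distance / gait speed).
"""

from tugseg import SimulationConfig, simulate_trial

cfg = SimulationConfig(seed=1, phase="preop", distance_m=5)
recording, ground_truth = simulate_trial(cfg)

print(f"trial: {len(recording)} samples at {recording.fs:.0f} Hz "
      f"({len(recording) / recording.fs:.1f} s), nodes: {sorted(recording.nodes)}")
print(f"{'subtask':<16}{'start (s)':>10}{'duration (s)':>14}")
for label, start, end in ground_truth.runs():
    print(f"{label:<16}{start / recording.fs:>10.2f}{(end - start) / recording.fs:>14.2f}")
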