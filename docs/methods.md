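# Methods

## Problem and pipeline

A TUG trial is a continuous multivariate time series from six IMU nodes
(chest, lower back, right/left thigh, right/left shank), each contributing
triaxial acceleration and triaxial angular velocity at a fixed 128 Hz. The
task is to partition the sample stream into eight subtasks in a known
temporal order. Plain sliding-window classification suffers from three
failure modes this pipeline is built around: *motion variability* across
recovery phases (addressed by per-phase classifiers), *fragmentation* of true
segments into short misclassified runs (addressed by a relabelling pass), and
*ambiguity* between classes with near-identical signatures — walking-out vs
walking-in, turning vs turning-around (addressed by order inference).

## Preprocessing

Each raw channel is smoothed with a centered moving average. The filter width
is configurable; the default is 5 samples (~39 ms at 128 Hz), wide enough to
suppress white sensor jitter yet an order of magnitude shorter than the ~1 s
chair transfers it must preserve. Edges use shrinking (partial) windows
rather than padding, so no fabricated values enter the stream and output
length equals input length. Resultants AT/GT are computed *after* filtering,
from the filtered axes. Acceleration units are carried as metadata
(`meta['accel_unit']`), never assumed.

## Windowing and features

Windows of 96, 128 or 160 samples (0.75/1/1.25 s) advance by half a window
(50% overlap); spans are `[i*h, i*h+W)` for `i = 0..⌊(L−W)/h⌋`, and a tail
shorter than one hop is not windowed (at reconstruction it inherits the last
window's label). Eight statistics per channel per window: mean, standard
deviation, variance, maximum, minimum, range, kurtosis, skewness. Statistic
conventions are not forced by the method, so the package fixes them: variance
and SD are population moments (divide by n); skewness is the standardized
third central moment; kurtosis is *excess* kurtosis (normal → 0), the common
signal-feature convention. A constant window gets kurtosis = skewness = 0 by
definition, so the 384-column matrix (8 × 8 × 6) is NaN-free for finite
input. Columns are ordered node-major (fixed placement order), then
statistic, then channel (ax, ay, az, gx, gy, gz, AT, GT) — deterministic, so
serialized models stay valid.

## Classification

Five techniques behind one interface: linear-kernel SVM (C = 1.0), kNN with
k = 9, Gaussian naive Bayes, CART, and AdaBoost with 100 rounds of depth-1
trees. Hyperparameters the method leaves open are fixed defaults exposed in
`ClassifierConfig` — reproducibility over tuning. Features are standardized
per column with a scaler fitted on training data only; the linear SVM and kNN
require it and the same convention is applied everywhere for uniformity.
Class imbalance (walking dominates the stream) is left unweighted by default,
with an optional `class_weight="balanced"` flag. *Multi* mode trains one
classifier per perioperative phase and dispatches on the trial's phase
metadata at prediction time; *single* mode pools all phases.

## Knowledge-based postprocessing

**Fragmentation modification** is implemented as a literal sequential
in-place pass over the 1-based window sequence: positions 1, N−1 and N are
pinned to sitting (a TUG trial starts and ends seated); then for i = 2..N−2 a
window differing from its (already possibly modified) predecessor is
overwritten with the predecessor's label when the next window already carries
that label (one-window fragment) or the window after next does while the next
does not (two-window fragment). The two-fragment rule intentionally repairs
only the first window and relies on the next iteration's one-fragment rule
for the second — this sequential dependency is part of the algorithm's
semantics and is covered by a test against an independently written
interpreter of the same pseudocode. The pass requires N ≥ 4 (it references
i+2 and the fixed end positions).

**Subtask inference** enforces the canonical order. Runs are grouped into
*episodes* (maximal stretches where walking-out/walking-in count as one group
and turning/turning-around as another, because those are the ambiguous
pairs). The longest turn episode flanked by walking episodes on both sides
anchors the trial as *the* turning subtask — by protocol the mid-test turn is
the dominant turning event; walking episodes before it become walking-out,
after it walking-in; turn episodes after the anchor become turning-around;
the first/last sitting episodes become initial/ending sitting. Episodes
impossible at their position (mid-trial sitting, a turn before the anchor, or
any class stepping backwards in the canonical order) are absorbed into the
preceding episode — a forward-only repair consistent with the idea that
earlier states are already confirmed. The output run structure is therefore
always a subsequence of the canonical eight-class order. If no turn episode
is walking-flanked, inference falls back to ordinal assignment (first turn
episode = turning, later = turning-around) and flags the trial
(`meta['turn_inference_fallback']`).

**Boundary reconstruction.** The method does not specify how overlapped
window labels map back to samples, so the convention is isolated in
`to_segments`: each sample belongs to the window whose center
`start + (W−1)/2` is nearest, ties to the earlier window; samples outside the
center range take the nearest end's label. With W = 128 and h = 64 this puts
the boundary between two windows exactly at the midpoint between centers
(e.g. sample 96 for windows starting at 0 and 64). Segment boundaries are
thus quantized to about one hop; the oracle-label tests bound the error at
one window.

## Evaluation

Scoring is per sample on the continuous stream over the eight output classes,
one-vs-rest: per class, sensitivity TP/(TP+FN), precision TP/(TP+FP),
accuracy (TP+TN)/(TP+FP+TN+FN); the overall figure is the unweighted mean of
per-class accuracies. A 0/0 metric is reported as absent (`None`), never NaN.
Cross-validation partitions *trials* (not windows) uniformly at random into p
folds (p = 5) with a fixed seed; scalers and classifiers are fitted per fold
on training trials only, and confusion counts are pooled across test folds
before metrics are computed. The report's manifest also carries the raw
(pre-postprocessing) stream metrics over the seven semantic classes and
per-phase overall accuracy. Precision is implemented by its standard
definition TP/(TP+FP).

## Synthetic data generator

The simulator emulates the protocol, not biomechanics. Per subtask it
superimposes idealized templates on a gravity baseline: seated thighs carry
gravity on the longitudinal axis, upright thighs on the vertical (a smooth
crossfade during transfers); chair transfers add a half-sine pitch
angular-velocity pulse on thighs (±120°/s) and trunk (±60°/s), opposite signs
for sit-to-stand vs stand-to-sit; walking adds cadence-locked sinusoids
dominant on the shanks (150°/s swing, alternating legs, ~1 step/s at
baseline); turns add sustained trunk yaw (90°/s mid-test turn for ~2 s,
85°/s pre-chair turn for ~2.5 s) with reduced stepping. Gaussian white noise
(0.05 g accel, 5°/s gyro at baseline) is added throughout.

Durations: sitting 5 s (SD 0.3) at both ends per protocol; transfers 1.0 s
(SD 0.15) at baseline; walking = distance / gait speed with 5% speed jitter.
Recovery phase acts multiplicatively: gait speed 1.0/0.6/0.75/0.9 m/s and
transition slow-down ×1.0/1.6/1.3/1.1 and noise inflation ×1.0/2.0/1.6/1.2
for preop/postop/2-week/6-week; the immediately-postoperative phase also sets
the walker flag, adding a 0.5 Hz arm-support sway (0.05 g) to the trunk
accelerometers. The walk back to the chair is slightly slower and flatter
than the walk out (`return_trip_factor = 0.9`, applied to cadence and swing
amplitude) — gait anticipating the sit-down differs mildly from free gait, so
the walking directions overlap heavily without being statistically identical;
setting the factor to 1.0 makes them indistinguishable at window level and
forces all direction information through the inference stage. The two turn
templates likewise differ in amplitude, duration and residual stepping but
share sign and channel. Ground-truth boundaries are crisp single samples by
default; an optional `boundary_jitter_s` blurs them to emulate the indistinct
transitions of real movement.

What passing tests on this generator do **not** show: robustness to
orientation drift, soft-tissue artefact, mid-trial hesitations or aborted
transfers, magnetometer effects, or real inter-subject kinematic diversity.
They do show that the segmentation logic — features, classifiers, fragment
repair, order inference, boundary reconstruction, metrics — is correct under
the protocol's structure with realistic class overlap and phase-dependent
variability.

## Numerical and design choices

- Sample spans are 0-based half-open `[start, end)`; durations derive from
  the sampling rate.
- Window-label attachment is by majority sample vote; exact ties resolve to
  the label dominating the window's earlier half, then to first occurrence.
- Trial seeds in cohorts derive from a root `SeedSequence`, keeping every
  trial independent yet fully reproducible from one integer.
- Fold partition is unstratified by default; phase stratification is a flag.
- Problem sizes in tests and examples (cohorts of 3–8 subjects, 1–2 trials
  per phase) were chosen as the smallest that exercise every phase and fold
  with stable statistics; the full 26 × 6 × 4 protocol cohort is generated in
  the cohort-count test only.

## Known limitations

- The anchor heuristic assumes one dominant mid-test turn; pathological
  sequences with no walking-flanked turn fall back to ordinal assignment and
  are flagged rather than repaired cleverly.
- Boundary accuracy is limited to about half a window by construction; no
  sub-window refinement against the raw signal is attempted.
- The simulator's noise is white and stationary within a phase; correlated
  sensor noise is not modelled.
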