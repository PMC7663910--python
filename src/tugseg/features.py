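"""Sliding-window segmentation and time-domain statistical features.

The preprocessed stream is cut into fixed-size windows with 50% overlap
(window sizes 96, 128 or 160 samples = 0.75, 1 or 1.25 s at 128 Hz).
From every window, eight statistics — mean, standard deviation,
variance, maximum, minimum, range, kurtosis and skewness — are computed
on each of the eight channels (three acceleration axes, three
angular-velocity axes, two resultants) of each of the six nodes,
giving 8 x 8 x 6 = 384 features per window.

Conventions: variance and standard deviation are population moments
(divide by n); skewness is the standardized third central moment;
kurtosis is excess kurtosis (a normal distribution scores 0).  A
constant window has kurtosis and skewness defined as 0, so the feature
matrix never contains NaN for finite input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (
    CHANNELS,
    PLACEMENTS,
    LabelSequence,
    TrialRecording,
)

#: Feature-statistic order (fixed; determines column ordering).
FEATURE_TYPES: tuple[str, ...] = (
    "mean",
    "std",
    "var",
    "max",
    "min",
    "range",
    "kurtosis",
    "skewness",
)

DEFAULT_WINDOW_SIZES = (96, 128, 160)


@dataclass(frozen=True)
class WindowSpec:
    """Window size in samples; hop is fixed at half the window (50% overlap)."""

    size: int = 128

    def __post_init__(self) -> None:
        if self.size < 2 or self.size % 2 != 0:
            raise ValueError(f"window size must be even and >= 2, got {self.size}")

    @property
    def hop(self) -> int:
        return self.size // 2

    def duration_s(self, fs: float) -> float:
        return self.size / fs


def make_windows(length: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Spans ``[i*hop, i*hop + size)`` for ``i = 0 .. (length-size)//hop``.

    Trailing samples shorter than one hop are not windowed.  A stream
    shorter than one window is rejected (pad or discard upstream).
    """
    W, h = spec.size, spec.hop
    if length < W:
        raise ValueError(
            f"stream of {length} samples is shorter than one window ({W}); "
            "pad the stream or reject the trial"
        )
    n = (length - W) // h + 1
    return [(i * h, i * h + W) for i in range(n)]


def _window_matrix(x: np.ndarray, spans: list[tuple[int, int]]) -> np.ndarray:
    W = spans[0][1] - spans[0][0]
    h = spans[1][0] - spans[0][0] if len(spans) > 1 else W
    return np.lib.stride_tricks.sliding_window_view(x, W)[:: h][: len(spans)]


def _stats_block(wm: np.ndarray) -> np.ndarray:
    """All eight statistics for a (n_windows, W) matrix -> (n_windows, 8)."""
    mean = wm.mean(axis=1)
    centered = wm - mean[:, None]
    m2 = (centered**2).mean(axis=1)
    m3 = (centered**3).mean(axis=1)
    m4 = (centered**4).mean(axis=1)
    std = np.sqrt(m2)
    mx = wm.max(axis=1)
    mn = wm.min(axis=1)
    ok = m2 > 0
    skew = np.zeros_like(mean)
    kurt = np.zeros_like(mean)
    skew[ok] = m3[ok] / m2[ok] ** 1.5
    kurt[ok] = m4[ok] / m2[ok] ** 2 - 3.0
    return np.column_stack([mean, std, m2, mx, mn, mx - mn, kurt, skew])


@dataclass
class WindowFeatureSet:
    """Feature matrix for one trial: ``n_windows x (8 stats * channels)``.

    Column order is node-major (fixed placement order), then statistic,
    then channel — mirroring the per-node feature table f1..f64.
    ``spans`` are the sample spans of the windows.
    """

    matrix: np.ndarray
    names: list[str]
    spans: list[tuple[int, int]]
    spec: WindowSpec
    fs: float
    meta: dict

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count does not match names")

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def feature_names(nodes: tuple[str, ...] = PLACEMENTS) -> list[str]:
    """Deterministic column names: node, then statistic, then channel."""
    return [
        f"{node}_{stat}_{ch}"
        for node in nodes
        for stat in FEATURE_TYPES
        for ch in CHANNELS
    ]


def window_features(trial: TrialRecording, spec: WindowSpec) -> WindowFeatureSet:
    """Extract the full statistical feature matrix from a preprocessed trial.

    Requires resultant channels (run :func:`tugseg.preprocess.preprocess_trial`
    first).  For a six-node trial the matrix has exactly 384 columns.
    """
    spans = make_windows(len(trial), spec)
    blocks: list[np.ndarray] = []
    for placement in PLACEMENTS:
        node = trial.nodes[placement]
        per_channel = [
            _stats_block(_window_matrix(node.channel(ch), spans)) for ch in CHANNELS
        ]
        # per_channel[c][:, s] -> column order stat-major, channel-minor
        stacked = np.stack(per_channel, axis=2)  # (n_win, 8 stats, 8 ch)
        blocks.append(stacked.reshape(len(spans), -1))
    matrix = np.hstack(blocks)
    if not np.all(np.isfinite(matrix)):
        raise FloatingPointError("non-finite feature values from finite input")
    return WindowFeatureSet(
        matrix=matrix,
        names=feature_names(),
        spans=spans,
        spec=spec,
        fs=trial.fs,
        meta=dict(trial.meta),
    )


def window_labels(gt: LabelSequence, spec: WindowSpec, length: int | None = None) -> LabelSequence:
    """Attach one ground-truth label per window by majority vote.

    Each window takes the most frequent sample label inside its span;
    on a tie, the tied label that dominates the window's earlier half
    wins (falling back to first occurrence within the window).
    """
    if gt.level != "sample":
        raise ValueError("window_labels expects a sample-level sequence")
    n = length if length is not None else len(gt.labels)
    spans = make_windows(n, spec)
    out: list[str] = []
    labels = gt.labels
    for s, e in spans:
        chunk = labels[s:e]
        counts: dict[str, int] = {}
        for lab in chunk:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        tied = [lab for lab, c in counts.items() if c == best]
        if len(tied) == 1:
            out.append(tied[0])
            continue
        half = chunk[: (e - s) // 2]
        half_counts = {lab: sum(1 for x in half if x == lab) for lab in tied}
        best_half = max(half_counts.values())
        tied_half = [lab for lab in tied if half_counts[lab] == best_half]
        if len(tied_half) == 1:
            out.append(tied_half[0])
        else:
            first = next(lab for lab in chunk if lab in tied_half)
            out.append(first)
    return LabelSequence(out, level="window", window_size=spec.size, hop=spec.hop)
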