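"""Core domain types and file I/O for TUG-trial sensor data.

A Timed Up and Go (TUG) trial is recorded by six inertial sensor nodes
(chest, lower back, right/left thigh, right/left shank), each providing
triaxial acceleration and triaxial angular velocity at a fixed sampling
rate (128 Hz by default).  The types here are shared by every pipeline
stage: raw recordings, label sequences on the sample or window timeline,
and the final list of subtask segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Fixed sensor placement order (determines feature ordering downstream).
PLACEMENTS: tuple[str, ...] = (
    "chest",
    "lower_back",
    "right_thigh",
    "left_thigh",
    "right_shank",
    "left_shank",
)

#: Channel order within a node: accelerometer axes, gyroscope axes, resultants.
CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz", "at", "gt")
RAW_CHANNELS: tuple[str, ...] = CHANNELS[:6]

#: Perioperative recovery phases of total knee arthroplasty.
PHASES: tuple[str, ...] = ("preop", "postop", "postop_2wk", "postop_6wk")

#: Seven semantic subtask labels predicted at window level.
SEMANTIC_LABELS: tuple[str, ...] = (
    "sitting",
    "sit_to_stand",
    "walking_out",
    "turning",
    "walking_in",
    "turning_around",
    "stand_to_sit",
)

#: Eight final output classes in canonical temporal order.
OUTPUT_LABELS: tuple[str, ...] = (
    "initial_sitting",
    "sit_to_stand",
    "walking_out",
    "turning",
    "walking_in",
    "turning_around",
    "stand_to_sit",
    "ending_sitting",
)

DEFAULT_FS = 128.0


class SchemaError(ValueError):
    """Raised when an input file violates the trial/segment schema."""


class VocabularyError(ValueError):
    """Raised when a label falls outside the vocabulary for its stage."""


def check_labels(labels: Sequence[str], vocabulary: Sequence[str]) -> None:
    """Raise :class:`VocabularyError` if any label is outside *vocabulary*."""
    vocab = set(vocabulary)
    bad = sorted({lab for lab in labels if lab not in vocab})
    if bad:
        raise VocabularyError(f"labels outside vocabulary: {bad}")


@dataclass
class SensorChannelSet:
    """Eight equal-length signal channels of one sensor node.

    ``ax, ay, az`` are acceleration axes (unit carried in trial metadata),
    ``gx, gy, gz`` angular-velocity axes (deg/s), and ``at, gt`` the
    resultant (Euclidean-norm) acceleration and angular velocity, which
    may be absent (``None``) until computed by preprocessing.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    at: np.ndarray | None = None
    gt: np.ndarray | None = None

    def __post_init__(self) -> None:
        lengths = {len(getattr(self, ch)) for ch in RAW_CHANNELS}
        if self.at is not None:
            lengths.add(len(self.at))
        if self.gt is not None:
            lengths.add(len(self.gt))
        if len(lengths) != 1:
            raise SchemaError(f"channel lengths differ: {sorted(lengths)}")
        for name in ("at", "gt"):
            series = getattr(self, name)
            if series is not None and np.any(np.asarray(series) < 0):
                raise SchemaError(f"resultant channel {name} has negative values")

    def __len__(self) -> int:
        return len(self.ax)

    def channel(self, name: str) -> np.ndarray:
        """Return channel *name*; raises if a resultant is not yet computed."""
        series = getattr(self, name)
        if series is None:
            raise SchemaError(f"channel {name} not computed; run preprocessing")
        return series

    @property
    def has_resultants(self) -> bool:
        return self.at is not None and self.gt is not None


@dataclass
class TrialRecording:
    """One TUG trial: six sensor nodes plus sampling rate and metadata.

    ``meta`` carries at least ``subject``, ``phase`` (one of
    :data:`PHASES`), ``distance_m`` (5 or 10), ``walker`` (bool) and
    ``trial`` (index).  The acceleration unit, if known, travels in
    ``meta['accel_unit']`` and is never hard-coded.
    """

    nodes: dict[str, SensorChannelSet]
    fs: float = DEFAULT_FS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(PLACEMENTS) - set(self.nodes)
        extra = set(self.nodes) - set(PLACEMENTS)
        if missing or extra:
            raise SchemaError(
                f"expected nodes {PLACEMENTS}; missing={sorted(missing)} "
                f"extra={sorted(extra)}"
            )
        lengths = {len(cs) for cs in self.nodes.values()}
        if len(lengths) != 1:
            raise SchemaError(f"node lengths differ: {sorted(lengths)}")
        if not self.fs > 0:
            raise SchemaError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(next(iter(self.nodes.values())))

    @property
    def phase(self) -> str | None:
        return self.meta.get("phase")

    def iter_channels(self) -> Iterator[tuple[str, str, np.ndarray]]:
        """Yield ``(placement, channel, series)`` in the fixed global order."""
        for placement in PLACEMENTS:
            node = self.nodes[placement]
            for ch in CHANNELS:
                yield placement, ch, node.channel(ch)


@dataclass
class LabelSequence:
    """Ordered subtask labels on the sample or window timeline.

    For window-level sequences, ``window_size`` and ``hop`` relate window
    index *i* to the sample span ``[i*hop, i*hop + window_size)``.
    ``meta`` carries provenance such as inference fallback flags.
    """

    labels: list[str]
    level: str = "sample"  # "sample" | "window"
    window_size: int | None = None
    hop: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("sample", "window"):
            raise ValueError(f"level must be 'sample' or 'window', got {self.level!r}")
        if self.level == "window" and (self.window_size is None or self.hop is None):
            raise ValueError("window-level sequence needs window_size and hop")
        self.labels = list(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def runs(self) -> list[tuple[str, int, int]]:
        """Maximal same-label runs as ``(label, start, end)``, half-open."""
        out: list[tuple[str, int, int]] = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[start]:
                out.append((self.labels[start], start, i))
                start = i
        return out


@dataclass
class SegmentList:
    """Contiguous, non-overlapping subtask segments tiling one trial.

    Each segment is ``(label, start_sample, end_sample)``, half-open
    ``[start, end)``; adjacent segments carry different labels.
    """

    segments: list[tuple[str, int, int]]
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        segs = [(str(c), int(s), int(e)) for c, s, e in self.segments]
        for c, s, e in segs:
            if not s < e:
                raise SchemaError(f"empty or inverted segment ({c}, {s}, {e})")
        for (c0, s0, e0), (c1, s1, e1) in zip(segs, segs[1:]):
            if s1 < e0:
                raise SchemaError(f"overlapping segments at {e0}/{s1}")
            if s1 > e0:
                raise SchemaError(f"gap between segments at {e0}/{s1}")
            if c1 == c0:
                raise SchemaError(f"adjacent segments share class {c0!r}")
        self.segments = segs

    def __len__(self) -> int:
        return len(self.segments)

    def labels(self) -> list[str]:
        return [c for c, _, _ in self.segments]

    def to_sample_labels(self) -> list[str]:
        """Expand to one label per sample over the covered span."""
        out: list[str] = []
        for c, s, e in self.segments:
            out.extend([c] * (e - s))
        return out


# ---------------------------------------------------------------------------
# I/O: one CSV per trial (long layout) + JSON sidecar metadata

def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write a trial as long-layout CSV with a ``.meta.json`` sidecar."""
    path = Path(path)
    frames = []
    n = len(trial)
    t = np.arange(n) / trial.fs
    for placement in PLACEMENTS:
        node = trial.nodes[placement]
        cols: dict = {"time": t, "node": placement}
        for ch in RAW_CHANNELS:
            cols[ch] = getattr(node, ch)
        if node.has_resultants:
            cols["at"] = node.at
            cols["gt"] = node.gt
        frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.8g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"fs": trial.fs, "meta": trial.meta}, indent=1))


def read_trial(path: str | Path) -> TrialRecording:
    """Read a trial CSV (+ JSON sidecar) written by :func:`write_trial`.

    Resultant columns are optional; when absent they stay uncomputed.
    Raises :class:`SchemaError` on a missing node or ragged lengths and
    on a non-monotone time column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time", "node", *RAW_CHANNELS}
    if not required.issubset(df.columns):
        raise SchemaError(f"missing columns: {sorted(required - set(df.columns))}")
    has_res = {"at", "gt"}.issubset(df.columns)

    sidecar = path.with_suffix(path.suffix + ".meta.json")
    fs, meta = DEFAULT_FS, {}
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        fs = float(payload.get("fs", DEFAULT_FS))
        meta = payload.get("meta", {})

    nodes: dict[str, SensorChannelSet] = {}
    for placement, grp in df.groupby("node", sort=False):
        tcol = grp["time"].to_numpy()
        if len(tcol) > 1 and np.any(np.diff(tcol) <= 0):
            raise SchemaError(f"non-monotone time column for node {placement!r}")
        kwargs = {ch: grp[ch].to_numpy(float) for ch in RAW_CHANNELS}
        if has_res:
            kwargs["at"] = grp["at"].to_numpy(float)
            kwargs["gt"] = grp["gt"].to_numpy(float)
        nodes[str(placement)] = SensorChannelSet(**kwargs)
    return TrialRecording(nodes=nodes, fs=fs, meta=meta)


def write_labels(seq: LabelSequence, path: str | Path) -> None:
    payload = {
        "level": seq.level,
        "labels": seq.labels,
        "window_size": seq.window_size,
        "hop": seq.hop,
        "meta": seq.meta,
    }
    Path(path).write_text(json.dumps(payload))


def read_labels(path: str | Path) -> LabelSequence:
    payload = json.loads(Path(path).read_text())
    return LabelSequence(
        labels=payload["labels"],
        level=payload["level"],
        window_size=payload.get("window_size"),
        hop=payload.get("hop"),
        meta=payload.get("meta", {}),
    )


def write_segments(seglist: SegmentList, path: str | Path) -> None:
    """Write segments as a JSON list of records with derived durations."""
    records = [
        {
            "class": c,
            "start_sample": s,
            "end_sample": e,
            "duration_s": (e - s) / seglist.fs,
        }
        for c, s, e in seglist.segments
    ]
    Path(path).write_text(json.dumps({"fs": seglist.fs, "segments": records}, indent=1))


def read_segments(path: str | Path) -> SegmentList:
    """Read a segment JSON file; validation errors surface as SchemaError."""
    payload = json.loads(Path(path).read_text())
    segments = [
        (r["class"], r["start_sample"], r["end_sample"]) for r in payload["segments"]
    ]
    return SegmentList(segments=segments, fs=float(payload.get("fs", DEFAULT_FS)))


def output_sample_labels(sample_labels: Sequence[str]) -> list[str]:
    """Map 7-class semantic sample labels to the 8 final classes.

    The first maximal sitting run becomes ``initial_sitting`` and the
    last becomes ``ending_sitting``; everything else is unchanged.
    """
    check_labels(sample_labels, SEMANTIC_LABELS)
    seq = LabelSequence(list(sample_labels), level="sample")
    runs = seq.runs()
    sit_runs = [i for i, (c, _, _) in enumerate(runs) if c == "sitting"]
    out = list(sample_labels)
    if sit_runs:
        first, last = sit_runs[0], sit_runs[-1]
        _, s, e = runs[first]
        out[s:e] = ["initial_sitting"] * (e - s)
        if last != first:
            _, s, e = runs[last]
            out[s:e] = ["ending_sitting"] * (e - s)
    return out
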