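"""Knowledge-based postprocessing of window label sequences.

Raw window classification of a TUG trial suffers from two systematic
errors: *fragmentation* (a true segment split by short misclassified
runs) and *ambiguity* (walking-out vs walking-in, turning vs turning
around, which have near-identical signal signatures).  Postprocessing
repairs both using prior knowledge of the protocol:

1. :func:`fragmentation_modification` — a sequential relabelling pass
   that pins the first and last two windows to sitting and absorbs one-
   or two-window runs whose neighbourhood carries a single other label.
2. :func:`subtask_inference` — enforces the canonical temporal order
   (initial sitting, sit-to-stand, walking-out, turning, walking-in,
   turning around, stand-to-sit, ending sitting): the dominant turn
   episode anchors the trial, walking runs are renamed by their side of
   it, and out-of-order runs are absorbed into their predecessor.
3. :func:`to_segments` — reconstructs sample-level boundaries from the
   overlapped windows (nearest-window-center rule) and emits the final
   segment list.
"""

from __future__ import annotations

import numpy as np

from .data_model import (
    DEFAULT_FS,
    OUTPUT_LABELS,
    SEMANTIC_LABELS,
    LabelSequence,
    SegmentList,
    check_labels,
)
from .features import WindowSpec

SITTING = "sitting"
WALK_CLASSES = frozenset({"walking_out", "walking_in"})
TURN_CLASSES = frozenset({"turning", "turning_around"})

#: Canonical position of each output class in the TUG protocol.
CANONICAL_INDEX = {label: i for i, label in enumerate(OUTPUT_LABELS)}


def fragmentation_modification(tug: LabelSequence) -> LabelSequence:
    """Relabel fragmented windows by their neighbourhood, sequentially.

    Mirrors the published pseudocode exactly, including its in-place
    semantics: position 1 and the last two positions (1-based) are set
    to sitting up front; then for i = 2..N-2, a window that differs from
    its (possibly already-modified) predecessor is overwritten with the
    predecessor's label when either the single successor (one-window
    fragment) or the successor-but-one (two-window fragment) already
    carries that label; finally the sitting pins are re-asserted.  The
    two-window rule deliberately leaves the second fragment window for
    the next iteration's one-window rule to fix.

    Requires at least four windows (the recursion inspects i+2 and the
    fixed end positions).
    """
    check_labels(tug.labels, SEMANTIC_LABELS)
    n = len(tug.labels)
    if n < 4:
        raise ValueError(f"fragmentation modification needs >= 4 windows, got {n}")
    subt = list(tug.labels)  # 0-based copy of the 1-based pseudocode array
    subt[0] = SITTING
    subt[n - 2] = SITTING
    subt[n - 1] = SITTING
    for i in range(1, n - 2):  # pseudocode i = 2 .. N-2
        if subt[i] != subt[i - 1] and subt[i - 1] == subt[i + 1]:
            subt[i] = subt[i - 1]
        elif (
            subt[i] != subt[i - 1]
            and subt[i + 1] != subt[i - 1]
            and subt[i + 2] == subt[i - 1]
        ):
            subt[i] = subt[i - 1]
    subt[0] = SITTING
    subt[n - 2] = SITTING
    subt[n - 1] = SITTING
    return LabelSequence(
        subt,
        level=tug.level,
        window_size=tug.window_size,
        hop=tug.hop,
        meta=dict(tug.meta),
    )


def _collapse(labels: list[str]) -> list[tuple[str, int]]:
    """Maximal runs as (label, length)."""
    runs: list[tuple[str, int]] = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1] = (lab, runs[-1][1] + 1)
        else:
            runs.append((lab, 1))
    return runs


def _group_of(label: str) -> str:
    if label in WALK_CLASSES:
        return "walk"
    if label in TURN_CLASSES:
        return "turn"
    return label  # sitting, sit_to_stand, stand_to_sit are their own groups


def subtask_inference(m: LabelSequence) -> LabelSequence:
    """Map a fragmentation-modified sequence onto the 8 canonical classes.

    Runs are first grouped into *episodes*: maximal stretches of
    same-group labels, where walking-out/walking-in form one group and
    turning/turning-around another (the ambiguous pairs).  The longest
    turn episode flanked by walking episodes on both sides anchors the
    trial as *the* turning subtask; walking episodes before it become
    walking-out and after it walking-in; turn episodes after the anchor
    become turning-around; the first and last sitting episodes become
    initial and ending sitting.  Episodes impossible at their position
    (a mid-trial sitting, a turn before the anchor, or any class moving
    backwards in the canonical order) are absorbed into the preceding
    episode, and adjacent same-class episodes merged, so the output run
    structure is always a subsequence of the canonical eight-class
    order.

    If no turn episode is flanked by walking on both sides (degenerate
    input), turn episodes are assigned ordinally (first = turning, later
    = turning around) and the sequence is flagged via
    ``meta['turn_inference_fallback'] = True``.
    """
    check_labels(m.labels, SEMANTIC_LABELS)
    if not m.labels:
        raise ValueError("empty label sequence")
    runs = _collapse(list(m.labels))
    meta = dict(m.meta)

    # -- collapse runs into group episodes ----------------------------------
    episodes: list[tuple[str, int]] = []  # (group, total window count)
    for label, length in runs:
        group = _group_of(label)
        if episodes and episodes[-1][0] == group:
            episodes[-1] = (group, episodes[-1][1] + length)
        else:
            episodes.append((group, length))

    # -- choose the anchoring turn episode ----------------------------------
    turn_eps = [i for i, (g, _) in enumerate(episodes) if g == "turn"]
    flanked = [
        i
        for i in turn_eps
        if 0 < i < len(episodes) - 1
        and episodes[i - 1][0] == "walk"
        and episodes[i + 1][0] == "walk"
    ]
    if flanked:
        anchor = max(flanked, key=lambda i: episodes[i][1])
    else:
        anchor = turn_eps[0] if turn_eps else None
        meta["turn_inference_fallback"] = True

    # -- assign one output class (or None = absorb) per episode -------------
    sit_eps = [i for i, (g, _) in enumerate(episodes) if g == SITTING]
    walk_eps = [i for i, (g, _) in enumerate(episodes) if g == "walk"]
    assigned: list[tuple[str | None, int]] = []
    for i, (group, length) in enumerate(episodes):
        cls: str | None
        if group == "walk":
            if anchor is not None:
                cls = "walking_out" if i < anchor else "walking_in"
            else:  # no turn at all: first walk episode is the outbound one
                cls = "walking_out" if i == walk_eps[0] else "walking_in"
        elif group == "turn":
            if i == anchor:
                cls = "turning"
            elif anchor is not None and i > anchor:
                cls = "turning_around"
            else:
                cls = None  # spurious turn before the anchor: absorb
        elif group == SITTING:
            if i == sit_eps[0]:
                cls = "initial_sitting"
            elif i == sit_eps[-1]:
                cls = "ending_sitting"
            else:
                cls = None  # mid-trial sitting is impossible: absorb
        else:
            cls = group  # sit_to_stand / stand_to_sit
        assigned.append((cls, length))

    # -- absorb, forward-only through the canonical order -------------------
    accepted: list[tuple[str, int]] = []
    last_idx = -1
    for cls, length in assigned:
        idx = CANONICAL_INDEX[cls] if cls is not None else -1
        if cls is not None and idx >= last_idx:
            if accepted and accepted[-1][0] == cls:
                accepted[-1] = (cls, accepted[-1][1] + length)
            else:
                accepted.append((cls, length))
                last_idx = idx
        elif accepted:
            accepted[-1] = (accepted[-1][0], accepted[-1][1] + length)
        else:
            # nothing accepted yet; a trial must open seated
            accepted.append(("initial_sitting", length))
            last_idx = CANONICAL_INDEX["initial_sitting"]

    out: list[str] = []
    for cls, length in accepted:
        out.extend([cls] * length)
    return LabelSequence(
        out,
        level=m.level,
        window_size=m.window_size,
        hop=m.hop,
        meta=meta,
    )


def to_segments(
    w: LabelSequence, spec: WindowSpec, length: int, fs: float = DEFAULT_FS
) -> SegmentList:
    """Reconstruct sample-level segments from overlapped window labels.

    Every sample is attributed to the window whose center
    ``start + (size-1)/2`` is nearest (ties go to the earlier window;
    samples before the first center take the first window's label and
    samples after the last center, including any unwindowed tail, take
    the last).  Maximal runs of the resulting per-sample labels become
    the segment list tiling ``[0, length)``.
    """
    if w.level != "window":
        raise ValueError("to_segments expects a window-level sequence")
    n_win = len(w.labels)
    if n_win == 0:
        raise ValueError("no windows to reconstruct from")
    centers = np.array(
        [i * spec.hop + (spec.size - 1) / 2.0 for i in range(n_win)]
    )
    # Boundary between windows i and i+1 sits at the midpoint of their
    # centers; a sample strictly past the midpoint belongs to i+1.  With
    # centers offset by 0.5 from the integer grid, a sample can tie two
    # centers only at an exact midpoint, where searchsorted(side='left')
    # keeps it with the earlier window.
    midpoints = (centers[:-1] + centers[1:]) / 2.0
    samples = np.arange(length)
    owner = np.searchsorted(midpoints, samples, side="left")
    labels = np.asarray(w.labels, dtype=object)[owner]

    segments: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, length + 1):
        if i == length or labels[i] != labels[start]:
            segments.append((str(labels[start]), start, i))
            start = i
    return SegmentList(segments=segments, fs=fs)


def postprocess(
    raw: LabelSequence, spec: WindowSpec, length: int, fs: float = DEFAULT_FS
) -> tuple[SegmentList, LabelSequence]:
    """Full postprocessing chain: fragment repair, inference, segments.

    Returns the final segment list plus the inferred window-level
    sequence (whose ``meta`` carries any inference fallback flag).
    """
    repaired = fragmentation_modification(raw)
    inferred = subtask_inference(repaired)
    return to_segments(inferred, spec, length, fs=fs), inferred
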