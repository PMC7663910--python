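"""Signal preprocessing: moving-average denoising and resultant channels.

Raw accelerometer/gyroscope axes are smoothed with a centered moving
average to suppress sensor jitter and muscle vibration, then the
resultant acceleration AT = sqrt(ax^2 + ay^2 + az^2) and resultant
angular velocity GT = sqrt(gx^2 + gy^2 + gz^2) are computed from the
filtered axes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import RAW_CHANNELS, SensorChannelSet, TrialRecording

#: Default filter width in samples (~39 ms at 128 Hz): short enough to
#: preserve ~1 s chair transfers, long enough to knock down white jitter.
DEFAULT_WIDTH = 5


def moving_average(x: np.ndarray, width: int = DEFAULT_WIDTH) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    ``width`` must be odd and >= 1 so the window is symmetric about each
    sample; near the boundaries the window shrinks to the available
    samples rather than padding with fabricated values.  Output length
    equals input length.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError(f"width must be a positive odd integer, got {width}")
    x = np.asarray(x, dtype=float)
    if width == 1:
        return x.copy()
    return (
        pd.Series(x)
        .rolling(window=width, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def resultant(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of three axis series."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError(f"axis lengths differ: {len(x)}, {len(y)}, {len(z)}")
    return np.sqrt(x * x + y * y + z * z)


def preprocess_trial(trial: TrialRecording, width: int = DEFAULT_WIDTH) -> TrialRecording:
    """Filter all raw channels of every node, then attach AT/GT resultants."""
    nodes = {}
    for placement, node in trial.nodes.items():
        filtered = {ch: moving_average(getattr(node, ch), width) for ch in RAW_CHANNELS}
        at = resultant(filtered["ax"], filtered["ay"], filtered["az"])
        gt = resultant(filtered["gx"], filtered["gy"], filtered["gz"])
        nodes[placement] = SensorChannelSet(**filtered, at=at, gt=gt)
    return TrialRecording(nodes=nodes, fs=trial.fs, meta=dict(trial.meta))
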