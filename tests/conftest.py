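import pytest

from tugseg import (
    SimulationConfig,
    WindowSpec,
    preprocess_trial,
    simulate_trial,
    window_labels,
)


@pytest.fixture(scope="session")
def clean_trial():
    """One deterministic low-noise 5-m trial with ground truth."""
    cfg = SimulationConfig(seed=42, phase="preop", distance_m=5)
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def preprocessed_trial(clean_trial):
    rec, _ = clean_trial
    return preprocess_trial(rec)


@pytest.fixture(scope="session")
def spec128():
    return WindowSpec(128)


@pytest.fixture(scope="session")
def oracle_window_labels(clean_trial, spec128):
    rec, gt = clean_trial
    return window_labels(gt, spec128, length=len(rec))
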