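"""Synthetic TUG-trial generator with sample-exact ground truth.

Emulates the clinical protocol: sit 5 s, stand up, walk 5 or 10 m, turn
around a cone, walk back, turn around in front of the chair, sit down,
sit 5 s.  Each subtask imprints an idealized kinematic template on the
six sensor nodes — a gravity offset while seated, a pitch angular-velocity
pulse on thighs and trunk for chair transfers, cadence-locked oscillation
dominant on the shanks while walking, and sustained trunk yaw while
turning — plus white Gaussian noise.  This is a signal-signature model for
exercising segmentation logic, not a biomechanical simulation.

Perioperative recovery phase scales the templates: later in recovery the
patient walks faster, transfers take less time and signals are less
noisy; immediately after surgery the reverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .data_model import (
    PHASES,
    PLACEMENTS,
    SEMANTIC_LABELS,
    LabelSequence,
    SensorChannelSet,
    TrialRecording,
)

TRUNK_NODES = ("chest", "lower_back")
THIGH_NODES = ("right_thigh", "left_thigh")
SHANK_NODES = ("right_shank", "left_shank")

#: Gait speed in m/s by recovery phase (preoperative baseline 1.0 m/s).
PHASE_GAIT_SPEED = {"preop": 1.0, "postop": 0.6, "postop_2wk": 0.75, "postop_6wk": 0.9}
#: Multiplier on transition/turn durations (slower early after surgery).
PHASE_SLOWDOWN = {"preop": 1.0, "postop": 1.6, "postop_2wk": 1.3, "postop_6wk": 1.1}
#: Multiplier on channel noise (movement variability early after surgery).
PHASE_NOISE = {"preop": 1.0, "postop": 2.0, "postop_2wk": 1.6, "postop_6wk": 1.2}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic trial; the seed fully determines output.

    Durations are means in seconds with Gaussian jitter (SDs below);
    chair transfers and one gait step last about one second at baseline.
    Amplitudes are free template parameters: accelerations in g,
    angular velocities in deg/s.
    """

    seed: int = 0
    phase: str = "preop"
    distance_m: float = 5.0
    fs: float = 128.0
    subject: int = 0
    trial: int = 0
    walker: bool = False

    gait_speed: float | None = None  # m/s; default from phase
    sitting_s: float = 5.0
    sitting_sd: float = 0.3
    transfer_s: float = 1.0  # sit-to-stand / stand-to-sit at baseline
    transfer_sd: float = 0.15
    turning_s: float = 2.0
    turning_sd: float = 0.3
    turning_around_s: float = 2.5
    turning_around_sd: float = 0.35
    gait_speed_sd_frac: float = 0.05

    accel_noise_sd: float = 0.05  # g, before phase scaling
    gyro_noise_sd: float = 5.0  # deg/s, before phase scaling
    boundary_jitter_s: float = 0.0  # optional ground-truth boundary blur

    # template amplitudes
    transfer_pitch_dps: float = 120.0  # thigh pitch rate during transfers
    trunk_pitch_dps: float = 60.0
    turn_yaw_dps: float = 90.0
    turn_around_yaw_dps: float = 85.0
    shank_swing_dps: float = 150.0
    thigh_swing_dps: float = 60.0
    cadence_hz: float = 1.0  # steps per second at baseline
    walk_accel_g: float = 0.3
    #: the walk back to the chair is slightly slower and flatter than the
    #: walk out (anticipation of sitting); 1.0 makes the directions
    #: statistically identical at window level
    return_trip_factor: float = 0.9
    walker_artifact_g: float = 0.05

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.distance_m not in (5.0, 10.0, 5, 10):
            raise ValueError(f"distance_m must be 5 or 10, got {self.distance_m}")
        for name in (
            "sitting_s", "transfer_s", "turning_s", "turning_around_s", "fs",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("accel_noise_sd", "gyro_noise_sd", "boundary_jitter_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def effective_gait_speed(self) -> float:
        return self.gait_speed if self.gait_speed is not None else PHASE_GAIT_SPEED[self.phase]


def _draw_durations(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, float]:
    """Draw per-subtask durations (s) for one trial in protocol order."""
    slow = PHASE_SLOWDOWN[cfg.phase]

    def pos(mean: float, sd: float) -> float:
        return max(0.2, rng.normal(mean, sd))

    speed = cfg.effective_gait_speed * max(
        0.5, 1.0 + rng.normal(0.0, cfg.gait_speed_sd_frac)
    )
    walk = cfg.distance_m / speed
    return {
        "sitting_start": pos(cfg.sitting_s, cfg.sitting_sd),
        "sit_to_stand": pos(cfg.transfer_s * slow, cfg.transfer_sd * slow),
        "walking_out": walk,
        "turning": pos(cfg.turning_s * slow, cfg.turning_sd * slow),
        "walking_in": cfg.distance_m
        / (
            speed
            * cfg.return_trip_factor
            * max(0.5, 1.0 + rng.normal(0.0, cfg.gait_speed_sd_frac / 2))
        ),
        "turning_around": pos(cfg.turning_around_s * slow, cfg.turning_around_sd * slow),
        "stand_to_sit": pos(cfg.transfer_s * slow, cfg.transfer_sd * slow),
        "sitting_end": pos(cfg.sitting_s, cfg.sitting_sd),
    }


def _half_sine(n: int) -> np.ndarray:
    return np.sin(np.linspace(0.0, math.pi, n, endpoint=False))


def _smoothstep(n: int) -> np.ndarray:
    x = np.linspace(0.0, 1.0, n, endpoint=False)
    return x * x * (3.0 - 2.0 * x)


def simulate_trial(cfg: SimulationConfig) -> tuple[TrialRecording, LabelSequence]:
    """Generate one trial and its sample-level semantic label sequence.

    Returns a recording (resultants not yet computed — that is the
    preprocessing stage's job) and ground-truth labels over the seven
    semantic subtasks, with sitting at both ends.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    durations = _draw_durations(cfg, rng)
    order = list(durations)  # protocol order
    n_per = {k: max(1, int(round(d * fs))) for k, d in durations.items()}
    n_total = sum(n_per.values())

    labels = np.empty(n_total, dtype=object)
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for key in order:
        semantic = "sitting" if key.startswith("sitting") else key
        spans[key] = (pos, pos + n_per[key])
        labels[pos : pos + n_per[key]] = semantic
        pos += n_per[key]

    # channels[(placement, ch)] built as template + noise
    sig = {
        (p, ch): np.zeros(n_total)
        for p in PLACEMENTS
        for ch in ("ax", "ay", "az", "gx", "gy", "gz")
    }

    # -- static gravity baselines -------------------------------------------
    # Trunk and shanks stay near vertical throughout; thighs are horizontal
    # while seated (gravity on x) and vertical while upright (gravity on z).
    for p in TRUNK_NODES + SHANK_NODES:
        sig[(p, "az")] += 1.0
    seated = np.zeros(n_total)
    for key in ("sitting_start", "sitting_end"):
        s, e = spans[key]
        seated[s:e] = 1.0
    s, e = spans["sit_to_stand"]
    seated[s:e] = 1.0 - _smoothstep(e - s)
    s, e = spans["stand_to_sit"]
    seated[s:e] = _smoothstep(e - s)
    for p in THIGH_NODES:
        sig[(p, "ax")] += seated
        sig[(p, "az")] += 1.0 - seated

    # -- chair transfers: pitch angular-velocity pulse ----------------------
    for key, sign in (("sit_to_stand", 1.0), ("stand_to_sit", -1.0)):
        s, e = spans[key]
        pulse = _half_sine(e - s)
        for p in THIGH_NODES:
            sig[(p, "gy")][s:e] += sign * cfg.transfer_pitch_dps * pulse
        for p in TRUNK_NODES:
            sig[(p, "gy")][s:e] += sign * cfg.trunk_pitch_dps * pulse

    # -- walking: cadence-locked oscillation, dominant on the shanks --------
    cadence = cfg.cadence_hz * cfg.effective_gait_speed / PHASE_GAIT_SPEED["preop"]
    cadence = max(0.5, cadence)
    for key, trip in (("walking_out", 1.0), ("walking_in", cfg.return_trip_factor)):
        s, e = spans[key]
        t = np.arange(e - s) / fs
        step_hz = cadence * trip
        for i, p in enumerate(SHANK_NODES):
            phase_off = math.pi * i  # legs alternate
            leg = np.sin(2.0 * math.pi * step_hz * t + phase_off)
            sig[(p, "gy")][s:e] += trip * cfg.shank_swing_dps * leg
            sig[(p, "ax")][s:e] += trip * cfg.walk_accel_g * leg
        for i, p in enumerate(THIGH_NODES):
            leg = np.sin(2.0 * math.pi * step_hz * t + math.pi * i)
            sig[(p, "gy")][s:e] += trip * cfg.thigh_swing_dps * leg
        for p in TRUNK_NODES:
            sig[(p, "az")][s:e] += 0.1 * trip * np.sin(4.0 * math.pi * step_hz * t)

    # -- turns: sustained trunk yaw; walking-in/out signatures identical and
    # the two turns nearly so — the deliberate source of class ambiguity.
    turn_setups = (
        ("turning", cfg.turn_yaw_dps, 0.4),  # mid-test turn: still stepping
        ("turning_around", cfg.turn_around_yaw_dps, 0.25),  # near the chair
    )
    for key, amp, stepping in turn_setups:
        s, e = spans[key]
        env = np.minimum(1.0, np.minimum(np.arange(e - s), np.arange(e - s)[::-1]) / (0.15 * fs))
        for p in TRUNK_NODES:
            sig[(p, "gz")][s:e] += amp * env
        for p in SHANK_NODES:
            t = np.arange(e - s) / fs
            sig[(p, "gy")][s:e] += stepping * cfg.shank_swing_dps * np.sin(2.0 * math.pi * cadence * t)

    # -- walker artefact: slow arm-support sway on trunk accelerometers -----
    if cfg.walker:
        t = np.arange(n_total) / fs
        sway = cfg.walker_artifact_g * np.sin(2.0 * math.pi * 0.5 * t)
        for p in TRUNK_NODES:
            sig[(p, "ax")] += sway

    # -- noise ---------------------------------------------------------------
    noise_scale = PHASE_NOISE[cfg.phase]
    for (p, ch), series in sig.items():
        sd = cfg.accel_noise_sd if ch.startswith("a") else cfg.gyro_noise_sd
        series += rng.normal(0.0, sd * noise_scale, n_total)

    # -- optional boundary blur in the ground truth --------------------------
    label_list = list(labels)
    if cfg.boundary_jitter_s > 0:
        jitter = int(cfg.boundary_jitter_s * fs)
        boundaries = [i for i in range(1, n_total) if label_list[i] != label_list[i - 1]]
        for b in boundaries:
            shift = int(rng.integers(-jitter, jitter + 1))
            lo, hi = sorted((b, max(1, min(n_total - 1, b + shift))))
            filler = label_list[b] if shift < 0 else label_list[b - 1]
            for i in range(lo, hi):
                label_list[i] = filler

    nodes = {
        p: SensorChannelSet(**{ch: sig[(p, ch)] for ch in ("ax", "ay", "az", "gx", "gy", "gz")})
        for p in PLACEMENTS
    }
    meta = {
        "subject": cfg.subject,
        "phase": cfg.phase,
        "distance_m": float(cfg.distance_m),
        "walker": cfg.walker,
        "trial": cfg.trial,
        "seed": cfg.seed,
        "accel_unit": "g",
        "gyro_unit": "deg/s",
        "durations_s": {k: round(v, 6) for k, v in durations.items()},
    }
    recording = TrialRecording(nodes=nodes, fs=fs, meta=meta)
    gt = LabelSequence(label_list, level="sample")
    assert set(gt.labels) <= set(SEMANTIC_LABELS)
    return recording, gt


def simulate_cohort(
    n_subjects: int,
    trials_per_phase: int,
    phases: tuple[str, ...] = PHASES,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
) -> list[tuple[TrialRecording, LabelSequence]]:
    """Simulate ``n_subjects × trials_per_phase × len(phases)`` trials.

    Walk distance alternates 5 m / 10 m with the trial index, so an even
    ``trials_per_phase`` yields equal counts per distance (the clinical
    protocol pairs three 5-m with three 10-m tests per phase).  Each
    trial's seed derives deterministically from ``seed``.
    """
    if n_subjects <= 0 or trials_per_phase <= 0 or not phases:
        raise ValueError("counts must be positive and phases non-empty")
    base = base_config if base_config is not None else SimulationConfig()
    out: list[tuple[TrialRecording, LabelSequence]] = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_subjects * len(phases) * trials_per_phase)
    i = 0
    for subject in range(n_subjects):
        for phase in phases:
            for trial in range(trials_per_phase):
                trial_seed = int(children[i].generate_state(1)[0] % (2**31))
                i += 1
                cfg = replace(
                    base,
                    seed=trial_seed,
                    subject=subject,
                    phase=phase,
                    trial=trial,
                    distance_m=5.0 if trial % 2 == 0 else 10.0,
                    walker=(phase == "postop"),
                )
                out.append(simulate_trial(cfg))
    return out
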