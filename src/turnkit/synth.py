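"""Synthetic multi-sensor IMU sessions with exact ground truth.

Emulates an intermittent-walk protocol: a subject stands still, walks a
straight bout, turns ~180 degrees, waits, and walks back, several times.
Five simulated IMUs (head HD, neck C7, lower back L5, ankles LA/RA) at a
nominal 128 Hz produce tri-axial accelerometer (g), gyroscope (deg/s) and
magnetometer (Gauss) streams.

Turn kinematics: each upper-body yaw profile is a minimum-jerk S-curve
(zero endpoint velocity, so turn start/end are kinematically sharp and the
ground truth unambiguous); head, neck and lower back onsets are staggered
by a configurable segment lag (sequential rotation, ~0.15 s per segment,
for the control-like preset; 0 for the en-bloc PD-like preset). Ankle yaw
is step-quantized: the turn angle is split into discrete per-step
minimum-jerk rotations separated by stance dwells, the two ankles
half-a-step out of phase. Gyro streams are the analytic yaw rate plus a
constant per-axis bias and white noise; accelerometer streams carry gravity
plus a double-frequency vertical gait oscillation during walking bouts;
the magnetometer sees a constant earth field rotated by the current yaw.

All randomness flows from one seeded generator; the same seed reproduces a
session bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    ANKLES,
    Direction,
    ImuRecording,
    LOCATIONS,
    SensorArraySession,
    StepEvent,
    TurnEvent,
    UPPER_BODY,
)

__all__ = ["SynthConfig", "GroundTruth", "simulate_session", "simulate_cohort",
           "control_like", "pd_like"]

_EARTH_FIELD = (-0.35, 0.22, 0.0)  # Gauss, (VT, AP, ML) at zero yaw


@dataclass
class SynthConfig:
    """Study-condition parameters of one simulated session.

    Two-tuples are (mean, SD) of per-turn draws. The control-like defaults
    describe a brisk ~180 deg turn in ~2.5 s with sequential head-to-pelvis
    rotation and ~3 steps; the PD-like preset (see :func:`pd_like`) slows
    the turn, removes the segment lag (en-bloc turning) and adds steps.
    """

    n_turns: int = 3
    turn_angle_deg: Tuple[float, float] = (180.0, 10.0)
    turn_duration_s: Tuple[float, float] = (2.5, 0.7)
    segment_lag_s: float = 0.15      # HD -> C7 -> L5 onset lag
    steps_per_turn: Tuple[float, float] = (3.0, 1.0)
    p_right: float = 0.5             # probability a turn goes right
    gyro_bias_dps: Tuple[float, float, float] = (0.5, -0.2, 0.3)
    noise_gyr_dps: float = 0.5
    noise_acc_g: float = 0.02
    noise_mag_gauss: float = 0.005
    gait_osc_g: float = 0.12         # vertical oscillation amplitude, walking
    gait_osc_hz: float = 2.0         # double the ~1 Hz stride frequency
    step_duty: float = 0.6           # fraction of a step slot spent rotating
    walk_s: float = 6.0
    wait_s: float = 2.0
    initial_still_s: float = 3.0
    fs: float = 128.0
    seed: int = 0
    locations: Tuple[str, ...] = LOCATIONS

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (0.5 < self.turn_duration_s[0] < 10):
            raise ValueError("mean turn duration must lie in (0.5, 10) s")


def control_like(**overrides) -> SynthConfig:
    """Preset emulating an older-adult control: brisk sequential turning."""
    return replace(SynthConfig(), **overrides)


def pd_like(**overrides) -> SynthConfig:
    """Preset emulating PD-like turning: slower, longer, en-bloc, more steps."""
    base = SynthConfig(
        turn_duration_s=(3.5, 1.0),
        turn_angle_deg=(165.0, 8.0),
        segment_lag_s=0.0,
        steps_per_turn=(5.0, 1.0),
        gait_osc_g=0.08,
    )
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Exact per-location turn windows, per-turn step windows, true yaw."""

    turns: Dict[str, List[TurnEvent]]
    steps_by_turn: List[Dict[str, List[StepEvent]]]
    yaw: Dict[str, np.ndarray]
    t: np.ndarray

    @property
    def l5_turns(self) -> List[TurnEvent]:
        return self.turns["L5"]


def _minjerk_angle(t: np.ndarray, t0: float, T: float, delta: float) -> np.ndarray:
    """Minimum-jerk yaw displacement delta over [t0, t0+T]."""
    tau = np.clip((t - t0) / T, 0.0, 1.0)
    return delta * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def _minjerk_rate(t: np.ndarray, t0: float, T: float, delta: float) -> np.ndarray:
    tau = (t - t0) / T
    inside = (tau > 0) & (tau < 1)
    tau = np.clip(tau, 0.0, 1.0)
    rate = (delta / T) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return np.where(inside, rate, 0.0)


def simulate_session(cfg: SynthConfig,
                     subject_id: str = "synthetic",
                     group_label: Optional[str] = None
                     ) -> Tuple[SensorArraySession, GroundTruth]:
    """Generate one session and its exact ground truth."""
    rng = np.random.default_rng(cfg.seed)

    # -- draw per-turn kinematics
    durations = np.clip(rng.normal(*cfg.turn_duration_s, cfg.n_turns), 0.8, 9.0)
    angles = np.clip(rng.normal(*cfg.turn_angle_deg, cfg.n_turns), 95.0, 350.0)
    signs = np.where(rng.random(cfg.n_turns) < cfg.p_right, 1.0, -1.0)
    n_steps = np.clip(np.rint(rng.normal(*cfg.steps_per_turn, cfg.n_turns)),
                      2, 5).astype(int)
    if np.any(durations * cfg.fs < 8):
        raise ValueError("infeasible config: fewer than 8 samples per turn")

    # -- lay out the timeline (upper-body onset staggered head -> neck -> L5)
    lag = {"HD": 0.0, "C7": cfg.segment_lag_s, "L5": 2 * cfg.segment_lag_s}
    cursor = cfg.initial_still_s
    walk_bouts: List[Tuple[float, float]] = []
    turn_onsets: List[float] = []
    for k in range(cfg.n_turns):
        walk_bouts.append((cursor, cursor + cfg.walk_s))
        cursor += cfg.walk_s
        turn_onsets.append(cursor)
        cursor += 2 * cfg.segment_lag_s + durations[k] + cfg.wait_s
    walk_bouts.append((cursor, cursor + cfg.walk_s))
    total_s = cursor + cfg.walk_s + 1.0
    n = int(round(total_s * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs

    walking = np.zeros(n, bool)
    for lo, hi in walk_bouts:
        walking |= (t >= lo) & (t < hi)

    # -- true yaw and yaw-rate per location
    psi: Dict[str, np.ndarray] = {loc: np.zeros(n) for loc in LOCATIONS}
    omega: Dict[str, np.ndarray] = {loc: np.zeros(n) for loc in LOCATIONS}
    truth_turns: Dict[str, List[TurnEvent]] = {loc: [] for loc in LOCATIONS}
    steps_by_turn: List[Dict[str, List[StepEvent]]] = []

    for k in range(cfg.n_turns):
        delta = signs[k] * angles[k]
        T = durations[k]
        for loc in UPPER_BODY:
            t0 = turn_onsets[k] + lag[loc]
            psi[loc] += _minjerk_angle(t, t0, T, delta)
            omega[loc] += _minjerk_rate(t, t0, T, delta)
            truth_turns[loc].append(
                TurnEvent(location=loc, start_s=t0, end_s=t0 + T, angle_deg=delta)
            )
        # ankles: step-quantized rotation inside the L5 window
        t0 = turn_onsets[k] + lag["L5"]
        per_turn_steps: Dict[str, List[StepEvent]] = {"inner": [], "outer": []}
        roles = {"inner": "RA", "outer": "LA"} if signs[k] > 0 \
            else {"inner": "LA", "outer": "RA"}
        slot = T / n_steps[k]
        rot = cfg.step_duty * slot
        step_angle = delta / n_steps[k]
        for role, ankle in roles.items():
            offset = 0.0 if role == "inner" else 0.5 * slot
            for s in range(n_steps[k]):
                s0 = t0 + offset + s * slot
                psi[ankle] += _minjerk_angle(t, s0, rot, step_angle)
                omega[ankle] += _minjerk_rate(t, s0, rot, step_angle)
                per_turn_steps[role].append(
                    StepEvent(ankle_role=role, start_s=s0, end_s=s0 + rot,
                              angle_deg=step_angle)
                )
            truth_turns[ankle].append(
                TurnEvent(location=ankle,
                          start_s=t0 + offset,
                          end_s=t0 + offset + (n_steps[k] - 1) * slot + rot,
                          angle_deg=delta)
            )
        steps_by_turn.append(per_turn_steps)

    # -- synthesize sensor streams
    recordings: Dict[str, ImuRecording] = {}
    osc_vt = cfg.gait_osc_g * np.sin(2 * np.pi * cfg.gait_osc_hz * t) * walking
    osc_ap = 0.5 * cfg.gait_osc_g * np.sin(np.pi * cfg.gait_osc_hz * t) * walking
    for loc in cfg.locations:
        psi_rad = np.deg2rad(psi[loc])
        c, s = np.cos(psi_rad), np.sin(psi_rad)
        scale = 1.0 if loc in UPPER_BODY else 2.0  # ankles shake harder
        gyr = np.vstack([
            omega[loc] + cfg.gyro_bias_dps[0] + rng.normal(0, cfg.noise_gyr_dps, n),
            cfg.gyro_bias_dps[1] + rng.normal(0, cfg.noise_gyr_dps, n),
            cfg.gyro_bias_dps[2] + rng.normal(0, cfg.noise_gyr_dps, n),
        ])
        acc = np.vstack([
            1.0 + scale * osc_vt + rng.normal(0, cfg.noise_acc_g, n),
            scale * osc_ap + rng.normal(0, cfg.noise_acc_g, n),
            0.5 * scale * osc_ap + rng.normal(0, cfg.noise_acc_g, n),
        ])
        m_vt, m_n, _ = _EARTH_FIELD
        mag = np.vstack([
            m_vt + rng.normal(0, cfg.noise_mag_gauss, n),
            m_n * c + rng.normal(0, cfg.noise_mag_gauss, n),
            -m_n * s + rng.normal(0, cfg.noise_mag_gauss, n),
        ])
        recordings[loc] = ImuRecording(location=loc, t=t, acc=acc, gyr=gyr,
                                       mag=mag, fs=cfg.fs)

    session = SensorArraySession(recordings=recordings, subject_id=subject_id,
                                 group_label=group_label)
    truth = GroundTruth(
        turns={loc: truth_turns[loc] for loc in cfg.locations},
        steps_by_turn=steps_by_turn,
        yaw={loc: psi[loc] for loc in cfg.locations},
        t=t,
    )
    return session, truth


def simulate_cohort(n_pd: int, n_cl: int, seed: int = 0,
                    pd_preset: Optional[SynthConfig] = None,
                    cl_preset: Optional[SynthConfig] = None,
                    subject_sd: float = 0.25
                    ) -> Tuple[List[SensorArraySession], List[str], List[GroundTruth]]:
    """Simulate a two-group cohort with subject-level variation.

    Each subject's turn-duration and step-count means are jittered around
    the preset means (SD ``subject_sd`` s and 0.5 steps) so that between-
    subject variance exists on top of turn-to-turn variance. Returns
    (sessions, labels, ground truths) with labels "PD"/"CL".
    """
    if n_pd < 2 or n_cl < 2:
        raise ValueError("need at least 2 subjects per group")
    pd_preset = pd_preset or pd_like()
    cl_preset = cl_preset or control_like()
    root = np.random.default_rng(seed)
    sessions, labels, truths = [], [], []
    for label, preset, count in (("PD", pd_preset, n_pd), ("CL", cl_preset, n_cl)):
        for i in range(count):
            sub_seed = int(root.integers(0, 2**31 - 1))
            jit = np.random.default_rng(sub_seed)
            cfg = replace(
                preset,
                seed=sub_seed,
                turn_duration_s=(
                    max(0.9, preset.turn_duration_s[0] + jit.normal(0, subject_sd)),
                    preset.turn_duration_s[1],
                ),
                steps_per_turn=(
                    preset.steps_per_turn[0] + jit.normal(0, 0.5),
                    preset.steps_per_turn[1],
                ),
            )
            sess, truth = simulate_session(cfg, subject_id=f"{label}{i:03d}",
                                           group_label=label)
            sessions.append(sess)
            labels.append(label)
            truths.append(truth)
    return sessions, labels, truths
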