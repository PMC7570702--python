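"""Turn start/end detection from yaw traces.

The detection rule: movement about the vertical axis is segmented at
zero-crossings of the (bias-corrected) vertical angular velocity; gradual
sub-turns in the same direction separated by less than 0.5 s are merged;
merged rotations are accepted as turns when they exceed the per-location
angle threshold (90 deg at the lower back, 30 deg at head, neck and
ankles) and last between 0.5 and 10 s.  Ankle data are re-labelled inner /
outer with respect to each lower-back turn's direction, and steps are the
ankle rotations of at least 30 deg inside the turn window.

A configurable deadband (default 5 deg/s) decides the sign of the angular
velocity: |omega| below the deadband counts as zero, which makes the
zero-crossing rule robust to gyro noise.  Set it to 0 to recover the
literal noise-free rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .types import Direction, StepEvent, TurnEvent, YawTrace

__all__ = [
    "DetectionConfig",
    "Segment",
    "zero_crossing_segments",
    "merge_gradual_turns",
    "detect_turns",
    "assign_inner_outer",
    "count_steps",
]


@dataclass
class DetectionConfig:
    """Thresholds of the turn-detection rule (angles deg, durations s)."""

    deadband_dps: float = 5.0
    l5_min_angle: float = 90.0
    other_min_angle: float = 30.0
    min_dur: float = 0.5
    max_dur: float = 10.0
    gradual_min_angle: float = 10.0
    gradual_max_gap: float = 0.5
    step_min_angle: float = 30.0
    step_pad_s: float = 0.5

    def min_angle(self, location: str) -> float:
        if location == "L5":
            return self.l5_min_angle
        if location in ("HD", "C7", "LA", "RA"):
            return self.other_min_angle
        raise ValueError(f"unknown location {location!r}")


@dataclass
class Segment:
    """A maximal interval of constant angular-velocity sign.

    ``angle_deg`` is the yaw displacement over the interval; ``subturns``
    lists the constituent (start_s, end_s, angle_deg) once segments are
    merged.
    """

    start_s: float
    end_s: float
    angle_deg: float
    subturns: Tuple = ()

    def __post_init__(self) -> None:
        if not self.subturns:
            self.subturns = ((self.start_s, self.end_s, self.angle_deg),)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def sign(self) -> int:
        return 1 if self.angle_deg >= 0 else -1


def zero_crossing_segments(trace: YawTrace, deadband_dps: float = 5.0) -> List[Segment]:
    """Split a yaw trace at zero-crossings of the vertical angular velocity.

    Samples with |omega| < deadband are treated as zero; each returned
    segment is a maximal run of one sign and carries its yaw displacement.
    A motionless trace yields an empty list.
    """
    omega = trace.omega_vt
    # a numerical epsilon guards the literal deadband=0 rule against
    # floating-point residue left by bias subtraction
    band = max(deadband_dps, 1e-6)
    sign = np.zeros(omega.size, dtype=np.int8)
    sign[omega >= band] = 1
    sign[omega <= -band] = -1

    segments: List[Segment] = []
    boundaries = np.flatnonzero(np.diff(sign)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [sign.size]))  # exclusive
    half = 0.5 / trace.fs  # the true crossing lies between samples
    for i0, i1 in zip(starts, ends):
        if sign[i0] == 0:
            continue
        j = i1 - 1
        segments.append(
            Segment(
                start_s=float(max(trace.t[i0] - half, trace.t[0])),
                end_s=float(min(trace.t[j] + half, trace.t[-1])),
                angle_deg=float(trace.psi[j] - trace.psi[i0]),
            )
        )
    return segments


def merge_gradual_turns(segments: Sequence[Segment],
                        min_angle: float = 10.0,
                        max_gap: float = 0.5) -> List[Segment]:
    """Combine gradual turns: consecutive same-direction segments, each with
    |angle| > ``min_angle`` deg, separated by gaps shorter than ``max_gap``
    seconds, become one segment whose angle is the sum of the sub-angles.

    Segments at or below ``min_angle`` are jitter: they neither merge nor
    break a merge chain (they simply occupy gap time). The operation is
    idempotent.
    """
    merged: List[Segment] = []
    chain: List[Segment] = []

    def flush() -> None:
        if not chain:
            return
        subs = tuple(s for seg in chain for s in seg.subturns)
        merged.append(
            Segment(
                start_s=chain[0].start_s,
                end_s=chain[-1].end_s,
                angle_deg=float(sum(s.angle_deg for s in chain)),
                subturns=subs,
            )
        )
        chain.clear()

    for seg in sorted(segments, key=lambda s: s.start_s):
        if abs(seg.angle_deg) <= min_angle:
            continue
        if chain and seg.sign == chain[-1].sign \
                and (seg.start_s - chain[-1].end_s) < max_gap:
            chain.append(seg)
        else:
            flush()
            chain.append(seg)
    flush()
    return merged


def detect_turns(trace: YawTrace, location: str | None = None,
                 config: DetectionConfig | None = None) -> List[TurnEvent]:
    """Full per-location detection: segment, merge, threshold.

    Keeps merged segments with |angle| >= 90 deg (L5) or >= 30 deg
    (HD/C7/LA/RA) and duration in [0.5, 10) s.
    """
    cfg = config or DetectionConfig()
    loc = location or trace.location
    min_angle = cfg.min_angle(loc)
    segments = zero_crossing_segments(trace, cfg.deadband_dps)
    merged = merge_gradual_turns(segments, cfg.gradual_min_angle, cfg.gradual_max_gap)
    events = []
    for seg in merged:
        if abs(seg.angle_deg) < min_angle:
            continue
        if not (cfg.min_dur <= seg.duration_s < cfg.max_dur):
            continue
        events.append(
            TurnEvent(
                location=loc,
                start_s=seg.start_s,
                end_s=seg.end_s,
                angle_deg=seg.angle_deg,
                subturns=seg.subturns,
            )
        )
    return events


def assign_inner_outer(l5_turn: TurnEvent) -> Dict[str, str]:
    """Map ankles to inner/outer roles for one lower-back turn.

    Right turn: inner = right ankle (RA), outer = left (LA); left turn the
    reverse. Removes turn-direction bias from ankle characteristics.
    """
    if l5_turn.direction == Direction.RIGHT:
        return {"inner": "RA", "outer": "LA"}
    return {"inner": "LA", "outer": "RA"}


def count_steps(ankle_trace: YawTrace, window: Tuple[float, float],
                direction: Direction, ankle_role: str,
                config: DetectionConfig | None = None) -> List[StepEvent]:
    """Steps within one lower-back turn from an ankle yaw trace.

    Within the turn window padded by ``step_pad_s`` on both sides (ankle
    rotation can lag the trunk), every same-sign rotation of at least 30 deg
    in the turn's direction counts as one step.  Rotations are the raw
    zero-crossing segments: successive steps are separated by stance pauses
    shorter than the gradual-turn gap, so merging would wrongly fuse them.
    """
    cfg = config or DetectionConfig()
    lo = window[0] - cfg.step_pad_s
    hi = window[1] + cfg.step_pad_s
    mask = (ankle_trace.t >= lo) & (ankle_trace.t <= hi)
    if not np.any(mask):
        return []
    sub = YawTrace(
        location=ankle_trace.location,
        t=ankle_trace.t[mask],
        psi=ankle_trace.psi[mask],
        omega_vt=ankle_trace.omega_vt[mask],
        fs=ankle_trace.fs,
    )
    want = 1 if direction == Direction.RIGHT else -1
    steps = []
    for seg in zero_crossing_segments(sub, cfg.deadband_dps):
        if seg.sign == want and abs(seg.angle_deg) >= cfg.step_min_angle:
            steps.append(
                StepEvent(
                    ankle_role=ankle_role,
                    start_s=seg.start_s,
                    end_s=seg.end_s,
                    angle_deg=seg.angle_deg,
                )
            )
    return steps


def subturn_events(turn: TurnEvent) -> List[TurnEvent]:
    """Expand a merged turn back into its sub-turn events (bookkeeping aid)."""
    return [
        replace(turn, start_s=s, end_s=e, angle_deg=a, subturns=((s, e, a),))
        for (s, e, a) in turn.subturns
    ]
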