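"""Core datatypes shared across turnkit modules.

Axis convention: every tri-axial array is ordered (VT, AP, ML) — vertical,
anterior-posterior, mediolateral — regardless of how the sensor was mounted;
the session sidecar declares the sensor-axis -> anatomical mapping and
:mod:`turnkit.io_formats` applies it on load.

Sign convention: yaw is the rotation angle about the anatomical vertical
axis; a left turn carries a negative angle, a right turn a positive one.

Time convention: seconds, 0-based at the session origin; events are
half-open intervals ``[start_s, end_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

#: The five sensor locations: head, neck (C7), lower back (L5), left/right ankle.
LOCATIONS = ("HD", "C7", "L5", "LA", "RA")
UPPER_BODY = ("HD", "C7", "L5")
ANKLES = ("LA", "RA")


class Direction(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


def direction_from_angle(angle_deg: float) -> Direction:
    """Left turn if the signed angle is negative, right otherwise."""
    return Direction.LEFT if angle_deg < 0 else Direction.RIGHT


@dataclass
class ImuRecording:
    """One location's synchronized tri-axial accel/gyro/mag streams.

    Units: ``t`` seconds, ``acc`` g, ``gyr`` deg/s, ``mag`` Gauss; all
    channel arrays are shaped ``(3, N)`` in VT/AP/ML order. ``mag`` may be
    None (magnetometer absent); ankle fusion then degrades to 6-DOF.
    """

    location: str
    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    mag: Optional[np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        n = self.t.size
        if n < 2:
            raise ValueError("recording needs at least 2 samples")
        for name in ("acc", "gyr", "mag"):
            arr = getattr(self, name)
            if arr is None:
                continue
            if arr.shape != (3, n):
                raise ValueError(f"{name} must be (3, {n}), got {arr.shape}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time vector must be strictly increasing")
        if abs(np.median(dt) - 1.0 / self.fs) >= 0.1 / self.fs:
            raise ValueError(
                f"median sample interval {np.median(dt):.6g}s inconsistent "
                f"with fs={self.fs} Hz"
            )

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class SensorArraySession:
    """A subject's full sensor-array recording (map location -> ImuRecording).

    The L5 (lower back) recording is required: it drives primary turn
    detection. All recordings share the session time origin.
    """

    recordings: dict
    subject_id: str
    group_label: Optional[str] = None  # "PD" or "CL"

    def __post_init__(self) -> None:
        if "L5" not in self.recordings:
            raise ValueError("session must contain an L5 (lower back) recording")
        if self.group_label is not None and self.group_label not in ("PD", "CL"):
            raise ValueError(f"group_label must be PD or CL, got {self.group_label!r}")

    def __getitem__(self, location: str) -> ImuRecording:
        return self.recordings[location]

    def __contains__(self, location: str) -> bool:
        return location in self.recordings


@dataclass
class EventAnnotation:
    """A rater's annotation of one turn (video frame times in seconds)."""

    turn_index: int
    start_s: float
    end_s: float
    rater_id: str
    direction: Direction = Direction.UNKNOWN

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")


@dataclass
class YawTrace:
    """Yaw angle about the vertical axis for one location.

    ``psi`` in degrees with ``psi[0] == 0`` by convention; ``omega_vt`` the
    bias-corrected vertical angular velocity in deg/s.
    """

    location: str
    t: np.ndarray
    psi: np.ndarray
    omega_vt: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega_vt = np.asarray(self.omega_vt, dtype=float)
        if not (self.t.size == self.psi.size == self.omega_vt.size):
            raise ValueError("t, psi, omega_vt must have equal length")


@dataclass
class TurnEvent:
    """A detected turn: signed angle, bounds, and its merged sub-turns."""

    location: str
    start_s: float
    end_s: float
    angle_deg: float
    subturns: tuple = ()  # tuple of (start_s, end_s, angle_deg)
    n_subturns: int = 0

    def __post_init__(self) -> None:
        if not self.subturns and self.n_subturns == 0:
            self.n_subturns = 1
        elif self.subturns:
            self.n_subturns = len(self.subturns)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def direction(self) -> Direction:
        return direction_from_angle(self.angle_deg)


@dataclass
class StepEvent:
    """One ankle rotation >= 30 deg within a turn window (a step/transition)."""

    ankle_role: str  # "inner" or "outer"
    start_s: float
    end_s: float
    angle_deg: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s
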