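"""Yaw estimation per sensor location.

Upper-body locations (head HD, neck C7, lower back L5) move slowly enough
that a *compensation* approach works: estimate the constant gyroscope bias
from the stillest window of the trace, subtract it, and integrate the
vertical angular velocity to yaw. Ankles move too fast for reliable bias
estimation, so their yaw comes from full 9-DOF sensor fusion
(accelerometer + gyroscope + magnetometer) with a gradient-descent
quaternion filter; with no magnetometer the filter degrades to 6-DOF
(gravity-only correction) with a warning.

All yaw traces are re-zeroed at the first sample: only yaw *displacement*
(the turn angle) is meaningful here, not absolute heading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .types import ANKLES, ImuRecording, UPPER_BODY, YawTrace

__all__ = [
    "OrientationConfig",
    "compensate_gyro",
    "integrate_yaw",
    "fuse_orientation_9dof",
    "estimate_yaw",
]


@dataclass
class OrientationConfig:
    """Tunables for yaw estimation.

    static_window_s: length of the low-motion window used for bias
        estimation (s). 2 s at 128 Hz gives 256 samples, enough to average
        gyro noise well below typical bias magnitudes.
    still_var_threshold_dps2: a window qualifies as "still" if the variance
        of the gyro magnitude within it is below this value ((deg/s)^2).
    highpass_enabled / highpass_cutoff_hz: optional zero-phase high-pass on
        the corrected vertical angular velocity to scrub residual
        sub-0.02 Hz drift; off by default (constant-bias removal suffices
        when the bias is stable over a trace).
    madgwick_beta: gradient-descent gain of the fusion filter (rad/s of
        gyro-error it can absorb); 0.1 balances convergence and noise.
    """

    static_window_s: float = 2.0
    still_var_threshold_dps2: float = 4.0
    highpass_enabled: bool = False
    highpass_cutoff_hz: float = 0.02
    madgwick_beta: float = 0.1


def compensate_gyro(rec: ImuRecording, static_window_s: float = 2.0,
                    config: OrientationConfig | None = None) -> np.ndarray:
    """Return bias-corrected gyro streams (3, N) in deg/s for HD/C7/L5.

    The per-axis constant bias is the mean over the window of length
    ``static_window_s`` with minimum moving variance of the gyro magnitude.
    If no window is still enough, falls back to the whole-trace per-axis
    median with a warning.
    """
    cfg = config or OrientationConfig(static_window_s=static_window_s)
    gyr = rec.gyr
    n = gyr.shape[1]
    w = max(2, int(round(cfg.static_window_s * rec.fs)))
    if n < w:
        raise ValueError(
            f"recording shorter ({n / rec.fs:.2f}s) than static window "
            f"({cfg.static_window_s}s)"
        )
    mag = np.linalg.norm(gyr, axis=0)
    mean = _moving_mean(mag, w)
    var = _moving_mean(mag**2, w) - mean**2
    i0 = int(np.argmin(var))
    if var[i0] < cfg.still_var_threshold_dps2:
        bias = gyr[:, i0:i0 + w].mean(axis=1)
    else:
        warnings.warn(
            "no still window found; falling back to whole-trace median bias"
        )
        bias = np.median(gyr, axis=1)
    corrected = gyr - bias[:, None]
    if cfg.highpass_enabled:
        b, a = butter(2, cfg.highpass_cutoff_hz, btype="highpass", fs=rec.fs)
        corrected = np.vstack([filtfilt(b, a, row) for row in corrected])
    return corrected


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Mean of each length-w window; output length N - w + 1."""
    c = np.concatenate(([0.0], np.cumsum(x)))
    return (c[w:] - c[:-w]) / w


def integrate_yaw(omega_vt: np.ndarray, fs: float, t: np.ndarray | None = None,
                  location: str = "L5") -> YawTrace:
    """Cumulative trapezoidal integration of vertical angular velocity.

    ``omega_vt`` in deg/s (bias-corrected); yields yaw in degrees with
    ``psi[0] = 0``.
    """
    omega_vt = np.asarray(omega_vt, dtype=float)
    if np.any(~np.isfinite(omega_vt)):
        raise ValueError("omega_vt contains NaN/inf samples")
    if t is None:
        t = np.arange(omega_vt.size) / fs
    psi = cumulative_trapezoid(omega_vt, t, initial=0.0)
    return YawTrace(location=location, t=np.asarray(t, float), psi=psi,
                    omega_vt=omega_vt, fs=fs)


# -- 9-DOF quaternion fusion --------------------------------------------------
#
# Gradient-descent orientation filter (Madgwick-style). Quaternion q = (w,x,y,z)
# rotates the sensor frame into the earth frame; earth z is up, gravity
# measured as +1 g along sensor z at rest; the magnetic reference is
# constrained to the earth x-z plane each step.  The filter is fully
# deterministic (no RNG).


def _madgwick_update(q: np.ndarray, gyr_rad: np.ndarray, acc: np.ndarray,
                     mag: np.ndarray | None, beta: float, dt: float) -> np.ndarray:
    q1, q2, q3, q4 = q
    gx, gy, gz = gyr_rad

    # quaternion rate from gyroscope
    qdot = 0.5 * np.array([
        -q2 * gx - q3 * gy - q4 * gz,
        q1 * gx + q3 * gz - q4 * gy,
        q1 * gy - q2 * gz + q4 * gx,
        q1 * gz + q2 * gy - q3 * gx,
    ])

    an = np.linalg.norm(acc)
    if an > 0:
        ax, ay, az = acc / an
        f_g = np.array([
            2 * (q2 * q4 - q1 * q3) - ax,
            2 * (q1 * q2 + q3 * q4) - ay,
            2 * (0.5 - q2**2 - q3**2) - az,
        ])
        J_g = np.array([
            [-2 * q3, 2 * q4, -2 * q1, 2 * q2],
            [2 * q2, 2 * q1, 2 * q4, 2 * q3],
            [0.0, -4 * q2, -4 * q3, 0.0],
        ])
        step = J_g.T @ f_g

        mn = np.linalg.norm(mag) if mag is not None else 0.0
        if mn > 0:
            mx, my, mz = mag / mn
            # earth-frame flux, then constrain to x-z plane
            hx = 2 * mx * (0.5 - q3**2 - q4**2) + 2 * my * (q2 * q3 - q1 * q4) \
                + 2 * mz * (q2 * q4 + q1 * q3)
            hy = 2 * mx * (q2 * q3 + q1 * q4) + 2 * my * (0.5 - q2**2 - q4**2) \
                + 2 * mz * (q3 * q4 - q1 * q2)
            hz = 2 * mx * (q2 * q4 - q1 * q3) + 2 * my * (q1 * q2 + q3 * q4) \
                + 2 * mz * (0.5 - q2**2 - q3**2)
            bx = np.hypot(hx, hy)
            bz = hz
            f_b = np.array([
                2 * bx * (0.5 - q3**2 - q4**2) + 2 * bz * (q2 * q4 - q1 * q3) - mx,
                2 * bx * (q2 * q3 - q1 * q4) + 2 * bz * (q1 * q2 + q3 * q4) - my,
                2 * bx * (q1 * q3 + q2 * q4) + 2 * bz * (0.5 - q2**2 - q3**2) - mz,
            ])
            J_b = np.array([
                [-2 * bz * q3, 2 * bz * q4,
                 -4 * bx * q3 - 2 * bz * q1, -4 * bx * q4 + 2 * bz * q2],
                [-2 * bx * q4 + 2 * bz * q2, 2 * bx * q3 + 2 * bz * q1,
                 2 * bx * q2 + 2 * bz * q4, -2 * bx * q1 + 2 * bz * q3],
                [2 * bx * q3, 2 * bx * q4 - 4 * bz * q2,
                 2 * bx * q1 - 4 * bz * q3, 2 * bx * q2],
            ])
            step = step + J_b.T @ f_b

        norm = np.linalg.norm(step)
        if norm > 0:
            qdot -= beta * step / norm

    q = q + qdot * dt
    return q / np.linalg.norm(q)


def fuse_orientation_9dof(rec: ImuRecording,
                          config: OrientationConfig | None = None) -> YawTrace:
    """Quaternion-fusion yaw for ankle recordings (LA/RA).

    Yaw is extracted from the fused quaternion, unwrapped across the +-180
    degree branch cut, and re-zeroed at the trace start; ``omega_vt`` is the
    time derivative of the fused yaw. Without magnetometer data the filter
    runs in 6-DOF mode (gravity correction only) with a warning.
    """
    cfg = config or OrientationConfig()
    if rec.mag is None:
        warnings.warn(
            f"{rec.location}: magnetometer absent, degrading to 6-DOF fusion"
        )
    # sensor axes for fusion: x=AP, y=ML, z=VT so that earth z is vertical
    acc = rec.acc[[1, 2, 0], :]
    gyr = np.deg2rad(rec.gyr[[1, 2, 0], :])
    mag = rec.mag[[1, 2, 0], :] if rec.mag is not None else None

    q = _initial_quaternion(acc[:, 0], mag[:, 0] if mag is not None else None)
    dt_all = np.diff(rec.t)
    n = rec.n_samples
    psi = np.empty(n)
    psi[0] = _yaw_from_quaternion(q)
    for i in range(1, n):
        q = _madgwick_update(
            q, gyr[:, i], acc[:, i],
            mag[:, i] if mag is not None else None,
            cfg.madgwick_beta, dt_all[i - 1],
        )
        psi[i] = _yaw_from_quaternion(q)
    psi = np.rad2deg(np.unwrap(psi))
    psi -= psi[0]
    omega_vt = np.gradient(psi, rec.t)
    return YawTrace(location=rec.location, t=rec.t, psi=psi,
                    omega_vt=omega_vt, fs=rec.fs)


def _yaw_from_quaternion(q: np.ndarray) -> float:
    """Yaw (radians) about earth z for a sensor-to-earth quaternion (w,x,y,z)."""
    w, x, y, z = q
    return np.arctan2(2 * (w * z + x * y), 1 - 2 * (y**2 + z**2))


def _initial_quaternion(acc0: np.ndarray, mag0: np.ndarray | None) -> np.ndarray:
    """Level-assumption initialisation: heading from the first mag sample."""
    if mag0 is not None and np.linalg.norm(mag0[:2]) > 0:
        psi0 = np.arctan2(-mag0[1], mag0[0])
    else:
        psi0 = 0.0
    return np.array([np.cos(psi0 / 2), 0.0, 0.0, np.sin(psi0 / 2)])


def estimate_yaw(rec: ImuRecording,
                 config: OrientationConfig | None = None) -> YawTrace:
    """Location-appropriate yaw: bias-compensated integration for the upper
    body, 9-DOF fusion for the ankles."""
    cfg = config or OrientationConfig()
    if rec.location in UPPER_BODY:
        corrected = compensate_gyro(rec, cfg.static_window_s, cfg)
        return integrate_yaw(corrected[0], rec.fs, rec.t, rec.location)
    if rec.location in ANKLES:
        return fuse_orientation_9dof(rec, cfg)
    raise ValueError(f"unknown location {rec.location!r}")
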