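"""Turning-characteristic extraction: the pinned 425-feature schema.

Per upper-body location (head HD, neck C7, lower back L5): 21 spatiotemporal
and 88 signal-based characteristics (109 each, 327 total). Per ankle role
(inner, outer): 9 spatiotemporal and 40 signal-based (49 each). Grand total
425. The schema is pinned in :func:`feature_manifest` and asserted in tests;
it is the single source of truth for feature identity and column order.

Spatiotemporal characteristics summarise the detected turn events (times,
angles, angular velocity theta/T in deg/s, angular frequency in rad/s over
0.1 s windows at the start, mid and end of each turn). "Variability" is the
sample standard deviation across turns.

Signal-based characteristics are computed per turn window and averaged over
turns: each axis (VT, AP, ML and the resultant R = sqrt(VT^2+AP^2+ML^2)) of
the accelerometer (g) and gyroscope (converted to rad/s) is linearly
detrended over the window and low-pass filtered (zero-phase 4th-order
Butterworth, 20 Hz cut-off) before RMS, jerk (da/dt, g/s) and angular
acceleration (domega/dt, rad/s^2) statistics are taken. Phase windows
(start/mid/end) default to equal thirds of the turn; a 0.1 s window mode is
available via :class:`FeaturesConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, detrend, filtfilt

from .pipeline import SessionAnalysis, analyze_session
from .types import (
    Direction,
    ImuRecording,
    SensorArraySession,
    StepEvent,
    TurnEvent,
    UPPER_BODY,
    YawTrace,
)

__all__ = [
    "FeaturesConfig",
    "FeatureEntry",
    "FeatureManifest",
    "FeatureVector",
    "feature_manifest",
    "extract_spatiotemporal",
    "extract_signal",
    "extract_session_features",
    "build_feature_matrix",
]

AXES = ("VT", "AP", "ML", "R")
PHASES = ("overall", "start", "mid", "end")
ROLES = ("inner", "outer")
DEG2RAD = np.pi / 180.0


@dataclass
class FeaturesConfig:
    """Signal-feature tunables.

    phase_mode: "thirds" splits each turn into three equal sub-windows for
        the start/mid/end signal statistics; "window" uses ``phase_window_s``
        second windows anchored at the turn start, midpoint and end.
    freq_window_s: window length for the spatiotemporal angular-frequency
        characteristics (always anchored windows, 0.1 s).
    lowpass_cutoff_hz / lowpass_order: Butterworth low-pass applied forward
        and backward (zero phase) to each detrended turn window.
    """

    phase_mode: str = "thirds"
    phase_window_s: float = 0.1
    freq_window_s: float = 0.1
    lowpass_cutoff_hz: float = 20.0
    lowpass_order: int = 4


@dataclass(frozen=True)
class FeatureEntry:
    feature_id: str
    location: str  # HD/C7/L5 or inner/outer
    category: str  # spatiotemporal | signal
    axis: str      # VT/AP/ML/R/none
    phase: str     # overall/start/mid/end/none
    statistic: str


@dataclass
class FeatureManifest:
    entries: List[FeatureEntry]

    @property
    def feature_ids(self) -> List[str]:
        return [e.feature_id for e in self.entries]

    def subset(self, locations: Optional[Sequence[str]] = None,
               category: Optional[str] = None) -> List[str]:
        """Feature ids filtered by location/role and category."""
        ids = []
        for e in self.entries:
            if locations is not None and e.location not in locations:
                continue
            if category is not None and category != "all" and e.category != category:
                continue
            ids.append(e.feature_id)
        return ids

    def counts(self) -> Dict[str, Dict[str, int]]:
        out: Dict[str, Dict[str, int]] = {}
        for e in self.entries:
            out.setdefault(e.location, {"spatiotemporal": 0, "signal": 0})
            out[e.location][e.category] += 1
        return out


@dataclass
class FeatureVector:
    subject_id: str
    values: Dict[str, float]
    n_turns_used: int


_STAT4 = ("mean", "min", "max", "sd")
_STAT2 = ("mean", "sd")
_JERK_STATS = ("rms", "max", "min", "range")


def feature_manifest() -> FeatureManifest:
    """The pinned 425-entry schema, in canonical column order."""
    entries: List[FeatureEntry] = []

    def add(fid, loc, cat, axis="none", phase="none", stat=""):
        entries.append(FeatureEntry(fid, loc, cat, axis, phase, stat))

    for loc in UPPER_BODY:
        # -- 21 spatiotemporal
        add(f"{loc}_n_turns", loc, "spatiotemporal", stat="count")
        add(f"{loc}_n_left", loc, "spatiotemporal", stat="count")
        add(f"{loc}_n_right", loc, "spatiotemporal", stat="count")
        for s in _STAT4:
            add(f"{loc}_turn_time_{s}", loc, "spatiotemporal", stat=s)
        for s in _STAT4:
            add(f"{loc}_turn_angle_{s}", loc, "spatiotemporal", stat=s)
        for s in _STAT2:
            add(f"{loc}_angular_velocity_{s}", loc, "spatiotemporal", stat=s)
        for s in _STAT2:
            add(f"{loc}_peak_angular_frequency_{s}", loc, "spatiotemporal", stat=s)
        for ph in ("start", "mid", "end"):
            for s in _STAT2:
                add(f"{loc}_angular_frequency_{ph}_{s}", loc, "spatiotemporal",
                    phase=ph, stat=s)
        # -- 88 signal-based
        for sig in ("acc", "gyr"):
            for ax in AXES:
                for ph in PHASES:
                    add(f"{loc}_{sig}_rms_{ax}_{ph}", loc, "signal", ax, ph, "rms")
        for deriv in ("jerk", "angacc"):
            for st in _JERK_STATS:
                for ax in AXES:
                    add(f"{loc}_{deriv}_{st}_{ax}_overall", loc, "signal", ax,
                        "overall", st)
            for ph in ("start", "mid", "end"):
                for ax in AXES:
                    add(f"{loc}_{deriv}_rms_{ax}_{ph}", loc, "signal", ax, ph, "rms")

    for role in ROLES:
        # -- 9 spatiotemporal
        for s in _STAT4:
            add(f"{role}_step_angle_{s}", role, "spatiotemporal", stat=s)
        for s in _STAT2:
            add(f"{role}_step_duration_{s}", role, "spatiotemporal", stat=s)
        for s in _STAT2:
            add(f"{role}_step_angular_velocity_{s}", role, "spatiotemporal", stat=s)
        add(f"{role}_steps_per_turn_mean", role, "spatiotemporal", stat="mean")
        # -- 40 signal-based (overall phase only: ankle activity inside a
        # turn is a burst of discrete steps, so phase splits are not stable)
        for sig in ("acc", "gyr"):
            for ax in AXES:
                add(f"{role}_{sig}_rms_{ax}_overall", role, "signal", ax,
                    "overall", "rms")
        for deriv in ("jerk", "angacc"):
            for st in _JERK_STATS:
                for ax in AXES:
                    add(f"{role}_{deriv}_{st}_{ax}_overall", role, "signal", ax,
                        "overall", st)

    return FeatureManifest(entries)


def _sd(x: np.ndarray) -> float:
    """Across-turn variability: sample SD, 0 for a single observation."""
    x = np.asarray(x, float)
    return float(np.std(x, ddof=1)) if x.size >= 2 else 0.0


def _window_mask(t: np.ndarray, lo: float, hi: float) -> slice:
    i0 = int(np.searchsorted(t, lo, side="left"))
    i1 = int(np.searchsorted(t, hi, side="right"))
    return slice(i0, i1)


def _nan_features(ids: Sequence[str]) -> Dict[str, float]:
    return {fid: float("nan") for fid in ids}


# -- spatiotemporal ----------------------------------------------------------

def extract_spatiotemporal(turns: Sequence[TurnEvent],
                           steps: Optional[Sequence[Sequence[StepEvent]]],
                           location: str,
                           trace: Optional[YawTrace] = None,
                           config: Optional[FeaturesConfig] = None) -> Dict[str, float]:
    """Spatiotemporal characteristics for one location or ankle role.

    For upper-body locations ``turns`` are that location's turn events and
    ``trace`` its yaw trace (needed for the angular-frequency features);
    ``steps`` is ignored. For roles ``inner``/``outer``, ``turns`` are the
    accepted L5 turns and ``steps`` the per-turn step-event lists.
    Zero accepted turns yields all-NaN.
    """
    cfg = config or FeaturesConfig()
    manifest = feature_manifest()
    ids = manifest.subset(locations=[location], category="spatiotemporal")
    if location in ROLES:
        return _spatiotemporal_role(turns, steps or [], location, ids)
    if not turns:
        return _nan_features(ids)
    if trace is None:
        raise ValueError("upper-body spatiotemporal features need the yaw trace")

    durations = np.array([tu.duration_s for tu in turns])
    angles = np.array([abs(tu.angle_deg) for tu in turns])
    angvel = angles / durations  # deg/s, theta / T

    peaks, ph_freq = [], {ph: [] for ph in ("start", "mid", "end")}
    for tu in turns:
        sl = _window_mask(trace.t, tu.start_s, tu.end_s)
        om = np.abs(trace.omega_vt[sl])
        peaks.append(np.max(om) * DEG2RAD if om.size else np.nan)
        w = cfg.freq_window_s
        anchors = {
            "start": (tu.start_s, tu.start_s + w),
            "mid": ((tu.start_s + tu.end_s - w) / 2, (tu.start_s + tu.end_s + w) / 2),
            "end": (tu.end_s - w, tu.end_s),
        }
        for ph, (lo, hi) in anchors.items():
            sw = _window_mask(trace.t, lo, hi)
            seg = np.abs(trace.omega_vt[sw])
            ph_freq[ph].append(np.mean(seg) * DEG2RAD if seg.size else np.nan)

    out = {
        f"{location}_n_turns": float(len(turns)),
        f"{location}_n_left": float(sum(tu.direction == Direction.LEFT for tu in turns)),
        f"{location}_n_right": float(sum(tu.direction == Direction.RIGHT for tu in turns)),
        f"{location}_turn_time_mean": float(np.mean(durations)),
        f"{location}_turn_time_min": float(np.min(durations)),
        f"{location}_turn_time_max": float(np.max(durations)),
        f"{location}_turn_time_sd": _sd(durations),
        f"{location}_turn_angle_mean": float(np.mean(angles)),
        f"{location}_turn_angle_min": float(np.min(angles)),
        f"{location}_turn_angle_max": float(np.max(angles)),
        f"{location}_turn_angle_sd": _sd(angles),
        f"{location}_angular_velocity_mean": float(np.mean(angvel)),
        f"{location}_angular_velocity_sd": _sd(angvel),
        f"{location}_peak_angular_frequency_mean": float(np.nanmean(peaks)),
        f"{location}_peak_angular_frequency_sd": _sd(peaks),
    }
    for ph in ("start", "mid", "end"):
        out[f"{location}_angular_frequency_{ph}_mean"] = float(np.nanmean(ph_freq[ph]))
        out[f"{location}_angular_frequency_{ph}_sd"] = _sd(ph_freq[ph])
    assert set(out) == set(ids)
    return out


def _spatiotemporal_role(l5_turns, steps_by_turn, role, ids) -> Dict[str, float]:
    all_steps: List[StepEvent] = [s for per_turn in steps_by_turn for s in per_turn]
    if not l5_turns or not all_steps:
        return _nan_features(ids)
    angles = np.array([abs(s.angle_deg) for s in all_steps])
    durs = np.array([s.duration_s for s in all_steps])
    with np.errstate(divide="ignore"):
        av = angles / durs
    counts = np.array([len(per_turn) for per_turn in steps_by_turn], float)
    return {
        f"{role}_step_angle_mean": float(np.mean(angles)),
        f"{role}_step_angle_min": float(np.min(angles)),
        f"{role}_step_angle_max": float(np.max(angles)),
        f"{role}_step_angle_sd": _sd(angles),
        f"{role}_step_duration_mean": float(np.mean(durs)),
        f"{role}_step_duration_sd": _sd(durs),
        f"{role}_step_angular_velocity_mean": float(np.mean(av)),
        f"{role}_step_angular_velocity_sd": _sd(av),
        f"{role}_steps_per_turn_mean": float(np.mean(counts)),
    }


# -- signal-based ------------------------------------------------------------

def _preprocess_window(arr3: np.ndarray, fs: float, cfg: FeaturesConfig,
                       do_detrend: bool = True) -> np.ndarray:
    """Optionally detrend, then zero-phase low-pass each axis; stack resultant.

    Returns a (4, M) array ordered VT, AP, ML, R. Detrending is applied for
    amplitude (RMS) statistics only: derivatives (jerk, angular
    acceleration) are taken on the filtered signal directly, because
    removing a linear trend would also remove the very rate-of-change those
    statistics measure.
    """
    x = detrend(arr3, axis=1, type="linear") if do_detrend else np.asarray(arr3, float)
    if cfg.lowpass_cutoff_hz < fs / 2:
        b, a = butter(cfg.lowpass_order, cfg.lowpass_cutoff_hz, fs=fs)
        padlen = min(3 * (max(len(a), len(b)) - 1), x.shape[1] - 1)
        x = filtfilt(b, a, x, axis=1, padlen=padlen)
    r = np.linalg.norm(x, axis=0)
    return np.vstack([x, r])


def _phase_slices(m: int, fs: float, cfg: FeaturesConfig) -> Dict[str, slice]:
    if cfg.phase_mode == "thirds":
        a, b = m // 3, 2 * m // 3
        return {"overall": slice(0, m), "start": slice(0, a),
                "mid": slice(a, b), "end": slice(b, m)}
    w = max(1, int(round(cfg.phase_window_s * fs)))
    mid0 = max(0, (m - w) // 2)
    return {
        "overall": slice(0, m),
        "start": slice(0, min(w, m)),
        "mid": slice(mid0, min(mid0 + w, m)),
        "end": slice(max(0, m - w), m),
    }


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if x.size else float("nan")


def _turn_signal_stats(rec: ImuRecording, turn: TurnEvent,
                       cfg: FeaturesConfig, role_prefix: str,
                       overall_only: bool) -> Optional[Dict[str, float]]:
    sl = _window_mask(rec.t, turn.start_s, turn.end_s)
    m = sl.stop - sl.start
    if m < 3:
        warnings.warn(f"turn window at {turn.start_s:.2f}s shorter than 3 samples; skipped")
        return None
    acc = _preprocess_window(rec.acc[:, sl], rec.fs, cfg)
    gyr = _preprocess_window(rec.gyr[:, sl] * DEG2RAD, rec.fs, cfg)
    dt = 1.0 / rec.fs
    jerk = np.gradient(
        _preprocess_window(rec.acc[:, sl], rec.fs, cfg, do_detrend=False),
        dt, axis=1)
    angacc = np.gradient(
        _preprocess_window(rec.gyr[:, sl] * DEG2RAD, rec.fs, cfg, do_detrend=False),
        dt, axis=1)
    phases = _phase_slices(m, rec.fs, cfg)
    if overall_only:
        phases = {"overall": phases["overall"]}

    out: Dict[str, float] = {}
    for name, sig in (("acc", acc), ("gyr", gyr)):
        for k, ax in enumerate(AXES):
            for ph, psl in phases.items():
                out[f"{role_prefix}_{name}_rms_{ax}_{ph}"] = _rms(sig[k, psl])
    for name, sig in (("jerk", jerk), ("angacc", angacc)):
        for k, ax in enumerate(AXES):
            x = sig[k]
            out[f"{role_prefix}_{name}_rms_{ax}_overall"] = _rms(x)
            out[f"{role_prefix}_{name}_max_{ax}_overall"] = float(np.max(x))
            out[f"{role_prefix}_{name}_min_{ax}_overall"] = float(np.min(x))
            out[f"{role_prefix}_{name}_range_{ax}_overall"] = float(np.ptp(x))
            if not overall_only:
                for ph in ("start", "mid", "end"):
                    out[f"{role_prefix}_{name}_rms_{ax}_{ph}"] = _rms(x[phases[ph]])
    return out


def extract_signal(rec, turns: Sequence[TurnEvent], location: str,
                   config: Optional[FeaturesConfig] = None,
                   role_map_by_turn: Optional[Sequence[Dict[str, str]]] = None
                   ) -> Dict[str, float]:
    """Signal-based characteristics, averaged over turns.

    For upper-body locations ``rec`` is that location's recording and
    ``turns`` its turn events. For roles ``inner``/``outer``, ``rec`` is a
    mapping ``{"LA": rec, "RA": rec}``, ``turns`` the accepted L5 turns and
    ``role_map_by_turn`` the per-turn role assignment (which ankle was
    inner/outer for each turn).
    """
    cfg = config or FeaturesConfig()
    ids = feature_manifest().subset(locations=[location], category="signal")
    if not turns:
        return _nan_features(ids)

    per_turn: List[Dict[str, float]] = []
    if location in ROLES:
        if role_map_by_turn is None:
            raise ValueError("role signal features need role_map_by_turn")
        for turn, roles in zip(turns, role_map_by_turn):
            ankle = roles[location]
            if ankle not in rec or rec[ankle] is None:
                continue
            stats = _turn_signal_stats(rec[ankle], turn, cfg, location, overall_only=True)
            if stats is not None:
                per_turn.append(stats)
    else:
        for turn in turns:
            stats = _turn_signal_stats(rec, turn, cfg, location, overall_only=False)
            if stats is not None:
                per_turn.append(stats)

    if not per_turn:
        return _nan_features(ids)
    out = {}
    for fid in ids:
        out[fid] = float(np.nanmean([d[fid] for d in per_turn]))
    return out


# -- session / cohort level --------------------------------------------------

def extract_session_features(analysis_or_session,
                             config: Optional[FeaturesConfig] = None,
                             detection=None, orientation=None) -> FeatureVector:
    """The full 425-entry feature vector for one session.

    Accepts either a precomputed :class:`SessionAnalysis` or a raw
    :class:`SensorArraySession` (which is analysed first). Features of
    absent locations are NaN, never silent zeros.
    """
    cfg = config or FeaturesConfig()
    if isinstance(analysis_or_session, SessionAnalysis):
        analysis = analysis_or_session
    else:
        analysis = analyze_session(analysis_or_session, detection, orientation)
    session = analysis.session
    values: Dict[str, float] = {}

    for loc in UPPER_BODY:
        if loc in analysis.yaw:
            turns = analysis.turns.get(loc, [])
            values.update(extract_spatiotemporal(turns, None, loc,
                                                 analysis.yaw[loc], cfg))
            values.update(extract_signal(session[loc], turns, loc, cfg))
        else:
            ids = feature_manifest().subset(locations=[loc])
            values.update(_nan_features(ids))

    l5_turns = analysis.l5_turns
    ankle_recs = {a: session.recordings.get(a) for a in ("LA", "RA")}
    for role in ROLES:
        steps_by_turn = [pt.get(role, []) for pt in analysis.steps_by_turn]
        values.update(_spatiotemporal_role(
            l5_turns, steps_by_turn, role,
            feature_manifest().subset(locations=[role], category="spatiotemporal")))
        values.update(extract_signal(ankle_recs, l5_turns, role, cfg,
                                     analysis.role_map_by_turn))

    return FeatureVector(subject_id=session.subject_id, values=values,
                         n_turns_used=len(l5_turns))


def build_feature_matrix(sessions: Sequence, config: Optional[FeaturesConfig] = None,
                         standardize: bool = False,
                         detection=None, orientation=None
                         ) -> Tuple[pd.DataFrame, FeatureManifest]:
    """Subjects x 425 feature matrix with manifest-fixed column order.

    ``sessions`` may be SensorArraySession or SessionAnalysis objects. With
    ``standardize=True`` each non-constant column is z-scored (NaN-aware);
    all-NaN columns are retained and flagged with a warning.
    """
    manifest = feature_manifest()
    rows, index = [], []
    for s in sessions:
        fv = extract_session_features(s, config, detection, orientation)
        rows.append([fv.values[fid] for fid in manifest.feature_ids])
        index.append(fv.subject_id)
    X = pd.DataFrame(rows, index=index, columns=manifest.feature_ids)
    all_nan = [c for c in X.columns if X[c].isna().all()]
    if all_nan:
        warnings.warn(f"{len(all_nan)} all-NaN feature columns retained")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1).replace(0.0, np.nan)
        X = (X - mu) / sd
    return X, manifest
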