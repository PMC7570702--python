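"""Plain-text session, event and annotation file formats.

A *session directory* holds one CSV per sensor location plus a JSON sidecar::

    session_dir/
        session.json        # subject_id, group_label, fs, units, axis_map
        L5.csv              # t,ax,ay,az,gx,gy,gz[,mx,my,mz]
        HD.csv  C7.csv  LA.csv  RA.csv   (any subset; L5 is mandatory)

The sidecar must declare units (no silent guessing): ``time`` in ``s`` or
``ms``; ``acc`` in ``g`` or ``m/s2``; ``gyr`` in ``deg/s`` or ``rad/s``;
``mag`` in ``gauss`` or ``uT``. ``axis_map`` maps anatomical axes to signed
sensor columns, e.g. ``{"VT": "-z", "AP": "x", "ML": "y"}``; it may be given
once or per location. Internally everything is converted to the package
units (s, g, deg/s, Gauss) and VT/AP/ML channel order.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .types import (
    Direction,
    EventAnnotation,
    ImuRecording,
    LOCATIONS,
    SensorArraySession,
    TurnEvent,
)

__all__ = [
    "read_session",
    "write_session",
    "read_events",
    "write_events",
    "read_annotations",
    "write_annotations",
    "ImuRecording",
    "SensorArraySession",
    "EventAnnotation",
]

_G = 9.80665  # m/s^2 per g
_UNIT_FACTORS = {
    "time": {"s": 1.0, "ms": 1e-3},
    "acc": {"g": 1.0, "m/s2": 1.0 / _G},
    "gyr": {"deg/s": 1.0, "rad/s": 180.0 / np.pi},
    "mag": {"gauss": 1.0, "uT": 0.01},
}
_DEFAULT_AXIS_MAP = {"VT": "x", "AP": "y", "ML": "z"}
_SENSOR_COLS = {"acc": ("ax", "ay", "az"), "gyr": ("gx", "gy", "gz"), "mag": ("mx", "my", "mz")}


def _axis_columns(axis_map: dict, prefix_cols: tuple) -> list:
    """Resolve an anatomical axis map to (column, sign) pairs in VT/AP/ML order."""
    out = []
    for axis in ("VT", "AP", "ML"):
        spec = axis_map[axis]
        sign = -1.0 if spec.startswith("-") else 1.0
        letter = spec.lstrip("+-")
        if letter not in ("x", "y", "z"):
            raise ValueError(f"axis_map entry {spec!r} must name x, y or z")
        out.append((prefix_cols["xyz".index(letter)], sign))
    return out


def _unit_factor(kind: str, unit: str) -> float:
    try:
        return _UNIT_FACTORS[kind][unit]
    except KeyError:
        raise ValueError(f"unsupported {kind} unit {unit!r}") from None


def read_session(path) -> SensorArraySession:
    """Load a session directory into a :class:`SensorArraySession`.

    Raises if the sidecar or its units are missing, if the L5 file is absent,
    or if any time vector is non-monotonic. A missing non-L5 location loads
    with a warning; operations that need it refuse later.
    """
    path = Path(path)
    sidecar_path = path / "session.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar {sidecar_path} not found")
    meta = json.loads(sidecar_path.read_text())
    if "units" not in meta:
        raise ValueError("sidecar must declare units (time/acc/gyr[/mag])")
    units = meta["units"]
    for kind in ("time", "acc", "gyr"):
        if kind not in units:
            raise ValueError(f"sidecar units must declare {kind!r}")
    fs_nominal = meta.get("fs")
    axis_map_meta = meta.get("axis_map", _DEFAULT_AXIS_MAP)

    recordings = {}
    for loc in LOCATIONS:
        f = path / f"{loc}.csv"
        if not f.exists():
            if loc == "L5":
                raise FileNotFoundError(f"required L5 recording missing in {path}")
            warnings.warn(f"location {loc} missing from session {path.name}")
            continue
        recordings[loc] = _read_recording(f, loc, units, axis_map_meta, fs_nominal)

    return SensorArraySession(
        recordings=recordings,
        subject_id=meta.get("subject_id", path.name),
        group_label=meta.get("group_label"),
    )


def _read_recording(f: Path, loc: str, units: dict, axis_map_meta, fs_nominal) -> ImuRecording:
    df = pd.read_csv(f)
    t = df["t"].to_numpy(float) * _unit_factor("time", units["time"])
    axis_map = axis_map_meta.get(loc, axis_map_meta) if _is_per_location(axis_map_meta) else axis_map_meta

    def gather(kind: str) -> Optional[np.ndarray]:
        cols = _SENSOR_COLS[kind]
        if not all(c in df.columns for c in cols):
            return None
        factor = _unit_factor(kind, units[kind]) if kind in units else None
        if factor is None:
            raise ValueError(f"{f} has {kind} columns but sidecar declares no {kind} unit")
        rows = [sign * df[col].to_numpy(float) * factor for col, sign in _axis_columns(axis_map, cols)]
        return np.vstack(rows)

    acc, gyr, mag = gather("acc"), gather("gyr"), gather("mag")
    if acc is None or gyr is None:
        raise ValueError(f"{f} lacks required accelerometer/gyroscope columns")
    if fs_nominal is not None and units["time"] == "s":
        fs = float(fs_nominal)
    else:
        fs = 1.0 / float(np.median(np.diff(t)))
    return ImuRecording(location=loc, t=t, acc=acc, gyr=gyr, mag=mag, fs=fs)


def _is_per_location(axis_map: dict) -> bool:
    return any(k in LOCATIONS for k in axis_map)


def write_session(session: SensorArraySession, path) -> Path:
    """Write a session directory in package units (s, g, deg/s, Gauss)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    any_rec = next(iter(session.recordings.values()))
    meta = {
        "subject_id": session.subject_id,
        "group_label": session.group_label,
        "fs": any_rec.fs,
        "units": {"time": "s", "acc": "g", "gyr": "deg/s", "mag": "gauss"},
        "axis_map": _DEFAULT_AXIS_MAP,  # internal order written as x=VT, y=AP, z=ML
    }
    (path / "session.json").write_text(json.dumps(meta, indent=2))
    for loc, rec in session.recordings.items():
        cols = {"t": rec.t}
        for kind, arr in (("acc", rec.acc), ("gyr", rec.gyr), ("mag", rec.mag)):
            if arr is None:
                continue
            for cname, row in zip(_SENSOR_COLS[kind], arr):
                cols[cname] = row
        pd.DataFrame(cols).to_csv(path / f"{loc}.csv", index=False, float_format="%.9g")
    return path


# -- turn-event files ---------------------------------------------------------

_EVENT_COLS = ["location", "start_s", "end_s", "angle_deg", "direction", "n_subturns"]


def write_events(events: List[TurnEvent], path) -> Path:
    """Write detected turns as CSV; events must be sorted by start time."""
    rows = []
    by_loc: dict = {}
    for ev in events:
        rows.append(
            {
                "location": ev.location,
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "angle_deg": ev.angle_deg,
                "direction": ev.direction.value,
                "n_subturns": ev.n_subturns,
            }
        )
        prev = by_loc.get(ev.location)
        if prev is not None and ev.start_s < prev:
            warnings.warn(f"overlapping events at {ev.location}; preserved as-is")
        by_loc[ev.location] = max(by_loc.get(ev.location, -np.inf), ev.end_s)
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, index=False, float_format="%.9g")
    return Path(path)


def read_events(path) -> List[TurnEvent]:
    df = pd.read_csv(path)
    events = []
    for _, r in df.iterrows():
        ev = TurnEvent(
            location=str(r["location"]),
            start_s=float(r["start_s"]),
            end_s=float(r["end_s"]),
            angle_deg=float(r["angle_deg"]),
            n_subturns=int(r["n_subturns"]),
        )
        if ev.direction.value != r["direction"]:
            warnings.warn(
                f"direction column {r['direction']!r} inconsistent with angle sign; "
                "using the sign convention"
            )
        events.append(ev)
    return events


# -- rater annotation files ---------------------------------------------------

_ANNOT_COLS = ["turn_index", "start_s", "end_s", "rater_id", "direction"]


def write_annotations(annotations: List[EventAnnotation], path) -> Path:
    rows = [
        {
            "turn_index": a.turn_index,
            "start_s": a.start_s,
            "end_s": a.end_s,
            "rater_id": a.rater_id,
            "direction": a.direction.value,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, index=False, float_format="%.9g")
    return Path(path)


def read_annotations(path) -> List[EventAnnotation]:
    df = pd.read_csv(path)
    return [
        EventAnnotation(
            turn_index=int(r["turn_index"]),
            start_s=float(r["start_s"]),
            end_s=float(r["end_s"]),
            rater_id=str(r["rater_id"]),
            direction=Direction(r["direction"]),
        )
        for _, r in df.iterrows()
    ]
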