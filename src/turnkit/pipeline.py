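"""Session-level orchestration: orientation -> turn detection -> steps.

Bundles the per-location yaw traces, detected turns and per-turn ankle step
events into one :class:`SessionAnalysis` that feature extraction and the
CLI consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .orientation import OrientationConfig, estimate_yaw
from .turn_detection import (
    DetectionConfig,
    assign_inner_outer,
    count_steps,
    detect_turns,
)
from .types import ANKLES, SensorArraySession, StepEvent, TurnEvent, YawTrace

__all__ = ["SessionAnalysis", "analyze_session"]


@dataclass
class SessionAnalysis:
    """Everything detected in one session.

    ``steps_by_turn`` has one entry per accepted L5 turn: a mapping
    ``{"inner": [StepEvent...], "outer": [...]}``; ``role_map_by_turn``
    records which physical ankle played each role for that turn.
    """

    session: SensorArraySession
    yaw: Dict[str, YawTrace]
    turns: Dict[str, List[TurnEvent]]
    steps_by_turn: List[Dict[str, List[StepEvent]]] = field(default_factory=list)
    role_map_by_turn: List[Dict[str, str]] = field(default_factory=list)

    @property
    def l5_turns(self) -> List[TurnEvent]:
        return self.turns.get("L5", [])


def analyze_session(session: SensorArraySession,
                    detection: Optional[DetectionConfig] = None,
                    orientation: Optional[OrientationConfig] = None,
                    locations: Optional[Sequence[str]] = None) -> SessionAnalysis:
    """Run yaw estimation and turn detection on every available location.

    ``locations`` restricts processing (e.g. ``["L5"]`` when only lower-back
    boundaries are needed); L5 is always included. Ankle step events are
    computed inside each L5 turn window with the inner/outer role mapping of
    that turn's direction; an absent ankle simply yields no steps for its
    role.
    """
    det = detection or DetectionConfig()
    ori = orientation or OrientationConfig()
    wanted = set(locations) | {"L5"} if locations is not None else set(session.recordings)

    yaw: Dict[str, YawTrace] = {}
    turns: Dict[str, List[TurnEvent]] = {}
    for loc, rec in session.recordings.items():
        if loc not in wanted:
            continue
        trace = estimate_yaw(rec, ori)
        yaw[loc] = trace
        turns[loc] = detect_turns(trace, loc, det)

    steps_by_turn: List[Dict[str, List[StepEvent]]] = []
    role_map_by_turn: List[Dict[str, str]] = []
    for l5_turn in turns.get("L5", []):
        roles = assign_inner_outer(l5_turn)
        per_turn: Dict[str, List[StepEvent]] = {}
        for role, ankle in roles.items():
            if ankle in yaw:
                per_turn[role] = count_steps(
                    yaw[ankle], (l5_turn.start_s, l5_turn.end_s),
                    l5_turn.direction, role, det,
                )
            else:
                per_turn[role] = []
        steps_by_turn.append(per_turn)
        role_map_by_turn.append(roles)

    return SessionAnalysis(
        session=session, yaw=yaw, turns=turns,
        steps_by_turn=steps_by_turn, role_map_by_turn=role_map_by_turn,
    )
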