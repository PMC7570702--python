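"""Run configuration: one JSON document covering every stage's tunables.

Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults); every pipeline run logs the fully resolved configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from .orientation import OrientationConfig
from .turn_detection import DetectionConfig
from .features import FeaturesConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DetectionSettings(_Strict):
    deadband_dps: float = 5.0
    l5_min_angle: float = 90.0
    other_min_angle: float = 30.0
    min_dur: float = 0.5
    max_dur: float = 10.0
    gradual_min_angle: float = 10.0
    gradual_max_gap: float = 0.5
    step_min_angle: float = 30.0
    step_pad_s: float = 0.5

    def to_dataclass(self) -> DetectionConfig:
        return DetectionConfig(**self.model_dump())


class OrientationSettings(_Strict):
    static_window_s: float = 2.0
    still_var_threshold_dps2: float = 4.0
    highpass_enabled: bool = False
    highpass_cutoff_hz: float = 0.02
    madgwick_beta: float = 0.1

    def to_dataclass(self) -> OrientationConfig:
        return OrientationConfig(**self.model_dump())


class FeatureSettings(_Strict):
    phase_mode: str = "thirds"
    phase_window_s: float = 0.1
    freq_window_s: float = 0.1
    lowpass_cutoff_hz: float = 20.0
    lowpass_order: int = 4

    def to_dataclass(self) -> FeaturesConfig:
        return FeaturesConfig(**self.model_dump())


class CohortSettings(_Strict):
    n_pd: int = 10
    n_cl: int = 10


class ClassifySettings(_Strict):
    max_components: int = 10
    n_components: int | None = None


class AgreementSettings(_Strict):
    match_tol_s: float = 2.0


class RunConfig(_Strict):
    """Top-level configuration for ``turnkit run``."""

    seed: int = 0
    detection: DetectionSettings = DetectionSettings()
    orientation: OrientationSettings = OrientationSettings()
    features: FeatureSettings = FeatureSettings()
    cohort: CohortSettings = CohortSettings()
    classify: ClassifySettings = ClassifySettings()
    agreement: AgreementSettings = AgreementSettings()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def dump(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
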