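"""Pipeline configuration: YAML in, validated dataclasses out.

``strict_regime`` pins every defaulted training/windowing field to the
reference regime (30/30 feature windows, length-20 images, 300 epochs,
batch 100, learning rate 0.001); otherwise the desk-scale defaults apply
(identical except 50 epochs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .classifiers import ModelSpec, TrainConfig
from .errors import ConfigError
from .synthetic_gait import AngleParams, GaitScheduleConfig, MusclePhaseProfile


@dataclass
class SimulatorConfig:
    schedule: GaitScheduleConfig = field(default_factory=GaitScheduleConfig)
    profile: MusclePhaseProfile = field(default_factory=MusclePhaseProfile)
    angle: AngleParams = field(default_factory=AngleParams)
    pressure_noise: float = 0.02
    ratio: int = 30
    speed_km_h: float | None = None  # preset overriding cycle_duration_s


@dataclass
class LabelerConfig:
    foot: str = "right"
    smoothing_len: int = 1
    threshold_frac: float = 0.3
    hysteresis_frac: float = 0.05


@dataclass
class FeatureConfig:
    win: int = 30
    step: int = 30
    image_length: int = 20
    image_step: int = 1
    normalize: bool = True


@dataclass
class EvaluationConfig:
    mode: str = "temporal"  # {"temporal", "kfold"}
    train_frac: float = 0.8
    k: int = 5


@dataclass
class PipelineConfig:
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    labeler: LabelerConfig = field(default_factory=LabelerConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    zero_phase_filter: bool = True
    single_information: bool = False
    strict_regime: bool = False
    seed: int = 0

    def resolved(self) -> "PipelineConfig":
        """Apply seed propagation, speed presets and strict-regime pinning."""
        from .synthetic_gait import speed_to_cycle_s

        cfg = self
        cfg.simulator.schedule.seed = cfg.seed
        cfg.training.seed = cfg.seed
        if cfg.simulator.speed_km_h is not None:
            cfg.simulator.schedule.cycle_duration_s = \
                speed_to_cycle_s(cfg.simulator.speed_km_h)
        if cfg.strict_regime:
            cfg.training = cfg.training.strict_regime()
            cfg.features = FeatureConfig(win=30, step=30, image_length=20,
                                         image_step=1,
                                         normalize=cfg.features.normalize)
        self.validate()
        return cfg

    def validate(self) -> None:
        self.simulator.schedule.validate()
        self.simulator.profile.validate()
        self.training.validate()
        self.model.validate()
        if self.evaluation.mode not in ("temporal", "kfold"):
            raise ConfigError(f"evaluation.mode must be temporal|kfold, "
                              f"got {self.evaluation.mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulator"]["profile"]["amplitudes"] = \
            np.asarray(self.simulator.profile.amplitudes).tolist()
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _update_dataclass(obj, data: dict, path: str) -> None:
    for key, value in data.items():
        if not hasattr(obj, key):
            raise ConfigError(f"unknown config key {path}.{key}")
        current = getattr(obj, key)
        if hasattr(current, "__dataclass_fields__") and isinstance(value, dict):
            _update_dataclass(current, value, f"{path}.{key}")
        else:
            setattr(obj, key, value)


def load_config(path: str | None = None, overrides: dict | None = None
                ) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus programmatic overrides."""
    cfg = PipelineConfig()
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
    if overrides:
        data = {**data, **overrides}
    if "model" in data and isinstance(data["model"], dict):
        m = data.pop("model")
        cfg.model = ModelSpec(kind=m.get("kind", "cnn"),
                              params=m.get("params", {}))
    if "simulator" in data and isinstance(data["simulator"], dict):
        sim = data["simulator"]
        prof = sim.get("profile")
        if prof and "amplitudes" in prof:
            prof["amplitudes"] = np.asarray(prof["amplitudes"], dtype=float)
        sched = sim.get("schedule")
        if sched and "phase_fractions" in sched:
            sched["phase_fractions"] = tuple(sched["phase_fractions"])
    _update_dataclass(cfg, data, "config")
    return cfg.resolved()
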