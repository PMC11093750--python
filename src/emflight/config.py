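"""Run configuration: YAML round-trip, profiles, and config hashing.

Every run artifact embeds the SHA-256 hash of its canonicalized config plus
the seed, so anything on disk is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .geometry import StepConfig
from .model import SteeringNetConfig, TrainConfig, reference_config, test_scale_config
from .sampling import PatchGeometry
from .synthetic import SceneConfig

__all__ = ["RunConfig", "config_hash", "load_config", "save_config"]


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        try:
            return obj.item()
        except Exception:
            pass
    return obj


def _tupled(d):
    """YAML gives lists; dataclasses here expect tuples for fixed-size fields."""
    if isinstance(d, list):
        return tuple(_tupled(v) for v in d)
    if isinstance(d, dict):
        return {k: _tupled(v) for k, v in d.items()}
    return d


@dataclass
class RunConfig:
    """Top-level configuration grouping all module configs."""

    profile: str = "test_scale"  # or "full"
    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    patch: PatchGeometry = field(default_factory=PatchGeometry)
    net: SteeringNetConfig | None = None
    train: TrainConfig = field(default_factory=TrainConfig)
    step: StepConfig = field(default_factory=StepConfig)

    def __post_init__(self):
        if self.net is None:
            self.net = (
                reference_config() if self.profile == "full" else test_scale_config()
            )
            if self.profile != "full":
                self.patch = PatchGeometry(shape=self.net.input_shape, p=self.patch.p,
                                           z_spacing=self.patch.z_spacing)

    def to_dict(self) -> dict:
        return _to_plain(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        out = cls(
            profile=d.get("profile", "test_scale"),
            seed=int(d.get("seed", 0)),
            scene=SceneConfig(**_tupled(d["scene"])) if "scene" in d else SceneConfig(),
            patch=PatchGeometry(**_tupled(d["patch"])) if "patch" in d else PatchGeometry(),
            net=SteeringNetConfig(**_tupled(d["net"])) if d.get("net") else None,
            train=TrainConfig(**_tupled(d["train"])) if "train" in d else TrainConfig(),
            step=StepConfig(**_tupled(d["step"])) if "step" in d else StepConfig(),
        )
        return out


def config_hash(cfg: RunConfig | dict) -> str:
    d = cfg.to_dict() if isinstance(cfg, RunConfig) else _to_plain(cfg)
    blob = json.dumps(d, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_config(path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig.from_dict(d)
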