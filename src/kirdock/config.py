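"""Run configuration: one YAML-serializable object embedded in every output."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .dockengine import DockConfig
from .interface import InterfaceThresholds

__all__ = ["ClusterConfig", "RunConfig"]


@dataclass(frozen=True)
class ClusterConfig:
    radius: float = 9.0
    pool_size: int = 1000


@dataclass
class RunConfig:
    """Top-level run parameters; round-trips through YAML unchanged."""

    dock: DockConfig = field(default_factory=DockConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    interface: InterfaceThresholds = field(default_factory=InterfaceThresholds)
    profile_n: int = 2000
    top_k: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        kwargs = dict(payload)
        for name, sub_cls in (("dock", DockConfig), ("cluster", ClusterConfig),
                              ("interface", InterfaceThresholds)):
            if name in kwargs and isinstance(kwargs[name], dict):
                valid = {f.name for f in fields(sub_cls)}
                kwargs[name] = sub_cls(**{k: v for k, v in kwargs[name].items()
                                          if k in valid})
        valid = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in kwargs.items() if k in valid})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)
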