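"""Single structured configuration for a full pipeline run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .bouts import BoutConfig
from .compliance import ComplianceConfig
from .detect import PlausibilityConfig
from .weartime import WeartimeConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All module configurations plus seed and logging level.

    Fully serializable; a run echoes its effective config into the output
    directory so derived outputs are reproducible from the manifest alone.
    """

    plausibility: PlausibilityConfig = field(default_factory=PlausibilityConfig)
    bouts: BoutConfig = field(default_factory=BoutConfig)
    weartime: WeartimeConfig = field(default_factory=WeartimeConfig)
    compliance: ComplianceConfig = field(default_factory=ComplianceConfig)
    model_path: str | None = None  # None -> packaged synthetic-calibrated model
    tz_offset_hours: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bouts"]["bin_edges"] = list(d["bouts"]["bin_edges"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "plausibility" in kwargs:
            kwargs["plausibility"] = PlausibilityConfig.from_dict(kwargs["plausibility"])
        if "bouts" in kwargs:
            b = dict(kwargs["bouts"])
            if "bin_edges" in b:
                b["bin_edges"] = tuple(b["bin_edges"])
            kwargs["bouts"] = BoutConfig(**b)
        if "weartime" in kwargs:
            kwargs["weartime"] = WeartimeConfig(**kwargs["weartime"])
        if "compliance" in kwargs:
            kwargs["compliance"] = ComplianceConfig(**kwargs["compliance"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})
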