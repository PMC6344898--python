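"""Run configuration: one YAML file is the single source of truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidParameterError


@dataclass
class FrapConfig:
    radius_um: float = 2.0
    mode: str = "prebleach"


@dataclass
class FcsConfig:
    fixed_tau_T: float = 4e-6
    kappa: float = 5.0
    estimator: str = "multi_tau"


@dataclass
class VolumesConfig:
    cell_fl: float = 2000.0
    nucleus_fl: float = 1180.0
    vesicle_fl: float = 1.014


@dataclass
class RunConfig:
    """Configuration shared by the end-to-end pipelines."""

    seed: int = 0
    pixel_size: float = 0.3  # um / px
    bit_depth: int = 16
    size_gate: tuple[float, float] = (20.0, 150.0)
    tracer_threshold: float | str = "auto"  # % of max, or "auto"
    frap: FrapConfig = field(default_factory=FrapConfig)
    fcs: FcsConfig = field(default_factory=FcsConfig)
    volumes: VolumesConfig = field(default_factory=VolumesConfig)
    input_dir: str | None = None
    output_dir: str = "oligoquant_out"
    overwrite: bool = True

    def __post_init__(self):
        if self.bit_depth not in (8, 12, 16):
            raise InvalidParameterError("bit_depth must be 8, 12 or 16")
        lo, hi = self.size_gate
        if not 0 < lo < hi:
            raise InvalidParameterError("size_gate must be ordered and positive")
        if (self.input_dir is not None
                and Path(self.input_dir) == Path(self.output_dir)):
            raise InvalidParameterError("input and output paths must differ")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("frap", FrapConfig), ("fcs", FcsConfig),
                         ("volumes", VolumesConfig)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        if "size_gate" in data:
            data["size_gate"] = tuple(data["size_gate"])
        return cls(**data)

    def to_yaml(self, path):
        from dataclasses import asdict
        data = asdict(self)
        data["size_gate"] = list(data["size_gate"])
        Path(path).write_text(yaml.safe_dump(data))
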