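"""Run configuration: a validated dataclass loadable from YAML.

Every analysis threshold is carried here with its default, and the whole
config is echoed into the run log so each run's thresholds are auditable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    quant_target: str
    quant_comparator: str
    annotations: str
    reference: str
    target_line: str = "hCMEC_D3"
    comparator_line: str = "HUVEC"
    fpkm: str | None = None
    atlas: str | None = None
    fold_threshold: float = 4.0
    fold_fraction: str = "internalization"
    expression_threshold: float = 5.0
    threshold_override_target: float | None = None
    threshold_override_comparator: float | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("fold_threshold", "expression_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("threshold_override_target", "threshold_override_comparator"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when set")
        if self.fold_fraction not in ("internalization", "surface"):
            raise ValueError("fold_fraction must be 'internalization' or 'surface'")
        for name in ("quant_target", "quant_comparator", "annotations", "reference", "fpkm", "atlas"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
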