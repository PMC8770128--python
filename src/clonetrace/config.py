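"""Run configuration: a YAML-serializable parameter block for the pipeline.

The config round-trips losslessly through YAML and rejects unknown keys,
so a typo in a config file fails loudly instead of silently using a
default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    n_perm: int = 10000
    mapping_n_perm: int = 100
    fdr_threshold: float = 0.1
    cut_height: float = 0.999
    tier_policy: str = "tier1_only"
    permutation_scheme: str = "within_cell"
    sticr: dict = field(default_factory=dict)  # SticrParams overrides
    tracker: dict = field(default_factory=dict)  # TrackerParams overrides
    inputs: dict = field(default_factory=dict)  # command-specific paths

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
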