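"""Run configuration: schema-checked YAML/dict config, serialized with outputs."""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import SchemaError

#: Every key a run config may carry, with defaults.
CONFIG_SCHEMA: dict[str, object] = {
    "seed": 0,
    "out_dir": "runs",
    "preset": "wildtype",
    "control_condition": "wildtype",
    "case_condition": None,
    "n_replicates": 5,
    "min_transitions": 3,
    "spike_fmol_per_ug": 2.0,
    "knn_k": 10,
    "fc_threshold": 2.0,
    "q_threshold": 0.05,
    "q_method": "bh",
    "observable_bounds": [7, 30],
    "log_base": 2,
    "n_background": 500,
    "calibration_replicates": 3,
}


@dataclass
class RunConfig:
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(CONFIG_SCHEMA)
        if unknown:
            raise SchemaError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        merged = dict(CONFIG_SCHEMA)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise SchemaError("config file must contain a mapping")
        return cls(values=data)

    def save(self, out_dir: str | Path) -> Path:
        """Serialize the full effective config into the output directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "run_config.json"
        path.write_text(json.dumps(self.values, indent=2, sort_keys=True))
        return path

    def substream(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the single config seed."""
        base = int(self.values["seed"])
        return (base * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
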