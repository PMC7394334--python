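"""Run configuration: defaults, YAML loading and flag overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunables of a pipeline run; serialized into the JSON run summary."""

    expression: str | None = None
    cell_line: str | None = None
    library: str | None = None
    probe_map: str | None = None
    drug_targets: str | None = None
    out_dir: str = "tdfe_out"

    dose_covariate: str = "index"  # or "log_dose"
    k1_override: int | None = None
    default_K: int = 6
    K_max: int | None = 8
    contribution_threshold: float = 0.95
    K_override: int | None = None
    gene_center: bool = False

    selection_threshold: float = 0.01
    enrichment_threshold: float = 0.01
    enrichment_universe: int | None = None
    enrichment_sided: str = "one"
    validation_background: int = 20000
    validation_alpha: float = 0.05
    validation_sided: str = "two"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("selection_threshold", "enrichment_threshold", "validation_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
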