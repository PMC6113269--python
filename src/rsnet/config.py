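"""Pipeline configuration: schema-validated JSON/YAML, fail-fast on
unknown keys."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .datatypes import CostGrid


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs.

    Defaults mirror the reference analysis: 90-node parcellation, global
    cost grid 0.03-0.40 and regional grid 0.03-0.10 (step 0.01), both
    weighted and binary modes, 10000 permutations, alpha and FDR q of
    0.05, band-pass 0.01-0.08 Hz.
    """

    output_dir: str = "rsnet_out"
    manifest: str | None = None  # None => simulate a cohort
    n_parcels: int = 90
    tr_seconds: float = 2.5
    global_grid: list[float] = field(
        default_factory=lambda: CostGrid.global_grid().costs
    )
    regional_grid: list[float] = field(
        default_factory=lambda: CostGrid.regional_grid().costs
    )
    modes: list[str] = field(default_factory=lambda: ["weighted", "binary"])
    n_perm: int = 10000
    n_restarts: int = 20
    n_null: int = 100
    alpha: float = 0.05
    fdr_q: float = 0.05
    low_hz: float = 0.01
    high_hz: float = 0.08
    master_seed: int = 0
    compute_sigma: bool = True
    # simulation block (used when manifest is None)
    n_group1: int = 57
    n_group2: int = 62
    n_samples: int = 200

    def __post_init__(self) -> None:
        for grid in (self.global_grid, self.regional_grid):
            CostGrid(grid)  # validates range/monotonicity
        bad = set(self.modes) - {"weighted", "binary"}
        if bad:
            raise ValueError(f"unknown mode(s): {sorted(bad)}")
        if not (0 < self.alpha < 1 and 0 < self.fdr_q < 1):
            raise ValueError("alpha and fdr_q must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        ) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
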