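"""Validated run configuration for the command-line pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .simulate import CampaignConfig


class ScreenParams(BaseModel):
    model_config = {"extra": "forbid"}

    plate_map: str | None = None  # optional separate plate-map CSV
    well_records: str  # per-well area CSV
    grubbs_alpha: float = Field(default=0.05, gt=0, le=0.2)
    z_min: float = 0.5
    cv_max: float = 10.0
    residual_max: float = 50.0
    n_replicates_expected: int = 2


class DrcParams(BaseModel):
    model_config = {"extra": "forbid"}

    input_csv: str  # compound_id, concentration_nM, response_pct


class SynergyParams(BaseModel):
    model_config = {"extra": "forbid"}

    input_csv: str  # conc1_nM, conc2_nM, viability_pct
    drug1: str = "drug1"
    drug2: str = "drug2"
    min_doses: int = 4


class RunConfig(BaseModel):
    """Top-level config; unknown keys are rejected."""

    model_config = {"extra": "forbid"}

    output_dir: str = "spheroscreen_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: CampaignConfig | None = None
    screen: ScreenParams | None = None
    drc: DrcParams | None = None
    synergy: SynergyParams | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    def write_resolved(self, out_dir: Path) -> Path:
        """Persist the fully-resolved config beside the run's outputs."""
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "resolved_config.json"
        path.write_text(json.dumps(self.model_dump(), indent=2, default=str) + "\n")
        return path
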