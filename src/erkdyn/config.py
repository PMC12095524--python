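"""Run configuration: validated, serializable, with per-module blocks.

Unknown keys are rejected with their key path; an empty file yields all
defaults; save/load round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateBlock(_Block):
    n_cells_per_well: int = 60
    replicates: int = 3
    noise_cv: float = 0.10
    clustered_fraction: float = 0.25
    batch_log10_sd: float = 0.15
    ode_dt: float = 1.0


class CalibrationBlock(_Block):
    k_au: float = 0.2          # associated fraction, unphosphorylated reporter
    k_ap: float = 0.8          # associated fraction, fully phosphorylated
    r_p: float = 1.0           # channel power ratio
    fa_noise_sd: float = 0.005  # measurement noise on synthetic phos-tag anchors


class FeaturesBlock(_Block):
    min_prominence_fraction: float = 0.10  # of the dataset activity IQR
    min_hours: float = 15.0


class ForwardBlock(_Block):
    n_folds: int = 5
    epochs: int = 25           # end-to-end driver default; CnnRegressor's own default is 100
    lr: float = 1e-3
    l2: float = 1e-3
    batch_size: int = 256
    target: str = "Egr-1"
    cnn: bool = True
    keep_last_n: int | None = None
    attribution_steps: int = 64


class ReverseBlock(_Block):
    folds: int = 10
    log_scale: bool = True


class ClassifyBlock(_Block):
    k: int = 5
    r_min: float = 0.7
    n_rounds: int = 500
    folds: int = 10
    hex_radius_um: float = 50.0
    min_cells_per_class: int = 20


class SimEtgBlock(_Block):
    n_genes: int = 50
    r2_thresholds: tuple[float, float] = (0.5, 0.8)
    dt: float = 1.0


class StatsBlock(_Block):
    alpha: float = 0.05


class RunConfig(_Block):
    seed: int = 0
    outdir: str = "erkdyn_out"
    verbosity: int = 1
    layout_path: str | None = None
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    calibration: CalibrationBlock = Field(default_factory=CalibrationBlock)
    features: FeaturesBlock = Field(default_factory=FeaturesBlock)
    forward: ForwardBlock = Field(default_factory=ForwardBlock)
    reverse: ReverseBlock = Field(default_factory=ReverseBlock)
    classify: ClassifyBlock = Field(default_factory=ClassifyBlock)
    simetg: SimEtgBlock = Field(default_factory=SimEtgBlock)
    stats: StatsBlock = Field(default_factory=StatsBlock)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = self.model_dump()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data))
        else:
            path.write_text(json.dumps(data, indent=1))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return RunConfig()
    data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    if data is None:
        return RunConfig()
    return RunConfig.model_validate(data)
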