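"""Pipeline configuration: one validated object controls every stage.

Any block can be overridden from a YAML or JSON file; every random draw in
the pipeline is governed by a named seed so a config fully determines a
run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import yaml
from pydantic import BaseModel, Field

from .generate import (
    DEFAULT_PERMEABILITY_THRESHOLD,
    DEFAULT_SOLUBILITY_THRESHOLD,
)
from .ranges import ParameterRanges
from .surrogate import DEFAULT_GRID

__all__ = ["PipelineConfig", "load_config"]


class SamplingConfig(BaseModel):
    n: int = 15_000
    seed: int = 0
    solubility_threshold: float = DEFAULT_SOLUBILITY_THRESHOLD
    permeability_threshold: float = DEFAULT_PERMEABILITY_THRESHOLD


class SolverConfig(BaseModel):
    t_end: float = 48.0
    dt: float = 0.05
    rtol: float = 1e-8
    atol_dose_scale: float = 1e-12
    ionization: str = "acid"
    #: abort the batch if more than this fraction of simulations fail
    max_failure_fraction: float = 0.01


class SplitConfig(BaseModel):
    test_fraction: float = 0.20
    seed: int = 1


class TrainingConfig(BaseModel):
    grid: Dict[str, List] = Field(default_factory=lambda: dict(DEFAULT_GRID))
    cv_folds: int = 5
    seed: int = 2
    algorithm: str = "random_forest"


class EvaluationConfig(BaseModel):
    bin_width: float = 5.0
    denominator_floor: float = 1e-6


class PipelineConfig(BaseModel):
    """Bundled settings for the full generate->simulate->train->evaluate run."""

    ranges: ParameterRanges = Field(default_factory=ParameterRanges)
    sampling: SamplingConfig = Field(default_factory=SamplingConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    training: TrainingConfig = Field(default_factory=TrainingConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def dump(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        )


def load_config(path: Optional[Union[str, Path]] = None) -> PipelineConfig:
    """Load a YAML/JSON config file on top of the defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)
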