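"""Validated run configuration for the end-to-end analyses.

A :class:`RunConfig` bundles the task, population and analysis parameters
of one synthetic end-to-end run. Every stochastic stage draws its own seed
from the master seed through a fixed counter scheme
(:meth:`RunConfig.stage_seed`), so any stage can be re-run in isolation
and whole reports are bit-reproducible. Configs load from JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator

#: fixed offsets of the per-stage seed stream
STAGE_OFFSETS = {"task": 1, "population": 2, "consistency": 3, "analysis": 4}


class TaskConfig(BaseModel):
    kind: str = "static"  # "static" | "dynamic"
    n_trials: int = Field(600, ge=1)
    accuracy: float = Field(0.98, ge=0.0, le=1.0)  # static only
    n_cues: int = Field(4, ge=2)  # dynamic only

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("static", "dynamic"):
            raise ValueError("task kind must be 'static' or 'dynamic'")
        return v


class PopulationConfig(BaseModel):
    n_neurons: int = Field(60, ge=1)
    tau_range: tuple[float, float] = (0.2, 0.8)
    alpha_total_range: tuple[float, float] = (0.2, 0.8)
    coupled: bool = True
    topography_slope: float = Field(0.5, ge=-1.0, le=1.0)
    distractor_fraction: float = Field(0.0, ge=0.0, le=1.0)
    negative_fraction: float = Field(0.5, ge=0.0, le=1.0)
    gain: float = Field(5.0, gt=0.0)
    baseline: float = Field(10.0, ge=0.0)
    noise_sd: float = Field(2.5, ge=0.0)
    n_subjects: int = Field(2, ge=1)


class AnalysisConfig(BaseModel):
    alpha: float = Field(0.05, gt=0.0, le=1.0)
    n_partitions: int = Field(200, ge=1)
    n_folds: int = Field(10, ge=2)
    grid_step: float = 0.025
    v_init: float = Field(0.5, ge=0.0, le=1.0)
    refit_linear: bool = True
    # analysis window descriptor; consumed by the rate-extraction layer of
    # real-data readers, not by the estimators (which take averaged rates)
    window_ms: tuple[float, float] = (200.0, 600.0)


class RunConfig(BaseModel):
    master_seed: int = 0
    task: TaskConfig = TaskConfig()
    population: PopulationConfig = PopulationConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    output_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        if stage not in STAGE_OFFSETS:
            raise KeyError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence([self.master_seed, STAGE_OFFSETS[stage]])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
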