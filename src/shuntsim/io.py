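"""Run configuration, metrics serialization and tabular output."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .experiments import SweepSpec
from .params import ModelParams
from .presets import PRESET_NAMES, params_from_dict
from .simulate import CycleMetrics, CycleTrajectory, SimConfig

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Validated description of one simulation or sweep run.

    Exactly one of ``preset`` (a shipped scenario name or a preset YAML
    path) or ``params`` (an inline parameter mapping in preset format)
    selects the model. ``seed`` is reserved plumbing: the core model is
    deterministic.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    preset: Optional[str] = None
    params: Optional[ModelParams] = None
    sim: SimConfig = SimConfig()
    sweep: Optional[SweepSpec] = None
    metrics_out: Optional[Path] = None
    trajectory_out: Optional[Path] = None
    seed: Optional[int] = None
    log_level: str = "INFO"

    @model_validator(mode="before")
    @classmethod
    def _inline_params(cls, values):
        if isinstance(values, dict):
            p = values.get("params")
            if isinstance(p, dict) and "chambers" in p:
                values = dict(values, params=params_from_dict(p))
            sw = values.get("sweep")
            if isinstance(sw, dict):
                values = dict(values, sweep=SweepSpec(**sw))
        return values

    @model_validator(mode="after")
    def _one_model(self) -> "RunConfig":
        if (self.preset is None) == (self.params is None):
            raise ValueError("exactly one of 'preset' or 'params' must be given")
        if self.preset is not None:
            name = self.preset.replace("-", "_")
            if name not in PRESET_NAMES and not Path(self.preset).exists():
                raise ValueError(
                    f"preset {self.preset!r} is neither a shipped preset "
                    f"{PRESET_NAMES} nor an existing file"
                )
        return self


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Schema violations raise with the offending field named (pydantic
    validation errors carry the field path).
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return RunConfig(**doc)


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    """Serialize a RunConfig back to YAML (round-trips with load_config)."""
    doc = cfg.model_dump(mode="json", exclude_none=True)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def metrics_to_dict(metrics: CycleMetrics) -> Dict:
    return dataclasses.asdict(metrics)


def write_metrics(metrics: CycleMetrics, path: Union[str, Path]) -> None:
    """Write cycle metrics as JSON, keys in declaration order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(metrics_to_dict(metrics), indent=2) + "\n")


def read_metrics(path: Union[str, Path]) -> CycleMetrics:
    """Inverse of :func:`write_metrics`."""
    return CycleMetrics(**json.loads(Path(path).read_text()))


def write_trajectory(traj: CycleTrajectory, path: Union[str, Path]) -> None:
    """Write one cycle as RFC-4180 CSV: time_s then every signal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj.to_dataframe().to_csv(path, index=False, lineterminator="\r\n")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
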