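"""Validated pipeline configuration (YAML-backed, strict schema).

The configuration is validated before any computation: unknown keys are
rejected, numeric constraints are enforced, and the loaded model converts
cleanly into the per-module config dataclasses.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import InvalidSpecError
from .gait import GaitConfig
from .preprocess import FilterSpec
from .sts import StsConfig
from .tug import TugConfig

__all__ = ["PipelineConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterModel(_Strict):
    order: int = Field(default=4, ge=1)
    cutoff_hz: float = Field(default=5.0, gt=0)
    zero_phase: bool = True

    def to_spec(self) -> FilterSpec:
        return FilterSpec(order=self.order, cutoff_hz=self.cutoff_hz, zero_phase=self.zero_phase)


class TugModel(_Strict):
    baseline_window_s: float = Field(default=0.5, gt=0)
    k_sigma: float = Field(default=3.0, ge=0)
    sustain_s: float = Field(default=0.1, gt=0)
    gyr_floor: float = Field(default=3.0, ge=0)
    turn_height_frac: float = Field(default=0.5, gt=0, lt=1)
    turn_min_sep_s: float = Field(default=2.0, gt=0)
    step_prominence_frac: float = Field(default=0.3, gt=0)
    step_floor: float = Field(default=1.0, ge=0)
    min_step_s: float = Field(default=0.25, gt=0)
    walk_onset_lead_s: float = Field(default=0.10, ge=0)
    t3_snap_pre_s: float = Field(default=0.45, ge=0)
    t3_snap_post_s: float = Field(default=0.10, ge=0)

    def to_config(self, filt: FilterSpec) -> TugConfig:
        return TugConfig(filter=filt, **self.model_dump())


class StsModel(_Strict):
    n_cycles: int = Field(default=5, ge=1)
    baseline_window_s: float = Field(default=0.5, gt=0)
    k_sigma: float = Field(default=3.0, ge=0)
    gyr_floor: float = Field(default=3.0, ge=0)
    min_lobe_s: float = Field(default=0.3, gt=0)
    merge_gap_s: float = Field(default=0.08, ge=0)
    max_intra_cycle_gap_s: float = Field(default=3.0, gt=0)
    side: str = Field(default="mean", pattern="^(mean|L|R)$")

    def to_config(self, filt: FilterSpec) -> StsConfig:
        return StsConfig(filter=filt, **self.model_dump())


class GaitModel(_Strict):
    prominence_frac: float = Field(default=0.3, gt=0)
    peak_floor: float = Field(default=0.5, ge=0)
    min_peak_sep_s: float = Field(default=0.08, gt=0)
    label_by: str = Field(default="order", pattern="^(order|amplitude)$")

    def to_config(self, filt: FilterSpec) -> GaitConfig:
        return GaitConfig(filter=filt, **self.model_dump())


class CohortModel(_Strict):
    """Simulated-cohort shortcut: sizes and seed for the built-in cell spec."""

    n_control: int = Field(default=20, ge=2)
    n_stroke: int = Field(default=21, ge=2)
    tests: list[str] = Field(default_factory=lambda: ["TUG", "STS", "10MWT"])
    rms_scale: float = Field(default=15.0, gt=0)


class PipelineConfig(_Strict):
    """Top-level pipeline configuration."""

    preprocess: FilterModel = Field(default_factory=FilterModel)
    tug: TugModel = Field(default_factory=TugModel)
    sts: StsModel = Field(default_factory=StsModel)
    gait: GaitModel = Field(default_factory=GaitModel)
    distance_m: float = Field(default=10.0, gt=0)
    seed: int = 0
    input_dir: str | None = None
    cohort: CohortModel | None = None
    out_dir: str | None = None

    def filter_spec(self) -> FilterSpec:
        return self.preprocess.to_spec()

    def tug_config(self) -> TugConfig:
        return self.tug.to_config(self.filter_spec())

    def sts_config(self) -> StsConfig:
        return self.sts.to_config(self.filter_spec())

    def gait_config(self) -> GaitConfig:
        return self.gait.to_config(self.filter_spec())


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown keys raise :class:`~mobiseg.errors.InvalidSpecError` before any
    computation runs. ``overrides`` replace top-level keys (used by the CLI
    for ``--seed``/``--out``).
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise InvalidSpecError(f"{path}: config must be a mapping")
        raw = loaded
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        raise InvalidSpecError(str(exc)) from exc


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of a validated configuration."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
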