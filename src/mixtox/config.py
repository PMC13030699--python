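"""Validated run configuration for the analysis pipeline.

A :class:`RunConfig` is validated up front (pydantic) so bad inputs fail
fast with field-level messages, before any computation starts.  Configs
round-trip through JSON; the pipeline logs the config hash alongside the
seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = ["FitOptions", "InteractionOptions", "RunConfig"]


class FitOptions(BaseModel):
    """4PL fit settings (see :class:`mixtox.dose_response.FourParamLogistic`)."""

    bottom_bounds: tuple[float, float] = (-10.0, 50.0)
    top_bounds: tuple[float, float] = (50.0, 150.0)
    hill_bounds: tuple[float, float] = (0.05, 10.0)
    fix_bottom: Optional[float] = None
    fix_top: Optional[float] = None
    ci_method: Literal["asymptotic_log", "bootstrap"] = "asymptotic_log"
    n_boot: int = Field(999, ge=99)

    @field_validator("bottom_bounds", "top_bounds", "hill_bounds")
    @classmethod
    def _ordered(cls, v):
        if v[0] >= v[1]:
            raise ValueError("bounds must be (low, high) with low < high")
        return v

    def estimator_kwargs(self) -> dict:
        return self.model_dump()


class InteractionOptions(BaseModel):
    """Mixture model and test settings."""

    model: Literal["effect_summation", "bliss", "loewe"] = "effect_summation"
    alpha: float = Field(0.05, gt=0, lt=1)
    use_fitted_curves: bool = False  # interpolate V_i from curves, not singles


class RunConfig(BaseModel):
    """Inputs, options and outputs of one pipeline run."""

    dose_table: Optional[Path] = None
    mixture_design_table: Optional[Path] = None
    observed_table: Optional[Path] = None
    singles_table: Optional[Path] = None  # measured V_i at mixture concentrations
    exposure_h: Optional[float] = Field(None, gt=0)
    fit: FitOptions = FitOptions()
    interaction: InteractionOptions = InteractionOptions()
    seed: int = 0
    output_dir: Path = Path("mixtox-out")

    @model_validator(mode="after")
    def _paths_exist(self):
        for name in ("dose_table", "mixture_design_table", "observed_table",
                     "singles_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name}: file not found: {p}")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def config_hash(self) -> str:
        """Stable short hash of the full config, for run logs."""
        payload = self.model_dump_json()
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
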