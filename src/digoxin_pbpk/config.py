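"""Run configuration: population defaults, overrides, regimen, outputs.

Precedence: CLI flags > config file > population defaults.  Every report
embeds the fully resolved parameter set so any number can be reproduced from
the report alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .drug_model import POPULATIONS, digoxin_parameters

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    population: str = "healthy_adult"
    parameter_overrides: dict[str, float] = Field(default_factory=dict)
    regimen: list[dict[str, Any]] = Field(
        default_factory=lambda: [
            {"route": "iv_bolus", "amount": 0.5, "unit": "mg", "start": 0.0}
        ]
    )
    age_days: Optional[float] = None
    body_weight_kg: Optional[float] = None
    t_end_h: float = 48.0
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    seed: int = 0
    output_dir: str = "results"
    quiet: bool = False

    @field_validator("population")
    @classmethod
    def _known_population(cls, v: str) -> str:
        if v not in POPULATIONS:
            raise ValueError(f"population must be one of {POPULATIONS}")
        return v

    @field_validator("parameter_overrides")
    @classmethod
    def _known_keys(cls, v: dict[str, float]) -> dict[str, float]:
        valid = set(digoxin_parameters("healthy_adult").__dataclass_fields__)
        unknown = set(v) - valid
        if unknown:
            raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
        return v

    def resolved_parameters(self):
        """Population defaults plus overrides, as a DrugParameters."""
        return digoxin_parameters(self.population).with_overrides(
            **self.parameter_overrides
        )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig(**data)
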