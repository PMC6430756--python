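"""Validated run configuration (YAML/JSON) for the CLI and workflows."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .exceptions import ConfigError
from .units import DEFAULT_PROTEIN_REGISTRY

__all__ = ["RunConfig", "UnitSettings", "SolverSettings", "OptimizerSettings", "NoiseSettings"]


class UnitSettings(BaseModel):
    peg_molecular_weight: float = Field(6000.0, gt=0)
    peg_solution_density: float = Field(1.0, gt=0)  # g/mL, for %(w/w) -> mol/L
    cohn_log_base: float = Field(10.0, gt=1)


class SolverSettings(BaseModel):
    rtol: float = Field(1.0e-12, gt=0)
    residual_tol: float = Field(1.0e-14, gt=0)


class OptimizerSettings(BaseModel):
    restarts: int = Field(10, ge=1)
    maxiter: int = Field(300, ge=1)
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "ln_k_eq": (0.0, 60.0),
            "n": (0.5, 10.0),
            "ln_beta0": (-12.0, 0.0),
            "beta1": (0.0, 1.0e3),
            "beta2": (0.0, 1.0e5),
        }
    )

    @field_validator("bounds")
    @classmethod
    def _bounds_ordered(cls, v):
        for key, (lo, hi) in v.items():
            if not lo < hi:
                raise ValueError(f"bound for {key} must satisfy lo < hi")
        return v


class NoiseSettings(BaseModel):
    cv: float = Field(0.02, ge=0)
    outlier_rate: float = Field(0.02, ge=0, lt=1)
    outlier_scale: tuple[float, float] = (1.5, 3.0)
    filter_threshold_pct: float = Field(5.0, gt=0)


class RunConfig(BaseModel):
    """Top-level configuration: units, solver, optimizer, noise, proteins."""

    units: UnitSettings = Field(default_factory=UnitSettings)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    optimizer: OptimizerSettings = Field(default_factory=OptimizerSettings)
    noise: NoiseSettings = Field(default_factory=NoiseSettings)
    proteins: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_REGISTRY)
    )

    @field_validator("proteins")
    @classmethod
    def _positive_mw(cls, v):
        for name, mw in v.items():
            if not mw > 0:
                raise ValueError(f"molecular weight for {name!r} must be > 0")
        return v

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            payload = yaml.safe_load(path.read_text()) or {}
            return cls.model_validate(payload)
        except ConfigError:
            raise
        except Exception as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def molecular_weight(self, protein: str) -> float:
        key = protein.lower()
        if key not in self.proteins:
            raise ConfigError(
                f"protein {protein!r} not in registry {sorted(self.proteins)}"
            )
        return self.proteins[key]

    def config_hash(self) -> str:
        """Stable short hash of the canonicalized configuration, for run logs."""
        text = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
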