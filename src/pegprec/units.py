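"""Conversions between laboratory units and the model's molar scale.

Protein is handled in mg/mL (equivalently g/L) at the bench and mol/L in
the model; PEG stocks are prepared in % (w/w) and modeled in mol/L.  The
% (w/w) conversion assumes a solution density (default 1.0 g/mL, the
dilute-aqueous approximation), which is exposed in :class:`PegSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import DomainError, InvalidParameterError

__all__ = [
    "ProteinSpec",
    "PegSpec",
    "DEFAULT_PROTEIN_REGISTRY",
    "protein_mgml_to_molar",
    "protein_molar_to_mgml",
    "peg_ww_to_molar",
    "peg_molar_to_ww",
]

#: Default molecular weights (g/mol).  Lysozyme and myoglobin are the
#: standard literature values for the purified proteins; BSA and the
#: generic mAb entries are editable conventions, not measured values.
DEFAULT_PROTEIN_REGISTRY: dict[str, float] = {
    "lysozyme": 14600.0,
    "myoglobin": 17000.0,
    "bsa": 66500.0,
    "mab": 150000.0,
}


@dataclass(frozen=True)
class ProteinSpec:
    """A protein identity with the molecular weight used for conversions."""

    name: str
    molecular_weight: float  # g/mol
    extinction_context: str | None = None

    def __post_init__(self) -> None:
        if not (self.molecular_weight > 0):
            raise InvalidParameterError("molecular_weight must be > 0")


@dataclass(frozen=True)
class PegSpec:
    """PEG species: molecular weight (g/mol) and solution density (g/mL)."""

    molecular_weight: float = 6000.0
    solution_density: float = 1.0

    def __post_init__(self) -> None:
        if not (self.molecular_weight > 0 and self.solution_density > 0):
            raise InvalidParameterError("PegSpec fields must be > 0")


def protein_mgml_to_molar(c: float, spec: ProteinSpec) -> float:
    """mg/mL -> mol/L (mg/mL is g/L; divide by the molecular weight)."""
    if c < 0:
        raise DomainError(f"protein concentration must be >= 0, got {c}")
    return c / spec.molecular_weight


def protein_molar_to_mgml(c: float, spec: ProteinSpec) -> float:
    """mol/L -> mg/mL."""
    if c < 0:
        raise DomainError(f"protein concentration must be >= 0, got {c}")
    return c * spec.molecular_weight


def peg_ww_to_molar(pct: float, spec: PegSpec = PegSpec()) -> float:
    """% (w/w) -> mol/L using the spec's solution density."""
    if not (0 <= pct < 100):
        raise DomainError(f"PEG %(w/w) must be in [0, 100), got {pct}")
    grams_per_litre = pct / 100.0 * spec.solution_density * 1000.0
    return grams_per_litre / spec.molecular_weight


def peg_molar_to_ww(c: float, spec: PegSpec = PegSpec()) -> float:
    """mol/L -> % (w/w)."""
    if c < 0:
        raise DomainError(f"PEG concentration must be >= 0, got {c}")
    return c * spec.molecular_weight / (spec.solution_density * 1000.0) * 100.0
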