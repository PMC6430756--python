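"""In-memory container for precipitation-screen datasets.

A :class:`ScreenDataset` holds one record per (condition, replicate set):
the well composition in molar units plus the replicate supernatant
readings.  Conditions form a (possibly incomplete) grid over distinct
initial-protein and PEG levels; the grid structure is what the
calibration/validation split operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .model import Condition

__all__ = ["ScreenRecord", "ScreenDataset"]


@dataclass(frozen=True)
class ScreenRecord:
    """One condition with its retained replicate supernatant readings (mol/L)."""

    condition: Condition
    replicates: tuple[float, ...]
    flagged: bool = False

    def __post_init__(self) -> None:
        if len(self.replicates) == 0:
            raise DomainError("a record needs at least one replicate")
        if any(r < 0 for r in self.replicates):
            raise DomainError("replicate concentrations must be >= 0")

    @property
    def mean(self) -> float:
        """Arithmetic mean of the retained replicates."""
        return float(np.mean(self.replicates))


@dataclass
class ScreenDataset:
    """A collection of screen records with provenance metadata."""

    records: list[ScreenRecord]
    protein_id: str = ""
    ph: float = float("nan")
    source: str = "simulated"  # "measured" | "simulated"
    molecular_weight: float | None = None

    def __len__(self) -> int:
        return len(self.records)

    def protein_levels(self) -> np.ndarray:
        """Sorted distinct initial-protein levels (mol/L)."""
        return np.unique([r.condition.c_p0 for r in self.records])

    def peg_levels(self) -> np.ndarray:
        """Sorted distinct PEG levels (mol/L)."""
        return np.unique([r.condition.c_peg for r in self.records])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(c_p0, c_peg, replicate-mean supernatant) arrays, one row per record."""
        c_p0 = np.array([r.condition.c_p0 for r in self.records])
        c_peg = np.array([r.condition.c_peg for r in self.records])
        y = np.array([r.mean for r in self.records])
        return c_p0, c_peg, y

    def with_records(self, records: list[ScreenRecord]) -> "ScreenDataset":
        return ScreenDataset(
            records=list(records),
            protein_id=self.protein_id,
            ph=self.ph,
            source=self.source,
            molecular_weight=self.molecular_weight,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-replicate frame, all concentrations in mol/L."""
        rows = []
        for rec in self.records:
            for j, val in enumerate(rec.replicates):
                rows.append(
                    {
                        "protein": self.protein_id,
                        "ph": self.ph,
                        "c_protein_initial": rec.condition.c_p0,
                        "protein_unit": "mol_per_l",
                        "c_peg": rec.condition.c_peg,
                        "peg_unit": "mol_per_l",
                        "replicate": j + 1,
                        "c_supernatant": val,
                    }
                )
        return pd.DataFrame(rows)
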