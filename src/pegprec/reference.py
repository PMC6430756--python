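"""Published reference parameter sets and the standard screen layout.

Five parameter sets — lysozyme, myoglobin, BSA, and one mAb at pH 7.5 and
pH 8.5 — span the realistic range for PEG-6000-induced precipitation of
small proteins through antibodies.  They serve as ground truth for
simulation studies and parameter-recovery tests.

The standard screen varies the initial protein concentration over eight
equidistant levels from 1.5 to 12 mg/mL and PEG 6000 over twelve
equidistant levels, up to 0.056 mol/L for the small proteins and up to
0.02 mol/L for the mAb (which precipitates at lower PEG).
"""

from __future__ import annotations

import numpy as np

from .model import IsothermParameters
from .units import DEFAULT_PROTEIN_REGISTRY, ProteinSpec

__all__ = [
    "REFERENCE_PARAMETERS",
    "REFERENCE_PROTEIN_SPECS",
    "REFERENCE_PEG_MAX",
    "standard_protein_levels_mgml",
    "standard_peg_levels",
]

REFERENCE_PARAMETERS: dict[str, IsothermParameters] = {
    "lysozyme": IsothermParameters(
        ln_k_eq=34.71, n=5.55, beta0=6.92e-3, beta1=92.9, beta2=2060.0
    ),
    "myoglobin": IsothermParameters(
        ln_k_eq=15.41, n=3.06, beta0=4.30e-4, beta1=118.0, beta2=1510.0
    ),
    "bsa": IsothermParameters(
        ln_k_eq=9.78, n=2.60, beta0=2.74e-3, beta1=140.0, beta2=1580.0
    ),
    "mab_ph7.5": IsothermParameters(
        ln_k_eq=22.53, n=3.65, beta0=1.46e-2, beta1=237.0, beta2=1.05e4
    ),
    "mab_ph8.5": IsothermParameters(
        ln_k_eq=19.83, n=3.22, beta0=3.77e-2, beta1=250.0, beta2=6.61e3
    ),
}

REFERENCE_PROTEIN_SPECS: dict[str, ProteinSpec] = {
    "lysozyme": ProteinSpec("lysozyme", DEFAULT_PROTEIN_REGISTRY["lysozyme"]),
    "myoglobin": ProteinSpec("myoglobin", DEFAULT_PROTEIN_REGISTRY["myoglobin"]),
    "bsa": ProteinSpec("bsa", DEFAULT_PROTEIN_REGISTRY["bsa"]),
    "mab_ph7.5": ProteinSpec("mab", DEFAULT_PROTEIN_REGISTRY["mab"]),
    "mab_ph8.5": ProteinSpec("mab", DEFAULT_PROTEIN_REGISTRY["mab"]),
}

#: Maximum PEG level (mol/L) of the standard screen per reference system.
REFERENCE_PEG_MAX: dict[str, float] = {
    "lysozyme": 0.056,
    "myoglobin": 0.056,
    "bsa": 0.056,
    "mab_ph7.5": 0.02,
    "mab_ph8.5": 0.02,
}


def standard_protein_levels_mgml(
    n_levels: int = 8, low: float = 1.5, high: float = 12.0
) -> np.ndarray:
    """Equidistant initial-protein levels in mg/mL (default 1.5 .. 12, 8 levels)."""
    return np.linspace(low, high, n_levels)


def standard_peg_levels(peg_max: float = 0.056, n_levels: int = 12) -> np.ndarray:
    """Twelve equidistant nonzero PEG levels ending at ``peg_max`` (mol/L).

    The spacing equals ``peg_max / n_levels``, i.e. the grid is
    ``peg_max/12, 2*peg_max/12, ..., peg_max`` by default.
    """
    return np.linspace(peg_max / n_levels, peg_max, n_levels)
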