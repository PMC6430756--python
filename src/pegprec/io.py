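"""Reading and writing screen datasets and related CSV artifacts.

The on-disk dataset format is tidy, one row per replicate, with explicit
unit columns so mg/mL, %(w/w) and molar data can coexist without ambient
guessing:

    protein, ph, c_protein_initial, protein_unit, c_peg, peg_unit,
    replicate, c_supernatant

``protein_unit`` applies to both ``c_protein_initial`` and
``c_supernatant`` (they are measured on the same scale); accepted values
are ``mg_per_ml`` and ``mol_per_l``.  ``peg_unit`` accepts ``mol_per_l``
and ``percent_ww``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .data import ScreenDataset, ScreenRecord
from .exceptions import ConfigError, DomainError
from .model import Condition
from .screen import PlateDesign
from .units import PegSpec, ProteinSpec, peg_ww_to_molar, protein_mgml_to_molar

__all__ = ["read_screen_csv", "write_screen_csv", "write_plate_design_csv", "write_curve_csv"]

REQUIRED_COLUMNS = (
    "protein",
    "ph",
    "c_protein_initial",
    "protein_unit",
    "c_peg",
    "peg_unit",
    "replicate",
    "c_supernatant",
)

_PROTEIN_UNITS = ("mg_per_ml", "mol_per_l")
_PEG_UNITS = ("mol_per_l", "percent_ww")


def read_screen_csv(path, config: RunConfig | None = None) -> ScreenDataset:
    """Load a tidy replicate-level CSV into a molar :class:`ScreenDataset`.

    Rows are grouped into replicate sets by (protein, ph, initial protein,
    PEG).  Negative concentrations and unknown units are rejected with the
    offending data row number (1-based, excluding the header).
    """
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"dataset file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"missing required columns: {missing}")

    proteins = df["protein"].astype(str).str.lower().unique()
    if len(proteins) != 1:
        raise ConfigError(f"expected a single protein per file, got {sorted(proteins)}")
    protein_name = proteins[0]
    spec = ProteinSpec(protein_name, config.molecular_weight(protein_name))
    peg_spec = PegSpec(
        molecular_weight=config.units.peg_molecular_weight,
        solution_density=config.units.peg_solution_density,
    )

    groups: dict[tuple, list[float]] = {}
    ph_values = set()
    for idx, row in df.iterrows():
        rownum = idx + 1
        p_unit = str(row["protein_unit"])
        g_unit = str(row["peg_unit"])
        if p_unit not in _PROTEIN_UNITS:
            raise ConfigError(f"row {rownum}: unknown protein_unit {p_unit!r}")
        if g_unit not in _PEG_UNITS:
            raise ConfigError(f"row {rownum}: unknown peg_unit {g_unit!r}")
        try:
            c0 = float(row["c_protein_initial"])
            cs = float(row["c_supernatant"])
            cg = float(row["c_peg"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"row {rownum}: unparseable concentration") from exc
        if c0 < 0 or cs < 0 or cg < 0:
            raise ConfigError(f"row {rownum}: negative concentration")
        try:
            if p_unit == "mg_per_ml":
                c0 = protein_mgml_to_molar(c0, spec)
                cs = protein_mgml_to_molar(cs, spec)
            if g_unit == "percent_ww":
                cg = peg_ww_to_molar(cg, peg_spec)
        except DomainError as exc:
            raise ConfigError(f"row {rownum}: {exc}") from exc
        ph = float(row["ph"])
        # NaN pH (unspecified) must still group rows together
        ph_key = None if np.isnan(ph) else ph
        if ph_key is not None:
            ph_values.add(ph)
        groups.setdefault((c0, cg, ph_key), []).append(cs)

    records = [
        ScreenRecord(
            condition=Condition(
                c_p0=c0,
                c_peg=cg,
                protein_id=protein_name,
                ph=float("nan") if ph is None else ph,
            ),
            replicates=tuple(reps),
        )
        for (c0, cg, ph), reps in sorted(
            groups.items(), key=lambda kv: (kv[0][0], kv[0][1])
        )
    ]
    ph_meta = ph_values.pop() if len(ph_values) == 1 else float("nan")
    return ScreenDataset(
        records=records,
        protein_id=protein_name,
        ph=ph_meta,
        source="measured",
        molecular_weight=spec.molecular_weight,
    )


def write_screen_csv(dataset: ScreenDataset, path) -> None:
    """Write a dataset as a tidy replicate-level CSV in molar units."""
    dataset.to_frame().to_csv(path, index=False)


def write_plate_design_csv(design: PlateDesign, path) -> None:
    """Write a plate layout CSV: plate, well, composition, replicate."""
    rows = [
        {
            "plate": w.plate,
            "well": w.well,
            "c_protein_initial_mgml": w.c_p0_mgml,
            "c_peg_molar": w.c_peg_molar,
            "replicate": w.replicate,
        }
        for w in design.wells
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curve_csv(peg_grid, c_p, path) -> None:
    """Write a predicted precipitation curve (mol/L vs mol/L)."""
    pd.DataFrame({"c_peg": np.asarray(peg_grid), "c_supernatant": np.asarray(c_p)}).to_csv(
        path, index=False
    )
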