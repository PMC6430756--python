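"""In-silico high-throughput precipitation screens.

Emulates a robotic 96-well screen: a full-factorial grid of initial
protein (mg/mL) and PEG (mol/L) levels, run in replicates, randomized to
well positions across as many plates as needed.  Supernatant readings are
perturbed by multiplicative lognormal noise (UV measurement after dilution
scales with signal) with an optional gross-error ("outlier") mechanism,
and cleaned by the triplicate pretreatment filter: if the percentage
standard error of a replicate set exceeds 5 %, the replicate farthest from
the median is dropped, iterating but never below two retained replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .data import ScreenDataset, ScreenRecord
from .exceptions import DomainError
from .model import Condition, IsothermParameters, solve_equilibrium_batch
from .units import ProteinSpec, protein_mgml_to_molar

__all__ = [
    "WellAssignment",
    "PlateDesign",
    "NoiseModel",
    "FilterResult",
    "design_screen",
    "simulate_screen",
    "triplicate_outlier_filter",
    "apply_outlier_filter",
]

WELLS_PER_PLATE = 96
_ROWS = "ABCDEFGH"


@dataclass(frozen=True)
class WellAssignment:
    """One pipetted well: plate index, well label, composition, replicate."""

    plate: int
    well: str
    c_p0_mgml: float
    c_peg_molar: float
    replicate: int


@dataclass(frozen=True)
class PlateDesign:
    """Randomized plate layout for a full-factorial screen."""

    wells: tuple[WellAssignment, ...]
    seed: int

    @property
    def n_plates(self) -> int:
        return 1 + max(w.plate for w in self.wells)

    def __len__(self) -> int:
        return len(self.wells)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for simulated supernatant readings.

    ``cv`` is the relative standard deviation of the multiplicative
    lognormal perturbation (mean-one, so expectations are unbiased);
    ``outlier_rate`` is the probability that a replicate is replaced by a
    gross error, scaled by a factor drawn uniformly from
    ``outlier_scale`` and applied in a random direction.
    """

    cv: float = 0.02
    outlier_rate: float = 0.02
    outlier_scale: tuple[float, float] = (1.5, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise DomainError("cv must be >= 0")
        if not (0 <= self.outlier_rate < 1):
            raise DomainError("outlier_rate must be in [0, 1)")


class FilterResult(NamedTuple):
    retained: tuple[float, ...]
    flagged: bool


def _well_label(index_on_plate: int) -> str:
    row, col = divmod(index_on_plate, 12)
    return f"{_ROWS[row]}{col + 1}"


def design_screen(
    protein_levels_mgml: Sequence[float],
    peg_levels_molar: Sequence[float],
    replicates: int = 3,
    seed: int = 0,
) -> PlateDesign:
    """Full-factorial screen design with randomized well positions.

    Every (protein level, PEG level, replicate) combination appears exactly
    once; wells fill consecutive 96-well plates in a seeded random order.
    """
    if len(protein_levels_mgml) == 0 or len(peg_levels_molar) == 0:
        raise DomainError("level lists must be non-empty")
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    combos = [
        (float(p), float(g), r)
        for p in protein_levels_mgml
        for g in peg_levels_molar
        for r in range(1, replicates + 1)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    wells = tuple(
        WellAssignment(
            plate=slot // WELLS_PER_PLATE,
            well=_well_label(slot % WELLS_PER_PLATE),
            c_p0_mgml=combos[k][0],
            c_peg_molar=combos[k][1],
            replicate=combos[k][2],
        )
        for slot, k in enumerate(order)
    )
    return PlateDesign(wells=wells, seed=seed)


def simulate_screen(
    params: IsothermParameters,
    design: PlateDesign,
    noise: NoiseModel,
    protein: ProteinSpec,
    ph: float = float("nan"),
) -> ScreenDataset:
    """Forward-simulate supernatant readings for every well of a design.

    Each unique condition is solved once (molar units); wells receive
    independent noise draws in design order, so the dataset is
    deterministic given the design and noise seeds.  Zero noise reproduces
    the solver output exactly.
    """
    conds = sorted({(w.c_p0_mgml, w.c_peg_molar) for w in design.wells})
    c_p0 = np.array([protein_mgml_to_molar(p, protein) for p, _ in conds])
    c_peg = np.array([g for _, g in conds])
    _, c_p = solve_equilibrium_batch(params, c_p0, c_peg)
    truth = {key: c_p[i] for i, key in enumerate(conds)}

    rng = np.random.default_rng(noise.seed)
    sigma = math.sqrt(math.log1p(noise.cv**2))  # lognormal sigma for exact CV
    readings: dict[tuple[float, float], list[tuple[int, float]]] = {
        key: [] for key in conds
    }
    for w in design.wells:
        value = truth[(w.c_p0_mgml, w.c_peg_molar)]
        if sigma > 0:
            value *= math.exp(rng.standard_normal() * sigma - 0.5 * sigma**2)
        if noise.outlier_rate > 0 and rng.random() < noise.outlier_rate:
            factor = rng.uniform(*noise.outlier_scale)
            if rng.random() < 0.5:
                factor = 1.0 / factor
            value *= factor
        readings[(w.c_p0_mgml, w.c_peg_molar)].append((w.replicate, value))

    records = []
    for (p_mgml, g), reps in readings.items():
        reps_sorted = tuple(v for _, v in sorted(reps))
        records.append(
            ScreenRecord(
                condition=Condition(
                    c_p0=protein_mgml_to_molar(p_mgml, protein),
                    c_peg=g,
                    protein_id=protein.name,
                    ph=ph,
                ),
                replicates=reps_sorted,
            )
        )
    records.sort(key=lambda r: (r.condition.c_p0, r.condition.c_peg))
    return ScreenDataset(
        records=records,
        protein_id=protein.name,
        ph=ph,
        source="simulated",
        molecular_weight=protein.molecular_weight,
    )


def triplicate_outlier_filter(
    replicates: Sequence[float],
    threshold_pct: float = 5.0,
    min_keep: int = 2,
) -> FilterResult:
    """Pretreatment filter on a replicate set.

    The percentage standard error is 100 * SEM / mean (SEM with the sample
    standard deviation).  While it exceeds ``threshold_pct`` and more than
    ``min_keep`` replicates remain, the replicate farthest from the median
    is dropped.  A set that still exceeds the threshold at ``min_keep``
    replicates — or whose mean is zero with nonzero spread, where the
    percentage is undefined — is returned unchanged-or-reduced with
    ``flagged=True``.
    """
    if len(replicates) < 2:
        raise DomainError("need at least 2 replicates")
    vals = [float(v) for v in replicates]
    while True:
        n = len(vals)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        sem = sd / math.sqrt(n)
        if sem == 0.0:
            return FilterResult(tuple(vals), False)
        if mean == 0.0:
            return FilterResult(tuple(vals), True)
        pct = 100.0 * sem / abs(mean)
        if pct <= threshold_pct:
            return FilterResult(tuple(vals), False)
        if n <= min_keep:
            return FilterResult(tuple(vals), True)
        med = float(np.median(vals))
        # drop the replicate farthest from the median (largest value on ties)
        idx = max(range(n), key=lambda i: (abs(vals[i] - med), vals[i]))
        vals.pop(idx)


def apply_outlier_filter(
    dataset: ScreenDataset, threshold_pct: float = 5.0
) -> ScreenDataset:
    """Apply :func:`triplicate_outlier_filter` to every record of a dataset."""
    records = []
    for rec in dataset.records:
        if len(rec.replicates) < 2:
            records.append(rec)
            continue
        retained, flagged = triplicate_outlier_filter(
            rec.replicates, threshold_pct=threshold_pct
        )
        records.append(
            ScreenRecord(condition=rec.condition, replicates=retained, flagged=flagged)
        )
    return dataset.with_records(records)
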