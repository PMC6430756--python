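"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from pegprec import (
    Condition,
    IsothermParameters,
    NoiseModel,
    REFERENCE_PARAMETERS,
    REFERENCE_PEG_MAX,
    REFERENCE_PROTEIN_SPECS,
    ScreenDataset,
    design_screen,
    equilibrium_residual,
    simulate_screen,
    standard_peg_levels,
    standard_protein_levels_mgml,
)


def bisection_root(params: IsothermParameters, condition: Condition, iters: int = 200) -> float:
    """Brute-force bisection oracle for the equilibrium root on [0, c_p0]."""
    lo, hi = 0.0, condition.c_p0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if equilibrium_residual(params, mid, condition) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def draw_random_instance(rng: np.random.Generator):
    """A random valid (parameters, condition) pair with sub-molar concentrations.

    Ranges bracket the published parameter sets while keeping the hydration
    exponent moderate, so residuals stay within double-precision range.
    """
    params = IsothermParameters(
        ln_k_eq=rng.uniform(5.0, 35.0),
        n=rng.uniform(0.5, 6.0),
        beta0=10.0 ** rng.uniform(-4.0, -2.0),
        beta1=rng.uniform(0.0, 100.0),
        beta2=rng.uniform(0.0, 2500.0),
    )
    condition = Condition(
        c_p0=10.0 ** rng.uniform(-5.0, -3.1),
        c_peg=10.0 ** rng.uniform(-2.5, -1.25),
    )
    return params, condition


def noiseless_dataset(key: str, seed: int = 1, replicates: int = 3) -> ScreenDataset:
    """Noise-free standard screen simulated from a reference parameter set."""
    design = design_screen(
        standard_protein_levels_mgml(),
        standard_peg_levels(REFERENCE_PEG_MAX[key]),
        replicates=replicates,
        seed=seed,
    )
    return simulate_screen(
        REFERENCE_PARAMETERS[key],
        design,
        NoiseModel(cv=0.0, outlier_rate=0.0, seed=seed),
        REFERENCE_PROTEIN_SPECS[key],
    )


@pytest.fixture(scope="session")
def lysozyme_params() -> IsothermParameters:
    return REFERENCE_PARAMETERS["lysozyme"]


@pytest.fixture(scope="session")
def lysozyme_dataset() -> ScreenDataset:
    return noiseless_dataset("lysozyme")
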