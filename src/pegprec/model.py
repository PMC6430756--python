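"""Core precipitation-isotherm model.

The model describes the equilibrium partitioning of a protein between
solution and precipitate when polyethylene glycol (PEG) is added.  The
precipitation of ``n`` protein molecules by one PEG molecule is treated as a
mass-action equilibrium in which the protein--protein complex is stabilized
by ``beta`` bulk-like ordered water molecules released from the hydrophobic
surfaces.  Collecting the constants yields the implicit isotherm

    k_eq = q**(1 + n*beta) / (c_p**n * c_peg),

with ``q`` the precipitated and ``c_p`` the dissolved (supernatant) protein
concentration, both in mol/L, and ``c_peg`` the PEG concentration in mol/L.
The hydration number depends on composition through

    beta = beta0 * exp(beta1 * c_peg + beta2 * c_p0),

where ``c_p0`` is the initial (total) protein concentration.  Total protein
is conserved between the phases: ``q + c_p = c_p0``.

All public concentrations are molar.  The classical semi-logarithmic Cohn
relation ``log10(S) = S0 - alpha*m`` is provided as an empirical baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, InvalidParameterError, SolverError

__all__ = [
    "IsothermParameters",
    "Condition",
    "EquilibriumState",
    "CohnParameters",
    "hydration_number",
    "equilibrium_residual",
    "solve_equilibrium",
    "solve_equilibrium_batch",
    "predict_supernatant_curve",
    "cohn_solubility",
]

#: default relative tolerance on the root q
DEFAULT_RTOL = 1e-12
#: default absolute tolerance on the isotherm residual (scaled by the
#: residual's endpoint magnitude when that exceeds unity)
DEFAULT_RESIDUAL_TOL = 1e-14


@dataclass(frozen=True)
class IsothermParameters:
    """The five constants of the mechanistic precipitation isotherm.

    Attributes
    ----------
    ln_k_eq : float
        Natural log of the lumped equilibrium coefficient (molar scale;
        absorbs the stoichiometric water-activity constant).
    n : float
        Number of protein molecules affected by one PEG molecule.  Need not
        be an integer; must be positive.
    beta0 : float
        Hydration number at infinite dilution of PEG and protein (> 0).
    beta1 : float
        PEG-concentration dependence of the hydration number, L/mol (>= 0).
    beta2 : float
        Initial-protein-concentration dependence, L/mol (>= 0).
    """

    ln_k_eq: float
    n: float
    beta0: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ln_k_eq):
            raise InvalidParameterError("ln_k_eq must be finite")
        if not (self.n > 0):
            raise InvalidParameterError(f"n must be > 0, got {self.n}")
        if not (self.beta0 > 0):
            raise InvalidParameterError(f"beta0 must be > 0, got {self.beta0}")
        if self.beta1 < 0 or self.beta2 < 0:
            raise InvalidParameterError("beta1 and beta2 must be >= 0")

    def to_dict(self) -> dict:
        return {
            "ln_k_eq": self.ln_k_eq,
            "n": self.n,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IsothermParameters":
        return cls(
            ln_k_eq=float(d["ln_k_eq"]),
            n=float(d["n"]),
            beta0=float(d["beta0"]),
            beta1=float(d["beta1"]),
            beta2=float(d["beta2"]),
        )


@dataclass(frozen=True)
class Condition:
    """Composition of one well: initial protein and PEG, both mol/L."""

    c_p0: float
    c_peg: float
    protein_id: str = ""
    ph: float = float("nan")

    def __post_init__(self) -> None:
        if self.c_p0 < 0 or self.c_peg < 0:
            raise DomainError(
                f"concentrations must be >= 0 (c_p0={self.c_p0}, c_peg={self.c_peg})"
            )


@dataclass(frozen=True)
class EquilibriumState:
    """Solved phase split for one condition (mol/L)."""

    condition: Condition
    q: float
    c_p: float


@dataclass(frozen=True)
class CohnParameters:
    """Cohn baseline: intercept ``s0`` (log mg/mL) and efficiency ``alpha``
    per % (w/w) PEG."""

    s0: float
    alpha: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.s0) and math.isfinite(self.alpha)):
            raise InvalidParameterError("Cohn parameters must be finite")


def hydration_number(params: IsothermParameters, c_peg: float, c_p0: float) -> float:
    """Hydration number ``beta = beta0 * exp(beta1*c_peg + beta2*c_p0)``.

    Strictly positive and non-decreasing in both concentrations; reduces to
    ``beta0`` at the origin.
    """
    if c_peg < 0 or c_p0 < 0:
        raise DomainError("c_peg and c_p0 must be >= 0")
    try:
        beta = params.beta0 * math.exp(params.beta1 * c_peg + params.beta2 * c_p0)
    except OverflowError:
        beta = math.inf
    if not math.isfinite(beta):
        raise InvalidParameterError(
            f"hydration number overflowed (beta1*c_peg + beta2*c_p0 = "
            f"{params.beta1 * c_peg + params.beta2 * c_p0:.3g})"
        )
    return beta


def equilibrium_residual(
    params: IsothermParameters, q: float, condition: Condition
) -> float:
    """Signed isotherm residual ``f(q)``.

    ``f(q) = q**(1+n*beta) - exp(ln_k_eq) * (c_p0-q)**n * c_peg`` with beta
    evaluated at (c_peg, c_p0).  ``f(0) <= 0``, ``f(c_p0) >= 0``, and f is
    strictly increasing on [0, c_p0] for sub-molar concentrations, so the
    equilibrium root is unique.  Powers are evaluated in log space to avoid
    overflow/underflow of the large exponent ``1 + n*beta``.
    """
    c_p0, c_peg = condition.c_p0, condition.c_peg
    if q < 0 or q > c_p0:
        raise DomainError(f"q={q} outside [0, c_p0={c_p0}]")
    beta = hydration_number(params, c_peg, c_p0)
    expo = 1.0 + params.n * beta
    t1 = 0.0 if q == 0.0 else math.exp(expo * math.log(q))
    rem = c_p0 - q
    if rem > 0.0 and c_peg > 0.0:
        t2 = math.exp(params.ln_k_eq + params.n * math.log(rem) + math.log(c_peg))
    else:
        t2 = 0.0
    return t1 - t2


def solve_equilibrium(
    params: IsothermParameters,
    condition: Condition,
    rtol: float = DEFAULT_RTOL,
    residual_tol: float = DEFAULT_RESIDUAL_TOL,
) -> EquilibriumState:
    """Solve the implicit isotherm for one condition.

    Uses a bracketed derivative-free root find (Brent) on [0, c_p0]; the
    residual's endpoint signs guarantee the bracket.  Degenerate inputs
    (no PEG or no protein) return q = 0 without invoking the solver.  Mass
    balance ``c_p = c_p0 - q`` closes the state.
    """
    c_p0, c_peg = condition.c_p0, condition.c_peg
    if c_p0 == 0.0 or c_peg == 0.0:
        return EquilibriumState(condition=condition, q=0.0, c_p=c_p0)

    def f(q: float) -> float:
        return equilibrium_residual(params, q, condition)

    f0, f1 = f(0.0), f(c_p0)
    if f0 > 0.0 or f1 < 0.0:
        raise SolverError(
            "no sign change on [0, c_p0]",
            payload={"params": params.to_dict(), "condition": condition, "f0": f0, "f1": f1},
        )
    try:
        q = brentq(f, 0.0, c_p0, xtol=1e-300, rtol=max(rtol, 4 * np.finfo(float).eps))
    except Exception as exc:  # pragma: no cover - defensive
        raise SolverError(
            f"root solve failed: {exc}",
            payload={"params": params.to_dict(), "condition": condition},
        ) from exc
    resid = f(q)
    scale = max(1.0, abs(f0), abs(f1))
    if abs(resid) > residual_tol * scale:
        # Steep residuals (large hydration exponent) cannot reach a small
        # residual even at machine-precision q; verify root enclosure in a
        # narrow window around q instead.
        lo = max(0.0, q * (1.0 - 10.0 * rtol))
        hi = min(c_p0, q * (1.0 + 10.0 * rtol))
        if not (f(lo) <= 0.0 <= f(hi)):
            raise SolverError(
                f"residual {resid:.3g} above tolerance and no enclosure",
                payload={"params": params.to_dict(), "condition": condition, "q": q},
            )
    return EquilibriumState(condition=condition, q=q, c_p=c_p0 - q)


def _newton_log_branch(a, b, r, ln_c0, x0, max_iter, xtol):
    """Vectorized safeguarded Newton for ``a*x - b*log(c0 - exp(x)) - r = 0``.

    The function is increasing and convex in x on (-inf, ln c0), and x0 is
    chosen on the non-negative side, so Newton iterates decrease
    monotonically to the root and stay inside the domain.
    """
    x = np.array(x0, dtype=float, copy=True)
    c0 = np.exp(ln_c0)
    for _ in range(max_iter):
        u = np.exp(x)
        denom = c0 - u
        # If rounding put an iterate at the domain edge, nudge it back in.
        bad = denom <= 0.0
        if np.any(bad):
            x = np.where(bad, x - 1e-12 * np.abs(x) - 1e-300, x)
            u = np.exp(x)
            denom = c0 - u
        with np.errstate(divide="ignore"):
            fval = a * x - b * np.log(denom) - r
        step = fval / (a + b * u / denom)
        x_new = x - step
        if np.all(np.abs(step) <= xtol * np.maximum(1.0, np.abs(x))):
            return x_new
        x = x_new
    return x


def solve_equilibrium_batch(
    params: IsothermParameters,
    c_p0: np.ndarray,
    c_peg: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    max_iter: int = 80,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the isotherm for arrays of conditions; returns ``(q, c_p)``.

    Works in log space on whichever phase variable is the smaller one, so
    both nearly-complete and barely-started precipitation are resolved
    without cancellation: with rhs = ln_k_eq + ln c_peg, the root of

        (1 + n*beta) * ln q - n * ln(c_p0 - q) = rhs

    is bracketed by closed-form upper bounds obtained by ignoring depletion;
    the sign of the residual at q = c_p0/2 (available in closed form)
    selects the branch.  Agrees with :func:`solve_equilibrium` to solver
    tolerance; used by the fitting loop where per-point ``brentq`` would
    dominate runtime.
    """
    c_p0 = np.asarray(c_p0, dtype=float)
    c_peg = np.asarray(c_peg, dtype=float)
    if c_p0.shape != c_peg.shape:
        raise DomainError("c_p0 and c_peg must have the same shape")
    if np.any(c_p0 < 0) or np.any(c_peg < 0):
        raise DomainError("concentrations must be >= 0")

    q = np.zeros_like(c_p0)
    c_p = c_p0.copy()
    active = (c_p0 > 0) & (c_peg > 0)
    if not np.any(active):
        return q, c_p

    cp0 = c_p0[active]
    cpeg = c_peg[active]
    expo_arg = params.beta1 * cpeg + params.beta2 * cp0
    if np.any(expo_arg > 700):
        raise InvalidParameterError("hydration number overflowed in batch solve")
    beta = params.beta0 * np.exp(expo_arg)
    e = 1.0 + params.n * beta
    n = params.n
    rhs = params.ln_k_eq + np.log(cpeg)
    ln_c0 = np.log(cp0)

    # Residual sign at q = c_p0/2: (e - n)*ln(c_p0/2) - rhs.
    g_mid = (e - n) * (ln_c0 + math.log(0.5)) - rhs
    q_branch = g_mid >= 0.0  # root in (0, c_p0/2]: solve for q

    x = np.empty_like(cp0)
    xtol = max(rtol, 1e-14)

    if np.any(q_branch):
        m = q_branch
        x0 = np.minimum((rhs[m] + n * ln_c0[m]) / e[m], ln_c0[m] + math.log(0.5))
        x[m] = _newton_log_branch(e[m], n, rhs[m], ln_c0[m], x0, max_iter, xtol)
    if np.any(~q_branch):
        m = ~q_branch
        # solve for supernatant s = c_p0 - q:  n*ln s - e*ln(c_p0-s) + rhs = 0
        x0 = np.minimum((e[m] * ln_c0[m] - rhs[m]) / n, ln_c0[m] + math.log(0.5))
        x[m] = _newton_log_branch(n, e[m], -rhs[m], ln_c0[m], x0, max_iter, xtol)

    val = np.exp(x)
    q_act = np.where(q_branch, val, cp0 - val)
    s_act = np.where(q_branch, cp0 - val, val)
    q[active] = np.clip(q_act, 0.0, cp0)
    c_p[active] = np.clip(s_act, 0.0, cp0)
    return q, c_p


def predict_supernatant_curve(
    params: IsothermParameters,
    c_p0: float,
    peg_grid,
    rtol: float = DEFAULT_RTOL,
) -> np.ndarray:
    """Supernatant concentration along a PEG grid (element-wise solve).

    Non-increasing along an ascending grid; ``c_peg = 0`` maps to ``c_p0``.
    """
    out = np.empty(len(peg_grid), dtype=float)
    for i, c_peg in enumerate(peg_grid):
        try:
            state = solve_equilibrium(
                params, Condition(c_p0=c_p0, c_peg=float(c_peg)), rtol=rtol
            )
        except SolverError as exc:
            exc.payload["grid_index"] = i
            raise
        out[i] = state.c_p
    return out


def cohn_solubility(cohn: CohnParameters, m: float, base: float = 10.0) -> float:
    """Cohn baseline solubility ``S = base**(s0 - alpha*m)`` in mg/mL.

    ``m`` is the PEG content in % (w/w); ``base`` defaults to 10 (the
    historical semi-log convention) and is configurable.
    """
    if m < 0:
        raise DomainError("PEG content m must be >= 0")
    return float(base ** (cohn.s0 - cohn.alpha * m))
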