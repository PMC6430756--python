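"""Parameter estimation for the precipitation isotherm.

The central object is :class:`PrecipitationIsotherm`, a scikit-learn style
regressor: ``X`` is an ``(n_samples, 2)`` array of ``[c_p0, c_peg]`` in
mol/L and ``y`` the observed replicate-mean supernatant concentration in
mol/L.  Fitting minimizes the sum of squared supernatant residuals by a
seeded, bounded simulated-annealing search (``scipy.optimize.dual_annealing``)
with restarts, each followed by a trust-region least-squares polish.  The
equilibrium coefficient and the dilute-limit hydration number are searched
on the log scale (they span many orders of magnitude across proteins);
``n``, ``beta1`` and ``beta2`` are searched linearly.

The calibration/validation split removes the records at the three highest
distinct initial-protein levels and the two highest distinct PEG levels
from the calibration set; the complement is the validation set.  On the
standard 8 x 12 screen this yields 50 calibration and 46 validation
records.  Prediction error on the validation set is reported as the root
mean square error of prediction (RMSEP), in mol/L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import dual_annealing, least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import ScreenDataset
from .exceptions import ConfigError, IdentifiabilityError
from .model import IsothermParameters, solve_equilibrium_batch

__all__ = [
    "DEFAULT_BOUNDS",
    "PrecipitationIsotherm",
    "FitResult",
    "sse_objective",
    "fit_parameters",
    "split_calibration_validation",
    "rmsep",
]

#: Search bounds in the optimizer's coordinates
#: (ln_k_eq, n, ln(beta0), beta1, beta2); chosen to cover the published
#: parameter sets for proteins from lysozyme to mAbs with wide margin.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "ln_k_eq": (0.0, 60.0),
    "n": (0.5, 10.0),
    "ln_beta0": (-12.0, 0.0),
    "beta1": (0.0, 1.0e3),
    "beta2": (0.0, 1.0e5),
}

_PARAM_ORDER = ("ln_k_eq", "n", "ln_beta0", "beta1", "beta2")


def _theta_to_params(theta: np.ndarray) -> IsothermParameters:
    return IsothermParameters(
        ln_k_eq=float(theta[0]),
        n=float(theta[1]),
        beta0=float(np.exp(theta[2])),
        beta1=float(theta[3]),
        beta2=float(theta[4]),
    )


def _params_to_theta(params: IsothermParameters) -> np.ndarray:
    return np.array(
        [params.ln_k_eq, params.n, np.log(params.beta0), params.beta1, params.beta2]
    )


def _restart_seed(seed: int, restart: int) -> int:
    """Deterministic per-restart seed below 2**31."""
    state = np.random.SeedSequence(entropy=seed, spawn_key=(restart,)).generate_state(1)
    return int(state[0] % (2**31 - 1))


class PrecipitationIsotherm(RegressorMixin, BaseEstimator):
    """Scikit-learn style regressor for the precipitation isotherm.

    Parameters
    ----------
    bounds : dict, optional
        Per-parameter search intervals keyed by
        ``ln_k_eq, n, ln_beta0, beta1, beta2``; defaults to
        :data:`DEFAULT_BOUNDS`.
    restarts : int
        Number of independently seeded annealing restarts.
    random_state : int
        Base seed; restart seeds are derived deterministically from it.
    maxiter : int
        Annealing iteration budget per restart.
    stop_rmse : float
        Restarts stop early once the best calibration RMSE falls below
        this (mol/L); effectively only triggers on noise-free data.
    solver_rtol : float
        Relative tolerance of the inner equilibrium solves.
    polish : bool
        Run a bounded trust-region least-squares refinement after each
        annealing restart.

    Attributes
    ----------
    params_ : IsothermParameters
        Best parameters found.
    objective_ : float
        Sum of squared supernatant residuals at ``params_`` (mol^2/L^2).
    rmse_ : float
        Root mean square residual on the training data (mol/L).
    diagnostics_ : dict
        Per-restart seeds, objectives, and iteration counts.
    """

    def __init__(
        self,
        bounds: dict | None = None,
        restarts: int = 10,
        random_state: int = 0,
        maxiter: int = 300,
        stop_rmse: float = 1.0e-10,
        solver_rtol: float = 1.0e-12,
        polish: bool = True,
    ):
        self.bounds = bounds
        self.restarts = restarts
        self.random_state = random_state
        self.maxiter = maxiter
        self.stop_rmse = stop_rmse
        self.solver_rtol = solver_rtol
        self.polish = polish

    # -- internals ---------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns [c_p0, c_peg] in mol/L")
        if not np.all(np.isfinite(X)) or np.any(X < 0):
            raise ValueError("X must be finite and non-negative")
        return X

    def _predict_theta(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        _, c_p = solve_equilibrium_batch(
            _theta_to_params(theta), X[:, 0], X[:, 1], rtol=self.solver_rtol
        )
        return c_p

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be a 1-D array matching X")
        if X.shape[0] < 5:
            raise IdentifiabilityError("need at least 5 conditions to fit 5 parameters")
        if np.unique(X[:, 0]).size < 2 or np.unique(X[:, 1]).size < 2:
            raise IdentifiabilityError(
                "need >= 2 distinct protein levels and >= 2 distinct PEG levels"
            )

        bounds = dict(DEFAULT_BOUNDS if self.bounds is None else self.bounds)
        missing = [k for k in _PARAM_ORDER if k not in bounds]
        if missing:
            raise ConfigError(f"bounds missing entries for {missing}")
        lo = np.array([bounds[k][0] for k in _PARAM_ORDER])
        hi = np.array([bounds[k][1] for k in _PARAM_ORDER])

        # Residuals are scaled by the data magnitude so the optimizer and
        # its stopping tolerances see O(1) numbers regardless of protein.
        scale = float(np.max(np.abs(y))) or 1.0

        def residuals(theta: np.ndarray) -> np.ndarray:
            return (self._predict_theta(theta, X) - y) / scale

        def objective(theta: np.ndarray) -> float:
            r = residuals(theta)
            return float(r @ r)

        stop_sse = X.shape[0] * (self.stop_rmse / scale) ** 2
        best_theta = None
        best_sse = np.inf
        restart_log = []
        for i in range(self.restarts):
            seed_i = _restart_seed(self.random_state, i)
            res = dual_annealing(
                objective,
                bounds=list(zip(lo, hi)),
                seed=seed_i,
                maxiter=self.maxiter,
            )
            theta_i, sse_i, nfev = res.x, float(res.fun), int(res.nfev)
            if self.polish:
                pol = least_squares(
                    residuals,
                    theta_i,
                    bounds=(lo, hi),
                    method="trf",
                    x_scale="jac",
                    ftol=1e-15,
                    xtol=1e-15,
                    gtol=1e-15,
                    max_nfev=20000,
                )
                if float(pol.fun @ pol.fun) < sse_i:
                    theta_i, sse_i = pol.x, float(pol.fun @ pol.fun)
                nfev += int(pol.nfev)
            restart_log.append({"seed": seed_i, "sse": sse_i * scale**2, "nfev": nfev})
            if sse_i < best_sse:
                best_sse, best_theta = sse_i, theta_i
            if best_sse <= stop_sse:
                break

        self.params_ = _theta_to_params(best_theta)
        self.objective_ = best_sse * scale**2
        self.rmse_ = float(np.sqrt(self.objective_ / X.shape[0]))
        self.n_features_in_ = 2
        self.diagnostics_ = {
            "random_state": self.random_state,
            "restarts_requested": self.restarts,
            "restarts_run": len(restart_log),
            "maxiter": self.maxiter,
            "bounds": {k: list(bounds[k]) for k in _PARAM_ORDER},
            "restart_log": restart_log,
            "converged": bool(np.isfinite(best_sse)),
        }
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = self._validate_X(X)
        return self._predict_theta(_params_to_theta(self.params_), X)


@dataclass
class FitResult:
    """Outcome of a calibration run, JSON-serializable for provenance."""

    params: IsothermParameters
    objective: float
    rmse_calibration: float
    rmsep_validation: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective": self.objective,
            "rmse_calibration": self.rmse_calibration,
            "rmsep_validation": self.rmsep_validation,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            params=IsothermParameters.from_dict(d["params"]),
            objective=float(d["objective"]),
            rmse_calibration=float(d["rmse_calibration"]),
            rmsep_validation=(
                None if d.get("rmsep_validation") is None else float(d["rmsep_validation"])
            ),
            diagnostics=dict(d.get("diagnostics", {})),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def sse_objective(params: IsothermParameters, data: ScreenDataset) -> float:
    """Sum of squared (observed mean - predicted) supernatant residuals."""
    if len(data) == 0:
        raise ConfigError("dataset is empty")
    c_p0, c_peg, y = data.arrays()
    _, c_p = solve_equilibrium_batch(params, c_p0, c_peg)
    r = y - c_p
    return float(r @ r)


def rmsep(params: IsothermParameters, data: ScreenDataset) -> float:
    """Root mean square error of prediction over a dataset (mol/L)."""
    if len(data) == 0:
        raise ConfigError("dataset is empty")
    return float(np.sqrt(sse_objective(params, data) / len(data)))


def split_calibration_validation(
    data: ScreenDataset,
    n_protein_excluded: int = 3,
    n_peg_excluded: int = 2,
) -> tuple[ScreenDataset, ScreenDataset]:
    """Level-based calibration/validation split.

    Calibration keeps records whose initial-protein level is not among the
    ``n_protein_excluded`` highest distinct levels AND whose PEG level is
    not among the ``n_peg_excluded`` highest; validation is the complement.
    The partition is exhaustive and disjoint, and duplicate conditions stay
    together because membership is decided per level.
    """
    p_levels = data.protein_levels()
    g_levels = data.peg_levels()
    if p_levels.size < n_protein_excluded + 1 or g_levels.size < n_peg_excluded + 1:
        raise ConfigError(
            f"need > {n_protein_excluded} distinct protein and > {n_peg_excluded} "
            f"distinct PEG levels, got {p_levels.size} and {g_levels.size}"
        )
    cal_p = set(p_levels[: p_levels.size - n_protein_excluded])
    cal_g = set(g_levels[: g_levels.size - n_peg_excluded])
    cal, val = [], []
    for rec in data.records:
        if rec.condition.c_p0 in cal_p and rec.condition.c_peg in cal_g:
            cal.append(rec)
        else:
            val.append(rec)
    return data.with_records(cal), data.with_records(val)


def fit_parameters(
    data: ScreenDataset,
    bounds: dict | None = None,
    seed: int = 0,
    restarts: int = 10,
    maxiter: int = 300,
    validation: ScreenDataset | None = None,
) -> FitResult:
    """Fit isotherm parameters to a screen dataset (replicate means).

    Thin wrapper over :class:`PrecipitationIsotherm`; optionally evaluates
    RMSEP on a held-out validation dataset.  Deterministic given
    ``(seed, restarts, bounds, data)``.
    """
    if len(data) < 5:
        raise IdentifiabilityError("need at least 5 conditions to fit 5 parameters")
    if data.protein_levels().size < 2 or data.peg_levels().size < 2:
        raise IdentifiabilityError(
            "need >= 2 distinct protein levels and >= 2 distinct PEG levels"
        )
    c_p0, c_peg, y = data.arrays()
    est = PrecipitationIsotherm(
        bounds=bounds, restarts=restarts, random_state=seed, maxiter=maxiter
    )
    est.fit(np.column_stack([c_p0, c_peg]), y)
    rmsep_val = None if validation is None else rmsep(est.params_, validation)
    return FitResult(
        params=est.params_,
        objective=est.objective_,
        rmse_calibration=est.rmse_,
        rmsep_validation=rmsep_val,
        diagnostics=est.diagnostics_,
    )
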