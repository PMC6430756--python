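"""Core isotherm: hydration number, residual, equilibrium solve, Cohn baseline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pegprec import (
    CohnParameters,
    Condition,
    DomainError,
    InvalidParameterError,
    IsothermParameters,
    cohn_solubility,
    equilibrium_residual,
    hydration_number,
    predict_supernatant_curve,
    solve_equilibrium,
    solve_equilibrium_batch,
)
from conftest import bisection_root, draw_random_instance


@pytest.fixture
def generic_params():
    return IsothermParameters(ln_k_eq=20.0, n=3.0, beta0=1e-3, beta1=100.0, beta2=2000.0)


class TestHydrationNumber:
    def test_reduces_to_beta0_at_origin(self, generic_params):
        assert hydration_number(generic_params, 0.0, 0.0) == generic_params.beta0

    def test_lysozyme_value(self, lysozyme_params):
        # beta0 * exp(beta1*0.02 + beta2*1.0274e-4) with the lysozyme constants
        beta = hydration_number(lysozyme_params, 0.02, 1.0274e-4)
        assert beta == pytest.approx(5.482e-2, rel=1e-3)

    def test_monotone_in_both_arguments(self, generic_params):
        base = hydration_number(generic_params, 0.01, 1e-4)
        assert hydration_number(generic_params, 0.015, 1e-4) > base
        assert hydration_number(generic_params, 0.01, 2e-4) > base

    def test_overflow_raises(self, generic_params):
        with pytest.raises(InvalidParameterError):
            hydration_number(generic_params, 100.0, 1.0)

    def test_negative_concentration_rejected(self, generic_params):
        with pytest.raises(DomainError):
            hydration_number(generic_params, -0.01, 0.0)


class TestParameterInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0.0},
            {"n": -1.0},
            {"beta0": 0.0},
            {"beta1": -1.0},
            {"beta2": -1.0},
            {"ln_k_eq": float("inf")},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(ln_k_eq=10.0, n=2.0, beta0=1e-3, beta1=10.0, beta2=100.0)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            IsothermParameters(**base)

    def test_negative_condition_rejected(self):
        with pytest.raises(DomainError):
            Condition(c_p0=-1e-4, c_peg=0.01)


class TestResidual:
    def test_endpoint_signs(self, lysozyme_params):
        cond = Condition(c_p0=8.219e-4, c_peg=0.04)
        f0 = equilibrium_residual(lysozyme_params, 0.0, cond)
        f1 = equilibrium_residual(lysozyme_params, cond.c_p0, cond)
        assert f0 < 0 < f1

    def test_zero_q_value(self, generic_params):
        cond = Condition(c_p0=2e-4, c_peg=0.02)
        expected = -math.exp(
            generic_params.ln_k_eq + generic_params.n * math.log(cond.c_p0)
        ) * cond.c_peg
        assert equilibrium_residual(generic_params, 0.0, cond) == pytest.approx(
            expected, rel=1e-12
        )

    def test_full_precipitation_value(self, generic_params):
        cond = Condition(c_p0=2e-4, c_peg=0.02)
        beta = hydration_number(generic_params, cond.c_peg, cond.c_p0)
        expected = math.exp((1 + generic_params.n * beta) * math.log(cond.c_p0))
        assert equilibrium_residual(generic_params, cond.c_p0, cond) == pytest.approx(
            expected, rel=1e-12
        )

    def test_q_outside_bracket_rejected(self, generic_params):
        cond = Condition(c_p0=2e-4, c_peg=0.02)
        with pytest.raises(DomainError):
            equilibrium_residual(generic_params, 3e-4, cond)

    def test_strictly_increasing_in_q(self):
        rng = np.random.default_rng(20240501)
        checked = 0
        while checked < 50:
            params, cond = draw_random_instance(rng)
            beta = hydration_number(params, cond.c_peg, cond.c_p0)
            # keep the power representable across the whole grid
            if (1 + params.n * beta) * math.log(0.01 * cond.c_p0) < -700:
                continue
            qs = np.linspace(0.01, 0.99, 200) * cond.c_p0
            vals = [equilibrium_residual(params, q, cond) for q in qs]
            assert np.all(np.diff(vals) > 0)
            checked += 1


class TestSolveEquilibrium:
    def test_no_peg_means_no_precipitate(self, lysozyme_params):
        state = solve_equilibrium(lysozyme_params, Condition(c_p0=5e-4, c_peg=0.0))
        assert state.q == 0.0 and state.c_p == 5e-4

    def test_no_protein(self, lysozyme_params):
        state = solve_equilibrium(lysozyme_params, Condition(c_p0=0.0, c_peg=0.02))
        assert state.q == 0.0 and state.c_p == 0.0

    def test_matches_bisection_oracle(self, lysozyme_params):
        cond = Condition(c_p0=8.219e-4, c_peg=0.040)
        state = solve_equilibrium(lysozyme_params, cond)
        oracle = bisection_root(lysozyme_params, cond)
        assert state.q == pytest.approx(oracle, rel=1e-10)

    def test_mass_conservation(self, lysozyme_params):
        cond = Condition(c_p0=4e-4, c_peg=0.03)
        state = solve_equilibrium(lysozyme_params, cond)
        assert abs(state.q + state.c_p - cond.c_p0) <= 1e-12 * cond.c_p0

    def test_vanishing_peg_limit(self):
        # at each protein's own maximum screen concentration, a vanishing
        # PEG level leaves essentially everything in solution
        from pegprec import (
            REFERENCE_PARAMETERS,
            REFERENCE_PROTEIN_SPECS,
            protein_mgml_to_molar,
        )

        for key, params in REFERENCE_PARAMETERS.items():
            c_p0 = protein_mgml_to_molar(12.0, REFERENCE_PROTEIN_SPECS[key])
            state = solve_equilibrium(params, Condition(c_p0=c_p0, c_peg=1e-12))
            assert state.q < 1e-6 * c_p0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_oracle_agreement_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        params, cond = draw_random_instance(rng)
        state = solve_equilibrium(params, cond)
        oracle = bisection_root(params, cond)
        assert state.q == pytest.approx(oracle, rel=1e-10, abs=1e-300)
        assert 0.0 <= state.q <= cond.c_p0


class TestBatchSolver:
    def test_agrees_with_scalar_path(self):
        rng = np.random.default_rng(7)
        params_list, conds = [], []
        for _ in range(100):
            p, c = draw_random_instance(rng)
            params_list.append(p)
            conds.append(c)
        for p, c in zip(params_list, conds):
            q, cp = solve_equilibrium_batch(p, np.array([c.c_p0]), np.array([c.c_peg]))
            state = solve_equilibrium(p, c)
            assert q[0] == pytest.approx(state.q, rel=1e-9, abs=1e-300)

    def test_degenerate_entries(self, lysozyme_params):
        q, cp = solve_equilibrium_batch(
            lysozyme_params, np.array([0.0, 5e-4, 5e-4]), np.array([0.02, 0.0, 0.02])
        )
        assert q[0] == 0.0 and cp[0] == 0.0
        assert q[1] == 0.0 and cp[1] == 5e-4
        assert 0 < q[2] <= 5e-4

    def test_mass_conservation_on_grids(self):
        from pegprec import (
            REFERENCE_PARAMETERS,
            REFERENCE_PEG_MAX,
            REFERENCE_PROTEIN_SPECS,
            protein_mgml_to_molar,
            standard_peg_levels,
            standard_protein_levels_mgml,
        )

        for key, params in REFERENCE_PARAMETERS.items():
            spec = REFERENCE_PROTEIN_SPECS[key]
            p = np.array(
                [protein_mgml_to_molar(v, spec) for v in standard_protein_levels_mgml()]
            )
            g = standard_peg_levels(REFERENCE_PEG_MAX[key])
            P, G = np.meshgrid(p, g, indexing="ij")
            q, cp = solve_equilibrium_batch(params, P.ravel(), G.ravel())
            assert np.all(np.abs(q + cp - P.ravel()) <= 1e-12 * P.ravel())


class TestPredictCurve:
    def test_empty_grid(self, lysozyme_params):
        assert len(predict_supernatant_curve(lysozyme_params, 5e-4, [])) == 0

    def test_zero_peg_returns_c_p0(self, lysozyme_params):
        curve = predict_supernatant_curve(lysozyme_params, 5e-4, [0.0])
        assert curve[0] == 5e-4

    def test_monotone_non_increasing(self, lysozyme_params):
        grid = np.linspace(0.056 / 12, 0.056, 12)
        curve = predict_supernatant_curve(lysozyme_params, 8.219e-4, grid)
        assert np.all(np.diff(curve) <= 0)


class TestCohnBaseline:
    @pytest.mark.parametrize(
        "s0, alpha, m, expected",
        [(1.0, 0.5, 0.0, 10.0), (1.0, 0.0, 50.0, 10.0), (1.0, 0.1, 10.0, 1.0)],
    )
    def test_values(self, s0, alpha, m, expected):
        assert cohn_solubility(CohnParameters(s0, alpha), m) == pytest.approx(expected)

    def test_alternative_base(self):
        assert cohn_solubility(CohnParameters(1.0, 0.0), 0.0, base=math.e) == pytest.approx(
            math.e
        )

    def test_negative_peg_rejected(self):
        with pytest.raises(DomainError):
            cohn_solubility(CohnParameters(1.0, 0.1), -1.0)
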