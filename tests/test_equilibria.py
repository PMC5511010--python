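"""Speciation solver: cubic coefficients, root selection, mass balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chapbind.equilibria import (
    BindingModel,
    CubicCoefficients,
    EquilibriumParams,
    InvalidParameterError,
    MixtureTotals,
    cubic_coefficients,
    solve_free_chaperone,
    solve_free_chaperone_oracle,
    species_concentrations,
)

K_UN = 22.7


class TestCubicCoefficients:
    def test_no_binding_degenerates_to_linear_equation(self):
        p = EquilibriumParams(K_UN, math.inf, math.inf)
        c = cubic_coefficients(p, MixtureTotals(6e-4, 3e-4), BindingModel.LINEAR)
        assert c.a == 0 and c.b == 0
        assert c.c == 1 + K_UN
        assert c.d == -(1 + K_UN) * 3e-4

    def test_zero_chaperone_makes_zero_a_root(self):
        p = EquilibriumParams(K_UN, 1e-6, 1e-6)
        c = cubic_coefficients(p, MixtureTotals(6e-4, 0.0), BindingModel.LINEAR)
        assert c.d == 0
        assert c(0.0) == 0

    @pytest.mark.parametrize("kind", list(BindingModel), ids=lambda m: m.value)
    def test_matches_direct_substitution(self, kind):
        """Coefficients agree with the printed formulas evaluated by hand."""
        p = EquilibriumParams(K_UN, 1e-6, 2e-6)
        N_T, K_T = 6e-4, 6e-4
        K1, K2 = 1e6, 5e5
        c = cubic_coefficients(p, MixtureTotals(N_T, K_T), kind)
        assert c.a == pytest.approx(K1 * K2, rel=1e-12)
        if kind is BindingModel.LINEAR:
            assert c.b == pytest.approx(K1 + K1 * K2 * (2 * N_T - K_T), rel=1e-12)
            assert c.c == pytest.approx(1 + K_UN + K1 * (N_T - K_T), rel=1e-12)
        else:
            assert c.b == pytest.approx(K1 + K2 + K1 * K2 * (2 * N_T - K_T), rel=1e-12)
            assert c.c == pytest.approx(1 + K_UN + (K1 + K2) * (N_T - K_T), rel=1e-12)
        assert c.d == pytest.approx(-(1 + K_UN) * K_T, rel=1e-12)

    def test_root_satisfies_cubic(self, model):
        p = EquilibriumParams(K_UN, 1e-6, 1e-6)
        t = MixtureTotals(6e-4, 6e-4)
        c = cubic_coefficients(p, t, model)
        x = solve_free_chaperone(p, t, model)
        assert abs(c(x)) / abs(c.d) < 1e-9

    def test_non_finite_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            EquilibriumParams(math.nan, 1e-6, 1e-6)
        with pytest.raises(InvalidParameterError):
            MixtureTotals(math.inf, 0.0)


class TestFreeChaperone:
    def test_nothing_binds_free_equals_total(self, model):
        p = EquilibriumParams(K_UN, math.inf, math.inf)
        assert solve_free_chaperone(p, MixtureTotals(6e-4, 3e-4), model) == 3e-4

    def test_zero_chaperone(self, model, tight_params):
        assert solve_free_chaperone(tight_params, MixtureTotals(6e-4, 0.0), model) == 0.0

    def test_tight_binding_root_is_tiny_and_matches_oracle(self, tight_params):
        t = MixtureTotals(6e-4, 3e-4)
        x = solve_free_chaperone(tight_params, t, BindingModel.LINEAR)
        ref = solve_free_chaperone_oracle(tight_params, t, BindingModel.LINEAR)
        assert x < 1e-3 * t.K_T
        assert x == pytest.approx(ref, rel=1e-10)

    def test_oracle_bracket_sign_argument(self, model, tight_params):
        # g(0) = -K_T < 0; the oracle must succeed for any valid totals
        for K_T in (1e-9, 1e-6, 1e-3, 5e-3):
            x = solve_free_chaperone_oracle(tight_params, MixtureTotals(6e-4, K_T), model)
            assert 0 <= x <= K_T

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(
        log_kd1=st.floats(-12, -2),
        log_kd2=st.floats(-12, -2),
        K_UN_=st.floats(0, 100),
        N_T=st.floats(0, 5e-3),
        K_T=st.floats(0, 5e-3),
        kind=st.sampled_from(list(BindingModel)),
    )
    def test_cubic_path_agrees_with_bracketed_oracle(
        self, log_kd1, log_kd2, K_UN_, N_T, K_T, kind
    ):
        p = EquilibriumParams(K_UN_, 10**log_kd1, 10**log_kd2)
        t = MixtureTotals(N_T, K_T)
        a = solve_free_chaperone(p, t, kind)
        b = solve_free_chaperone_oracle(p, t, kind)
        # absolute floor: the bracketed oracle locates the root to machine
        # precision of [0, K_T]; when the root is many orders of magnitude
        # smaller than K_T, relative agreement is conditioning-limited
        assert a == pytest.approx(b, rel=1e-10, abs=1e-15 * max(K_T, 1e-30))

    def test_free_chaperone_nondecreasing_in_total(self, model, tight_params):
        K_Ts = np.linspace(0, 3e-3, 60)
        xs = [
            solve_free_chaperone(tight_params, MixtureTotals(6e-4, kt), model)
            for kt in K_Ts
        ]
        assert all(b >= a - 1e-18 for a, b in zip(xs, xs[1:]))


class TestSpeciesConcentrations:
    def test_no_chaperone_pure_folding_equilibrium(self, model):
        p = EquilibriumParams(K_UN, 1e-7, 1e-6)
        sp = species_concentrations(p, MixtureTotals(6e-4, 0.0), model)
        assert sp.U == pytest.approx(6e-4 / (1 + K_UN), rel=1e-12)
        assert sp.N == pytest.approx(K_UN * sp.U, rel=1e-12)
        assert sp.bound_1to1 == 0 and sp.bound_2to1 == 0

    def test_mass_balance_and_equilibrium_relations(self, model):
        p = EquilibriumParams(K_UN, 1e-7, 1e-6)
        t = MixtureTotals(6e-4, 1.2e-3)
        sp = species_concentrations(p, t, model)
        assert sp.client_total == pytest.approx(t.N_T, rel=1e-9)
        assert sp.chaperone_total == pytest.approx(t.K_T, rel=1e-9)
        assert sp.N / sp.U == pytest.approx(K_UN, rel=1e-12)
        if model is BindingModel.LINEAR:
            assert sp.UK == pytest.approx(p.K1 * sp.U * sp.K, rel=1e-12)
            assert sp.UK2 == pytest.approx(p.K1 * p.K2 * sp.U * sp.K**2, rel=1e-9)
        else:
            assert sp.UKA == pytest.approx(p.K1 * sp.U * sp.K, rel=1e-12)
            assert sp.UKB == pytest.approx(p.K2 * sp.U * sp.K, rel=1e-12)
            assert sp.UKAB == pytest.approx(p.K1 * p.K2 * sp.U * sp.K**2, rel=1e-9)

    def test_concentrations_match_oracle_solution(self):
        p = EquilibriumParams(K_UN, 1e-7, 1e-6)
        t = MixtureTotals(6e-4, 1.2e-3)
        sp = species_concentrations(p, t, BindingModel.LINEAR)
        x = solve_free_chaperone_oracle(p, t, BindingModel.LINEAR)
        U = t.N_T / (1 + K_UN + p.K1 * x + p.K1 * p.K2 * x**2)
        assert sp.K == pytest.approx(x, rel=1e-9)
        assert sp.U == pytest.approx(U, rel=1e-9)
        assert sp.UK == pytest.approx(p.K1 * U * x, rel=1e-9)

    def test_square_identical_sites_are_symmetric(self):
        p = EquilibriumParams(K_UN, 1e-7, 1e-7)
        sp = species_concentrations(p, MixtureTotals(6e-4, 9e-4), BindingModel.SQUARE)
        assert sp.UKA == sp.UKB

    def test_square_kd_swap_relabels_sites(self):
        t = MixtureTotals(6e-4, 9e-4)
        sp1 = species_concentrations(
            EquilibriumParams(K_UN, 1e-8, 1e-6), t, BindingModel.SQUARE
        )
        sp2 = species_concentrations(
            EquilibriumParams(K_UN, 1e-6, 1e-8), t, BindingModel.SQUARE
        )
        assert sp1.UKA == pytest.approx(sp2.UKB, rel=1e-9)
        assert sp1.UKB == pytest.approx(sp2.UKA, rel=1e-9)
        assert sp1.UKAB == pytest.approx(sp2.UKAB, rel=1e-9)
        assert sp1.K == pytest.approx(sp2.K, rel=1e-9)

    def test_single_site_limit_matches_closed_form_quadratic(self):
        """Kd2 -> inf reduces the linear scheme to one-site binding, for which
        free chaperone solves K1*x^2 + (1 + K_UN + K1*(N_T - K_T))*x - (1+K_UN)*K_T = 0."""
        p = EquilibriumParams(K_UN, 1e-7, math.inf)
        t = MixtureTotals(6e-4, 4e-4)
        x = solve_free_chaperone(p, t, BindingModel.LINEAR)
        a = p.K1
        b = 1 + K_UN + p.K1 * (t.N_T - t.K_T)
        c = -(1 + K_UN) * t.K_T
        x_quad = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
        assert x == pytest.approx(x_quad, rel=1e-9)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        log_kd1=st.floats(-12, -2),
        log_kd2=st.floats(-12, -2),
        N_T=st.floats(1e-6, 5e-3),
        K_T=st.floats(0, 5e-3),
        kind=st.sampled_from(list(BindingModel)),
    )
    def test_mass_conservation_property(self, log_kd1, log_kd2, N_T, K_T, kind):
        p = EquilibriumParams(K_UN, 10**log_kd1, 10**log_kd2)
        sp = species_concentrations(p, MixtureTotals(N_T, K_T), kind)
        assert sp.client_total == pytest.approx(N_T, rel=1e-9)
        assert sp.chaperone_total == pytest.approx(K_T, rel=1e-9, abs=1e-25)
        assert all(v >= 0 for v in sp.as_dict().values())
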