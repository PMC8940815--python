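"""Structural-model tests: wiring, mass balance, closed forms, solver oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pulmodeconv.defaults import GRID_DOSE, grid_parameters
from pulmodeconv.models import (
    AbsorptionVariant,
    ConfigurationError,
    ParameterSet,
    Route,
    VariantName,
    analytic_auc,
    build_disposition_matrix,
    build_rate_matrix,
    slowest_half_life,
    solve_amounts,
    solve_profiles,
)

from conftest import ALL_ONE_DIRECTIONAL

DOSE = 100.0


def _times(horizon=48.0, n=241):
    return np.linspace(0.0, horizon, n)


class TestWiring:
    def test_iv_route_bypasses_lung(self, model_i):
        """i.v. dosing enters the central compartment; the plasma profile
        equals the pure disposition model and the lung stays empty."""
        variant, params = model_i
        times = _times()
        prof = solve_profiles(variant, params, DOSE, Route.IV, times)
        disp = build_disposition_matrix(params)
        amounts = solve_amounts(disp, [(0.0, DOSE)], times)
        np.testing.assert_allclose(
            prof.c_plasma, amounts[disp.central_index] / params.v1, rtol=1e-9
        )
        assert np.all(prof.c_lung == 0.0)

    def test_nal_lung_outflow_is_absorption_plus_loss(self, disposition_2cmt):
        variant = AbsorptionVariant.from_name(VariantName.NAL)
        params = ParameterSet(**disposition_2cmt, f_pul=0.5, k_fast=0.05, k_nal=2.4)
        system = build_rate_matrix(variant, params, Route.INHALED)
        lung = system.lung_indices[0]
        assert system.matrix[lung, lung] == pytest.approx(-(0.05 + 2.4))

    def test_simplex_violation_rejected(self, disposition_2cmt):
        params = ParameterSet(**disposition_2cmt, f_pul=0.4, f_fast=0.6,
                              k_fast=1.0, f_slow=0.3, k_slow=0.1)
        with pytest.raises(ConfigurationError, match="sum to 1"):
            build_rate_matrix(AbsorptionVariant.from_name("II"), params, Route.INHALED)

    def test_missing_parameter_named_in_error(self, disposition_2cmt):
        params = ParameterSet(**disposition_2cmt, f_pul=0.4, f_fast=0.6,
                              k_fast=1.0, f_slow=0.4)  # k_slow absent
        with pytest.raises(ConfigurationError, match="k_slow"):
            build_rate_matrix(AbsorptionVariant.from_name("II"), params, Route.INHALED)

    def test_backflow_only_for_semimechanistic(self):
        with pytest.raises(ConfigurationError, match="back-flow"):
            AbsorptionVariant(VariantName.I, 1, has_backflow=True)

    def test_no_central_to_lung_entry_without_backflow(self):
        for name in ALL_ONE_DIRECTIONAL:
            variant, params = grid_parameters(name)
            system = build_rate_matrix(variant, params, Route.INHALED)
            block = system.matrix[np.ix_(system.lung_indices, [system.central_index])]
            assert np.all(block == 0.0), name

    def test_backflow_model_has_central_to_lung_entry(self):
        variant, params = grid_parameters("SemiMechanistic")
        system = build_rate_matrix(variant, params, Route.INHALED)
        assert system.matrix[system.lung_indices[0], system.central_index] == params.k_back


class TestSolution:
    def test_model_i_lung_is_monoexponential(self, model_i):
        """Closed form: c_lung(t) = F*D*exp(-k t) / V_lung, independent of CL."""
        variant, params = model_i
        times = _times()
        prof = solve_profiles(variant, params, DOSE, Route.INHALED, times)
        expected = params.f_pul * DOSE * np.exp(-params.k_fast * times) / params.v_lung
        np.testing.assert_allclose(prof.c_lung, expected, rtol=1e-9)

    @pytest.mark.parametrize("name", ALL_ONE_DIRECTIONAL + ["SemiMechanistic"])
    def test_mass_balance(self, name):
        """Compartment amounts plus eliminated/lost drug equal the delivered
        dose (F_pul * dose for inhalation) at every time point."""
        variant, params = grid_parameters(name)
        system = build_rate_matrix(variant, params, Route.INHALED)
        amounts = solve_amounts(system, [(0.0, DOSE)], _times())
        total = amounts.sum(axis=0)
        np.testing.assert_allclose(total, params.f_pul * DOSE, rtol=1e-8)

    @pytest.mark.parametrize("name", ALL_ONE_DIRECTIONAL)
    def test_matrix_exponential_agrees_with_ode_integrator(self, name):
        """Independent oracle: adaptive stiff integration of the same system
        must agree with the matrix-exponential solution to ~1e-6."""
        variant, params = grid_parameters(name)
        system = build_rate_matrix(variant, params, Route.INHALED)
        times = np.linspace(0.0, 48.0, 200)
        x0 = DOSE * system.dose_in
        ref = solve_ivp(
            lambda t, x: system.matrix @ x, (0.0, 48.0), x0, t_eval=times,
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        ours = solve_amounts(system, [(0.0, DOSE)], times)
        scale = np.max(np.abs(ref.y))
        assert np.max(np.abs(ours - ref.y)) / scale < 1e-6

    def test_superposition(self, model_ii):
        variant, params = model_ii
        times = _times()
        one = solve_profiles(variant, params, DOSE, Route.INHALED, times)
        two = solve_profiles(variant, params, 2 * DOSE, Route.INHALED, times)
        np.testing.assert_allclose(two.c_plasma, 2 * one.c_plasma, rtol=1e-10)
        np.testing.assert_allclose(two.c_lung, 2 * one.c_lung, rtol=1e-10)

    def test_multiple_doses_superpose(self, model_i):
        variant, params = model_i
        system = build_rate_matrix(variant, params, Route.INHALED)
        times = np.linspace(0.0, 72.0, 289)
        both = solve_amounts(system, [(0.0, DOSE), (24.0, DOSE)], times)
        first = solve_amounts(system, [(0.0, DOSE)], times)
        second = solve_amounts(system, [(24.0, DOSE)], times)
        np.testing.assert_allclose(both, first + second, rtol=1e-10, atol=1e-12)

    def test_lung_monotone_after_bolus(self):
        for name in ALL_ONE_DIRECTIONAL:
            variant, params = grid_parameters(name)
            prof = solve_profiles(variant, params, DOSE, Route.INHALED, _times())
            assert np.all(np.diff(prof.c_lung) <= 1e-12), name

    def test_high_clearance_limit(self, model_ii):
        """CL -> inf drives plasma to ~0 while the lung profile (one-way
        absorption) is unchanged."""
        from dataclasses import replace

        variant, params = model_ii
        times = _times()
        base = solve_profiles(variant, params, DOSE, Route.INHALED, times)
        fast = solve_profiles(variant, replace(params, cl=3e6), DOSE, Route.INHALED, times)
        np.testing.assert_allclose(fast.c_lung, base.c_lung, rtol=1e-9)
        assert fast.c_plasma[1:].max() < 1e-3 * base.c_plasma[1:].max()


class TestAnalyticAUC:
    def test_lung_auc_formula_example(self):
        """Dose 100, F_pul 0.5, k_a 0.1/h, V_lung 0.84 L -> 595.238 ug*h/L."""
        variant = AbsorptionVariant.from_name("I")
        params = ParameterSet(cl=30.0, v1=20.0, f_pul=0.5, k_fast=0.1, v_lung=0.84)
        auc = analytic_auc(variant, params, 100.0, Route.INHALED, "lung")
        assert auc == pytest.approx(595.238, abs=1e-3)

    def test_plasma_auc_dose_f_over_cl(self, model_ii):
        variant, params = model_ii
        iv = analytic_auc(variant, params, DOSE, Route.IV, "plasma")
        inh = analytic_auc(variant, params, DOSE, Route.INHALED, "plasma")
        assert iv == pytest.approx(DOSE / params.cl)
        assert inh == pytest.approx(DOSE * params.f_pul / params.cl)

    def test_degenerate_model_ii_reduces_to_model_i(self, disposition_2cmt):
        ii = ParameterSet(**disposition_2cmt, f_pul=0.5, f_fast=1.0, k_fast=0.1,
                          f_slow=0.0, k_slow=0.01)
        i = ParameterSet(**disposition_2cmt, f_pul=0.5, k_fast=0.1)
        auc_ii = analytic_auc(AbsorptionVariant.from_name("II"), ii, DOSE,
                              Route.INHALED, "lung")
        auc_i = analytic_auc(AbsorptionVariant.from_name("I"), i, DOSE,
                             Route.INHALED, "lung")
        assert auc_ii == pytest.approx(auc_i, rel=1e-12)

    @pytest.mark.parametrize("name", ALL_ONE_DIRECTIONAL)
    def test_analytic_vs_numeric_integration(self, name):
        """Trapezoidal integration of the solved lung profile out to ~20
        slowest half-lives reproduces the closed form to < 0.1%."""
        variant, params = grid_parameters(name)
        analytic = analytic_auc(variant, params, DOSE, Route.INHALED, "lung")
        horizon = 20.0 * slowest_half_life(variant, params)
        times = np.linspace(0.0, horizon, 20001)
        prof = solve_profiles(variant, params, DOSE, Route.INHALED, times)
        numeric = np.trapezoid(prof.c_lung, times)
        assert abs(numeric / analytic - 1.0) < 1e-3

    def test_backflow_lung_auc_unsupported(self):
        variant, params = grid_parameters("SemiMechanistic")
        with pytest.raises(ConfigurationError, match="back-flow"):
            analytic_auc(variant, params, DOSE, Route.INHALED, "lung")


class TestCanonicalisation:
    def test_label_switching_removed(self, disposition_2cmt):
        """Swapped (fraction, rate) pairs map to the same canonical set."""
        variant = AbsorptionVariant.from_name("II")
        a = ParameterSet(**disposition_2cmt, f_pul=0.4, f_fast=0.3, k_fast=0.1,
                         f_slow=0.7, k_slow=1.5)  # mislabelled: 'fast' is slower
        canon = a.canonical(variant)
        assert canon.k_fast == pytest.approx(1.5)
        assert canon.f_fast == pytest.approx(0.7)
        assert canon.k_slow == pytest.approx(0.1)
        assert canon.f_slow == pytest.approx(0.3)

    def test_iiib_expands_to_explicit_rates(self, disposition_2cmt):
        variant = AbsorptionVariant.from_name("IIIb")
        p = ParameterSet(**disposition_2cmt, f_pul=0.5, f_fast=0.25, f_med=0.4,
                         f_slow=0.35, k_fast=15.0, pf1=0.7 / 15.0, pf2=0.023 / 0.7)
        canon = p.canonical(variant)
        assert canon.k_med == pytest.approx(0.7)
        assert canon.k_slow == pytest.approx(0.023)
        assert canon.pf1 is None

    def test_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            ParameterSet(cl=-1.0, v1=20.0)
        with pytest.raises(ConfigurationError):
            ParameterSet(cl=30.0, v1=20.0, f_pul=1.5)
        with pytest.raises(ConfigurationError):
            ParameterSet(cl=30.0, v1=20.0, q2=10.0)  # v2 missing
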