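"""Tracer experiment: coupled simulation, linearization, modes, FCR."""

import numpy as np
import pytest

from fcrnkinetics import (
    FcrCurveParameters,
    LinearTracerParameters,
    fcr_endogenous,
    fcr_endogenous_full,
    fcr_identifiable_combinations,
    fcr_tracer,
    fcr_tracer_asymptotic,
    linearize,
    modal_decomposition,
    simulate_coupled,
    simulate_linear_tracer,
    steady_state,
)

from conftest import random_kinetic_parameters

TIMES_25D = np.arange(0.0, 25.25, 0.25)


class TestLinearize:
    def test_k43_closed_form(self, lit_params):
        """k43 = kon·Rtot·k03·(k14+koff) / (IE·kon + k03·v3·(k14+koff)):
        1000·14·3·105 / (15·1000 + 3·0.34·105) = 291.9157... day⁻¹."""
        ltp = linearize(lit_params, 15.0)
        assert ltp.k43 == pytest.approx(4410000.0 / 15107.1, rel=1e-12)
        assert ltp.k34 == lit_params.koff

    def test_low_synthesis_limit(self, lit_params):
        """As IE → 0 the receptor pool is empty and k43 → kon·Rtot/v3."""
        ltp = linearize(lit_params, 1e-12)
        assert ltp.k43 == pytest.approx(lit_params.kon * lit_params.Rtot / lit_params.v3, rel=1e-9)

    def test_receptor_occupancy_consistency(self, rng):
        """k43·v3/kon + x̂4 = Rtot: the effective binding rate sees exactly
        the free receptors left by the endogenous steady state."""
        for _ in range(20):
            p = random_kinetic_parameters(rng)
            IE = float(rng.uniform(0.5, 50))
            ltp = linearize(p, IE)
            x4 = steady_state(p, IE).x4_hat
            assert ltp.k43 * p.v3 / p.kon + x4 == pytest.approx(p.Rtot, rel=1e-10)


class TestCoupledSimulation:
    def test_zero_dose_leaves_endogenous_at_steady_state(self, lit_params):
        traj = simulate_coupled(lit_params, 0.0, 15.0, TIMES_25D)
        assert np.max(np.abs(traj.tracer)) < 1e-9  # zero up to solver tolerance
        ss = steady_state(lit_params, 15.0).as_array()
        assert np.max(np.abs(traj.endogenous - ss) / ss) < 1e-6

    def test_small_dose_does_not_perturb_endogenous(self, lit_params):
        """A 0.01 μmol dose (typical tracer scale) moves endogenous plasma
        IgG by less than 0.01% over the 25-day experiment."""
        traj = simulate_coupled(lit_params, 0.01, 15.0, TIMES_25D)
        x1_hat = steady_state(lit_params, 15.0).x1_hat
        assert np.max(np.abs(traj.endogenous[:, 0] - x1_hat)) / x1_hat < 1e-4

    def test_tracer_mass_conservation(self, lit_params):
        """Dose minus cumulative endosomal degradation equals body tracer.

        The elimination flux k03·x3T rises on the minutes scale, so the
        quadrature grid must be geometric near t = 0 to resolve it.
        """
        times = np.concatenate(([0.0], np.geomspace(1e-5, 25.0, 800)))
        traj = simulate_coupled(lit_params, 1.0, 15.0, times, rtol=1e-10, atol=1e-12)
        body = traj.tracer.sum(axis=1)
        flux = lit_params.k03 * traj.tracer[:, 2]
        cum = np.concatenate(([0.0], np.cumsum((flux[1:] + flux[:-1]) / 2 * np.diff(times))))
        assert np.max(np.abs(body + cum - 1.0)) < 1e-5

    @pytest.mark.parametrize("dose,close", [(1.0, True), (100.0, False)])
    def test_linearization_validity_depends_on_dose(self, lit_params, dose, close):
        """The linear tracer model tracks the nonlinear one within 1% for a
        1 μmol dose but visibly diverges at 100 μmol, where the tracer
        itself saturates FcRn."""
        traj = simulate_coupled(lit_params, dose, 15.0, TIMES_25D, rtol=1e-10, atol=1e-12)
        _, lin_states = simulate_linear_tracer(linearize(lit_params, 15.0), dose, TIMES_25D)
        scale = np.max(np.abs(traj.tracer), axis=0)
        rel = np.max(np.abs(lin_states - traj.tracer) / scale)
        if close:
            assert rel < 0.01
        else:
            assert rel > 0.10


class TestLinearTracer:
    def test_initial_observations_are_unity(self, lit_theta):
        tc, _ = simulate_linear_tracer(lit_theta, 0.37, TIMES_25D)
        assert tc.y1[0] == pytest.approx(1.0, rel=1e-10)
        assert tc.y2[0] == pytest.approx(1.0, rel=1e-10)
        assert np.all(np.diff(tc.y2) <= 1e-12)  # body retention never grows

    def test_no_elimination_keeps_body_fraction_at_one(self, lit_theta):
        frozen = LinearTracerParameters(
            **{**dict(zip(lit_theta.PARAM_NAMES, lit_theta.as_array())), "k03": 0.0}
        )
        tc, _ = simulate_linear_tracer(frozen, 1.0, TIMES_25D)
        assert np.max(np.abs(tc.y2 - 1.0)) < 1e-9

    def test_observed_fractions_invariant_to_dose(self, lit_theta):
        tc_a, _ = simulate_linear_tracer(lit_theta, 0.005, TIMES_25D)
        tc_b, _ = simulate_linear_tracer(lit_theta, 5.0, TIMES_25D)
        assert tc_a.y1 == pytest.approx(tc_b.y1, rel=1e-10)
        assert tc_a.y2 == pytest.approx(tc_b.y2, rel=1e-10)

    def test_modal_solution_matches_ode_integration(self, lit_theta):
        _, modal = simulate_linear_tracer(lit_theta, 1.0, TIMES_25D, method="modal")
        _, ode = simulate_linear_tracer(lit_theta, 1.0, TIMES_25D, method="ode")
        assert np.max(np.abs(modal - ode)) < 1e-8


class TestModalDecomposition:
    def test_initial_condition_sums(self, lit_theta):
        md = modal_decomposition(lit_theta, D=2.5)
        sums = md.amplitudes.sum(axis=1)
        assert sums[0] == pytest.approx(2.5, rel=1e-10)
        assert sums[1:] == pytest.approx(np.zeros(3), abs=1e-10)

    def test_rates_real_negative_and_ordered(self, lit_theta):
        md = modal_decomposition(lit_theta)
        assert np.isrealobj(md.rates)
        assert np.all(md.rates < 0)
        assert np.all(np.diff(np.abs(md.rates)) < 0)  # descending |λ|


class TestFcrTracer:
    def test_two_forms_agree_identically(self, lit_theta):
        series = fcr_tracer(lit_theta, TIMES_25D)
        assert series.rate_form == pytest.approx(series.flux_form, rel=1e-10)

    def test_plateau_reached_and_matches_asymptote(self, lit_theta):
        """FCR_T(t) levels off after ~5 days and approaches k03·A34/A14."""
        series = fcr_tracer(lit_theta, np.array([0.5, 5.0, 14.0, 100.0]))
        f_inf = fcr_tracer_asymptotic(lit_theta)
        assert abs(series.rate_form[-1] - f_inf) / f_inf < 1e-3
        assert abs(series.rate_form[2] - f_inf) / f_inf < 0.02  # near-plateau at day 14
        assert abs(series.rate_form[0] - f_inf) / f_inf > 0.02  # still settling at 12 h
        # approach to the plateau is monotone in the deviation
        dev = np.abs(series.rate_form - f_inf)
        assert np.all(np.diff(dev) < 0)

    def test_no_elimination_gives_zero_fcr(self, lit_theta):
        frozen = LinearTracerParameters(
            **{**dict(zip(lit_theta.PARAM_NAMES, lit_theta.as_array())), "k03": 0.0}
        )
        series = fcr_tracer(frozen, TIMES_25D)
        assert np.max(np.abs(series.rate_form)) == 0.0

    def test_asymptote_approximates_endogenous_fcr(self, lit_params):
        """FCR_T∞ is within 10% of FCR_E(x̂1) = IE/x̂1 — the approximation
        underlying the use of the endogenous curve on tracer data."""
        ltp = linearize(lit_params, 15.0)
        f_inf = fcr_tracer_asymptotic(ltp)
        f_e = 15.0 / steady_state(lit_params, 15.0).x1_hat
        assert abs(f_inf - f_e) / f_e < 0.10


class TestFcrEndogenous:
    def test_no_recycling_collapses_to_k31(self, psi_ref):
        """With ψ2 = 0 everything pinocytosed is lost: FCR ≡ k31."""
        psi = FcrCurveParameters(k31=0.2, psi1=5.0, psi2=1e-14)
        x = np.array([1.0, 10.0, 500.0, 5e4])
        assert fcr_endogenous(psi, x) == pytest.approx(np.full(4, 0.2), rel=1e-10)

    def test_saturation_limits(self, psi_ref):
        """FCR → k31 as x → ∞ (salvage overwhelmed) and
        FCR → k31·ψ1/(ψ1+ψ2) as x → 0⁺ (maximal salvage)."""
        hi = fcr_endogenous(psi_ref, 1e6)
        lo = fcr_endogenous(psi_ref, 1e-6)
        assert hi == pytest.approx(psi_ref.k31, rel=1e-3)
        assert lo == pytest.approx(
            psi_ref.k31 * psi_ref.psi1 / (psi_ref.psi1 + psi_ref.psi2), rel=1e-3
        )

    def test_root_of_steady_state_quadratic(self, rng):
        """The curve value solves FCR² + c1·FCR + c0 = 0 (1000 draws)."""
        for _ in range(1000):
            psi = FcrCurveParameters(*np.exp(rng.uniform(np.log(0.01), np.log(100), 3)))
            x = float(np.exp(rng.uniform(np.log(0.1), np.log(5000))))
            f = fcr_endogenous(psi, x)
            # quadratic in ψ-form: x·F² + (ψ1+ψ2−k31·x)·F − k31·ψ1 = 0
            resid = x * f**2 + (psi.psi1 + psi.psi2 - psi.k31 * x) * f - psi.k31 * psi.psi1
            scale = max(x * f**2, (psi.psi1 + psi.psi2) * f, psi.k31 * x * f, psi.k31 * psi.psi1)
            assert abs(resid) < 1e-10 * scale

    def test_full_parameter_form_equals_psi_form(self, rng):
        """Mapping ψ1 = k03·v3·(k14+koff)/kon, ψ2 = k14·Rtot makes the two
        FCR expressions identical (1000 random parameter draws)."""
        for _ in range(1000):
            p = random_kinetic_parameters(rng)
            psi = fcr_identifiable_combinations(p)
            x = float(np.exp(rng.uniform(np.log(1), np.log(2000))))
            assert fcr_endogenous_full(p, x) == pytest.approx(fcr_endogenous(psi, x), rel=1e-9)

    def test_steady_state_consistency(self, rng):
        """FCR_E(x̂1) = I0/x̂1 exactly: at equilibrium, elimination balances
        synthesis."""
        for _ in range(200):
            p = random_kinetic_parameters(rng)
            I0 = float(np.exp(rng.uniform(np.log(0.5), np.log(200))))
            x1 = steady_state(p, I0).x1_hat
            assert fcr_endogenous_full(p, x1) == pytest.approx(I0 / x1, rel=1e-8)

    def test_rejects_nonpositive_plasma_quantity(self, psi_ref):
        with pytest.raises(ValueError):
            fcr_endogenous(psi_ref, 0.0)
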