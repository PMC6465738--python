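"""Structural identifiability: transfer-coefficient map and FCR combinations."""

import numpy as np
import pytest
from numpy.polynomial import polynomial as P

from fcrnkinetics import (
    LinearTracerParameters,
    check_fcr_identifiability,
    check_timecourse_identifiability,
    fcr_endogenous,
    fcr_endogenous_full,
    fcr_identifiable_combinations,
    fcr_quadratic_coefficients,
    linearize,
    simulate_linear_tracer,
    transfer_coefficients,
)
from fcrnkinetics.identifiability import transfer_coefficients_jacobian

from conftest import random_kinetic_parameters


def random_theta(rng, lo=1e-2, hi=1e3) -> LinearTracerParameters:
    return LinearTracerParameters(*np.exp(rng.uniform(np.log(lo), np.log(hi), 7)))


class TestTransferCoefficients:
    def test_unit_rates(self):
        """With all seven rates equal to 1: φ7 (trace term) = 7 and the
        plasma-numerator constant φ1 = 1·(1·2 + 1) = 3."""
        phi = transfer_coefficients(LinearTracerParameters(*np.ones(7)))
        assert phi.phi7 == 7.0
        assert phi.phi1 == 3.0

    def test_structural_equalities(self, rng):
        """The shared denominator and the Σxᵢ output force φ4=φ11, φ5=φ12,
        φ6=φ13 and φ7=φ10=φ14 for any parameter values."""
        for _ in range(1000):
            phi = transfer_coefficients(random_theta(rng))
            assert phi.phi4 == phi.phi11
            assert phi.phi5 == phi.phi12
            assert phi.phi6 == phi.phi13
            assert phi.phi7 == phi.phi10 == phi.phi14
            assert np.all(phi.as_array() > 0)

    def test_matches_numeric_state_space_realization(self, rng):
        """The explicit polynomials agree with the characteristic-polynomial
        / adjugate expansion of the (A, B, C) realization at 50 random θ."""
        for _ in range(50):
            theta = random_theta(rng, 0.1, 10)
            phi = transfer_coefficients(theta).as_array()
            A = theta.system_matrix()
            den = np.real(np.poly(A))[::-1]  # ascending: [φ4, φ5, φ6, φ7, 1]
            # numerators via G_i(s)·den(s) = C_i·adj(sI−A)·B evaluated by
            # polynomial interpolation over sample points s
            s_pts = np.linspace(0.5, 8.5, 9)
            C = np.array([[1.0, 0, 0, 0], [1.0, 1, 1, 1]])
            B = np.array([1.0, 0, 0, 0])
            num_vals = []
            for s in s_pts:
                G = C @ np.linalg.solve(s * np.eye(4) - A, B)
                den_s = np.polyval(den[::-1], s)
                num_vals.append(G * den_s)
            num_vals = np.array(num_vals)
            n1 = np.polyfit(s_pts, num_vals[:, 0], 3)[::-1]
            n2 = np.polyfit(s_pts, num_vals[:, 1], 3)[::-1]
            expected = np.concatenate([n1[:3], den[:4], n2[:3], den[:4]])
            assert phi == pytest.approx(expected, rel=1e-6, abs=1e-8)


class TestTimecourseIdentifiability:
    def test_literature_theta_is_uniquely_identifiable(self, lit_theta):
        report = check_timecourse_identifiability(lit_theta, n_starts=100, seed=3)
        assert report.jacobian_rank == 7
        assert report.locally_identifiable
        assert report.globally_unique is True
        assert report.details["n_counterexamples"] == 0

    def test_disconnected_model_is_rank_deficient(self, lit_theta):
        """k31 = 0 cuts plasma off from the endosomal chain: the downstream
        rates can no longer be seen in the outputs."""
        vals = dict(zip(lit_theta.PARAM_NAMES, lit_theta.as_array()))
        vals["k31"] = 0.0
        report = check_timecourse_identifiability(
            LinearTracerParameters(**vals), n_starts=0
        )
        assert report.jacobian_rank < 7
        assert not report.locally_identifiable

    def test_random_generic_points_have_full_rank(self, rng):
        for _ in range(20):
            report = check_timecourse_identifiability(random_theta(rng), n_starts=0)
            assert report.jacobian_rank == 7

    def test_symbolic_route_falls_back_gracefully(self, lit_theta):
        """With a near-zero time cap the exact polynomial solve cannot
        finish; the report must still arrive via the numerical fallback."""
        report = check_timecourse_identifiability(
            lit_theta, n_starts=10, seed=0, method="auto", symbolic_timeout=0.05
        )
        assert report.jacobian_rank == 7
        assert report.globally_unique in (True, None)

    def test_multistart_uniqueness_at_random_points(self, rng):
        """No alternative positive θ reproduces Φ(θ0) (spot check)."""
        for i in range(3):
            report = check_timecourse_identifiability(
                random_theta(rng, 0.1, 100), n_starts=40, seed=100 + i
            )
            assert report.globally_unique is True

    def test_io_equivalence_of_matched_coefficients(self, lit_theta, rng):
        """Two θ with equal Φ produce identical (y1, y2): here θa = θb, the
        sanity direction of coefficient-map consistency."""
        times = np.linspace(0, 25, 51)
        tc_a, _ = simulate_linear_tracer(lit_theta, 1.0, times)
        theta_b = LinearTracerParameters(*lit_theta.as_array())
        tc_b, _ = simulate_linear_tracer(theta_b, 2.0, times)
        assert tc_a.y1 == pytest.approx(tc_b.y1, rel=1e-12)


class TestFcrIdentifiability:
    def test_identifiable_combinations_literature_values(self, lit_params):
        """ψ2 = 5·14 = 70 μmol/day; ψ1 = 3·0.34·105/1000 = 0.1071 μmol/day."""
        psi = fcr_identifiable_combinations(lit_params)
        assert psi.k31 == lit_params.k31
        assert psi.psi2 == pytest.approx(70.0, rel=1e-12)
        assert psi.psi1 == pytest.approx(0.1071, rel=1e-10)

    def test_scale_invariance_of_kon_v3(self, lit_params):
        """Doubling kon and v3 together changes neither ψ nor the curve."""
        p2 = lit_params.replace(kon=2 * lit_params.kon, v3=2 * lit_params.v3)
        psi1 = fcr_identifiable_combinations(lit_params)
        psi2 = fcr_identifiable_combinations(p2)
        assert psi1.as_array() == pytest.approx(psi2.as_array(), rel=1e-12)
        x = np.geomspace(1, 2000, 50)
        assert fcr_endogenous_full(lit_params, x) == pytest.approx(
            fcr_endogenous_full(p2, x), rel=1e-12
        )

    def test_quadratic_coefficients_depend_only_on_psi(self, rng):
        """Vectors sharing (k31, ψ1, ψ2) give identical coefficient maps."""
        for _ in range(10):
            p = random_kinetic_parameters(rng)
            # move along the unidentifiable manifold: scale k14 and Rtot
            # inversely, and kon with k03·(k14+koff) to hold ψ fixed
            f = float(rng.uniform(0.5, 2.0))
            k14b = p.k14 * f
            Rtotb = p.Rtot / f
            konb = p.kon * (p.k03 * (k14b + p.koff)) / (p.k03 * (p.k14 + p.koff))
            p2 = p.replace(k14=k14b, Rtot=Rtotb, kon=konb)
            assert fcr_identifiable_combinations(p).as_array() == pytest.approx(
                fcr_identifiable_combinations(p2).as_array(), rel=1e-12
            )
            c1a, c0a = fcr_quadratic_coefficients(p)
            c1b, c0b = fcr_quadratic_coefficients(p2)
            x = np.exp(rng.uniform(np.log(1), np.log(2000), 100))
            assert c1a(x) == pytest.approx(c1b(x), rel=1e-10)
            assert c0a(x) == pytest.approx(c0b(x), rel=1e-10)
            # and the FCR curves coincide everywhere
            xs = np.geomspace(1, 2000, 200)
            assert np.max(np.abs(fcr_endogenous_full(p, xs) - fcr_endogenous_full(p2, xs))) < 1e-12 * np.max(np.abs(fcr_endogenous_full(p, xs)))

    def test_curve_value_zeroes_quadratic(self, lit_params, rng):
        c1, c0 = fcr_quadratic_coefficients(lit_params)
        x = np.exp(rng.uniform(np.log(1), np.log(2000), 100))
        f = fcr_endogenous_full(lit_params, x)
        resid = f**2 + c1(x) * f + c0(x)
        assert np.max(np.abs(resid)) < 1e-9 * np.max(f**2 + np.abs(c1(x)) * f)

    def test_constant_coefficient_negative(self, lit_params):
        """c0 < 0 for all x1E > 0, guaranteeing exactly one positive root."""
        _, c0 = fcr_quadratic_coefficients(lit_params)
        assert np.all(c0(np.geomspace(0.1, 1e4, 100)) < 0)

    def test_rank_three_identifiable_set(self, lit_params, rng):
        report = check_fcr_identifiability(lit_params)
        assert report.jacobian_rank == 3
        assert report.locally_identifiable
        assert len(report.identifiable_combinations) == 3
        for _ in range(10):
            assert check_fcr_identifiability(random_kinetic_parameters(rng)).jacobian_rank == 3
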