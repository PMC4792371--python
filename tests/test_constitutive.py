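"""Constitutive model: ingredient functions, pointwise stress, simulation
against closed-form linear viscoelastic oracles."""

import numpy as np
import pytest

from clotrheo.constitutive import (ModelState, evaluate_stress,
                                   formation_factor_elastic,
                                   formation_factor_viscous, simulate,
                                   softening_equilibrium, step_softening,
                                   stiffening_factor,
                                   viscous_dissipation_factor)
from clotrheo.errors import InvalidInputError, InvalidStateError
from clotrheo.kinematics import shear_deformation_gradient
from clotrheo.linear_spectrum import (analytic_moduli,
                                      extract_moduli_from_trace)
from clotrheo.parameters import ModelParameters
from clotrheo.protocol import Phase, DeformationProtocol

TWO_PI = 2.0 * np.pi


def osc_protocol(omega, gamma0, cycles):
    return DeformationProtocol((Phase("oscillation", cycles * TWO_PI / omega,
                                      omega=omega, gamma0=gamma0),))


class TestFormationFactors:
    def test_zero_at_delay_time(self, truth_params):
        assert formation_factor_viscous(truth_params.t0, truth_params) == 0.0
        assert formation_factor_elastic(truth_params.t0, truth_params) == 0.0

    def test_one_time_constant(self, truth_params):
        t = truth_params.t0 + truth_params.tc
        fv = formation_factor_viscous(t, truth_params)
        assert fv == pytest.approx(1.0 - np.exp(-1.0), rel=1e-12)
        assert formation_factor_elastic(t, truth_params) == \
            pytest.approx(fv ** 2, rel=1e-12)

    def test_monotone_limit_and_ordering(self, truth_params):
        t = np.linspace(0.0, 20 * truth_params.tc, 200)
        fv = formation_factor_viscous(t, truth_params)
        fe = formation_factor_elastic(t, truth_params)
        assert np.all(np.diff(fv) >= 0)
        assert fv[-1] == pytest.approx(1.0, abs=1e-8)
        # fe = fv^2 <= fv on [0, 1]
        assert np.all(fe <= fv + 1e-15)


class TestNonlinearFactors:
    def test_stiffening_at_rest_and_substitution(self):
        p = ModelParameters(1, 0, 0, 0, 0, 0, k1=2.0, n1=0.5)
        assert stiffening_factor(3.0, p) == 1.0
        assert stiffening_factor(7.0, p) == pytest.approx(3.0)

    def test_stiffening_symmetric_in_strain(self, truth_params):
        for g in (0.3, 1.2):
            ib_pos = 3.0 + g ** 2
            ib_neg = 3.0 + (-g) ** 2
            assert stiffening_factor(ib_pos, truth_params) == \
                stiffening_factor(ib_neg, truth_params)

    def test_dissipation_values(self):
        p = ModelParameters(1, 0, 0, 0, 0, 0, k2=0.5)
        assert viscous_dissipation_factor(3.0, p) == 1.0
        assert viscous_dissipation_factor(5.0, p) == pytest.approx(2.0)
        p0 = ModelParameters(1, 0, 0, 0, 0, 0, k2=0.0)
        assert viscous_dissipation_factor(9.0, p0) == 1.0

    def test_softening_equilibrium(self):
        p = ModelParameters(1, 0, 0, 0, 0, 0, a=1.0)
        assert softening_equilibrium(3.0, p) == 1.0
        assert softening_equilibrium(4.0, p) == pytest.approx(np.exp(-1.0))
        g = np.linspace(0.0, 2.0, 50)
        vals = softening_equilibrium(3.0 + g ** 2, p)
        assert np.all(np.diff(vals) < 0)

    def test_invalid_invariant_rejected(self, truth_params):
        with pytest.raises(InvalidInputError):
            stiffening_factor(2.5, truth_params)
        with pytest.raises(InvalidStateError):
            softening_equilibrium(2.5, truth_params)


class TestStepSoftening:
    def test_exact_exponential_solution(self):
        """Against the closed form x(t) = x_inf + (x0 - x_inf) e^{-cx t}
        over five decay times."""
        x, x_inf, cx = 1.0, 0.4, 0.7
        dt = 0.01
        n = int(5.0 / cx / dt)
        out = x
        for _ in range(n):
            out = step_softening(out, x_inf, cx, dt)
        exact = x_inf + (x - x_inf) * np.exp(-cx * n * dt)
        assert out == pytest.approx(exact, abs=1e-6)

    def test_never_increases_and_never_undershoots(self):
        assert step_softening(0.3, 0.5, 1.0, 10.0) == 0.3
        out = step_softening(1.0, 0.4, 100.0, 10.0)
        assert 0.4 <= out <= 1.0

    def test_zero_rate_freezes_state(self):
        assert step_softening(0.9, 0.1, 0.0, 5.0) == 0.9


class TestEvaluateStress:
    def test_undeformed_state_is_stress_free(self, truth_params):
        tau, parts = evaluate_stress(ModelState.virgin(), np.eye(3),
                                     np.zeros((3, 3)), 0.0, truth_params)
        assert np.allclose(tau, 0.0)
        for part in parts.values():
            assert np.allclose(part, 0.0)

    def test_pure_viscous_steady_shear(self):
        """Only dashpots, strain held at zero crossing: tau12 =
        (eta_p + eta00) * rate."""
        p = ModelParameters(0, 0, 0, eta00=0.7, eta10=0, eta20=0,
                            k2=0.5, eta_plasma=0.004)
        rate = 2.0
        D = 0.5 * rate * np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        tau, _ = evaluate_stress(ModelState.virgin(), np.eye(3), D, 0.0, p)
        assert tau[0, 1] == pytest.approx((0.004 + 0.7) * rate)

    def test_pure_equilibrium_elastic_shear(self):
        """Neo-Hookean equilibrium spring alone: tau12 = G00 * gamma."""
        p = ModelParameters(G00=120.0, G10=0, G20=0, eta00=0, eta10=0,
                            eta20=0, eta_plasma=0.0)
        F = shear_deformation_gradient(0.25)
        tau, _ = evaluate_stress(ModelState.virgin(), F, np.zeros((3, 3)),
                                 0.0, p)
        assert tau[0, 1] == pytest.approx(120.0 * 0.25)


class TestSimulate:
    def test_linear_regime_matches_analytic_spectrum(self, truth_params):
        """Small-amplitude oscillation with nonlinearities disabled matches
        the closed-form G', G'' within 1% after discarding transients."""
        p = truth_params.replace(a=0, cx=0, k1=0, n1=0, k2=0)
        for omega in (0.63, 6.3, 63.0):
            res = simulate(osc_protocol(omega, 1e-4, 15), p, mature=True)
            gp, gpp = extract_moduli_from_trace(res.trace, omega,
                                                discard_cycles=5, window=8)
            gp_a, gpp_a = analytic_moduli(omega, p)
            assert gp == pytest.approx(gp_a, rel=0.01)
            assert gpp == pytest.approx(gpp_a, rel=0.01)

    def test_maxwell_startup_oracle(self):
        """Single-mode start-up of steady shear at Wi = rate*lambda = 0.01:
        tau12(t) = eta*rate*(1 - e^{-t/lambda}) within 1%."""
        lam, G = 1.0, 40.0
        p = ModelParameters(0, G, 0, 0, lam * G, 0, eta_plasma=0.0)
        rate = 0.01 / lam
        proto = DeformationProtocol((Phase("steady", 5 * lam, rate=rate),))
        res = simulate(proto, p, mature=True)
        exact = lam * G * rate * (1.0 - np.exp(-res.trace.time / lam))
        err = np.abs(res.trace.stress - exact) / (lam * G * rate)
        assert np.max(err) < 0.01

    def test_zero_strain_protocol_is_stress_free(self, truth_params):
        proto = osc_protocol(TWO_PI, 0.0, 5)
        res = simulate(proto, truth_params, mature=True)
        assert np.allclose(res.trace.stress, 0.0)

    def test_softening_states_never_increase(self, truth_params):
        """Every x_i trace is non-increasing under an amplitude sweep."""
        phases = tuple(Phase("oscillation", 5.0, omega=TWO_PI, gamma0=g)
                       for g in (0.1, 1.0, 0.05))
        res = simulate(DeformationProtocol(phases), truth_params,
                       mature=True)
        assert np.all(np.diff(res.x, axis=0) <= 1e-12)

    def test_loop_energy_nonnegative(self, truth_params):
        from clotrheo.laos import loop_area, segment_cycles
        res = simulate(osc_protocol(TWO_PI, 0.5, 5), truth_params,
                       mature=True)
        for cyc in segment_cycles(res.trace, TWO_PI):
            assert loop_area(cyc) >= 0.0

    def test_formation_phase_angle_decreases(self, truth_params):
        """During formation the loss angle decreases after t0 (fluid to
        solid transition)."""
        from clotrheo.synthetic import generate_dataset
        ds = generate_dataset(truth_params)
        curve = ds.formation_curve
        delta = curve.delta()
        m = curve.time > truth_params.t0 + 30.0
        assert np.all(np.diff(delta[m]) < 0.0)

    def test_reduces_to_linear_generalized_maxwell(self, truth_params):
        """k1 = k2 = 0, a = 0, mature: moduli extracted at moderate
        amplitude equal the closed form within integration tolerance."""
        p = truth_params.replace(a=0, cx=0, k1=0, n1=0, k2=0)
        omega = 2.0
        res = simulate(osc_protocol(omega, 0.05, 15), p, mature=True)
        gp, gpp = extract_moduli_from_trace(res.trace, omega,
                                            discard_cycles=5, window=8)
        gp_a, gpp_a = analytic_moduli(omega, p)
        assert gp == pytest.approx(gp_a, rel=0.005)
        assert gpp == pytest.approx(gpp_a, rel=0.005)

    def test_chained_simulation_continuity(self, truth_params):
        """Carrying final_state into a second simulate call reproduces a
        single longer run at the sample points."""
        p = truth_params.replace(k2=0.5)
        proto_a = osc_protocol(TWO_PI, 0.3, 3)
        res_a = simulate(proto_a, p, mature=True)
        res_b = simulate(proto_a, p, mature=True,
                         initial_state=res_a.final_state)
        full = simulate(osc_protocol(TWO_PI, 0.3, 6), p, mature=True)
        assert np.allclose(res_b.trace.stress, full.trace.stress[-len(
            res_b.trace):], rtol=1e-6, atol=1e-9)
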