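"""Lissajous-Bowditch cycle segmentation and feature extraction."""

import numpy as np
import pytest

from clotrheo.constitutive import simulate
from clotrheo.errors import (DegenerateFeatureError, InsufficientDataError)
from clotrheo.laos import (CycleFeatures, LissajousCycle, cycle_features,
                           extract_stiffening, loop_area,
                           minimal_strain_modulus, segment_cycles,
                           softening_curve)
from clotrheo.linear_spectrum import analytic_moduli
from clotrheo.protocol import Phase, DeformationProtocol
from clotrheo.trace import RheoTrace

TWO_PI = 2.0 * np.pi


def sine_trace(omega=TWO_PI, gamma0=0.5, cycles=3, rate=256,
               stress_fn=None):
    n = int(cycles * rate)
    t = np.arange(n) / (rate * omega / TWO_PI)
    strain = gamma0 * np.sin(omega * t)
    stress = stress_fn(t, strain) if stress_fn else 100.0 * strain
    return RheoTrace(t, strain, stress)


def make_cycle(omega=TWO_PI, gamma0=0.5, rate=256, stress_fn=None):
    tr = sine_trace(omega, gamma0, cycles=2, rate=rate,
                    stress_fn=stress_fn)
    return segment_cycles(tr, omega)[0]


class TestSegmentCycles:
    def test_thirty_seconds_at_one_hertz(self):
        tr = sine_trace(cycles=30)
        assert len(segment_cycles(tr, TWO_PI)) == 30

    def test_two_cycle_sine(self):
        cycles = segment_cycles(sine_trace(cycles=2), TWO_PI)
        assert len(cycles) == 2
        for c in cycles:
            assert len(c) == 256
            assert abs(c.strain[0]) < 1e-9

    def test_zero_strain_rejected(self):
        t = np.linspace(0, 10, 1000)
        with pytest.raises(InsufficientDataError):
            segment_cycles(RheoTrace(t, np.zeros_like(t), np.ones_like(t)),
                           TWO_PI)

    def test_partial_cycle_rejected(self):
        tr = sine_trace(cycles=0.75)
        with pytest.raises(InsufficientDataError):
            segment_cycles(tr, TWO_PI)


class TestMinimalStrainModulus:
    def test_pure_elastic_loop(self):
        cyc = make_cycle(stress_fn=lambda t, g: 80.0 * g)
        assert minimal_strain_modulus(cyc) == pytest.approx(80.0)

    def test_cubic_stiffening_loop(self):
        """tau = G*gamma + k*gamma^3 sampled at 256/cycle: the tangent at
        zero strain is G within 1%."""
        cyc = make_cycle(stress_fn=lambda t, g: 50.0 * g + 400.0 * g ** 3)
        # the windowed regression carries an O((0.1 gamma0)^2) cubic bias
        assert minimal_strain_modulus(cyc) == pytest.approx(50.0, rel=0.015)

    def test_pure_viscous_loop_has_zero_slope(self):
        """tau ~ cos(wt): dtau/dgamma -> 0 at gamma = 0 by the chain rule,
        and the branch average cancels the viscous offset."""
        cyc = make_cycle(stress_fn=lambda t, g: 5.0 * np.cos(TWO_PI * t))
        assert abs(minimal_strain_modulus(cyc)) < 0.3


class TestCycleFeatures:
    def test_pure_elastic_features(self):
        g0 = 0.5
        cyc = make_cycle(gamma0=g0, stress_fn=lambda t, g: 80.0 * g)
        f = cycle_features(cyc)
        assert f.tau0 == pytest.approx(80.0 * g0, rel=1e-3)
        assert f.width == pytest.approx(0.0, abs=1e-6)
        assert f.tau_half == pytest.approx(40.0 * g0, rel=1e-3)

    def test_pure_viscous_width(self):
        """gamma = g0 sin, tau = eta*w*g0 cos: width at (sqrt2/2) g0 is
        sqrt2 * eta * w * g0."""
        eta, g0 = 2.0, 0.5
        cyc = make_cycle(gamma0=g0,
                         stress_fn=lambda t, g: eta * TWO_PI * g0
                         * np.cos(TWO_PI * t))
        f = cycle_features(cyc)
        assert f.width == pytest.approx(np.sqrt(2) * eta * TWO_PI * g0,
                                        rel=0.01)

    def test_simulated_cycle_features_finite(self, truth_params):
        proto = DeformationProtocol((Phase("oscillation", 5.0,
                                           omega=TWO_PI, gamma0=0.5),))
        res = simulate(proto, truth_params, mature=True)
        f = cycle_features(segment_cycles(res.trace, TWO_PI)[-1])
        assert np.isfinite([f.gamma0, f.tau0, f.Gm, f.tau_half,
                            f.tau_sqrt2, f.width]).all()
        assert f.width >= 0.0

    def test_linear_loop_area_matches_loss_modulus(self, truth_params):
        """Dissipated energy per cycle = pi * G'' * gamma0^2 in the linear
        regime, within 2%."""
        p = truth_params.replace(a=0, cx=0, k1=0, n1=0, k2=0)
        omega, g0 = TWO_PI, 1e-3
        proto = DeformationProtocol((Phase("oscillation", 10.0,
                                           omega=omega, gamma0=g0),))
        res = simulate(proto, p, mature=True)
        cyc = segment_cycles(res.trace, omega)[-1]
        _, gpp = analytic_moduli(omega, p)
        assert loop_area(cyc) == pytest.approx(np.pi * gpp * g0 ** 2,
                                               rel=0.02)

    def test_sampling_rate_consistency(self):
        """Doubling samples per cycle changes the features by < 0.5%."""
        def fn(t, g):
            return 60.0 * g + 30.0 * g ** 3 + 2.0 * np.cos(TWO_PI * t)
        f1 = cycle_features(make_cycle(rate=256, stress_fn=fn))
        f2 = cycle_features(make_cycle(rate=512, stress_fn=fn))
        for name in ("gamma0", "tau0", "Gm", "tau_half", "tau_sqrt2"):
            assert getattr(f2, name) == pytest.approx(getattr(f1, name),
                                                      rel=0.005)

    def test_steady_cycles_repeat_without_softening(self, truth_params):
        """With a = 0 the cycle features are identical across repeated
        cycles after the transient."""
        p = truth_params.replace(a=0, cx=0)
        proto = DeformationProtocol((Phase("oscillation", 10.0,
                                           omega=TWO_PI, gamma0=0.3),))
        res = simulate(proto, p, mature=True)
        cycles = segment_cycles(res.trace, TWO_PI)
        f_prev = cycle_features(cycles[-2])
        f_last = cycle_features(cycles[-1])
        for name in ("tau0", "Gm", "tau_half", "tau_sqrt2", "width"):
            assert getattr(f_last, name) == pytest.approx(
                getattr(f_prev, name), rel=0.005)


class TestExtractStiffening:
    def test_direct_substitution(self):
        feats = [CycleFeatures(gamma0=0.01, tau0=2.0, Gm=0.0, tau_half=0.0,
                               tau_sqrt2=0.0, width=0.0)]
        pts = extract_stiffening(feats, x0_values=[1.0],
                                 tau_ve_values=[0.0], G00=100.0)
        assert pts[0] == (0.01, pytest.approx(2.0))

    def test_degenerate_denominator_rejected(self):
        feats = [CycleFeatures(gamma0=0.0, tau0=1.0, Gm=0.0, tau_half=0.0,
                               tau_sqrt2=0.0, width=0.0)]
        with pytest.raises(DegenerateFeatureError):
            extract_stiffening(feats, [1.0], [0.0], 100.0)


class TestSofteningCurve:
    def test_normalization(self):
        out = softening_curve([200.0, 150.0, 100.0])
        assert np.allclose(out, [1.0, 0.75, 0.5])

    def test_zero_initial_value_rejected(self):
        with pytest.raises(DegenerateFeatureError):
            softening_curve([0.0, 1.0])
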