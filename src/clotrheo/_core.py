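"""Compiled fixed-step integrator for simple-shear protocols.

The public kinematics/constitutive modules expose the tensor operations on
plain numpy arrays; this module contains the numba-compiled inner loop used
by :func:`clotrheo.constitutive.simulate` for speed.  It is specialized to
simple shear (F upper-triangular with F[0,1] = gamma), for which the
deformation gradient inverse is analytic.

State layout: Cp is a (2, 3, 3) array (one inelastic right Cauchy-Green
tensor per Maxwell mode), x is (3,) = (x0 equilibrium, x1, x2).  The
parameter vector is

    p = [G00, G10, G20, eta00, eta10, eta20, eta_p, t0, tc,
         a, cx, k1, n1, k2]

Per RK4 step the per-mode flow rule dCp/dt = Cp . F^{-1} . Dp . F is
advanced with Cp-dependent stages (gamma, f_e, f_v evaluated at the stage
times); afterwards Cp is symmetrized and the softening states are advanced
with the exact exponential sub-step of the linear relaxation ODE.
"""

import numpy as np
from numba import njit

# parameter vector indices
_G00, _G10, _G20, _E00, _E10, _E20, _EP, _T0, _TC, _A, _CX, _K1, _N1, _K2 = \
    range(14)


def params_to_vector(params) -> np.ndarray:
    return np.array([
        params.G00, params.G10, params.G20,
        params.eta00, params.eta10, params.eta20,
        params.eta_plasma, params.t0, params.tc,
        params.a, params.cx, params.k1, params.n1, params.k2,
    ], dtype=np.float64)


@njit(cache=True)
def _inv3(A, out):
    """Inverse of a 3x3 matrix via the adjugate; returns det."""
    a, b, c = A[0, 0], A[0, 1], A[0, 2]
    d, e, f = A[1, 0], A[1, 1], A[1, 2]
    g, h, i = A[2, 0], A[2, 1], A[2, 2]
    A11 = e * i - f * h
    A12 = c * h - b * i
    A13 = b * f - c * e
    A21 = f * g - d * i
    A22 = a * i - c * g
    A23 = c * d - a * f
    A31 = d * h - e * g
    A32 = b * g - a * h
    A33 = a * e - b * d
    det = a * A11 + b * A21 + c * A31
    inv_det = 1.0 / det
    out[0, 0] = A11 * inv_det
    out[0, 1] = A12 * inv_det
    out[0, 2] = A13 * inv_det
    out[1, 0] = A21 * inv_det
    out[1, 1] = A22 * inv_det
    out[1, 2] = A23 * inv_det
    out[2, 0] = A31 * inv_det
    out[2, 1] = A32 * inv_det
    out[2, 2] = A33 * inv_det
    return det


@njit(cache=True)
def _mode_rate(Cp, gamma, x, G, eta_eff, fe, rate_out, Be_out):
    """dCp/dt for one Maxwell mode at total shear strain gamma.

    Also fills Be_out with the mode's elastic Finger tensor.  eta_eff is the
    current (formation-scaled) viscosity; modes with eta_eff <= 0 or G <= 0
    are degenerate and contribute a zero rate.
    """
    Cpinv = np.empty((3, 3))
    _inv3(Cp, Cpinv)
    # Be = F . Cp^{-1} . F^T with F = I + gamma*e12:
    # row/col operations instead of full matmuls
    for i in range(3):
        for j in range(3):
            Be_out[i, j] = Cpinv[i, j]
    # F.M: row0 += gamma*row1 ; M.F^T: col0 += gamma*col1
    for j in range(3):
        Be_out[0, j] += gamma * Be_out[1, j]
    for i in range(3):
        Be_out[i, 0] += gamma * Be_out[i, 1]

    if G <= 0.0 or eta_eff <= 0.0:
        for i in range(3):
            for j in range(3):
                rate_out[i, j] = 0.0
        return

    # Dp = x*fe*G*(Be - I) / (2*eta_eff)
    c = x * fe * G / (2.0 * eta_eff)
    Dp = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            Dp[i, j] = c * Be_out[i, j]
        Dp[i, i] -= c

    # M = F^{-1}.Dp.F with F^{-1} = I - gamma*e12:
    # F^{-1}.Dp: row0 -= gamma*row1 ; (.)F: col1 += gamma*col0
    M = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            M[i, j] = Dp[i, j]
    for j in range(3):
        M[0, j] -= gamma * M[1, j]
    for i in range(3):
        M[i, 1] += gamma * M[i, 0]

    # rate = Cp.M + (Cp.M)^T  (spin-free flow: the symmetric pair keeps
    # Cp symmetric and yields the Maxwell relaxation time eta/G)
    for i in range(3):
        for j in range(3):
            s = 0.0
            for k in range(3):
                s += Cp[i, k] * M[k, j]
            rate_out[i, j] = s
    for i in range(3):
        for j in range(i, 3):
            v = rate_out[i, j] + rate_out[j, i]
            rate_out[i, j] = v
            rate_out[j, i] = v


@njit(cache=True)
def _formation_factors(t, t0, tc):
    if t <= t0:
        return 0.0, 0.0
    fv = 1.0 - np.exp(-(t - t0) / tc)
    return fv * fv, fv


@njit(cache=True)
def _integrate_phase(kind, t_start, omega, amp_or_rate, gamma_offset,
                     mature, dt, n_samples, n_sub, p, Cp, x,
                     t_out, gamma_out, rate_out, tau_out, parts_out,
                     x_out, cp_out):
    """Integrate one protocol phase, sampling every n_sub steps.

    Returns the index of the first bad sample (state lost finiteness), or
    -1 on success.  Cp (2,3,3) and x (3,) are advanced in place.
    """
    G = np.empty(2)
    G[0] = p[_G10]
    G[1] = p[_G20]
    eta = np.empty(2)
    eta[0] = p[_E10]
    eta[1] = p[_E20]
    a = p[_A]
    cx = p[_CX]

    k1r = np.empty((2, 3, 3))
    k2r = np.empty((2, 3, 3))
    k3r = np.empty((2, 3, 3))
    k4r = np.empty((2, 3, 3))
    Cp_stage = np.empty((3, 3))
    Be = np.empty((2, 3, 3))
    Be_tmp = np.empty((3, 3))

    decay = np.exp(-cx * dt) if cx > 0.0 else 1.0

    for s in range(n_samples):
        for sub in range(n_sub):
            t_loc = (s * n_sub + sub) * dt
            t_abs = t_start + t_loc
            # stage strains
            if kind == 0:
                g1 = gamma_offset + amp_or_rate * np.sin(omega * t_loc)
                g2 = gamma_offset + amp_or_rate * np.sin(
                    omega * (t_loc + 0.5 * dt))
                g3 = g2
                g4 = gamma_offset + amp_or_rate * np.sin(omega * (t_loc + dt))
            else:
                g1 = gamma_offset + amp_or_rate * t_loc
                g2 = gamma_offset + amp_or_rate * (t_loc + 0.5 * dt)
                g3 = g2
                g4 = gamma_offset + amp_or_rate * (t_loc + dt)

            if mature == 1:
                fe1 = fv1 = fe2 = fv2 = fe4 = fv4 = 1.0
            else:
                fe1, fv1 = _formation_factors(t_abs, p[_T0], p[_TC])
                fe2, fv2 = _formation_factors(t_abs + 0.5 * dt, p[_T0],
                                              p[_TC])
                fe4, fv4 = _formation_factors(t_abs + dt, p[_T0], p[_TC])

            for m in range(2):
                _mode_rate(Cp[m], g1, x[m + 1], G[m], fv1 * eta[m], fe1,
                           k1r[m], Be_tmp)
                for i in range(3):
                    for j in range(3):
                        Cp_stage[i, j] = Cp[m, i, j] + 0.5 * dt * k1r[m, i, j]
                _mode_rate(Cp_stage, g2, x[m + 1], G[m], fv2 * eta[m], fe2,
                           k2r[m], Be_tmp)
                for i in range(3):
                    for j in range(3):
                        Cp_stage[i, j] = Cp[m, i, j] + 0.5 * dt * k2r[m, i, j]
                _mode_rate(Cp_stage, g3, x[m + 1], G[m], fv2 * eta[m], fe2,
                           k3r[m], Be_tmp)
                for i in range(3):
                    for j in range(3):
                        Cp_stage[i, j] = Cp[m, i, j] + dt * k3r[m, i, j]
                _mode_rate(Cp_stage, g4, x[m + 1], G[m], fv4 * eta[m], fe4,
                           k4r[m], Be_tmp)
                for i in range(3):
                    for j in range(3):
                        Cp[m, i, j] += (dt / 6.0) * (
                            k1r[m, i, j] + 2.0 * k2r[m, i, j]
                            + 2.0 * k3r[m, i, j] + k4r[m, i, j])
                # symmetrize to kill round-off drift (spin-free flow)
                for i in range(3):
                    for j in range(i + 1, 3):
                        v = 0.5 * (Cp[m, i, j] + Cp[m, j, i])
                        Cp[m, i, j] = v
                        Cp[m, j, i] = v

            # softening update (exact exponential sub-step, frozen x_inf)
            if a > 0.0 and cx > 0.0:
                # equilibrium mode: elastic Finger tensor = total B
                xinf = np.exp(-a * np.abs(g4))
                if x[0] > xinf:
                    x[0] = xinf + (x[0] - xinf) * decay
                for m in range(2):
                    _mode_rate(Cp[m], g4, x[m + 1], G[m], -1.0, 1.0,
                               k1r[m], Be_tmp)  # only Be is needed
                    ibe = Be_tmp[0, 0] + Be_tmp[1, 1] + Be_tmp[2, 2] - 3.0
                    if ibe < 0.0:
                        ibe = 0.0
                    xinf = np.exp(-a * np.sqrt(ibe))
                    if x[m + 1] > xinf:
                        x[m + 1] = xinf + (x[m + 1] - xinf) * decay

        # ---- sample -----------------------------------------------------
        t_loc = (s + 1) * n_sub * dt
        t_abs = t_start + t_loc
        if kind == 0:
            gamma = gamma_offset + amp_or_rate * np.sin(omega * t_loc)
            gdot = amp_or_rate * omega * np.cos(omega * t_loc)
        else:
            gamma = gamma_offset + amp_or_rate * t_loc
            gdot = amp_or_rate

        if mature == 1:
            fe = 1.0
            fv = 1.0
        else:
            fe, fv = _formation_factors(t_abs, p[_T0], p[_TC])

        g2b = gamma * gamma  # I_B - 3 of the total Finger tensor
        fvi = 1.0 + p[_K2] * g2b
        fss = (1.0 + p[_K1] * g2b) ** p[_N1]

        tau_v = (p[_EP] + fv * fvi * p[_E00]) * gdot
        tau_e = fe * x[0] * fss * p[_G00] * gamma
        tau_m = 0.0
        ok = True
        for m in range(2):
            _mode_rate(Cp[m], gamma, x[m + 1], G[m], -1.0, 1.0,
                       k1r[m], Be[m])
            tve = x[m + 1] * fe * G[m] * Be[m, 0, 1]
            parts_out[s, 2 + m] = tve
            tau_m += tve
            for i in range(3):
                for j in range(3):
                    if not np.isfinite(Cp[m, i, j]):
                        ok = False
                    cp_out[s, m, i, j] = Cp[m, i, j]
        t_out[s] = t_abs
        gamma_out[s] = gamma
        rate_out[s] = gdot
        parts_out[s, 0] = tau_v
        parts_out[s, 1] = tau_e
        tau_out[s] = tau_v + tau_e + tau_m
        for m in range(3):
            x_out[s, m] = x[m]
        if not (ok and np.isfinite(tau_out[s])):
            return s
    return -1
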