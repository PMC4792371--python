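"""Stepwise parameter estimation from the three-part rheometry protocol.

Stage 1 fits the six linear parameters (G00, G10, G20, eta00, eta10,
eta20) to the frequency sweep; stage 2 fixes them and fits the formation
parameters (t0, tc) to the formation moduli curve; stage 3 fits the five
nonlinear parameters from per-amplitude-step Lissajous-cycle features:
an initial guess for the softening pair (a, cx) comes from the normalized
minimal-strain-modulus series, then the procedure alternates between
fitting the stiffening pair (k1, n1) to the stiffening values extracted
from the peak stresses and refitting (a, cx) to the peak-stress series,
until the largest relative parameter change drops below 0.01; the
dissipation coefficient k2 is fitted last to the quarter-amplitude
stresses, where the viscous contribution is large.

All minimizations use bounded trust-region-reflective nonlinear least
squares, restarted from several perturbed initial values.

Fit quality is summarized by the mean relative stress error

    zeta = (1/N) sum |tau_exp - tau_model| / |tau_model|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constitutive import ModelState, SimulationResult, simulate
from .errors import (FitFailureError, InsufficientDataError,
                     InvalidInputError, StageFailureError)
from .formation import FORMATION_OMEGA, FormationCurve, fit_formation
from .laos import (SQRT2_2, branch_stress, cycle_features,
                   minimal_strain_modulus, segment_cycles)
from .linear_spectrum import FrequencySweep, analytic_moduli
from .parameters import ModelParameters
from .protocol import Phase, DeformationProtocol
from .trace import RheoTrace

__all__ = ["FitResult", "fit_linear_spectrum", "fit_nonlinear",
           "mean_relative_error", "fit_full", "laos_step_features",
           "CONVERGENCE_THRESHOLD"]

#: relative parameter-change threshold of the alternating loop
CONVERGENCE_THRESHOLD = 0.01


@dataclass
class FitResult:
    """Outcome of (part of) the stepwise fitting procedure."""

    params: ModelParameters
    zeta: float
    iterations: int
    converged: bool
    stage_residuals: dict = field(default_factory=dict)
    #: combined peak-stress objective after each alternating iteration
    objective_history: list = field(default_factory=list)
    multistart_seed: int | None = None
    #: non-fatal diagnostics (e.g. unidentifiable parameters)
    warnings: list = field(default_factory=list)


def mean_relative_error(tau_exp, tau_model, rel_floor: float = 1e-3
                        ) -> float:
    """Mean relative stress error zeta.

    Samples where |tau_model| < rel_floor * max|tau_model| are excluded
    (the raw oscillatory stress crosses zero every half cycle, where the
    relative error is undefined).  Scale-invariant.
    """
    tau_exp = np.asarray(tau_exp, dtype=float)
    tau_model = np.asarray(tau_model, dtype=float)
    if tau_exp.shape != tau_model.shape or tau_exp.size == 0:
        raise InvalidInputError("series must be non-empty and equal length")
    mmax = np.max(np.abs(tau_model))
    if mmax == 0:
        raise InvalidInputError("model stress identically zero")
    m = np.abs(tau_model) >= rel_floor * mmax
    return float(np.mean(np.abs(tau_exp[m] - tau_model[m])
                         / np.abs(tau_model[m])))


def _multistart(residuals, x0, bounds, n_starts: int, seed: int,
                log_scale: bool = True):
    """Bounded trf least squares from ``n_starts`` initial points (the
    given one plus random perturbations); returns the lowest-cost solution.
    """
    rng = np.random.default_rng(seed)
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    x0 = np.clip(np.asarray(x0, float), lo, hi)
    best = None
    for k in range(n_starts):
        if k == 0:
            xk = x0
        elif log_scale:
            xk = np.clip(x0 * np.exp(rng.normal(0.0, 0.7, x0.size)), lo, hi)
        else:
            xk = np.clip(x0 + rng.normal(0.0, 0.5 * (hi - lo + 1.0)), lo, hi)
        try:
            sol = least_squares(residuals, xk, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if sol.success and np.all(np.isfinite(sol.x)) and (
                best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError("all least-squares starts failed")
    return best


# --------------------------------------------------------------------------
# stage 1: linear spectrum
# --------------------------------------------------------------------------

def fit_linear_spectrum(sweep: FrequencySweep,
                        eta_plasma: float | None = None,
                        n_starts: int = 5, seed: int = 0) -> ModelParameters:
    """Fit the six linear parameters to a frequency sweep.

    Relative (per-channel) residuals on G' and G''; eta_plasma is held
    fixed.  Modes are returned ordered by decreasing relaxation time.
    """
    if len(sweep) < 6:
        raise InsufficientDataError("need >= 6 sweep points")
    span = sweep.omega[-1] / sweep.omega[0]
    if span < 10 ** 1.5:
        raise InsufficientDataError("sweep must span >= 1.5 decades")
    etap = ModelParameters(0, 0, 0, 0, 0, 0).eta_plasma \
        if eta_plasma is None else eta_plasma
    w = sweep.omega
    # heuristics: equilibrium modulus from the low-frequency plateau, the
    # two modes bracketing the sweep window, dashpot from the high-w loss
    g00_0 = max(sweep.Gp[0], 1e-6)
    dg = max(sweep.Gp[-1] - sweep.Gp[0], 1e-3 * g00_0)
    lam1_0, lam2_0 = 2.0 / w[0], 2.0 / w[-1]
    eta00_0 = max(sweep.Gpp[-1] / (2.0 * w[-1]), 1e-6)
    x0 = np.array([g00_0, 0.5 * dg, 0.5 * dg,
                   eta00_0, 0.5 * dg * lam1_0, 0.5 * dg * lam2_0])
    gp_floor = max(1e-3 * float(np.max(sweep.Gp)), 1e-12)
    gpp_floor = max(1e-3 * float(np.max(sweep.Gpp)),
                    1e-6 * float(np.max(sweep.Gp)), 1e-12)
    sgp = 1.0 / np.maximum(sweep.Gp, gp_floor)
    sgpp = 1.0 / np.maximum(sweep.Gpp, gpp_floor)

    def residuals(theta):
        p = ModelParameters(G00=theta[0], G10=theta[1], G20=theta[2],
                            eta00=theta[3], eta10=theta[4], eta20=theta[5],
                            eta_plasma=etap)
        try:
            gp, gpp = analytic_moduli(w, p)
        except Exception:
            return np.full(2 * len(w), 1e6)
        return np.concatenate([(gp - sweep.Gp) * sgp,
                               (gpp - sweep.Gpp) * sgpp])

    lo = np.full(6, 1e-9)
    hi = np.array([1e7, 1e7, 1e7, 1e5, 1e7, 1e7])
    best = _multistart(residuals, x0, (lo, hi), n_starts, seed)
    G00, G10, G20, eta00, eta10, eta20 = [float(v) for v in best.x]
    # order modes by decreasing relaxation time
    modes = sorted([(G10, eta10), (G20, eta20)],
                   key=lambda ge: ge[1] / ge[0] if ge[0] > 0 else 0.0,
                   reverse=True)
    return ModelParameters(G00=G00, G10=modes[0][0], G20=modes[1][0],
                           eta00=eta00, eta10=modes[0][1],
                           eta20=modes[1][1], eta_plasma=etap)


# --------------------------------------------------------------------------
# LAOS feature pipeline
# --------------------------------------------------------------------------

def laos_step_features(trace: RheoTrace, omega: float):
    """Group a LAOS trace into amplitude steps and compute features.

    Steps are detected by relative jumps (> 20 %) of the per-cycle strain
    amplitude.  Returns ``(step_features, per_cycle)`` where
    ``step_features`` holds the features of the LAST full cycle of each
    step (closest to the softening steady state) and ``per_cycle`` is a
    record array with per-cycle time, amplitude, minimal-strain modulus
    and step index (used for the softening-kinetics initial guess).
    """
    cycles = segment_cycles(trace, omega)
    if not cycles:
        raise InsufficientDataError("no full cycles in LAOS trace")
    step_of = np.zeros(len(cycles), dtype=int)
    for i in range(1, len(cycles)):
        prev, cur = cycles[i - 1].gamma0, cycles[i].gamma0
        jump = abs(cur - prev) / max(prev, 1e-12) > 0.2
        step_of[i] = step_of[i - 1] + (1 if jump else 0)
    step_features = []
    per_cycle = []
    for s in range(step_of.max() + 1):
        idx = np.flatnonzero(step_of == s)
        step_features.append(cycle_features(cycles[int(idx[-1])]))
        for i in idx:
            c = cycles[int(i)]
            width_s2 = (branch_stress(c, SQRT2_2 * c.gamma0, "rising")
                        - branch_stress(c, SQRT2_2 * c.gamma0, "falling"))
            width_h = (branch_stress(c, 0.5 * c.gamma0, "rising")
                       - branch_stress(c, 0.5 * c.gamma0, "falling"))
            per_cycle.append((float(c.time[0]), c.gamma0,
                              minimal_strain_modulus(c),
                              float(c.stress[int(np.argmax(c.strain))]),
                              width_s2, width_h, s))
    per_cycle = np.array(per_cycle,
                         dtype=[("time", float), ("gamma0", float),
                                ("Gm", float), ("tau0", float),
                                ("width", float), ("width_half", float),
                                ("step", int)])
    return step_features, per_cycle


def _phase_cycles(res: SimulationResult, i: int, omega: float):
    """Reshape one phase into (n_cycles, samples_per_period) stress rows
    plus the (identical) per-cycle strain grid."""
    period = 2.0 * np.pi / omega
    sl = res.phase_slice(i)
    g = res.trace.strain[sl]
    s = res.trace.stress[sl]
    t = res.trace.time[sl]
    per = int(round(period / (t[1] - t[0])))
    n_cyc = len(g) // per
    return (g[:n_cyc * per].reshape(n_cyc, per),
            s[:n_cyc * per].reshape(n_cyc, per))


def _per_cycle_model_gm(res: SimulationResult, omega: float):
    """Minimal-strain modulus of every cycle, per phase, vectorized.

    The strain grid repeats exactly cycle to cycle, so the regression
    design (|gamma| <= 0.1 gamma0, split by branch, slope via normal
    equations, branches averaged) is fixed per phase and applies to all
    cycles at once.
    """
    out = []
    for i in range(int(res.phase_index.max()) + 1):
        g2, s2 = _phase_cycles(res, i, omega)
        g_ref = g2[0]
        dg = np.gradient(g_ref)
        near = np.abs(g_ref) <= 0.1 * np.max(np.abs(g_ref))
        slopes = []
        for branch in (dg > 0, dg < 0):
            idx = near & branch
            x = g_ref[idx]
            xc = x - x.mean()
            sc = s2[:, idx]
            slopes.append((sc - sc.mean(axis=1, keepdims=True)) @ xc
                          / (xc @ xc))
        out.append(0.5 * (slopes[0] + slopes[1]))
    return out


def _per_cycle_model_width(res: SimulationResult, omega: float,
                           target_frac: float = SQRT2_2,
                           window: float = 0.15):
    """Signed loop width at target_frac * gamma0 of every cycle, per phase.

    Uses the same local-regression estimator as the measured side
    (vectorized: the strain grid repeats exactly cycle to cycle).  The
    signed rising-minus-falling difference is positive for dissipative
    loops and unbiased under zero-mean stress noise.
    """
    out = []
    for i in range(int(res.phase_index.max()) + 1):
        g2, s2 = _phase_cycles(res, i, omega)
        g_ref = g2[0]
        g0 = np.max(np.abs(g_ref))
        target = target_frac * g0
        dg = np.gradient(g_ref)
        vals = []
        for branch in (dg > 0, dg < 0):
            idx = branch & (np.abs(g_ref - target) <= window * g0)
            x = g_ref[idx] - target
            A = np.column_stack([np.ones(x.size), x])
            proj = np.linalg.pinv(A)[0]  # row extracting the intercept
            vals.append(s2[:, idx] @ proj)
        out.append(vals[0] - vals[1])
    return out


def _per_cycle_model_peaks(res: SimulationResult, omega: float):
    """Per-cycle values at the strain peak, grouped by protocol phase.

    Returns, per phase, a record array with the model peak stress tau0,
    the peak strain gamma0, the equilibrium softening state x0 and the
    summed Maxwell shear stress tau_ve at that instant.  The sample rate
    is an integer number of samples per period, so each phase reshapes
    exactly into cycles.
    """
    period = 2.0 * np.pi / omega
    out = []
    for i in range(int(res.phase_index.max()) + 1):
        sl = res.phase_slice(i)
        g = res.trace.strain[sl]
        s = res.trace.stress[sl]
        t = res.trace.time[sl]
        x0 = res.x[sl][:, 0]
        tau_ve = res.parts[sl][:, 2] + res.parts[sl][:, 3]
        per = int(round(period / (t[1] - t[0])))
        n_cyc = len(g) // per
        rows = np.arange(n_cyc)
        g2 = g[:n_cyc * per].reshape(n_cyc, per)
        peak = np.argmax(g2, axis=1)
        rec = np.empty(n_cyc, dtype=[("tau0", float), ("gamma0", float),
                                     ("x0", float), ("tau_ve", float)])
        rec["tau0"] = s[:n_cyc * per].reshape(n_cyc, per)[rows, peak]
        rec["gamma0"] = g2[rows, peak]
        rec["x0"] = x0[:n_cyc * per].reshape(n_cyc, per)[rows, peak]
        rec["tau_ve"] = tau_ve[:n_cyc * per].reshape(n_cyc, per)[rows, peak]
        out.append(rec)
    return out


def _laos_protocol_from_amplitudes(amplitudes, omega: float,
                                   step_duration: float
                                   ) -> DeformationProtocol:
    phases = tuple(Phase("oscillation", step_duration, omega=omega,
                         gamma0=float(g), label=f"laos:{i}")
                   for i, g in enumerate(amplitudes))
    return DeformationProtocol(phases)


def _last_cycle_model_values(res: SimulationResult, omega: float):
    """Per-phase model values from the last full cycle: peak stress tau0,
    softening state x0 and summed Maxwell shear stress at the peak, and the
    rising-branch stresses at gamma0/2 and (sqrt2/2)*gamma0.

    Works directly on the simulation arrays (no re-segmentation), using
    the known phase layout.
    """
    period = 2.0 * np.pi / omega
    out = []
    n_phases = int(res.phase_index.max()) + 1
    for i in range(n_phases):
        sl = res.phase_slice(i)
        t = res.trace.time[sl]
        m = t > t[-1] - period + 1e-9
        g = res.trace.strain[sl][m]
        s = res.trace.stress[sl][m]
        j = int(np.argmax(g))
        x0 = res.x[sl][m][j, 0]
        tau_ve = res.parts[sl][m][j, 2] + res.parts[sl][m][j, 3]
        gamma0 = float(np.max(np.abs(g)))
        dg = np.gradient(g, t[m])

        def branch(mask, target):
            gb, sb = g[mask], s[mask]
            order = np.argsort(gb)
            return float(np.interp(target, gb[order], sb[order]))

        tau_half = branch(dg > 0, 0.5 * gamma0)
        tau_sqrt2 = branch(dg > 0, SQRT2_2 * gamma0)
        width = abs(tau_sqrt2 - branch(dg < 0, SQRT2_2 * gamma0))
        out.append((gamma0, float(s[j]), float(x0), float(tau_ve),
                    tau_half, tau_sqrt2, width))
    return np.array(out, dtype=[("gamma0", float), ("tau0", float),
                                ("x0", float), ("tau_ve", float),
                                ("tau_half", float), ("tau_sqrt2", float),
                                ("width", float)])


# --------------------------------------------------------------------------
# stage 3: nonlinear parameters
# --------------------------------------------------------------------------

def _mode_weights(linear_params: ModelParameters, omega: float):
    """In-phase stiffness weight and relative elastic-strain amplitude of
    each Maxwell mode at frequency omega (linear-regime estimates)."""
    weights, strains = [], []
    for G, eta in linear_params.maxwell_modes:
        if G > 0 and eta > 0:
            lw = (eta / G) * omega
            weights.append(G * lw ** 2 / (1.0 + lw ** 2))
            strains.append(lw / math.sqrt(1.0 + lw ** 2))
        else:
            weights.append(0.0)
            strains.append(0.0)
    return np.array(weights), np.array(strains)


def _preconditioned_state(a: float, cx: float, gamma_pre: float,
                          linear_params: ModelParameters, omega: float):
    """State after long small-amplitude exposure before the LAOS sweep.

    The softening state only decreases, so prolonged oscillation at
    amplitude gamma_pre drives each x_i to exp(-a * gamma_e,i) with
    gamma_e,i the mode's elastic strain amplitude (= gamma_pre for the
    equilibrium mode).  Cp starts at identity: the Maxwell transient
    decays within seconds and the fitted features use the last cycle of
    each 30 s step.
    """
    from .constitutive import ModelState
    _, strains = _mode_weights(linear_params, omega)
    state = ModelState.virgin()
    if a > 0 and cx > 0:
        state.x[0] = math.exp(-a * gamma_pre)
        state.x[1] = math.exp(-a * gamma_pre * strains[0])
        state.x[2] = math.exp(-a * gamma_pre * strains[1])
    return state


def _softening_guess(per_cycle, omega: float,
                     linear_params: ModelParameters,
                     n_starts: int = 1, seed: int = 0):
    """Initial (a, cx) from the normalized per-cycle G_m series.

    Two direct estimates, each robust to the mode mixing that a detailed
    G_m model would need to resolve: the equilibrium coefficient from the
    softening level reached at the largest amplitude,
    a ~ -ln(G_m_end / G_m(0)) / gamma0_max, and the rate from the
    geometric within-step decay of G_m toward that level during the
    largest-amplitude step (while x > x_inf the state relaxes at exactly
    cx).  Starting values only — the alternating loop refines them.
    """
    T = 2.0 * np.pi / omega
    steps = per_cycle["step"]
    s_big = int(steps[np.argmax(per_cycle["gamma0"])])
    big = per_cycle[steps == s_big]
    gm0 = per_cycle["Gm"][0]
    g0_max = float(np.max(big["gamma0"]))
    level = float(big["Gm"][-1] / gm0)
    a = float(np.clip(-math.log(max(level, 1e-6)) / g0_max, 0.05, 10.0))

    y = big["Gm"] / gm0
    gap = y - level
    pos = gap > 0.05 * max(gap[0], 1e-9)
    if np.count_nonzero(pos) >= 3:
        # ln(gap) decays linearly at rate cx while x > x_inf
        t = np.arange(len(y))[pos] * T
        slope = np.polyfit(t, np.log(gap[pos]), 1)[0]
        cx = float(np.clip(-slope, 1e-3, 10.0))
    else:
        cx = 0.1
    return a, cx


def fit_nonlinear(step_features, linear_params: ModelParameters,
                  omega: float = FORMATION_OMEGA, per_cycle=None,
                  step_duration: float = 30.0, max_iter: int = 50,
                  n_starts: int = 3, seed: int = 0,
                  n_stiffening_steps: int | None = None) -> FitResult:
    """Iterative estimation of (a, cx, k1, n1, k2) from per-step features.

    ``step_features`` are the last-cycle features of each amplitude step
    (including, if present, the final return-to-small-amplitude step, which
    is simulated but not fitted against for stiffening); ``per_cycle`` is
    the per-cycle record from :func:`laos_step_features` used for the
    initial softening guess.

    Raises :class:`FitFailureError` if the alternating loop has not
    converged (relative parameter change < 0.01) after ``max_iter``
    iterations.
    """
    feats = list(step_features)
    if len(feats) < 3:
        raise InsufficientDataError("need >= 3 amplitude steps")
    amplitudes = np.array([f.gamma0 for f in feats])
    # steps used for stiffening/softening objectives: the increasing ramp
    if n_stiffening_steps is None:
        n_fit = int(np.argmax(amplitudes)) + 1
    else:
        n_fit = n_stiffening_steps
    tau0_meas = np.array([f.tau0 for f in feats])[:n_fit]
    protocol = _laos_protocol_from_amplitudes(amplitudes[:n_fit], omega,
                                              step_duration)
    # per-cycle peak-stress series of the fitted steps: resolves the
    # within-step softening kinetics, which the one-value-per-step series
    # cannot (a large-a/small-cx pair mimics it)
    cycle_tau0_meas = None
    if per_cycle is not None:
        cycle_tau0_meas = [per_cycle["tau0"][per_cycle["step"] == s]
                           for s in range(n_fit)]

    last_sim = {}

    gamma_pre = float(amplitudes[0])
    _, _pre_strains = _mode_weights(linear_params, omega)

    def _unsoftened(a: float) -> tuple[ModelParameters, np.ndarray]:
        """Mature moduli and preconditioned x for softening coefficient a.

        The sweep measures the moduli of the pre-softened clot,
        G_tilde_i = x_pre,i * G_i0 with x_pre,i = exp(-a * gamma_e,i) at
        the small pre-LAOS amplitude (the viscosities are measured
        unbiased: the apparent relaxation time is eta_i / (x_i G_i)).
        Dividing out x_pre and starting the simulation from x = x_pre
        keeps the linear and nonlinear stages mutually consistent.
        """
        xpre = np.array([math.exp(-a * gamma_pre),
                         math.exp(-a * gamma_pre * _pre_strains[0]),
                         math.exp(-a * gamma_pre * _pre_strains[1])]) \
            if a > 0 else np.ones(3)
        p = linear_params.replace(G00=linear_params.G00 / xpre[0],
                                  G10=linear_params.G10 / xpre[1],
                                  G20=linear_params.G20 / xpre[2])
        return p, xpre

    def run(a, cx, k1, n1, k2) -> np.ndarray:
        a = max(a, 0.0)
        base, xpre = _unsoftened(a)
        p = base.replace(a=a, cx=max(cx, 0.0), k1=max(k1, 0.0),
                         n1=min(max(n1, 0.0), 5.0), k2=max(k2, 0.0))
        init = ModelState.virgin()
        if a > 0 and p.cx > 0:
            init.x[:] = xpre
        res = simulate(protocol, p, mature=True, initial_state=init,
                       steps_per_period=100, relax_resolution=10)
        last_sim["res"] = res
        last_sim["G00"] = p.G00
        return _last_cycle_model_values(res, omega)

    if per_cycle is not None:
        a, cx = _softening_guess(per_cycle, omega, linear_params, n_starts,
                                 seed)
    else:
        a, cx = 1.0, 0.1
    k1, n1, k2 = 0.0, 1.0, 0.0
    history = []
    converged = False
    iterations = 0

    def _aligned_peaks(res: SimulationResult):
        """Per-cycle model peak records aligned with the measured series.

        Returns (measured tau0, model records) concatenated over the
        fitted steps; the trailing min(n_meas, n_model) cycles of each
        step are matched (segmentation may drop a leading partial cycle).
        """
        model = _per_cycle_model_peaks(res, omega)
        meas_list, mod_list = [], []
        for s in range(n_fit):
            if cycle_tau0_meas is not None:
                meas, mod = cycle_tau0_meas[s], model[s]
                k = min(len(meas), len(mod))
                meas_list.append(meas[-k:])
                mod_list.append(mod[-k:])
            else:
                meas_list.append(tau0_meas[s:s + 1])
                mod_list.append(model[s][-1:])
        return np.concatenate(meas_list), np.concatenate(mod_list)

    # measured per-cycle G_m (aligned per step like tau0); the G_m series
    # is ~4x less noisy than single-sample peak stresses and directly
    # resolves the softening kinetics
    cycle_gm_meas = None
    if per_cycle is not None:
        cycle_gm_meas = [per_cycle["Gm"][per_cycle["step"] == s]
                         for s in range(n_fit)]

    def _gm_residuals(res: SimulationResult):
        if cycle_gm_meas is None:
            return np.empty(0)
        model = _per_cycle_model_gm(res, omega)
        out = []
        for s in range(n_fit):
            meas, mod = cycle_gm_meas[s], model[s]
            k = min(len(meas), len(mod))
            out.append((mod[-k:] - meas[-k:]) / np.abs(meas[-k:]))
        return np.concatenate(out)

    for iterations in range(1, max_iter + 1):
        prev = np.array([a, cx, k1, n1])

        # (i) stiffening at fixed (a, cx): x0, the peak strain and the
        # Maxwell peak stress do not depend on (k1, n1), so one simulation
        # gives the peak-stress residual as a closed form in (k1, n1) —
        # the stiffening-extraction balance tau0 = x0 G00 gamma0 f_ss +
        # sum tau_ve rearranged
        run(a, cx, k1, n1, 0.0)
        meas_c, mod_c = _aligned_peaks(last_sim["res"])
        elast = mod_c["x0"] * last_sim["G00"] * mod_c["gamma0"]

        def fss_residuals(theta):
            model_tau0 = elast * (1.0 + theta[0] * mod_c["gamma0"] ** 2
                                  ) ** theta[1] + mod_c["tau_ve"]
            return (model_tau0 - meas_c) / np.abs(meas_c)

        sol = _multistart(fss_residuals, np.array([max(k1, 0.1),
                                                   max(n1, 0.3)]),
                          (np.array([0.0, 0.0]), np.array([1e3, 5.0])),
                          n_starts, seed + iterations)
        k1, n1 = float(sol.x[0]), float(sol.x[1])

        # (ii) softening at fixed (k1, n1): peak-stress plus G_m-series
        # residuals, full simulation per evaluation
        def tau0_residuals(theta):
            try:
                run(theta[0], theta[1], k1, n1, 0.0)
            except Exception:
                return np.full(2 * len(meas_c), 1e6)
            meas, mod = _aligned_peaks(last_sim["res"])
            return np.concatenate([(mod["tau0"] - meas) / np.abs(meas),
                                   _gm_residuals(last_sim["res"])])

        sol = least_squares(tau0_residuals, np.array([a, cx]),
                            bounds=(np.array([1e-4, 1e-5]),
                                    np.array([20.0, 20.0])), method="trf",
                            xtol=1e-10)
        a, cx = float(sol.x[0]), float(sol.x[1])
        history.append(2.0 * sol.cost)

        change = np.max(np.abs(np.array([a, cx, k1, n1]) - prev)
                        / np.maximum(np.abs(prev), 1e-12))
        if change < CONVERGENCE_THRESHOLD:
            converged = True
            break

    if not converged:
        raise FitFailureError(
            f"alternating softening/stiffening loop did not converge in "
            f"{max_iter} iterations", residual_report={"history": history})

    # joint polish of the coupled quartet from the alternation's fixed
    # point: the block-coordinate loop zigzags slowly in the softening/
    # stiffening valley, so a few joint trust-region steps on the same
    # peak-stress residual remove the remaining coupling bias
    def joint_residuals(theta):
        try:
            run(theta[0], theta[1], theta[2], theta[3], 0.0)
        except Exception:
            return np.full(2, 1e6)
        meas, mod = _aligned_peaks(last_sim["res"])
        return np.concatenate([(mod["tau0"] - meas) / np.abs(meas),
                               _gm_residuals(last_sim["res"])])

    sol = least_squares(joint_residuals, np.array([a, cx, k1, n1]),
                        bounds=(np.array([1e-4, 1e-5, 0.0, 0.0]),
                                np.array([20.0, 20.0, 1e3, 5.0])),
                        method="trf", xtol=1e-12, ftol=1e-12)
    if sol.cost <= (history[-1] / 2.0 if history else np.inf):
        a, cx, k1, n1 = [float(v) for v in sol.x]
        history.append(2.0 * sol.cost)

    # (iii) dissipation last, from the stresses at gamma0/2 and
    # (sqrt2/2) gamma0 on both branches.  The branch difference — the loop
    # width — is what isolates the viscous contribution from the much
    # larger elastic stress; widths of single cycles are noisy, so the
    # per-cycle widths of the trailing cycles of each step are averaged.
    if per_cycle is not None:
        width_meas = {
            frac: [per_cycle[col][per_cycle["step"] == s]
                   for s in range(n_fit)]
            for frac, col in ((SQRT2_2, "width"), (0.5, "width_half"))}
    else:
        width_meas = {SQRT2_2: [np.array([f.width])
                                for f in feats[:n_fit]]}
    width_scale = {frac: [max(float(np.mean(np.abs(w))), 1e-9)
                          for w in series]
                   for frac, series in width_meas.items()}
    meas_half = np.array([f.tau_half for f in feats[:n_fit]])
    meas_sqrt2 = np.array([f.tau_sqrt2 for f in feats[:n_fit]])

    def k2_residuals(theta):
        try:
            m = run(a, cx, k1, n1, theta[0])
        except Exception:
            return np.full(2 * n_fit, 1e6)
        out = [(m["tau_half"] - meas_half) / np.abs(meas_half),
               (m["tau_sqrt2"] - meas_sqrt2) / np.abs(meas_sqrt2)]
        for frac, series in width_meas.items():
            widths = _per_cycle_model_width(last_sim["res"], omega,
                                            target_frac=frac)
            for s in range(n_fit):
                meas, mod = series[s], widths[s]
                k = min(len(meas), len(mod))
                out.append((mod[-k:] - meas[-k:]) / width_scale[frac][s])
        return np.concatenate(out)

    sol = least_squares(k2_residuals, np.array([max(k2, 0.1)]),
                        bounds=(np.array([0.0]), np.array([1e3])),
                        method="trf")
    k2 = float(sol.x[0])

    base, _ = _unsoftened(a)
    params = base.replace(a=a, cx=cx, k1=k1, n1=n1, k2=k2)
    warnings_ = []
    if k1 < 0.01:
        warnings_.append("k1 ~ 0: no measurable strain stiffening, "
                         "n1 is unidentifiable")
    return FitResult(params=params, zeta=math.nan, iterations=iterations,
                     converged=converged,
                     stage_residuals={"tau0": history[-1] if history
                                      else math.nan,
                                      "quarter": 2.0 * sol.cost},
                     objective_history=history, multistart_seed=seed,
                     warnings=warnings_)


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

def fit_full(formation_curve: FormationCurve | None,
             sweep: FrequencySweep | None, laos_trace: RheoTrace | None,
             omega: float = FORMATION_OMEGA, n_starts: int = 5,
             seed: int = 0, step_duration: float = 30.0) -> FitResult:
    """Chain the three fitting stages and score the LAOS fit with zeta.

    Raises :class:`StageFailureError` naming the failing stage when an
    input is missing or a stage does not converge.
    """
    if sweep is None:
        raise StageFailureError("linear-spectrum", "frequency sweep missing")
    if formation_curve is None:
        raise StageFailureError("formation", "formation curve missing")
    if laos_trace is None:
        raise StageFailureError("laos", "LAOS trace missing")

    try:
        linear = fit_linear_spectrum(sweep, n_starts=n_starts, seed=seed)
    except FitFailureError as exc:
        raise StageFailureError("linear-spectrum", str(exc)) from exc

    try:
        t0, tc = fit_formation(formation_curve, omega, linear,
                               n_starts=n_starts, seed=seed + 1)
    except FitFailureError as exc:
        raise StageFailureError("formation", str(exc)) from exc
    linear = linear.replace(t0=t0, tc=tc)

    try:
        feats, per_cycle = laos_step_features(laos_trace, omega)
        nl = fit_nonlinear(feats, linear, omega=omega, per_cycle=per_cycle,
                           step_duration=step_duration,
                           n_starts=max(n_starts - 2, 1), seed=seed + 2)
    except FitFailureError as exc:
        raise StageFailureError("laos", str(exc)) from exc

    params = nl.params.replace(t0=t0, tc=tc)

    # zeta over the whole LAOS trace: resimulate with the fitted set
    amplitudes = [f.gamma0 for f in feats]
    protocol = _laos_protocol_from_amplitudes(amplitudes, omega,
                                              step_duration)
    init = _preconditioned_state(params.a, params.cx, amplitudes[0],
                                 params, omega)
    res = simulate(protocol, params, mature=True, initial_state=init)
    t_rel = laos_trace.time - laos_trace.time[0] + res.trace.time[0]
    model_stress = np.interp(t_rel, res.trace.time, res.trace.stress)
    zeta = mean_relative_error(laos_trace.stress, model_stress)

    return FitResult(params=params, zeta=zeta, iterations=nl.iterations,
                     converged=nl.converged,
                     stage_residuals=nl.stage_residuals,
                     objective_history=nl.objective_history,
                     multistart_seed=seed, warnings=nl.warnings)
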