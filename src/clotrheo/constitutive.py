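"""The nonlinear viscoelastic clot model and its time-domain simulation.

Stress decomposition (extra stress; no hydrostatic pressure term):

    tau = tau_v + tau_e + sum_i tau_ve_i

    tau_v    = 2 (eta_p + f_v(t) f_vi(I_B) eta00) D          viscous dashpot
    tau_e    = f_e(t) x0 f_ss(I_B) G00 (B - I)               equilibrium spring
    tau_ve_i = x_i f_e(t) G_i0 (B_e,i - I)                   Maxwell modes

with per-mode inelastic flow D_p,i = tau_ve_i / (2 f_v(t) eta_i0), formation
factors f_v = 1 - exp(-(t-t0)/tc) (0 before t0) and f_e = f_v^2, strain
stiffening f_ss = (1 + k1 (I_B-3))^n1, nonlinear dissipation
f_vi = 1 + k2 (I_B-3), and softening states x_i relaxing toward
exp(-a sqrt(I_Be,i - 3)) at rate cx (never increasing).

Softening is applied exactly once per mode: the mature moduli G_i0 are
multiplied by x_i (for the equilibrium mode additionally by f_ss); the
equilibrium-dashpot viscosity is modulated by f_vi but not by any x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _core
from .errors import (IntegrationFailureError, InvalidInputError,
                     InvalidParameterError, InvalidStateError)
from .kinematics import elastic_finger_from_cp, finger_tensor
from .parameters import ModelParameters
from .protocol import OSCILLATION, DeformationProtocol
from .trace import RheoTrace

__all__ = [
    "formation_factor_viscous", "formation_factor_elastic",
    "stiffening_factor", "viscous_dissipation_factor",
    "softening_equilibrium", "step_softening",
    "ModelState", "evaluate_stress", "simulate", "SimulationResult",
]


# --------------------------------------------------------------------------
# scalar ingredient functions
# --------------------------------------------------------------------------

def formation_factor_viscous(t: float, params: ModelParameters) -> float:
    """f_v(t): 0 for t <= t0, else 1 - exp(-(t - t0)/tc); in [0, 1)."""
    if params.tc <= 0:
        raise InvalidParameterError("tc must be > 0")
    t = np.asarray(t, dtype=float)
    out = np.where(t <= params.t0, 0.0,
                   -np.expm1(-(t - params.t0) / params.tc))
    return float(out) if out.ndim == 0 else out


def formation_factor_elastic(t: float, params: ModelParameters) -> float:
    """f_e(t) = f_v(t)^2 (the moduli lag the viscosities during formation)."""
    fv = formation_factor_viscous(t, params)
    return fv * fv


def stiffening_factor(I_B: float, params: ModelParameters) -> float:
    """Strain stiffening f_ss = (1 + k1 (I_B - 3))^n1; equals 1 at I_B = 3.

    Depends on the strain only through I_B - 3 = gamma^2 in simple shear,
    hence symmetric in gamma.
    """
    I_B = np.asarray(I_B, dtype=float)
    if np.any(I_B < 3.0 - 1e-9):
        raise InvalidInputError("I_B must be >= 3")
    base = 1.0 + params.k1 * np.maximum(I_B - 3.0, 0.0)
    if np.any(base < 0.0):
        raise InvalidParameterError("stiffening base (1 + k1*(I_B-3)) < 0")
    out = base ** params.n1
    return float(out) if out.ndim == 0 else out


def viscous_dissipation_factor(I_B: float, params: ModelParameters) -> float:
    """Nonlinear dissipation f_vi = 1 + k2 (I_B - 3); equals 1 at I_B = 3."""
    I_B = np.asarray(I_B, dtype=float)
    if np.any(I_B < 3.0 - 1e-9):
        raise InvalidInputError("I_B must be >= 3")
    out = 1.0 + params.k2 * np.maximum(I_B - 3.0, 0.0)
    return float(out) if out.ndim == 0 else out


def softening_equilibrium(I_Be: float, params: ModelParameters) -> float:
    """Softening equilibrium x_inf = exp(-a sqrt(I_Be - 3)), in (0, 1].

    I_Be marginally below 3 (round-off from the tensor algebra) is clamped;
    larger violations raise.
    """
    I_Be = np.asarray(I_Be, dtype=float)
    if np.any(I_Be < 3.0 - 1e-9):
        raise InvalidStateError("elastic Finger invariant < 3")
    out = np.exp(-params.a * np.sqrt(np.maximum(I_Be - 3.0, 0.0)))
    return float(out) if out.ndim == 0 else out


def step_softening(x: float, x_inf: float, cx: float, dt: float) -> float:
    """Advance the softening ODE dx/dt = -cx (x - x_inf) if x > x_inf else 0.

    Uses the exact exponential solution over the step (unconditionally
    stable); the result never increases and never undershoots x_inf.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    if x <= x_inf or cx == 0.0:
        return x
    return x_inf + (x - x_inf) * math.exp(-cx * dt)


# --------------------------------------------------------------------------
# state and pointwise stress evaluation
# --------------------------------------------------------------------------

@dataclass
class ModelState:
    """Internal state at one time point: per-mode inelastic right
    Cauchy-Green tensors (2, 3, 3) and softening states (x0, x1, x2)."""

    time: float
    Cp: np.ndarray
    x: np.ndarray

    @classmethod
    def virgin(cls, time: float = 0.0) -> "ModelState":
        """Stress-free initial state: Cp = I per mode, x = 1."""
        return cls(time=time, Cp=np.broadcast_to(np.eye(3), (2, 3, 3)).copy(),
                   x=np.ones(3))

    def validate(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.shape != (3,) or np.any(x <= 0) or np.any(x > 1 + 1e-12):
            raise InvalidStateError(f"x must be in (0, 1], got {x}")
        Cp = np.asarray(self.Cp, dtype=float)
        if Cp.shape != (2, 3, 3) or not np.all(np.isfinite(Cp)):
            raise InvalidStateError("Cp must be a finite (2, 3, 3) array")
        for m in range(2):
            if not np.allclose(Cp[m], Cp[m].T, atol=1e-8):
                raise InvalidStateError(f"Cp[{m}] not symmetric")
            try:
                np.linalg.cholesky(Cp[m])
            except np.linalg.LinAlgError:
                raise InvalidStateError(
                    f"Cp[{m}] not positive-definite") from None

    def copy(self) -> "ModelState":
        return ModelState(self.time, np.array(self.Cp, dtype=float),
                          np.array(self.x, dtype=float))


def evaluate_stress(state: ModelState, F: np.ndarray, D: np.ndarray,
                    t: float, params: ModelParameters, mature: bool = True):
    """Total extra stress tensor and per-mode breakdown at one instant.

    Works for arbitrary (invertible) F and symmetric D.  Returns
    ``(tau, parts)`` with ``parts`` a dict holding the 3x3 contributions
    'viscous', 'elastic', 'maxwell_1', 'maxwell_2'.
    """
    state.validate()
    F = np.asarray(F, dtype=float)
    D = np.asarray(D, dtype=float)
    fe = 1.0 if mature else formation_factor_elastic(t, params)
    fv = 1.0 if mature else formation_factor_viscous(t, params)

    B = finger_tensor(F)
    I_B = float(np.trace(B))
    fss = stiffening_factor(I_B, params)
    fvi = viscous_dissipation_factor(I_B, params)

    I = np.eye(3)
    tau_v = 2.0 * (params.eta_plasma + fv * fvi * params.eta00) * D
    tau_e = fe * state.x[0] * fss * params.G00 * (B - I)
    parts = {"viscous": tau_v, "elastic": tau_e}
    tau = tau_v + tau_e
    for m, (G, eta) in enumerate(params.maxwell_modes):
        if G <= 0 or eta <= 0:
            tau_m = np.zeros((3, 3))
        else:
            Be = elastic_finger_from_cp(state.Cp[m], F)
            tau_m = state.x[m + 1] * fe * G * (Be - I)
        parts[f"maxwell_{m + 1}"] = tau_m
        tau = tau + tau_m
    return tau, parts


# --------------------------------------------------------------------------
# time-domain simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Sampled output of :func:`simulate`.

    ``trace`` holds (time, strain, shear stress); ``parts`` is an (n, 4)
    array with the shear components of (viscous, equilibrium-elastic,
    Maxwell-1, Maxwell-2) stress; ``x`` the (n, 3) softening-state history;
    ``Cp`` the (n, 2, 3, 3) inelastic tensor history; ``final_state`` the
    state at the last sample (for chaining simulations).
    """

    trace: RheoTrace
    strain_rate: np.ndarray
    parts: np.ndarray
    x: np.ndarray
    Cp: np.ndarray
    final_state: ModelState
    phase_index: np.ndarray  # protocol phase of each sample

    def phase_slice(self, index: int) -> slice:
        idx = np.flatnonzero(self.phase_index == index)
        if idx.size == 0:
            raise InvalidInputError(f"no samples in phase {index}")
        return slice(int(idx[0]), int(idx[-1]) + 1)


def _phase_dt(phase, params: ModelParameters, steps_per_period: int,
              relax_resolution: int):
    """Integration step: at least ``steps_per_period`` steps per oscillation
    period and dt <= lambda_min / relax_resolution (accuracy + stability of
    the per-mode relaxation)."""
    lambdas = params.relaxation_times()
    dt = min(lambdas) / relax_resolution if lambdas else math.inf
    if phase.kind == OSCILLATION:
        dt = min(dt, phase.period / steps_per_period)
    else:
        dt = min(dt, phase.duration / 1000.0)
    return dt


def simulate(protocol: DeformationProtocol, params: ModelParameters,
             mature=True, initial_state: ModelState | None = None,
             steps_per_period: int = 200,
             relax_resolution: int = 20) -> SimulationResult:
    """Integrate the model under a prescribed simple-shear protocol.

    Parameters
    ----------
    mature : bool or sequence of bool
        If True (per phase), the clot is fully formed during that phase
        (f_e = f_v = 1); if False, the formation factors are evaluated at
        absolute protocol time.  A scalar applies to every phase.
    initial_state : ModelState, optional
        Starting state; defaults to the virgin state (Cp = I, x = 1).

    Raises
    ------
    IntegrationFailureError
        If the state loses finiteness; carries ``last_valid_time``.
    """
    if isinstance(mature, bool):
        mature_flags = [mature] * len(protocol.phases)
    else:
        mature_flags = list(mature)
        if len(mature_flags) != len(protocol.phases):
            raise InvalidInputError("one mature flag per phase required")

    state = (initial_state.copy() if initial_state is not None
             else ModelState.virgin())
    state.validate()
    Cp = np.ascontiguousarray(state.Cp, dtype=np.float64)
    x = np.ascontiguousarray(state.x, dtype=np.float64)
    p = _core.params_to_vector(params)

    chunks = []
    t_start = 0.0
    gamma_offset = 0.0
    for i_phase, phase in enumerate(protocol.phases):
        rate = protocol.phase_sample_rate(phase)
        sample_dt = 1.0 / rate
        n_samples = max(int(round(phase.duration * rate)), 1)
        dt_target = _phase_dt(phase, params, steps_per_period,
                              relax_resolution)
        n_sub = max(int(math.ceil(sample_dt / dt_target)), 1)
        dt = sample_dt / n_sub

        t_out = np.empty(n_samples)
        gamma_out = np.empty(n_samples)
        rate_out = np.empty(n_samples)
        tau_out = np.empty(n_samples)
        parts_out = np.empty((n_samples, 4))
        x_out = np.empty((n_samples, 3))
        cp_out = np.empty((n_samples, 2, 3, 3))

        kind = 0 if phase.kind == OSCILLATION else 1
        amp = phase.gamma0 if kind == 0 else phase.rate
        bad = _core._integrate_phase(
            kind, t_start, phase.omega, amp, gamma_offset,
            1 if mature_flags[i_phase] else 0, dt, n_samples, n_sub, p,
            Cp, x, t_out, gamma_out, rate_out, tau_out, parts_out,
            x_out, cp_out)
        if bad >= 0:
            last = t_out[bad - 1] if bad > 0 else t_start
            raise IntegrationFailureError(
                f"integration failed in phase {i_phase} "
                f"({phase.label or phase.kind})", last_valid_time=float(last))
        chunks.append((t_out, gamma_out, rate_out, tau_out, parts_out,
                       x_out, cp_out,
                       np.full(n_samples, i_phase, dtype=np.int64)))
        t_start += n_samples * sample_dt
        if kind == 0:
            gamma_offset += phase.gamma0 * math.sin(
                phase.omega * n_samples * sample_dt)
        else:
            gamma_offset += phase.rate * n_samples * sample_dt

    t = np.concatenate([c[0] for c in chunks])
    trace = RheoTrace(t, np.concatenate([c[1] for c in chunks]),
                      np.concatenate([c[3] for c in chunks]))
    result = SimulationResult(
        trace=trace,
        strain_rate=np.concatenate([c[2] for c in chunks]),
        parts=np.concatenate([c[4] for c in chunks]),
        x=np.concatenate([c[5] for c in chunks]),
        Cp=np.concatenate([c[6] for c in chunks]),
        final_state=ModelState(float(t[-1]), Cp.copy(), x.copy()),
        phase_index=np.concatenate([c[7] for c in chunks]),
    )
    return result
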