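"""Time-resolved moduli during clot formation and (t0, tc) estimation.

During formation the clot moduli scale with f_e(t) = f_v(t)^2 and the clot
viscosities with f_v(t) = 1 - exp(-(t - t0)/tc) (0 before the delay t0), so
at a fixed measurement frequency the storage and loss moduli rise at
different rates and the loss angle delta decreases after t0 — the
fluid-to-solid transition.  ``fit_formation`` recovers (t0, tc) from a
measured G'(t), G''(t) curve by weighted nonlinear least squares, with the
mature moduli already fixed from the frequency sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidInputError
from .linear_spectrum import analytic_moduli
from .parameters import ModelParameters

__all__ = ["FormationCurve", "formation_moduli", "fit_formation"]

#: formation-phase measurement frequency, rad/s (1 Hz protocol)
FORMATION_OMEGA = 2.0 * np.pi


@dataclass(frozen=True)
class FormationCurve:
    """G'(t), G''(t) during clot formation at a fixed frequency."""

    time: np.ndarray
    Gp: np.ndarray
    Gpp: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        gp = np.asarray(self.Gp, dtype=float)
        gpp = np.asarray(self.Gpp, dtype=float)
        if not (len(t) == len(gp) == len(gpp)) or len(t) < 3:
            raise InvalidInputError("need >= 3 equal-length samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "Gp", gp)
        object.__setattr__(self, "Gpp", gpp)

    def __len__(self):
        return len(self.time)

    def delta(self) -> np.ndarray:
        """Loss angle arctan(G''/G') [rad]."""
        return np.arctan2(self.Gpp, self.Gp)


def formation_moduli(t, omega: float, params: ModelParameters):
    """(G'(t), G''(t)) of the forming clot at frequency ``omega``.

    Evaluates the closed-form spectrum with G_i -> f_e(t) G_i0 and
    eta_i -> f_v(t) eta_i0 (plasma viscosity constant); before t0 only the
    plasma contributes: G' = 0, G'' = eta_p * omega.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    fv = np.where(t <= params.t0, 0.0, -np.expm1(-(t - params.t0) / params.tc))
    Gp = np.empty_like(t)
    Gpp = np.empty_like(t)
    for i, (fe_i, fv_i) in enumerate(zip(fv * fv, fv)):
        if fv_i == 0.0:
            Gp[i] = 0.0
            Gpp[i] = params.eta_plasma * omega
        else:
            gp, gpp = analytic_moduli(omega, params, moduli_scale=fe_i,
                                      visc_scale=fv_i)
            Gp[i], Gpp[i] = gp, gpp
    if Gp.size == 1:
        return float(Gp[0]), float(Gpp[0])
    return Gp, Gpp


def _rise_time_bound(curve: FormationCurve) -> float:
    """Upper bound for t0: time of the first sample whose G' exceeds 5x the
    noise floor (floor = max of G' over the first three samples, or a tiny
    absolute level for clean data)."""
    floor = max(float(np.max(np.abs(curve.Gp[:3]))),
                1e-6 * float(np.max(np.abs(curve.Gp))), 1e-12)
    above = np.flatnonzero(curve.Gp > 5.0 * floor)
    if above.size == 0:
        return float(curve.time[-1])
    return float(curve.time[int(above[0])])


def fit_formation(curve: FormationCurve, omega: float,
                  mature_params: ModelParameters,
                  n_starts: int = 5, seed: int = 0) -> tuple[float, float]:
    """Estimate (t0, tc) from a formation curve by joint least squares.

    G' and G'' residuals are each normalized by the channel maximum so the
    (much larger) storage modulus does not dominate the objective.  t0 is
    bounded by [0, first-signal time]; tc > 0.  Multi-start with perturbed
    initial values guards against local minima.

    Raises :class:`FitFailureError` when the curve carries no signal or the
    optimizer fails to converge.
    """
    gp_max = float(np.max(curve.Gp))
    gpp_max = float(np.max(curve.Gpp))
    plasma_gpp = mature_params.eta_plasma * omega
    if gp_max <= 0 or gpp_max <= plasma_gpp * 1.001:
        raise FitFailureError("formation curve carries no clot signal",
                              residual_report={"Gp_max": gp_max,
                                               "Gpp_max": gpp_max})
    t0_hi = max(_rise_time_bound(curve), curve.time[1])
    span = float(curve.time[-1] - curve.time[0])
    w_gp = 1.0 / gp_max
    w_gpp = 1.0 / gpp_max

    def residuals(theta):
        p = mature_params.replace(t0=theta[0], tc=theta[1])
        gp, gpp = formation_moduli(curve.time, omega, p)
        return np.concatenate([(gp - curve.Gp) * w_gp,
                               (gpp - curve.Gpp) * w_gpp])

    rng = np.random.default_rng(seed)
    best = None
    x0_base = np.array([0.5 * t0_hi, 0.2 * span])
    for k in range(n_starts):
        x0 = x0_base if k == 0 else np.array([
            rng.uniform(0.0, t0_hi), rng.uniform(0.02 * span, 0.8 * span)])
        try:
            sol = least_squares(residuals, x0, bounds=([0.0, 1e-6],
                                                       [t0_hi, 10.0 * span]),
                                method="trf")
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError("formation fit did not converge",
                              residual_report={"n_starts": n_starts})
    return float(best.x[0]), float(best.x[1])
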