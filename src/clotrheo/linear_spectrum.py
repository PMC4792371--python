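"""Closed-form linear viscoelastic response and moduli extraction.

For the two-mode generalized Maxwell model the storage and loss moduli are

    G'(w)  = G00 + sum_i G_i (lam_i w)^2 / (1 + (lam_i w)^2)
    G''(w) = (eta_p + eta00) w + sum_i G_i lam_i w / (1 + (lam_i w)^2)

with lam_i = eta_i0 / G_i0.  The same formulas, with the formation-scaled
moduli, describe the forming clot (see :mod:`clotrheo.formation`).
:func:`extract_moduli_from_trace` emulates a rheometer's oscillatory
readout: a least-squares projection of the stress onto sin/cos at the
imposed frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (InsufficientDataError, InvalidInputError,
                     InvalidParameterError, UndefinedPhaseError)
from .parameters import ModelParameters
from .trace import RheoTrace

__all__ = ["FrequencySweep", "analytic_moduli", "phase_angle",
           "extract_moduli_from_trace", "default_sweep_frequencies"]


@dataclass(frozen=True)
class FrequencySweep:
    """Storage/loss moduli [Pa] versus angular frequency [rad/s]."""

    omega: np.ndarray
    Gp: np.ndarray
    Gpp: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.omega, dtype=float)
        gp = np.asarray(self.Gp, dtype=float)
        gpp = np.asarray(self.Gpp, dtype=float)
        if not (len(w) == len(gp) == len(gpp)):
            raise InvalidInputError("omega/Gp/Gpp must have equal length")
        if np.any(w <= 0) or np.any(np.diff(w) <= 0):
            raise InvalidInputError("omega must be positive and strictly "
                                    "increasing")
        if np.any(gp < 0) or np.any(gpp < 0):
            raise InvalidInputError("moduli must be >= 0")
        object.__setattr__(self, "omega", w)
        object.__setattr__(self, "Gp", gp)
        object.__setattr__(self, "Gpp", gpp)

    def __len__(self):
        return len(self.omega)


def default_sweep_frequencies(n: int = 10) -> np.ndarray:
    """n log-spaced frequencies over the experimental range 0.63-63 rad/s."""
    return np.geomspace(0.63, 63.0, n)


def analytic_moduli(omega, params: ModelParameters,
                    moduli_scale: float = 1.0, visc_scale: float = 1.0):
    """(G', G'') of the generalized Maxwell model at ``omega`` [rad/s].

    ``moduli_scale``/``visc_scale`` multiply all clot moduli G_i0 and clot
    viscosities eta_i0 (used for the forming clot, where they are f_e(t)
    and f_v(t)); the plasma viscosity is never scaled.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise InvalidInputError("omega must be > 0")
    Gp = np.full_like(omega, moduli_scale * params.G00, dtype=float)
    Gpp = (params.eta_plasma + visc_scale * params.eta00) * omega
    for G, eta in params.maxwell_modes:
        if G == 0.0 and eta == 0.0:
            continue
        if G <= 0.0:
            raise InvalidParameterError(
                "Maxwell mode with zero modulus but nonzero viscosity has "
                "an undefined relaxation time")
        Gs = moduli_scale * G
        etas = visc_scale * eta
        if Gs == 0.0:
            continue
        lam_w = (etas / Gs) * omega
        denom = 1.0 + lam_w ** 2
        Gp = Gp + Gs * lam_w ** 2 / denom
        Gpp = Gpp + Gs * lam_w / denom
    return Gp, Gpp


def phase_angle(Gp, Gpp):
    """Loss angle delta = arctan(G''/G'), in [0, pi/2] for moduli >= 0."""
    Gp = np.asarray(Gp, dtype=float)
    Gpp = np.asarray(Gpp, dtype=float)
    if np.any((Gp == 0) & (Gpp == 0)):
        raise UndefinedPhaseError("phase angle undefined for G' = G'' = 0")
    out = np.arctan2(Gpp, Gp)
    return float(out) if out.ndim == 0 else out


def extract_moduli_from_trace(trace: RheoTrace, omega: float,
                              window: float = 5.0,
                              discard_cycles: float = 5.0):
    """Oscillatory moduli from a sampled trace by harmonic projection.

    The first ``discard_cycles`` periods are dropped as switching
    transient; the stress over the next ``window`` periods is projected
    (linear least squares) onto sin/cos at ``omega``.  The strain amplitude
    and phase reference are obtained by projecting the strain signal the
    same way, so the result is insensitive to the trace's time origin.

    Returns ``(Gp, Gpp)`` in Pa.
    """
    if omega <= 0:
        raise InvalidInputError("omega must be > 0")
    period = 2.0 * np.pi / omega
    t0 = trace.time[0] + discard_cycles * period
    t1 = t0 + window * period
    if t1 > trace.time[-1] + 1e-9:
        raise InsufficientDataError(
            f"trace spans {(trace.time[-1] - trace.time[0]) / period:.2f} "
            f"periods; need {discard_cycles + window}")
    m = (trace.time >= t0) & (trace.time <= t1)
    t = trace.time[m]
    design = np.column_stack([np.sin(omega * t), np.cos(omega * t),
                              np.ones_like(t)])
    (gs, gc, _), *_ = np.linalg.lstsq(design, trace.strain[m], rcond=None)
    (ss, sc, _), *_ = np.linalg.lstsq(design, trace.stress[m], rcond=None)
    gamma0 = float(np.hypot(gs, gc))
    if gamma0 <= 0:
        raise InsufficientDataError("zero strain amplitude in window")
    # rotate stress phasor into the strain's phase frame:
    # strain = gamma0 sin(wt + phi), phi = atan2(gc, gs)
    cos_phi, sin_phi = gs / gamma0, gc / gamma0
    in_phase = ss * cos_phi + sc * sin_phi
    quad = sc * cos_phi - ss * sin_phi
    return in_phase / gamma0, quad / gamma0
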