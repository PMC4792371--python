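"""Finite-strain tensor kinematics for simple shear.

The deformation is described by the deformation gradient F, multiplicatively
split into an elastic and an inelastic part, F = F_e . F_p.  The strain
measures used by the constitutive model are the Finger tensor B = F.F^T and
its elastic counterpart B_e = F_e.F_e^T.  For numerical work the inelastic
right Cauchy-Green tensor C_p = F_p^T.F_p = F^T.B_e^{-1}.F is evolved in
time; assuming spin-free inelastic flow its rate is

    dC_p/dt = C_p . F^{-1} . D_p . F,

with D_p the inelastic rate-of-deformation tensor.  All tensors are plain
3x3 numpy arrays (dimensionless).
"""

from __future__ import annotations

import numpy as np

from .errors import (DegenerateDeformationError, IntegrationFailureError,
                     InvalidInputError)

__all__ = [
    "shear_deformation_gradient",
    "finger_tensor",
    "elastic_finger_from_cp",
    "update_inelastic_cauchy_green",
    "first_invariant",
    "shear_strain_measure",
]

_I3 = np.eye(3)


def shear_deformation_gradient(gamma: float) -> np.ndarray:
    """Deformation gradient of a simple shear with shear strain ``gamma``.

    Returns the upper-triangular matrix with F[0, 1] = gamma and a unit
    diagonal; det(F) = 1 (simple shear is isochoric).
    """
    gamma = float(gamma)
    if not np.isfinite(gamma):
        raise InvalidInputError(f"shear strain must be finite, got {gamma!r}")
    F = np.eye(3)
    F[0, 1] = gamma
    return F


def finger_tensor(F: np.ndarray) -> np.ndarray:
    """Finger tensor B = F . F^T (symmetric positive-definite)."""
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3) or not np.all(np.isfinite(F)):
        raise InvalidInputError("F must be a finite 3x3 matrix")
    if abs(np.linalg.det(F)) < 1e-12:
        raise DegenerateDeformationError("singular deformation gradient")
    return F @ F.T


def elastic_finger_from_cp(Cp: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Elastic Finger tensor B_e = F . C_p^{-1} . F^T.

    Inverts the defining relation C_p = F^T . B_e^{-1} . F.  The result is
    symmetrized to suppress round-off asymmetry.
    """
    Cp = np.asarray(Cp, dtype=float)
    F = np.asarray(F, dtype=float)
    if abs(np.linalg.det(F)) < 1e-12:
        raise DegenerateDeformationError("singular deformation gradient")
    try:
        Cp_inv = np.linalg.inv(Cp)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDeformationError(f"singular C_p: {exc}") from exc
    Be = F @ Cp_inv @ F.T
    return 0.5 * (Be + Be.T)


def _cp_rate(Cp: np.ndarray, F_inv: np.ndarray, F: np.ndarray,
             Dp: np.ndarray) -> np.ndarray:
    half = Cp @ F_inv @ Dp @ F
    return half + half.T


def update_inelastic_cauchy_green(Cp: np.ndarray, F: np.ndarray,
                                  Dp: np.ndarray, dt: float) -> np.ndarray:
    """Advance C_p over one step of the spin-free inelastic flow rule.

    The rate is the symmetric pair

        dC_p/dt = C_p . F^{-1} . D_p . F  +  (C_p . F^{-1} . D_p . F)^T,

    which follows from C_p = F^T . B_e^{-1} . F with a symmetric (spin-free)
    inelastic velocity gradient; the symmetric pair (rather than the first
    term alone) is required for the mode to relax with time constant
    lambda = eta/G and hence to agree with the closed-form linear spectrum.
    Integrated with a classical RK4 step (F and D_p held at their step
    values); the result is symmetrized against round-off drift.  Positive
    definiteness is checked; a step that loses it is rejected.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    Cp = np.asarray(Cp, dtype=float)
    F = np.asarray(F, dtype=float)
    Dp = np.asarray(Dp, dtype=float)
    try:
        F_inv = np.linalg.inv(F)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDeformationError(f"singular F: {exc}") from exc

    k1 = _cp_rate(Cp, F_inv, F, Dp)
    k2 = _cp_rate(Cp + 0.5 * dt * k1, F_inv, F, Dp)
    k3 = _cp_rate(Cp + 0.5 * dt * k2, F_inv, F, Dp)
    k4 = _cp_rate(Cp + dt * k3, F_inv, F, Dp)
    Cp_new = Cp + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    Cp_new = 0.5 * (Cp_new + Cp_new.T)

    if not np.all(np.isfinite(Cp_new)):
        raise IntegrationFailureError("non-finite C_p after step")
    # cheapest SPD check for a 3x3: Cholesky
    try:
        np.linalg.cholesky(Cp_new)
    except np.linalg.LinAlgError:
        raise IntegrationFailureError(
            "C_p lost positive definiteness") from None
    return Cp_new


def first_invariant(T: np.ndarray) -> float:
    """First invariant (trace) of a tensor."""
    return float(np.trace(np.asarray(T)))


def shear_strain_measure(B: np.ndarray, tol: float = 1e-9) -> float:
    """sqrt(I_B - 3): for simple shear this equals |gamma|.

    Values of I_B slightly below 3 (round-off) are clamped to 3 within
    ``tol``; larger violations raise.
    """
    ib = first_invariant(B)
    if ib < 3.0 - tol:
        raise InvalidInputError(f"first invariant {ib} < 3")
    return np.sqrt(max(ib - 3.0, 0.0))
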