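"""Lissajous-Bowditch cycle analysis of LAOS traces.

A LAOS trace is segmented into closed strain-stress loops (one oscillation
period each).  The scalar descriptors consumed by the fitting procedure
are: the strain amplitude gamma0, the stress tau0 at maximal strain (where
the viscous contribution vanishes), the minimal-strain modulus G_m (the
loop slope at zero strain, whose decay quantifies softening), the stresses
at gamma0/2 and (sqrt(2)/2) gamma0 on the rising branch, and the loop width
at (sqrt(2)/2) gamma0 (a measure of viscous dissipation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFeatureError, InsufficientDataError
from .trace import RheoTrace

__all__ = ["LissajousCycle", "CycleFeatures", "segment_cycles",
           "minimal_strain_modulus", "cycle_features", "extract_stiffening",
           "softening_curve", "loop_area", "loop_width",
           "signed_loop_width"]

SQRT2_2 = np.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class LissajousCycle:
    """One strain-stress loop: samples of a single oscillation period."""

    time: np.ndarray
    strain: np.ndarray
    stress: np.ndarray
    omega: float

    @property
    def gamma0(self) -> float:
        return float(np.max(np.abs(self.strain)))

    def __len__(self):
        return len(self.strain)


@dataclass(frozen=True)
class CycleFeatures:
    """Scalar descriptors of one Lissajous-Bowditch cycle."""

    gamma0: float        # strain amplitude [-]
    tau0: float          # stress at maximal strain [Pa]
    Gm: float            # minimal-strain modulus [Pa]
    tau_half: float      # stress at gamma0/2, rising branch [Pa]
    tau_sqrt2: float     # stress at (sqrt2/2) gamma0, rising branch [Pa]
    width: float         # loop width at (sqrt2/2) gamma0 [Pa]


def segment_cycles(trace: RheoTrace, omega: float) -> list[LissajousCycle]:
    """Split a trace into full cycles delimited by upward strain
    zero-crossings; partial leading/trailing cycles are discarded.

    Strains within round-off of zero are snapped to zero before crossing
    detection; crossings closer than half a period (noise chatter) are
    merged.  A leading or trailing segment spanning a full period (within
    sampling tolerance) counts as a cycle even without an explicit
    boundary crossing sample.
    """
    g = trace.strain
    gmax = np.max(np.abs(g))
    if gmax == 0.0:
        raise InsufficientDataError("zero strain throughout")
    z = np.where(np.abs(g) <= 1e-9 * gmax, 0.0, g)
    up = np.flatnonzero((z[:-1] < 0.0) & (z[1:] >= 0.0)) + 1
    start = [0] if (z[0] == 0.0 and len(z) > 1 and z[1] > 0.0) else []
    up = np.unique(np.concatenate([start, up]).astype(int))
    period = 2.0 * np.pi / omega
    if up.size >= 2:
        keep = [int(up[0])]
        for i in up[1:]:
            if trace.time[int(i)] - trace.time[keep[-1]] > 0.5 * period:
                keep.append(int(i))
        up = np.array(keep)
    up = list(int(i) for i in up)
    if up:
        dt = float(np.median(np.diff(trace.time)))
        if up[0] > 0 and trace.time[up[0]] - trace.time[0] >= \
                period - 1.5 * dt:
            up.insert(0, 0)
        if trace.time[-1] - trace.time[up[-1]] >= period - 1.5 * dt:
            up.append(len(g))
    if len(up) < 2:
        raise InsufficientDataError("fewer than one full cycle in trace")
    cycles = []
    for a, b in zip(up[:-1], up[1:]):
        cycles.append(LissajousCycle(trace.time[a:b], trace.strain[a:b],
                                     trace.stress[a:b], omega))
    return cycles


def _branch_masks(cycle: LissajousCycle):
    """Boolean masks of the rising (d gamma/dt > 0) and falling branches."""
    dgdt = np.gradient(cycle.strain, cycle.time)
    return dgdt > 0, dgdt < 0


def minimal_strain_modulus(cycle: LissajousCycle,
                           window: float = 0.1) -> float:
    """Slope d tau/d gamma at gamma = 0.

    Estimated by linear regression of stress on strain over
    |gamma| <= window * gamma0, separately on the rising and falling
    branches, then averaged — the branch average cancels the (antisymmetric)
    viscous offset.
    """
    g0 = cycle.gamma0
    if g0 == 0.0:
        raise DegenerateFeatureError("zero-amplitude cycle")
    rising, falling = _branch_masks(cycle)
    slopes = []
    for branch in (rising, falling):
        # widen the nominal window if the sampling is too coarse to give
        # a meaningful regression (at 100 samples/cycle the 0.1 gamma0
        # window holds only ~3 points per branch)
        w = window
        m = branch & (np.abs(cycle.strain) <= w * g0)
        while np.count_nonzero(m) < 3 and w < 0.30:
            w *= 1.5
            m = branch & (np.abs(cycle.strain) <= w * g0)
        if np.count_nonzero(m) < 3:
            raise InsufficientDataError(
                "too few samples in the minimal-strain window")
        A = np.column_stack([cycle.strain[m], np.ones(np.count_nonzero(m))])
        (slope, _), *_ = np.linalg.lstsq(A, cycle.stress[m], rcond=None)
        slopes.append(slope)
    return float(0.5 * (slopes[0] + slopes[1]))


def _interp_on_branch(cycle: LissajousCycle, mask: np.ndarray,
                      gamma_target: float) -> float:
    """Linear interpolation of stress at gamma_target among the branch's
    samples (the branch's strain is monotone up to sampling noise)."""
    g = cycle.strain[mask]
    s = cycle.stress[mask]
    order = np.argsort(g)
    g, s = g[order], s[order]
    if not (g[0] - 1e-12 <= gamma_target <= g[-1] + 1e-12):
        raise InsufficientDataError(
            f"target strain {gamma_target} outside branch range")
    return float(np.interp(gamma_target, g, s))


def branch_stress(cycle: LissajousCycle, gamma_target: float,
                  branch: str = "rising", window: float = 0.15) -> float:
    """Stress at a target strain on one branch, by local linear regression.

    Regresses stress on strain over |gamma - gamma_target| <=
    window * gamma0 on the requested branch and evaluates the line at the
    target — a lower-variance estimator of the same quantity as two-point
    interpolation when the stress carries measurement noise.
    """
    rising, falling = _branch_masks(cycle)
    mask = (rising if branch == "rising" else falling) & (
        np.abs(cycle.strain - gamma_target) <= window * cycle.gamma0)
    n = np.count_nonzero(mask)
    if n < 2:
        return _interp_on_branch(cycle,
                                 rising if branch == "rising" else falling,
                                 gamma_target)
    x = cycle.strain[mask] - gamma_target
    A = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(A, cycle.stress[mask], rcond=None)
    return float(coef[0])


def signed_loop_width(cycle: LissajousCycle, gamma_target: float) -> float:
    """tau_rising - tau_falling at a positive target strain: positive for
    a dissipative loop, and unbiased under zero-mean stress noise."""
    rising, falling = _branch_masks(cycle)
    up = _interp_on_branch(cycle, rising, gamma_target)
    down = _interp_on_branch(cycle, falling, gamma_target)
    return up - down


def loop_width(cycle: LissajousCycle, gamma_target: float) -> float:
    """|tau_rising - tau_falling| at a positive target strain."""
    return abs(signed_loop_width(cycle, gamma_target))


def loop_area(cycle: LissajousCycle) -> float:
    """Enclosed (dissipated-energy) area of the loop, via the shoelace
    formula on the closed strain-stress polygon; positive for a clockwise
    dissipative loop traversal."""
    g = np.append(cycle.strain, cycle.strain[0])
    s = np.append(cycle.stress, cycle.stress[0])
    return float(abs(np.sum(g[:-1] * s[1:] - g[1:] * s[:-1])) / 2.0)


def cycle_features(cycle: LissajousCycle) -> CycleFeatures:
    """All scalar descriptors of one cycle.

    tau0 is read at the single sample of maximal strain (the strain rate
    vanishes there, so the stress is smooth and needs no smoothing);
    tau_half and tau_sqrt2 are interpolated on the rising branch.
    """
    g0 = cycle.gamma0
    if g0 == 0.0:
        raise DegenerateFeatureError("zero-amplitude cycle")
    i_max = int(np.argmax(cycle.strain))
    tau0 = float(cycle.stress[i_max])
    rising, _ = _branch_masks(cycle)
    tau_half = _interp_on_branch(cycle, rising, 0.5 * g0)
    tau_sqrt2 = _interp_on_branch(cycle, rising, SQRT2_2 * g0)
    width = loop_width(cycle, SQRT2_2 * g0)
    return CycleFeatures(gamma0=g0, tau0=tau0,
                         Gm=minimal_strain_modulus(cycle),
                         tau_half=tau_half, tau_sqrt2=tau_sqrt2, width=width)


def extract_stiffening(features, x0_values, tau_ve_values,
                       G00: float) -> list[tuple[float, float]]:
    """Stiffening values implied by measured peak stresses.

    Solves the peak-stress balance for the stiffening function:

        f_ss(gamma0) = (tau0 - sum_i tau_ve_i) / (x0 * G00 * gamma0)

    where ``x0_values`` and ``tau_ve_values`` (summed Maxwell shear stress
    at maximal strain) come from a model evaluation at the current
    softening parameters.  Returns (gamma0, f_ss) pairs.
    """
    out = []
    for feat, x0, tau_ve in zip(features, x0_values, tau_ve_values):
        denom = x0 * G00 * feat.gamma0
        if abs(denom) < 1e-12:
            raise DegenerateFeatureError(
                "x0 * G00 * gamma0 ~ 0 in stiffening extraction")
        out.append((feat.gamma0, (feat.tau0 - tau_ve) / denom))
    return out


def softening_curve(gm_values) -> np.ndarray:
    """Minimal-strain moduli normalized by the first value, G_m / G_m(0)."""
    gm = np.asarray(gm_values, dtype=float)
    if gm.size == 0:
        raise InsufficientDataError("no G_m values")
    if gm[0] == 0.0:
        raise DegenerateFeatureError("zero initial G_m")
    return gm / gm[0]
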