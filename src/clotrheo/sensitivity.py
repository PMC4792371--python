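"""Variance-based (Sobol) sensitivity analysis of the nonlinear parameters.

Three scalar outputs summarize the three nonlinear features during the
strain interval of amplitude 1 of a LAOS sweep:

* O_so (softening): relative decrease of the peak stress tau0 over the
  interval, (tau0_first - tau0_last) / tau0_first;
* O_ss (strain stiffening): maximum stress during the interval divided by
  the linear equilibrium modulus G00;
* O_vi (viscous dissipation): width of the FIRST Lissajous-Bowditch cycle
  of the interval, at strain (sqrt2/2) * gamma0.

Main (S_i) and total (S_i^T) Sobol indices of the five parameters
(a, cx, k1, n1, k2) are computed from a generalized polynomial chaos
metamodel: parameters are drawn from uniform ranges by quasi-random Sobol
sequence, the model runs once per sample, and a total-degree polynomial
expansion in orthonormal (shifted) Legendre polynomials is fitted by least
squares; the indices then follow analytically from the expansion
coefficients.  A Saltelli pick-and-freeze Monte Carlo estimator is
provided as an independent cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from numpy.polynomial.legendre import legval
from scipy.stats import qmc

from .constitutive import simulate
from .errors import InvalidInputError, InvalidParameterError
from .laos import SQRT2_2
from .parameters import ModelParameters, default_parameters
from .protocol import DeformationProtocol, laos_protocol

__all__ = ["ParameterRange", "SensitivityResult", "model_outputs",
           "sobol_pce", "sobol_montecarlo_oracle", "required_runs",
           "default_ranges", "NONLINEAR_PARAMETERS", "clot_model_function"]

#: the five parameters of the nonlinear part of the model, in order
NONLINEAR_PARAMETERS = ("a", "cx", "k1", "n1", "k2")

OUTPUT_NAMES = ("O_so", "O_ss", "O_vi")


@dataclass(frozen=True)
class ParameterRange:
    """Uniform sampling range for one parameter."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise InvalidParameterError(
                f"{self.name}: low must be < high, got "
                f"[{self.low}, {self.high}]")


def default_ranges(params: ModelParameters | None = None,
                   spread: float = 0.5) -> tuple[ParameterRange, ...]:
    """+-50 % uniform ranges around the nonlinear defaults."""
    p = params if params is not None else default_parameters()
    return tuple(ParameterRange(n, (1 - spread) * getattr(p, n),
                                (1 + spread) * getattr(p, n))
                 for n in NONLINEAR_PARAMETERS)


@dataclass
class SensitivityResult:
    """Main and total Sobol indices per output and parameter.

    ``main`` and ``total`` map output name -> array over parameters (in
    ``parameters`` order); ``variance`` maps output name -> output
    variance; ``n_runs`` is the number of model evaluations used.
    """

    parameters: tuple[str, ...]
    outputs: tuple[str, ...]
    main: dict
    total: dict
    variance: dict
    n_runs: int

    def table(self):
        """Rows of (parameter, output, S, S_T)."""
        rows = []
        for out in self.outputs:
            for j, p in enumerate(self.parameters):
                rows.append((p, out, float(self.main[out][j]),
                             float(self.total[out][j])))
        return rows


# --------------------------------------------------------------------------
# model outputs
# --------------------------------------------------------------------------

def model_outputs(params: ModelParameters,
                  protocol: DeformationProtocol | None = None,
                  steps_per_period: int = 100,
                  relax_resolution: int = 10) -> tuple[float, float, float]:
    """(O_so, O_ss, O_vi) from a LAOS amplitude-sweep simulation."""
    if protocol is None:
        protocol = laos_protocol(final_small_step=False)
    amps = [ph.gamma0 for ph in protocol.phases]
    try:
        i_big = next(i for i, g in enumerate(amps)
                     if abs(g - 1.0) < 1e-9)
    except StopIteration:
        raise InvalidInputError(
            "LAOS protocol must include the amplitude-1 step") from None
    res = simulate(protocol, params, mature=True,
                   steps_per_period=steps_per_period,
                   relax_resolution=relax_resolution)
    sl = res.phase_slice(i_big)
    t = res.trace.time[sl]
    g = res.trace.strain[sl]
    s = res.trace.stress[sl]
    omega = protocol.phases[i_big].omega
    per = int(round(2.0 * np.pi / omega / (t[1] - t[0])))
    n_cyc = len(g) // per
    g2 = g[:n_cyc * per].reshape(n_cyc, per)
    s2 = s[:n_cyc * per].reshape(n_cyc, per)
    peak = np.argmax(g2, axis=1)
    tau0 = s2[np.arange(n_cyc), peak]
    o_so = float((tau0[0] - tau0[-1]) / tau0[0]) if tau0[0] != 0 else 0.0
    o_ss = float(np.max(s) / params.G00) if params.G00 > 0 else math.inf
    # width of the first cycle at (sqrt2/2) gamma0
    g_ref = g2[0]
    gamma0 = float(np.max(np.abs(g_ref)))
    target = SQRT2_2 * gamma0
    dg = np.gradient(g_ref)
    vals = []
    for branch in (dg > 0, dg < 0):
        idx = np.flatnonzero(branch)
        order = idx[np.argsort(g_ref[idx])]
        gx = g_ref[order]
        j = int(np.clip(np.searchsorted(gx, target), 1, len(gx) - 1))
        w = (target - gx[j - 1]) / (gx[j] - gx[j - 1])
        vals.append(s2[0, order[j - 1]] * (1 - w) + s2[0, order[j]] * w)
    o_vi = float(abs(vals[0] - vals[1]))
    return o_so, o_ss, o_vi


def clot_model_function(ranges, base_params: ModelParameters | None = None,
                        protocol: DeformationProtocol | None = None):
    """Vectorize model_outputs over rows of nonlinear-parameter samples."""
    base = base_params if base_params is not None else default_parameters()
    names = [r.name for r in ranges]

    def f(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        out = np.empty((len(X), 3))
        for i, row in enumerate(X):
            p = base.replace(**dict(zip(names, row)))
            out[i] = model_outputs(p, protocol=protocol)
        return out

    return f


# --------------------------------------------------------------------------
# polynomial chaos expansion
# --------------------------------------------------------------------------

def required_runs(n_params: int, degree: int) -> int:
    """Five-fold oversampling of the total-degree basis size,
    5 * C(n_params + degree, degree)."""
    if n_params < 1 or degree < 1:
        raise InvalidInputError("n_params and degree must be >= 1")
    return 5 * math.comb(n_params + degree, degree)


def _multi_indices(dim: int, degree: int) -> np.ndarray:
    idx = [m for m in product(range(degree + 1), repeat=dim)
           if sum(m) <= degree]
    idx.sort(key=lambda m: (sum(m), m))
    return np.array(idx, dtype=int)


def _legendre_design(U: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Design matrix of orthonormal shifted Legendre polynomials on [0,1]."""
    Z = 2.0 * U - 1.0
    dim = U.shape[1]
    max_deg = int(indices.max())
    # P[d][:, j] = P_d(Z[:, j])
    P = np.empty((max_deg + 1, *Z.shape))
    for d in range(max_deg + 1):
        c = np.zeros(d + 1)
        c[d] = 1.0
        P[d] = legval(Z, c) * math.sqrt(2 * d + 1)
    A = np.ones((len(U), len(indices)))
    for k, m in enumerate(indices):
        for j, d in enumerate(m):
            if d > 0:
                A[:, k] *= P[d, :, j]
    return A


def _indices_from_coefficients(coeffs: np.ndarray, indices: np.ndarray):
    """Main/total Sobol indices from orthonormal-basis coefficients."""
    var = float(np.sum(coeffs[1:] ** 2))
    dim = indices.shape[1]
    main = np.zeros(dim)
    total = np.zeros(dim)
    # zero-variance flag: variance negligible against the mean response
    if var <= 1e-24 * max(float(coeffs[0] ** 2), 1e-30):
        return main, total, 0.0
    for k in range(1, len(indices)):
        m = indices[k]
        active = m > 0
        contribution = coeffs[k] ** 2 / var
        total[active] += contribution
        if active.sum() == 1:
            main[active] += contribution
    return main, total, var


def sobol_pce(ranges, n_runs: int | None = None, seed: int = 0,
              degree: int = 3, model=None,
              base_params: ModelParameters | None = None
              ) -> SensitivityResult:
    """Sobol indices via regression (point-collocation) polynomial chaos.

    Parameters are sampled by a scrambled Sobol sequence over the uniform
    ranges; the model is evaluated once per sample; a total-degree
    ``degree`` expansion is fitted per output by least squares.  ``model``
    defaults to the clot LAOS outputs; any callable mapping an (n, d)
    sample array to an (n, k) output array can be substituted.

    Raises :class:`InvalidInputError` if ``n_runs`` is below five times
    the number of expansion terms, or if the regression is rank-deficient.
    """
    ranges = tuple(ranges)
    dim = len(ranges)
    indices = _multi_indices(dim, degree)
    n_terms = len(indices)
    if n_runs is None:
        n_runs = 5 * n_terms
    if n_runs < 5 * n_terms:
        raise InvalidInputError(
            f"n_runs={n_runs} below the five-fold rule "
            f"(need >= {5 * n_terms} for {n_terms} terms)")
    if model is None:
        model = clot_model_function(ranges, base_params=base_params)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-two n
        sampler = qmc.Sobol(d=dim, scramble=True, seed=seed)
        U = sampler.random(n_runs)
    lo = np.array([r.low for r in ranges])
    hi = np.array([r.high for r in ranges])
    X = lo + U * (hi - lo)
    Y = np.atleast_2d(np.asarray(model(X), dtype=float))
    if Y.shape[0] != n_runs:
        Y = Y.T
    n_out = Y.shape[1]

    A = _legendre_design(U, indices)
    if np.linalg.matrix_rank(A) < n_terms:
        raise InvalidInputError(
            "rank-deficient collocation design: increase n_runs")
    coeffs, *_ = np.linalg.lstsq(A, Y, rcond=None)

    outputs = (OUTPUT_NAMES if n_out == 3
               else tuple(f"Y{j}" for j in range(n_out)))
    main, total, variance = {}, {}, {}
    for j, name in enumerate(outputs):
        m, t, v = _indices_from_coefficients(coeffs[:, j], indices)
        main[name], total[name], variance[name] = m, t, v
    return SensitivityResult(parameters=tuple(r.name for r in ranges),
                             outputs=outputs, main=main, total=total,
                             variance=variance, n_runs=n_runs)


# --------------------------------------------------------------------------
# Monte Carlo oracle
# --------------------------------------------------------------------------

def sobol_montecarlo_oracle(ranges, n: int = 1000, seed: int = 0,
                            model=None,
                            base_params: ModelParameters | None = None
                            ) -> SensitivityResult:
    """Saltelli pick-and-freeze Monte Carlo Sobol estimates.

    Uses 2 base sample blocks A, B of size ``n`` plus one hybrid block per
    parameter (total cost n * (d + 2) model runs); main indices by the
    Saltelli 2010 estimator, total indices by the Jansen estimator.
    Intended as an independent cross-check of :func:`sobol_pce`.
    """
    ranges = tuple(ranges)
    dim = len(ranges)
    if model is None:
        model = clot_model_function(ranges, base_params=base_params)
    rng = np.random.default_rng(seed)
    lo = np.array([r.low for r in ranges])
    hi = np.array([r.high for r in ranges])
    A = lo + rng.random((n, dim)) * (hi - lo)
    B = lo + rng.random((n, dim)) * (hi - lo)
    fA = np.atleast_2d(np.asarray(model(A), dtype=float))
    fB = np.atleast_2d(np.asarray(model(B), dtype=float))
    n_out = fA.shape[1]
    f_all = np.concatenate([fA, fB])
    var = np.var(f_all, axis=0, ddof=1)
    mean = np.mean(f_all, axis=0)
    main = np.zeros((dim, n_out))
    total = np.zeros((dim, n_out))
    for i in range(dim):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = np.atleast_2d(np.asarray(model(ABi), dtype=float))
        with np.errstate(invalid="ignore", divide="ignore"):
            # centering fB reduces estimator variance without bias
            main[i] = np.mean((fB - mean) * (fABi - fA), axis=0) / var
            total[i] = 0.5 * np.mean((fA - fABi) ** 2, axis=0) / var
    outputs = (OUTPUT_NAMES if n_out == 3
               else tuple(f"Y{j}" for j in range(n_out)))
    return SensitivityResult(
        parameters=tuple(r.name for r in ranges), outputs=outputs,
        main={name: main[:, j] for j, name in enumerate(outputs)},
        total={name: total[:, j] for j, name in enumerate(outputs)},
        variance={name: float(var[j]) for j, name in enumerate(outputs)},
        n_runs=n * (dim + 2))
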