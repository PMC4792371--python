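"""Material parameters of the clot constitutive model.

The model is a two-mode generalized Maxwell model (equilibrium spring G00,
equilibrium dashpot eta00 in parallel with plasma viscosity eta_plasma, and
two Maxwell modes (G10, eta10), (G20, eta20)) extended with

* formation kinetics: moduli scale with ``f_e(t) = f_v(t)**2`` and
  viscosities with ``f_v(t) = 1 - exp(-(t - t0)/tc)`` after a delay ``t0``;
* deformation-history softening: per-mode state parameters ``x_i`` decaying
  toward ``exp(-a*sqrt(I_Be - 3))`` at rate ``cx``;
* strain stiffening of the equilibrium spring:
  ``f_ss = (1 + k1*(I_B - 3))**n1``;
* nonlinear viscous dissipation of the equilibrium dashpot:
  ``f_vi = 1 + k2*(I_B - 3)``.

Units: moduli in Pa, viscosities in Pa*s, times in s; all nonlinearity
coefficients are dimensionless except ``cx`` (1/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

from .errors import InvalidParameterError, ParseError

__all__ = ["ModelParameters", "default_parameters"]

#: plasma viscosity, Pa*s (a material constant, not a fitted quantity)
PLASMA_VISCOSITY = 0.004

#: names of the thirteen fitted parameters, in pipeline order
FIT_PARAMETER_NAMES = (
    "G00", "G10", "G20", "eta00", "eta10", "eta20",
    "t0", "tc", "a", "cx", "k1", "n1", "k2",
)


@dataclass(frozen=True)
class ModelParameters:
    """All material constants of the clot model.

    Attributes
    ----------
    G00, G10, G20 : float
        Mature moduli of the equilibrium mode and the two Maxwell modes [Pa].
    eta00, eta10, eta20 : float
        Mature viscosities of the equilibrium dashpot and Maxwell modes [Pa*s].
    eta_plasma : float
        Constant plasma viscosity [Pa*s].
    t0, tc : float
        Formation delay time and time constant [s].
    a : float
        Softening-equilibrium coefficient [-].
    cx : float
        Softening rate [1/s].
    k1, n1 : float
        Strain-stiffening coefficients [-].
    k2 : float
        Nonlinear viscous-dissipation coefficient [-].
    """

    G00: float
    G10: float
    G20: float
    eta00: float
    eta10: float
    eta20: float
    t0: float = 0.0
    tc: float = 1.0
    a: float = 0.0
    cx: float = 0.0
    k1: float = 0.0
    n1: float = 0.0
    k2: float = 0.0
    eta_plasma: float = PLASMA_VISCOSITY

    def __post_init__(self):
        for f in fields(self):
            object.__setattr__(self, f.name, float(getattr(self, f.name)))
        for name in ("G00", "G10", "G20", "eta00", "eta10", "eta20",
                     "eta_plasma", "t0", "cx"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(
                    f"{name} must be finite and >= 0, got {v!r}")
        for name in ("tc",):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"tc must be > 0, got {v!r}")
        for name in ("a", "k1", "n1", "k2"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        if self.k1 < 0:
            # (1 + k1*(I_B - 3))**n1 must stay >= 0 on the strain range of
            # interest; negative k1 makes the base negative at finite strain.
            raise InvalidParameterError("k1 must be >= 0")
        if self.k2 < 0:
            raise InvalidParameterError("k2 must be >= 0")

    # -- derived quantities -------------------------------------------------

    @property
    def maxwell_modes(self) -> tuple[tuple[float, float], ...]:
        """(modulus, viscosity) pairs of the Maxwell modes; degenerate modes
        (zero modulus or viscosity) carry no stress and are kept as-is."""
        return ((self.G10, self.eta10), (self.G20, self.eta20))

    def relaxation_times(self) -> tuple[float, ...]:
        """Mature relaxation times lambda_i = eta_i0 / G_i0 of the active
        Maxwell modes (modes with zero modulus or viscosity are skipped)."""
        return tuple(eta / g for g, eta in self.maxwell_modes
                     if g > 0 and eta > 0)

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    # -- flat key=value parameter file --------------------------------------

    def to_file(self, path) -> None:
        """Write a flat ``key = value`` parameter file.

        Units: moduli Pa, viscosities Pa*s, times s, cx 1/s; a, k1, n1, k2
        dimensionless (stated in the file header).
        """
        lines = [
            "# clotrheo model parameters",
            "# units: G* [Pa], eta* [Pa.s], t0/tc [s], cx [1/s];"
            " a, k1, n1, k2 dimensionless",
        ]
        for f in fields(self):
            lines.append(f"{f.name} = {float(getattr(self, f.name))!r}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "ModelParameters":
        values: dict[str, float] = {}
        with open(path) as fh:
            for i, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParseError(f"expected 'key = value', got {raw!r}",
                                     line=i)
                key, _, val = line.partition("=")
                try:
                    values[key.strip()] = float(val)
                except ValueError:
                    raise ParseError(f"non-numeric value {val.strip()!r}",
                                     line=i) from None
        return cls.from_dict(values)


def default_parameters() -> ModelParameters:
    """Reference parameter set for a whole-blood-like clot.

    Chosen to reproduce the characteristic rheology of a mature whole-blood
    clot: a solid-like frequency response with G' an order of magnitude
    above G'' over 0.63-63 rad/s, Maxwell viscosities far above the
    equilibrium-dashpot viscosity, a formation delay of a couple of minutes
    with the moduli plateauing within 30 min, softening that levels off
    within a 30 s amplitude step, and clearly visible strain stiffening and
    nonlinear viscous dissipation at strain amplitude 1.
    """
    return ModelParameters(
        G00=300.0, G10=40.0, G20=20.0,
        eta00=0.5, eta10=40.0, eta20=2.0,
        t0=120.0, tc=300.0,
        a=1.0, cx=0.05, k1=2.0, n1=1.0, k2=2.0,
    )
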