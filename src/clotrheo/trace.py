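"""RheoTrace: sampled (time, strain, stress) series.

The universal exchange object between the simulator, the feature
extractors and the fitting procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["RheoTrace"]


@dataclass(frozen=True)
class RheoTrace:
    """Sampled rheometry signal: time [s], shear strain [-], shear stress
    [Pa], all one-dimensional arrays of equal length with strictly
    increasing, finite time."""

    time: np.ndarray
    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        g = np.asarray(self.strain, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        if not (t.ndim == g.ndim == s.ndim == 1
                and len(t) == len(g) == len(s)):
            raise InvalidInputError("time/strain/stress must be equal-length "
                                    "1-D arrays")
        if len(t) == 0:
            raise InvalidInputError("empty trace")
        for name, arr in (("time", t), ("strain", g), ("stress", s)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise InvalidInputError(
                    f"non-finite {name} at row {int(bad[0])}")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "strain", g)
        object.__setattr__(self, "stress", s)

    def __len__(self) -> int:
        return len(self.time)

    def slice_time(self, t_min: float, t_max: float) -> "RheoTrace":
        """Sub-trace with t_min < t <= t_max."""
        m = (self.time > t_min) & (self.time <= t_max)
        if not np.any(m):
            raise InvalidInputError("empty time window")
        return RheoTrace(self.time[m], self.strain[m], self.stress[m])

    def with_stress(self, stress: np.ndarray) -> "RheoTrace":
        return RheoTrace(self.time, self.strain, np.asarray(stress, float))
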