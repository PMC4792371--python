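"""Deformation protocols: piecewise descriptions of the imposed shear strain.

A protocol is an ordered list of contiguous phases.  Oscillatory phases
impose ``gamma(t) = gamma0 * sin(omega * (t - t_start))``; steady phases
impose a constant shear rate.  The standard three-part rheometry protocol
(formation, frequency sweep, LAOS amplitude sweep) is provided by
:func:`standard_protocol`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["Phase", "DeformationProtocol", "standard_protocol",
           "laos_amplitudes", "formation_phase", "frequency_sweep_phases",
           "laos_phases"]

TWO_PI = 2.0 * math.pi

# phase kinds
OSCILLATION = "oscillation"
STEADY = "steady"


@dataclass(frozen=True)
class Phase:
    """One protocol phase.

    kind 'oscillation': gamma(t) = gamma0 * sin(omega*(t - t_start)); the
    duration should be an integer number of periods so strain is continuous
    across phase boundaries.  kind 'steady': gamma grows at constant rate
    ``rate`` from the strain at phase start (used for start-up flows).
    """
    kind: str
    duration: float
    omega: float = 0.0       # rad/s (oscillation)
    gamma0: float = 0.0      # strain amplitude (oscillation)
    rate: float = 0.0        # 1/s (steady)
    label: str = ""

    def __post_init__(self):
        if self.kind not in (OSCILLATION, STEADY):
            raise InvalidInputError(f"unknown phase kind {self.kind!r}")
        if not (self.duration > 0 and math.isfinite(self.duration)):
            raise InvalidInputError("phase duration must be > 0")
        if self.kind == OSCILLATION and not (self.omega > 0):
            raise InvalidInputError("oscillation phase needs omega > 0")

    @property
    def period(self) -> float:
        return TWO_PI / self.omega if self.kind == OSCILLATION else math.inf


@dataclass(frozen=True)
class DeformationProtocol:
    """Contiguous sequence of phases plus the output sample rate [Hz].

    ``sample_rate=None`` selects, per phase, max(100 Hz, 20 samples per
    oscillation period) — an emulation of a rheometer ADC that tracks the
    imposed frequency.
    """
    phases: tuple[Phase, ...]
    sample_rate: float | None = None

    def __post_init__(self):
        if len(self.phases) == 0:
            raise InvalidInputError("protocol needs at least one phase")
        if self.sample_rate is not None:
            fmax = max((p.omega / TWO_PI for p in self.phases
                        if p.kind == OSCILLATION), default=0.0)
            if self.sample_rate < 20.0 * fmax:
                raise InvalidInputError(
                    "sample_rate must be >= 20x the highest frequency")

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration for p in self.phases))

    def phase_start_times(self) -> np.ndarray:
        starts = np.concatenate(
            [[0.0], np.cumsum([p.duration for p in self.phases])[:-1]])
        return starts

    def phase_sample_rate(self, phase: Phase) -> float:
        """Output sample rate for one phase.

        For oscillation phases the rate is snapped to an integer number of
        samples per period so that phases spanning whole periods end
        exactly on a strain zero-crossing (no spurious DC strain carried
        into later phases)."""
        base = (float(self.sample_rate) if self.sample_rate is not None
                else (max(100.0, 20.0 * phase.omega / TWO_PI)
                      if phase.kind == OSCILLATION else 100.0))
        if phase.kind == OSCILLATION:
            per_period = max(int(math.ceil(base * phase.period)), 8)
            return per_period / phase.period
        return base

    def strain(self, t: np.ndarray) -> np.ndarray:
        """Imposed shear strain at (sorted) times ``t`` since protocol start."""
        t = np.asarray(t, dtype=float)
        starts = self.phase_start_times()
        out = np.zeros_like(t)
        gamma_offset = 0.0
        for start, phase in zip(starts, self.phases):
            end = start + phase.duration
            m = (t >= start) & (t < end) if end < self.total_duration \
                else (t >= start) & (t <= end + 1e-12)
            local = t[m] - start
            if phase.kind == OSCILLATION:
                out[m] = gamma_offset + phase.gamma0 * np.sin(
                    phase.omega * local)
                gamma_offset += phase.gamma0 * math.sin(
                    phase.omega * phase.duration)
            else:
                out[m] = gamma_offset + phase.rate * local
                gamma_offset += phase.rate * phase.duration
        return out


def laos_amplitudes(n_steps: int = 11, low: float = 0.01,
                    high: float = 1.0) -> np.ndarray:
    """Logarithmically spaced LAOS strain amplitudes (default 0.01 -> 1 in
    11 steps)."""
    return np.geomspace(low, high, n_steps)


def formation_phase(duration: float = 1800.0, omega: float = TWO_PI,
                    gamma0: float = 0.01) -> Phase:
    """Formation monitoring: small oscillation at 1 Hz, amplitude 0.01,
    for 30 min."""
    return Phase(OSCILLATION, duration, omega=omega, gamma0=gamma0,
                 label="formation")


def frequency_sweep_phases(n_freq: int = 10, omega_min: float = 0.63,
                           omega_max: float = 63.0, gamma0: float = 0.01,
                           cycles_per_freq: int = 10) -> list[Phase]:
    """Frequency sweep 0.63 -> 63 rad/s at amplitude 0.01.

    Each frequency is held for an integer number of cycles so that the
    strain is continuous across steps.
    """
    phases = []
    for i, omega in enumerate(np.geomspace(omega_min, omega_max, n_freq)):
        phases.append(Phase(OSCILLATION, cycles_per_freq * TWO_PI / omega,
                            omega=float(omega), gamma0=gamma0,
                            label=f"sweep:{i}"))
    return phases


def laos_phases(n_steps: int = 11, step_duration: float = 30.0,
                omega: float = TWO_PI, final_small_step: bool = True
                ) -> list[Phase]:
    """LAOS amplitude sweep: 0.01 -> 1 in ``n_steps`` logarithmic steps at
    1 Hz, 30 s each, followed by one final step back at amplitude 0.01."""
    phases = [Phase(OSCILLATION, step_duration, omega=omega,
                    gamma0=float(g), label=f"laos:{i}")
              for i, g in enumerate(laos_amplitudes(n_steps))]
    if final_small_step:
        phases.append(Phase(OSCILLATION, step_duration, omega=omega,
                            gamma0=0.01, label=f"laos:{n_steps}"))
    return phases


def standard_protocol(sample_rate: float | None = None) -> DeformationProtocol:
    """The full three-part rheometry protocol.

    1. formation: 1 Hz, amplitude 0.01, 30 min;
    2. frequency sweep: 0.63 -> 63 rad/s at amplitude 0.01;
    3. LAOS: amplitude 0.01 -> 1 in 11 logarithmic steps at 1 Hz, 30 s per
       step, then one final 30 s step at amplitude 0.01.
    """
    phases = [formation_phase()] + frequency_sweep_phases() + laos_phases()
    return DeformationProtocol(tuple(phases), sample_rate=sample_rate)


def laos_protocol(sample_rate: float | None = None, **kwargs
                  ) -> DeformationProtocol:
    """The LAOS amplitude sweep alone (mature clot)."""
    return DeformationProtocol(tuple(laos_phases(**kwargs)),
                               sample_rate=sample_rate)
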