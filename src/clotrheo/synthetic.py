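"""Rheometer-like synthetic datasets with known ground truth.

Emulates the three-part measurement (formation at 1 Hz / amplitude 0.01
for 30 min; frequency sweep 0.63-63 rad/s; LAOS amplitude sweep 0.01 -> 1
in 11 logarithmic steps at 1 Hz, 30 s per step, then one final 0.01 step)
by simulating the constitutive model through the whole protocol with state
continuity, converting the first two phases to moduli the way a rheometer
readout would (harmonic projection per window), and adding measurement
noise to the stress.  Strain is treated as exactly imposed
(rheometer-controlled); noise is multiplicative Gaussian on the stress
plus a small additive floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import simulate
from .errors import InvalidInputError
from .formation import FormationCurve
from .linear_spectrum import FrequencySweep, extract_moduli_from_trace
from .parameters import ModelParameters
from .protocol import DeformationProtocol, standard_protocol
from .trace import RheoTrace

__all__ = ["NoiseSpec", "SyntheticDataset", "generate_dataset",
           "noisy_replicates", "package_dataset", "apply_noise"]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise on the stress signal.

    stress -> stress * (1 + N(0, relative_sd)) + N(0, absolute_sd)
    """

    relative_sd: float = 0.02
    absolute_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.relative_sd < 0 or self.absolute_sd < 0:
            raise InvalidInputError("noise SDs must be >= 0")


def apply_noise(stress: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.relative_sd == 0 and noise.absolute_sd == 0:
        return np.array(stress, dtype=float)
    rng = np.random.default_rng(noise.seed)
    out = np.array(stress, dtype=float)
    if noise.relative_sd > 0:
        out *= 1.0 + rng.normal(0.0, noise.relative_sd, out.shape)
    if noise.absolute_sd > 0:
        out += rng.normal(0.0, noise.absolute_sd, out.shape)
    return out


@dataclass
class SyntheticDataset:
    """One synthetic experiment with its ground truth.

    ``formation_curve`` (time, G', G'') and ``sweep`` (omega, G', G'') are
    the moduli the rheometer would report for the first two phases; the
    LAOS phase is kept as the raw (time, strain, stress) trace.  The
    noise-free raw traces of all phases are retained for oracle checks.
    """

    formation_curve: FormationCurve
    sweep: FrequencySweep
    laos_trace: RheoTrace
    truth: ModelParameters
    noise: NoiseSpec
    clean_trace: RheoTrace          # full-protocol noise-free trace
    laos_clean: RheoTrace           # LAOS phase, noise-free


def generate_dataset(params: ModelParameters,
                     protocol: DeformationProtocol | None = None,
                     noise: NoiseSpec | None = None,
                     formation_window: float = 10.0) -> SyntheticDataset:
    """Simulate the full protocol and package the three measured outputs.

    The formation phase (phase 0) runs with the formation kinetics active;
    all later phases are mature.  Formation moduli are extracted per
    non-overlapping ``formation_window``-second window; sweep moduli per
    frequency step discard 5 transient cycles.  The same noisy stress
    signal underlies all three outputs (one rheometer run).
    """
    if protocol is None:
        protocol = standard_protocol()
    res = _simulate_protocol(params, protocol)
    return package_dataset(res, params, protocol, noise,
                           formation_window=formation_window)


def noisy_replicates(params: ModelParameters, noise_specs,
                     protocol: DeformationProtocol | None = None,
                     formation_window: float = 10.0):
    """Independent noisy datasets sharing one clean simulation.

    Emulates repeating the measurement of the same clot with fresh
    instrument noise; far cheaper than re-simulating per replicate.
    """
    if protocol is None:
        protocol = standard_protocol()
    res = _simulate_protocol(params, protocol)
    return [package_dataset(res, params, protocol, ns,
                            formation_window=formation_window)
            for ns in noise_specs]


def _simulate_protocol(params, protocol):
    labels = [p.label for p in protocol.phases]
    if not (labels and labels[0] == "formation"
            and any(l.startswith("sweep") for l in labels)
            and any(l.startswith("laos") for l in labels)):
        raise InvalidInputError("protocol must contain formation, sweep and "
                                "laos phases")
    mature = [i != 0 for i in range(len(protocol.phases))]
    return simulate(protocol, params, mature=mature)


def package_dataset(res, params: ModelParameters,
                    protocol: DeformationProtocol,
                    noise: NoiseSpec | None = None,
                    formation_window: float = 10.0) -> SyntheticDataset:
    """Apply noise to a simulated protocol run and build the three outputs."""
    if noise is None:
        noise = NoiseSpec(relative_sd=0.0, absolute_sd=0.0)
    labels = [p.label for p in protocol.phases]
    sweep_idx = [i for i, l in enumerate(labels) if l.startswith("sweep")]
    laos_idx = [i for i, l in enumerate(labels) if l.startswith("laos")]
    clean = res.trace
    noisy_stress = apply_noise(clean.stress, noise)
    noisy = clean.with_stress(noisy_stress)

    # phase 1 -> formation moduli curve
    sl = res.phase_slice(0)
    ph = protocol.phases[0]
    form_trace = RheoTrace(clean.time[sl], clean.strain[sl],
                           noisy_stress[sl])
    n_win = int(protocol.phases[0].duration // formation_window)
    times, gps, gpps = [], [], []
    for k in range(n_win):
        t0 = k * formation_window
        sub = form_trace.slice_time(t0 - 1e-9, t0 + formation_window)
        # one cycle of margin: sampling starts one dt into the window
        gp, gpp = extract_moduli_from_trace(
            sub, ph.omega, discard_cycles=0.0,
            window=formation_window * ph.omega / (2.0 * np.pi) - 1.0)
        times.append(t0 + 0.5 * formation_window)
        gps.append(max(gp, 0.0))
        gpps.append(max(gpp, 0.0))
    curve = FormationCurve(np.array(times), np.array(gps), np.array(gpps))

    # phase 2 -> frequency sweep moduli
    omegas, gps, gpps = [], [], []
    for i in sweep_idx:
        sl = res.phase_slice(i)
        ph = protocol.phases[i]
        sub = RheoTrace(clean.time[sl], clean.strain[sl], noisy_stress[sl])
        n_cyc = ph.duration * ph.omega / (2.0 * np.pi)
        gp, gpp = extract_moduli_from_trace(sub, ph.omega, discard_cycles=5.0,
                                            window=n_cyc - 6.0)
        omegas.append(ph.omega)
        gps.append(max(gp, 0.0))
        gpps.append(max(gpp, 0.0))
    sweep = FrequencySweep(np.array(omegas), np.array(gps), np.array(gpps))

    # phase 3 -> raw LAOS trace
    a, b = res.phase_slice(laos_idx[0]).start, res.phase_slice(
        laos_idx[-1]).stop
    laos = RheoTrace(clean.time[a:b], clean.strain[a:b], noisy_stress[a:b])
    laos_clean = RheoTrace(clean.time[a:b], clean.strain[a:b],
                           clean.stress[a:b])

    return SyntheticDataset(formation_curve=curve, sweep=sweep,
                            laos_trace=laos, truth=params, noise=noise,
                            clean_trace=clean, laos_clean=laos_clean)
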