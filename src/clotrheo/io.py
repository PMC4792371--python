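"""File I/O: delimited text readers/writers and run reports.

One canonical dialect for every table: comma-separated, '.' decimal, a
required header row.  Rheometer exports vary wildly; strict validation of
a single dialect beats format sniffing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError
from .formation import FormationCurve
from .linear_spectrum import FrequencySweep
from .trace import RheoTrace

__all__ = ["read_trace", "write_trace", "read_sweep", "write_sweep",
           "read_formation_curve", "write_formation_curve",
           "write_feature_table", "write_report"]


def _read_table(path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; header row "
                         f"'{','.join(columns)}' required")
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            # +2: header line plus 1-based numbering
            raise InvalidInputError(
                f"{path}: non-finite {col} at line {int(bad[0]) + 2}")
        df[col] = vals
    return df[list(columns)]


def read_trace(path) -> RheoTrace:
    """Read a time,strain,stress trace (s, -, Pa)."""
    df = _read_table(path, ("time", "strain", "stress"))
    return RheoTrace(df["time"].to_numpy(), df["strain"].to_numpy(),
                     df["stress"].to_numpy())


def write_trace(trace: RheoTrace, path) -> None:
    pd.DataFrame({"time": trace.time, "strain": trace.strain,
                  "stress": trace.stress}).to_csv(path, index=False)


def read_sweep(path) -> FrequencySweep:
    """Read an omega,Gp,Gpp frequency sweep (rad/s, Pa, Pa)."""
    df = _read_table(path, ("omega", "Gp", "Gpp"))
    return FrequencySweep(df["omega"].to_numpy(), df["Gp"].to_numpy(),
                          df["Gpp"].to_numpy())


def write_sweep(sweep: FrequencySweep, path) -> None:
    pd.DataFrame({"omega": sweep.omega, "Gp": sweep.Gp,
                  "Gpp": sweep.Gpp}).to_csv(path, index=False)


def read_formation_curve(path) -> FormationCurve:
    """Read a time,Gp,Gpp formation curve (s, Pa, Pa)."""
    df = _read_table(path, ("time", "Gp", "Gpp"))
    return FormationCurve(df["time"].to_numpy(), df["Gp"].to_numpy(),
                          df["Gpp"].to_numpy())


def write_formation_curve(curve: FormationCurve, path) -> None:
    pd.DataFrame({"time": curve.time, "Gp": curve.Gp,
                  "Gpp": curve.Gpp}).to_csv(path, index=False)


def write_feature_table(features, path) -> None:
    """Per-amplitude-step cycle features as step,gamma0,tau0,Gm,tau_half,
    tau_sqrt2,width."""
    rows = [{"step": i, "gamma0": f.gamma0, "tau0": f.tau0, "Gm": f.Gm,
             "tau_half": f.tau_half, "tau_sqrt2": f.tau_sqrt2,
             "width": f.width} for i, f in enumerate(features)]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(payload: dict, path) -> None:
    """Machine-readable JSON report (parameters, diagnostics, seed)."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default)
                          + "\n")
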