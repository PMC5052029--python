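"""Plain-text trace I/O: two-column delimited files with a unit header."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from glica.trace import Trace


def write_trace(path: str | Path, trace: Trace) -> None:
    """Write a trace as ``time_s,value`` CSV with a one-line unit header."""
    path = Path(path)
    header = f"time_s,value_{trace.units or 'au'}"
    data = np.column_stack([trace.times, trace.values])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def read_trace(path: str | Path) -> Trace:
    """Read a two-column delimited trace file written by :func:`write_trace`.

    The sampling interval is recovered from the time column (must be
    uniform); the unit label comes from the header.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    units = ""
    parts = header.replace("\t", ",").split(",")
    if len(parts) >= 2 and parts[1].startswith("value"):
        units = parts[1].removeprefix("value").lstrip("_")
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value)")
    t, v = data[:, 0], data[:, 1]
    dts = np.diff(t)
    if dts.size == 0:
        raise ValueError(f"{path}: trace needs at least two samples")
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: non-uniform sampling")
    return Trace(values=v, dt=dt, t0=float(t[0]), units=units)
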