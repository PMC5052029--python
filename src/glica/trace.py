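"""Uniformly sampled time-series container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_DT = 1.0 / 20_000.0  # 20 kHz acquisition grid


@dataclass
class Trace:
    """A uniformly sampled time series (current in pA or voltage in mV).

    Parameters
    ----------
    values : array-like
        Sample values; must be finite.
    dt : float
        Sampling interval in seconds (> 0). Default 50 us (20 kHz).
    t0 : float
        Time of the first sample in seconds.
    units : str
        Unit label, e.g. ``"pA"`` or ``"mV"``.
    """

    values: np.ndarray
    dt: float = DEFAULT_DT
    t0: float = 0.0
    units: str = ""
    _times: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.values.ndim != 1:
            raise ValueError("Trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Trace values must be finite")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Total span covered by the samples, in seconds."""
        return self.dt * self.values.size

    def __len__(self) -> int:
        return self.values.size

    def copy(self, values: np.ndarray | None = None) -> "Trace":
        """Return a copy, optionally with replaced values on the same grid."""
        v = self.values.copy() if values is None else np.asarray(values, float)
        return Trace(values=v, dt=self.dt, t0=self.t0, units=self.units)

    def index_of(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (ties round toward zero)."""
        x = (t - self.t0) / self.dt
        return int(np.ceil(x - 0.5))
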