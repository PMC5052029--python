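"""Calcium dynamics and dye fluorescence forward model.

Cytosolic calcium follows a single-pool balance

    d[Ca]/dt = influx_gain * i_ca(t) - ([Ca] - ca_rest) / tau_extrusion

and the dye reports it through single-site equilibrium binding
``F = F_max * [Ca] / ([Ca] + K_d)`` (fast-buffer approximation: transients
are seconds-scale, dye kinetics are ms-scale, so binding is treated as
instantaneous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glica.diffusion import BufferSpec, FLUO4
from glica.trace import Trace


@dataclass(frozen=True)
class CalciumModel:
    """Calcium-handling and dye parameters.

    Attributes
    ----------
    influx_gain : float
        Calcium concentration increment per unit of Ca-current charge,
        in nM per (pA*s).
    tau_extrusion : float
        Clearance time constant in s (default 3.16 s).
    ca_rest : float
        Resting calcium in nM (default 100).
    dye : BufferSpec
        Indicator dye; its ``K_d`` sets fluorescence saturation
        (default Fluo-4, K_d = 335 nM).
    f_max : float
        Fluorescence at dye saturation, arbitrary units.
    """

    influx_gain: float = 10.0
    tau_extrusion: float = 3.16
    ca_rest: float = 100.0
    dye: BufferSpec = FLUO4
    f_max: float = 1000.0

    def __post_init__(self) -> None:
        if self.tau_extrusion <= 0:
            raise ValueError("tau_extrusion must be > 0")
        if self.ca_rest <= 0:
            raise ValueError("ca_rest must be > 0")

    def fluorescence(self, ca_nM: np.ndarray) -> np.ndarray:
        """Dye fluorescence for a calcium concentration (nM)."""
        return self.f_max * ca_nM / (ca_nM + self.dye.K_d)

    @property
    def f_rest(self) -> float:
        return float(self.fluorescence(np.asarray(self.ca_rest)))


def simulate_calcium_fluorescence(model: CalciumModel,
                                  i_ca: Trace) -> tuple[Trace, Trace]:
    """Propagate a Ca-channel current into calcium and fluorescence traces.

    Parameters
    ----------
    model : CalciumModel
    i_ca : Trace
        Calcium-channel current in pA, positive for inward flux.

    Returns
    -------
    (ca, F) : tuple of Trace
        Calcium concentration in nM and dye fluorescence (a.u.), on the
        input grid.

    Raises
    ------
    ValueError
        If the integrated calcium goes negative (unphysical influx trace).
    """
    dt = i_ca.dt
    decay = np.exp(-dt / model.tau_extrusion)
    drive = model.influx_gain * i_ca.values * model.tau_extrusion * (1.0 - decay)
    # exact update for piecewise-constant influx:
    #   x[k] = x[k-1] * decay + drive[k]   (x = calcium above rest, nM)
    from scipy.signal import lfilter

    x = lfilter([1.0], [1.0, -decay], drive)
    ca = model.ca_rest + x
    if np.any(ca < 0):
        raise ValueError("calcium went negative; check influx trace sign")
    ca_tr = Trace(values=ca, dt=dt, t0=i_ca.t0, units="nM")
    f_tr = Trace(values=model.fluorescence(ca), dt=dt, t0=i_ca.t0, units="au")
    return ca_tr, f_tr
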