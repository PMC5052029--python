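"""Buffered-calcium diffusion: binding ratios, apparent diffusivity, fronts.

A mobile indicator dye and immobile endogenous buffer slow calcium spread.
Each buffer contributes a differential binding ratio

    kappa = [B]_total * K_d / (K_d + [Ca]_rest)^2

and the apparent diffusion coefficient of total calcium is

    D_app = (D_Ca + sum_mobile D_B * kappa_B) / (1 + sum_all kappa_B).

The purely diffusional propagation front is two-regime: an early
diffusion-dominated regime ``x(t) = 2 sqrt(D_app t)`` up to a crossover at
one tenth of the clearance time constant, and a configurable late-time form
(extrusion-limited) beyond it. The default late-time form is a linear
continuation with velocity ``2 sqrt(D_app / tau_decay)``, shifted to join
the early regime continuously at the crossover; it is deliberately
pluggable because the extrusion-limited expression is model-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

#: Default free-calcium diffusion coefficient in cytosol, um^2/s.
D_CA_UM2_S = 223.0

#: Default resting calcium, nM.
CA_REST_NM = 100.0

#: Default transient clearance time constant, s.
TAU_DECAY_S = 3.16

#: Crossover between front regimes as a fraction of tau_decay.
CROSSOVER_TAU_FRACTION = 0.1


@dataclass(frozen=True)
class BufferSpec:
    """One calcium-binding species.

    Attributes
    ----------
    name : str
    total_concentration : float
        Total buffer concentration in uM (> 0 unless ``fixed_kappa`` set).
    K_d : float
        Dissociation constant in nM (> 0 unless ``fixed_kappa`` set).
    D_B : float
        Buffer diffusion coefficient in um^2/s; 0 for an immobile buffer.
    fixed_kappa : float, optional
        Binding ratio given directly, for buffers specified only by kappa.
    """

    name: str = ""
    total_concentration: float = 0.0  # uM
    K_d: float = 0.0  # nM
    D_B: float = 0.0  # um^2/s
    fixed_kappa: float | None = None

    def __post_init__(self) -> None:
        if self.D_B < 0:
            raise ValueError("D_B must be >= 0")
        if self.fixed_kappa is None:
            if self.total_concentration <= 0 or self.K_d <= 0:
                raise ValueError(
                    "total_concentration and K_d must be > 0 "
                    "unless fixed_kappa is given")
        elif self.fixed_kappa < 0:
            raise ValueError("fixed_kappa must be >= 0")

    @property
    def mobile(self) -> bool:
        return self.D_B > 0


#: The indicator dye used throughout: 200 uM, K_d 335 nM, D 100 um^2/s.
FLUO4 = BufferSpec(name="Fluo-4", total_concentration=200.0, K_d=335.0,
                   D_B=100.0)

#: Immobile endogenous buffer, specified only by its binding ratio.
ENDOGENOUS = BufferSpec(name="endogenous", fixed_kappa=20.0, D_B=0.0)


def binding_ratio(b: BufferSpec, ca_rest: float = CA_REST_NM) -> float:
    """Differential calcium-binding ratio kappa of one buffer.

    ``kappa = [B]_total * K_d / (K_d + [Ca]_rest)^2`` with concentrations in
    nM; a ``fixed_kappa`` is returned verbatim.
    """
    if b.fixed_kappa is not None:
        return b.fixed_kappa
    b_tot_nM = b.total_concentration * 1e3
    return b_tot_nM * b.K_d / (b.K_d + ca_rest) ** 2


LateTimeForm = Callable[[np.ndarray, "DiffusionModel"], np.ndarray]


def _linear_continuation(t: np.ndarray, m: "DiffusionModel") -> np.ndarray:
    """Default late-time front: linear, velocity 2*sqrt(D_app/tau), continuous."""
    tc = m.crossover
    x_c = 2.0 * np.sqrt(m.D_app * tc)
    v = 2.0 * np.sqrt(m.D_app / m.tau_decay)
    return x_c + v * (t - tc)


@dataclass(frozen=True)
class DiffusionModel:
    """Cytosol model: free-calcium diffusivity plus a list of buffers."""

    D_Ca: float = D_CA_UM2_S
    ca_rest: float = CA_REST_NM
    buffers: tuple = (FLUO4, ENDOGENOUS)
    tau_decay: float = TAU_DECAY_S
    crossover: float | None = None  # s; default tau_decay / 10
    late_time_form: LateTimeForm = field(default=_linear_continuation,
                                         repr=False, compare=False)
    continuity_tol: float = 1e-6  # um; warn if late form jumps at crossover

    def __post_init__(self) -> None:
        if self.D_Ca <= 0 or self.ca_rest <= 0 or self.tau_decay <= 0:
            raise ValueError("D_Ca, ca_rest, tau_decay must be > 0")
        if self.crossover is None:
            object.__setattr__(self, "crossover",
                               CROSSOVER_TAU_FRACTION * self.tau_decay)
        if self.crossover <= 0:
            raise ValueError("crossover must be > 0")

    @property
    def kappas(self) -> dict[str, float]:
        return {b.name or f"buffer{i}": binding_ratio(b, self.ca_rest)
                for i, b in enumerate(self.buffers)}

    @property
    def D_app(self) -> float:
        return apparent_diffusion_coefficient(self)


def apparent_diffusion_coefficient(m: DiffusionModel) -> float:
    """Apparent diffusion coefficient of total calcium, um^2/s.

    ``D_app = (D_Ca + sum_mobile D_B kappa_B) / (1 + sum_all kappa_B)``;
    with no buffers this reduces to the free-calcium value.
    """
    num = m.D_Ca
    den = 1.0
    for b in m.buffers:
        k = binding_ratio(b, m.ca_rest)
        den += k
        if b.mobile:
            num += b.D_B * k
    return num / den


def diffusion_front(t: float | np.ndarray, m: DiffusionModel) -> float | np.ndarray:
    """Distance (um) reached by a purely diffusional calcium front at time t (s).

    Early regime (t <= crossover): ``x = 2 sqrt(D_app t)``. Late regime:
    the model's configurable ``late_time_form`` (default: continuous linear
    continuation). Emits a warning if the configured late form is
    discontinuous at the crossover.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    d_app = m.D_app
    tc = m.crossover
    early = 2.0 * np.sqrt(d_app * np.minimum(t_arr, tc))
    late = m.late_time_form(np.maximum(t_arr, tc), m)
    jump = abs(float(m.late_time_form(np.asarray([tc]), m)[0])
               - 2.0 * np.sqrt(d_app * tc))
    if jump > m.continuity_tol:
        warnings.warn(
            f"late-time front form jumps by {jump:.3g} um at the crossover",
            RuntimeWarning, stacklevel=2)
    out = np.where(t_arr <= tc, early, late)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def predicted_onset_delay(distance: float, m: DiffusionModel,
                          t_max: float = 1e4) -> float:
    """Time (s) for the diffusional front to reach ``distance`` (um).

    Numerical inverse of :func:`diffusion_front` by root bracketing on the
    monotone front curve. Raises ``ValueError`` with an "unreachable" message
    if the front never reaches the distance within ``t_max`` seconds.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if distance == 0:
        return 0.0
    f = lambda t: diffusion_front(t, m) - distance
    if f(t_max) < 0:
        raise ValueError(f"distance {distance} um unreachable by the "
                         f"diffusional front within {t_max} s")
    return float(brentq(f, 0.0, t_max, xtol=1e-9))
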