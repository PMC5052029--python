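"""Single-compartment membrane model with phenomenological voltage-gated channels.

The compartment obeys

    C_m dV/dt = -(V - E_rest)/R_in - sum_i I_i(V, t) + I_inj(t)

with each channel current ``I = gbar * m^p * h * (V - E_rev)`` where the
activation gate ``m`` and optional inactivation gate ``h`` relax
first-order toward Boltzmann steady states. Integration is fixed-step
exponential Euler on the stimulus grid (20 kHz by default); the step is
halved only when the solution blows up.

Units: mV, ms, pA, pF, nS, MOhm (so ``nS * mV = pA`` and ``nS / pF = 1/ms``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from glica.trace import Trace

V_BLOWUP_MV = 200.0  # |V| beyond this aborts the integration


class IntegrationError(RuntimeError):
    """Raised when the explicit integration diverges."""


@dataclass(frozen=True)
class GateSpec:
    """First-order gate with Boltzmann steady state.

    ``x_inf(V) = 1 / (1 + exp(-(V - v_half)/slope))``; a negative ``slope``
    makes the gate close with depolarization (inactivation).
    """

    v_half: float  # mV
    slope: float   # mV; sign sets activation (+) vs inactivation (-)
    tau: float     # ms, voltage-independent relaxation time

    def steady_state(self, v: float | np.ndarray) -> float | np.ndarray:
        return 1.0 / (1.0 + np.exp(-(v - self.v_half) / self.slope))


@dataclass(frozen=True)
class ChannelSpec:
    """One voltage-gated conductance.

    ``gbar = 0`` removes the channel (models pharmacological block:
    4-AP for the A-type current, TTX for Na, TEA for delayed K,
    Cd/Ni for Ca).
    """

    kind: str  # {"A_type_K", "fast_Na", "delayed_K", "lowthresh_Ca"}
    gbar: float  # nS
    reversal: float  # mV
    activation: GateSpec
    activation_power: int = 1
    inactivation: GateSpec | None = None

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")


@dataclass(frozen=True)
class CellParams:
    """Passive properties plus the set of active conductances."""

    R_in: float = 250.0  # MOhm
    C_m: float = 12.0    # pF
    E_rest: float = -85.0  # mV (current-clamp holding level)
    conductances: tuple = ()

    def __post_init__(self) -> None:
        if self.R_in <= 0 or self.C_m <= 0:
            raise ValueError("R_in and C_m must be > 0")

    @property
    def tau_membrane_ms(self) -> float:
        # MOhm * pF = us; convert to ms
        return self.R_in * self.C_m * 1e-3

    def without(self, *kinds: str) -> "CellParams":
        """Copy with the named channel kinds removed (gbar set to 0)."""
        kept = tuple(c for c in self.conductances if c.kind not in kinds)
        return replace(self, conductances=kept)

    def passive(self) -> "CellParams":
        """Copy with every active conductance removed."""
        return replace(self, conductances=())


# --------------------------------------------------------------------------
# Calibration: the channel kinetics below are declared model fiction. They
# are constrained only by the qualitative behaviours the generator must
# reproduce (see tests/test_calibration.py):
#   * A-type K: half-activation near -55 mV so shortening of PSPs engages
#     above -60 mV; inactivation over tens of ms so a 100 Hz / 100 ms train
#     progressively broadens PSPs; removing it (gbar=0) removes both effects.
#   * fast Na: small, fast, strongly inactivating; boosts PSP amplitude by
#     ~15-30% without firing spikes while the A-current is present, and
#     supports spikelets when the A-current is removed.
#   * delayed K: high threshold, slow; essentially silent for single PSPs.
#   * low-threshold Ca: engages near -45 mV; supplies the calcium influx
#     driving the fluorescence stage.
# --------------------------------------------------------------------------

DEFAULT_CHANNELS: dict[str, ChannelSpec] = {
    "A_type_K": ChannelSpec(
        kind="A_type_K", gbar=16.0, reversal=-95.0,
        activation=GateSpec(v_half=-55.0, slope=6.0, tau=1.0),
        inactivation=GateSpec(v_half=-65.0, slope=-6.0, tau=15.0),
    ),
    "fast_Na": ChannelSpec(
        kind="fast_Na", gbar=16.0, reversal=55.0,
        activation=GateSpec(v_half=-42.0, slope=5.0, tau=0.3),
        inactivation=GateSpec(v_half=-55.0, slope=-5.0, tau=1.5),
    ),
    "delayed_K": ChannelSpec(
        kind="delayed_K", gbar=5.0, reversal=-95.0,
        activation=GateSpec(v_half=-25.0, slope=8.0, tau=4.0),
    ),
    "lowthresh_Ca": ChannelSpec(
        kind="lowthresh_Ca", gbar=1.5, reversal=120.0,
        activation=GateSpec(v_half=-45.0, slope=6.0, tau=2.0),
        inactivation=GateSpec(v_half=-65.0, slope=-7.0, tau=40.0),
    ),
}

#: Map from pharmacological condition label to the channel kinds it removes.
CONDITION_BLOCKS: dict[str, tuple[str, ...]] = {
    "control": (),
    "4AP": ("A_type_K",),
    "TTX": ("fast_Na",),
    "TEA": ("delayed_K",),
    "CdNi": ("lowthresh_Ca",),
    "Cs": ("A_type_K", "delayed_K"),
    "passive": ("A_type_K", "fast_Na", "delayed_K", "lowthresh_Ca"),
}


def default_cell(condition: str = "control", R_in: float = 250.0,
                 C_m: float = 12.0, E_rest: float = -85.0) -> CellParams:
    """Build the calibrated default cell for a pharmacological condition."""
    try:
        blocked = CONDITION_BLOCKS[condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"choose from {sorted(CONDITION_BLOCKS)}") from None
    chans = tuple(c for k, c in DEFAULT_CHANNELS.items() if k not in blocked)
    return CellParams(R_in=R_in, C_m=C_m, E_rest=E_rest, conductances=chans)


def _integrate(cell: CellParams, inj: np.ndarray, dt_ms: float,
               substeps: int) -> tuple[np.ndarray, np.ndarray]:
    chans = cell.conductances
    g_leak = 1e3 / cell.R_in  # nS
    h_ms = dt_ms / substeps
    n = inj.size

    v = cell.E_rest
    # flat parameter arrays for the inner loop; inactivation-free channels
    # get a dummy gate pinned at 1 via ah = 0
    mv_half = np.array([c.activation.v_half for c in chans])
    m_slope = np.array([c.activation.slope for c in chans])
    hv_half = np.array([c.inactivation.v_half if c.inactivation else 0.0
                        for c in chans])
    h_slope = np.array([c.inactivation.slope if c.inactivation else -1.0
                        for c in chans])
    am = np.array([1.0 - np.exp(-h_ms / c.activation.tau) for c in chans])
    ah = np.array([1.0 - np.exp(-h_ms / c.inactivation.tau)
                   if c.inactivation else 0.0 for c in chans])
    gbar = np.array([c.gbar for c in chans])
    erev = np.array([c.reversal for c in chans])
    pw = np.array([float(c.activation_power) for c in chans])
    is_ca = np.array([c.kind == "lowthresh_Ca" for c in chans])

    m = 1.0 / (1.0 + np.exp(-(v - mv_half) / m_slope)) if chans else np.zeros(0)
    h = np.where(ah > 0, 1.0 / (1.0 + np.exp(-(v - hv_half) / h_slope)), 1.0) \
        if chans else np.zeros(0)

    # standing Ca current at rest is balanced by extrusion in the
    # fluorescence stage; report influx relative to it
    ica_rest = -np.sum((gbar * m ** pw * h * (v - erev))[is_ca]) if chans \
        else 0.0
    # current-clamp holding: a constant bias cancels the net standing
    # channel current so that zero injection rests exactly at E_rest
    i_hold = float(np.sum(gbar * m ** pw * h * (v - erev))) if chans else 0.0
    inj = inj + i_hold

    V = np.empty(n)
    i_ca = np.zeros(n)
    for k in range(n):
        for _ in range(substeps):
            if chans:
                m += (1.0 / (1.0 + np.exp(-(v - mv_half) / m_slope)) - m) * am
                h += (1.0 / (1.0 + np.exp(-(v - hv_half) / h_slope)) - h) * ah
                g = gbar * m ** pw * h
                g_tot = g_leak + g.sum()
                v_inf = (g_leak * cell.E_rest + (g * erev).sum() + inj[k]) / g_tot
            else:
                g_tot = g_leak
                v_inf = cell.E_rest + inj[k] / g_leak
            v += (v_inf - v) * (1.0 - np.exp(-h_ms * g_tot / cell.C_m))
            if abs(v) > V_BLOWUP_MV:
                raise IntegrationError(
                    f"|V| exceeded {V_BLOWUP_MV} mV at t={k * dt_ms:.3f} ms; "
                    "retry with a smaller step (substeps hint)")
        V[k] = v
        if chans:
            # inward Ca current reported with positive sign (influx)
            i_ca[k] = -np.sum((gbar * m ** pw * h * (v - erev))[is_ca]) \
                - ica_rest
    return V, i_ca


def simulate_membrane(cell: CellParams, inj: Trace,
                      max_step_halvings: int = 4) -> tuple[Trace, Trace]:
    """Integrate the membrane equation for an injected-current trace.

    Parameters
    ----------
    cell : CellParams
        Passive and active membrane parameters.
    inj : Trace
        Injected current in pA on the integration grid.
    max_step_halvings : int
        How many times to halve the internal step after a blow-up before
        giving up.

    Returns
    -------
    (V, i_ca) : tuple of Trace
        Membrane voltage in mV and the low-threshold Ca-channel current in
        pA (reported with positive sign for inward flux), both on the
        stimulus grid.
    """
    dt_ms = inj.dt * 1e3
    substeps = 1
    for attempt in range(max_step_halvings + 1):
        try:
            V, i_ca = _integrate(cell, inj.values, dt_ms, substeps)
            break
        except IntegrationError:
            if attempt == max_step_halvings:
                raise
            substeps *= 2
    v_tr = Trace(values=V, dt=inj.dt, t0=inj.t0, units="mV")
    ca_tr = Trace(values=i_ca, dt=inj.dt, t0=inj.t0, units="pA")
    return v_tr, ca_tr
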