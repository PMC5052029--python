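"""Construction of injected-current stimuli and stimulus-strength normalization.

The quantal building block is a difference-of-exponentials current shaped
like a miniature EPSC, peak-normalized and scaled to the quantal amplitude
(default 12 pA). Stronger stimuli are built by linear superposition: every
quantum adds one copy of the unit waveform, so trains and randomly dispersed
barrages are exact sums of time-shifted quanta. Stimulus strength across
cells with different input resistance is expressed as the product
``Q * R_in`` in multiples of a 250 MOhm reference cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from glica.trace import DEFAULT_DT, Trace

logger = logging.getLogger(__name__)

#: Reference input resistance (MOhm) used to express normalized strength.
REFERENCE_RIN_MOHM = 250.0

#: Default quantal current amplitude in pA.
DEFAULT_QUANTAL_AMPLITUDE_PA = 12.0

#: Default mini kinetics (ms). Not uniquely constrained by data; chosen to
#: give a sub-millisecond rise and a few-ms-long quantal EPSC. Config keys.
DEFAULT_RISE_TAU_MS = 0.2
DEFAULT_DECAY_TAU_MS = 1.2


@dataclass(frozen=True)
class QuantalKinetics:
    """Kinetic description of the unitary (single-quantum) EPSC current.

    Attributes
    ----------
    amplitude : float
        Peak current of one quantum in pA (>= 0).
    rise_tau : float
        Rising time constant in ms (> 0).
    decay_tau : float
        Decaying time constant in ms (> rise_tau).
    polarity : int
        +1 for the excitatory (inward-depolarizing) waveform, -1 for the
        inverted hyperpolarizing probe used to measure passive responses.
    """

    amplitude: float = DEFAULT_QUANTAL_AMPLITUDE_PA
    rise_tau: float = DEFAULT_RISE_TAU_MS
    decay_tau: float = DEFAULT_DECAY_TAU_MS
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("need decay_tau > rise_tau > 0, got "
                             f"rise={self.rise_tau}, decay={self.decay_tau}")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")

    @property
    def peak_time_ms(self) -> float:
        """Time to peak of the difference-of-exponentials waveform, in ms."""
        tr, td = self.rise_tau, self.decay_tau
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def unit_charge_ms(self) -> float:
        """Integral (pA*ms) of the peak-normalized waveform scaled to amplitude.

        Closed form: amplitude * (decay_tau - rise_tau) / peak_value, where
        peak_value is the unnormalized difference-of-exponentials maximum.
        """
        tr, td = self.rise_tau, self.decay_tau
        tp = self.peak_time_ms
        peak = np.exp(-tp / td) - np.exp(-tp / tr)
        return self.amplitude * (td - tr) / peak


@dataclass(frozen=True)
class StimTrain:
    """Onset schedule of a multi-quantum stimulus."""

    onsets: tuple  # onset times in ms, sorted non-decreasing
    quanta_per_onset: tuple  # positive integer quanta at each onset

    def __post_init__(self) -> None:
        if len(self.onsets) != len(self.quanta_per_onset):
            raise ValueError("onsets and quanta_per_onset length mismatch")
        if any(b < a for a, b in zip(self.onsets, self.onsets[1:])):
            raise ValueError("onsets must be sorted non-decreasing")
        if any(int(q) != q or q < 1 for q in self.quanta_per_onset):
            raise ValueError("quanta_per_onset must be positive integers")

    @property
    def total_Q(self) -> int:
        return int(sum(self.quanta_per_onset))


@dataclass(frozen=True)
class StrengthNorm:
    """Stimulus strength expressed as Q * R_in, normalized to 250 MOhm."""

    Q: int
    R_in: float  # MOhm
    product: float = field(init=False)  # Q * MOhm
    equivalents_250: float = field(init=False)

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("Q must be >= 0")
        if self.R_in <= 0:
            raise ValueError("R_in must be > 0")
        object.__setattr__(self, "product", self.Q * self.R_in)
        object.__setattr__(self, "equivalents_250",
                           self.product / REFERENCE_RIN_MOHM)


def _snap_to_sample(t_ms: float, dt_s: float) -> int:
    """Snap an onset (ms) to the nearest sample index; ties round toward 0."""
    x = (t_ms * 1e-3) / dt_s
    return int(np.ceil(x - 0.5))


def _unit_waveform(kin: QuantalKinetics, dt: float, duration_s: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials on the sampling grid."""
    t = np.arange(int(round(duration_s / dt))) * dt * 1e3  # ms
    w = np.exp(-t / kin.decay_tau) - np.exp(-t / kin.rise_tau)
    peak = w.max()
    if peak <= 0:
        raise ValueError("degenerate kinetics produced a non-positive peak")
    return w / peak


def build_quantal_epsc(kin: QuantalKinetics | None = None,
                       dt: float = DEFAULT_DT,
                       duration: float | None = None) -> Trace:
    """Build the unitary quantal EPSC current waveform.

    The waveform is a difference of exponentials, peak-normalized and scaled
    so that its maximal absolute value equals ``kin.amplitude`` (with sign
    set by ``kin.polarity``). It starts at zero and has decayed to below 1%
    of the peak by the end of the trace.

    Parameters
    ----------
    kin : QuantalKinetics, optional
        Kinetic parameters; defaults give a 12 pA quantum.
    dt : float
        Sampling interval in seconds.
    duration : float, optional
        Trace duration in seconds; default covers ten decay time constants.

    Returns
    -------
    Trace
        Current trace in pA.
    """
    if kin is None:
        kin = QuantalKinetics()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration is None:
        duration = 10.0 * kin.decay_tau * 1e-3
    unit = _unit_waveform(kin, dt, duration)
    return Trace(values=kin.polarity * kin.amplitude * unit,
                 dt=dt, units="pA")


def _superpose(kin: QuantalKinetics, dt: float, duration_s: float,
               onset_samples: np.ndarray, quanta: np.ndarray) -> Trace:
    """Sum scaled unit waveforms at the given sample onsets."""
    n = int(round(duration_s / dt))
    unit = kin.polarity * kin.amplitude * _unit_waveform(kin, dt, duration_s)
    out = np.zeros(n)
    for i, q in zip(onset_samples, quanta):
        if i >= n:
            raise ValueError(f"onset sample {i} beyond trace buffer ({n})")
        m = n - i
        out[i:] += q * unit[:m]
    return Trace(values=out, dt=dt, units="pA")


def build_psp_train(kin: QuantalKinetics | None = None,
                    n: int = 10,
                    rate: float = 100.0,
                    Q: int = 1,
                    dt: float = DEFAULT_DT,
                    duration: float | None = None) -> Trace:
    """Build a regular train of ``n`` mock EPSCs at ``rate`` Hz, each of ``Q`` quanta.

    Onsets are spaced ``1/rate`` apart starting at t=0 and snapped to the
    sampling grid; the waveform is the exact linear superposition of the
    scaled quantal currents.
    """
    if kin is None:
        kin = QuantalKinetics()
    if n < 1:
        raise ValueError("n must be >= 1")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if Q < 0:
        raise ValueError("Q must be >= 0")
    isi_ms = 1e3 / rate
    onsets_ms = np.arange(n) * isi_ms
    if duration is None:
        duration = (onsets_ms[-1] + 10.0 * kin.decay_tau) * 1e-3
    if onsets_ms[-1] * 1e-3 >= duration:
        raise ValueError("train longer than trace buffer")
    idx = np.array([_snap_to_sample(t, dt) for t in onsets_ms])
    return _superpose(kin, dt, duration, idx, np.full(n, Q))


def build_gaussian_train(kin: QuantalKinetics | None = None,
                         n_syn: int = 100,
                         q_per_syn: int = 10,
                         sd: float = 25.0,
                         center: float = 125.0,
                         dt: float = DEFAULT_DT,
                         duration: float | None = None,
                         seed: int | np.random.Generator = 0
                         ) -> tuple[Trace, np.ndarray]:
    """Build a Gaussian-dispersed quantal barrage.

    Each of ``n_syn`` synapses releases ``q_per_syn`` vesicles at times drawn
    i.i.d. from Normal(center, sd) (ms); the stimulus is the superposition of
    one quantal current per release event.

    Release times falling outside the trace window are clipped to the window
    edge and logged (total quantal count is preserved).

    Returns
    -------
    (Trace, ndarray)
        The current trace in pA and the drawn release times (ms), for
        ground-truth bookkeeping.
    """
    if kin is None:
        kin = QuantalKinetics()
    if n_syn < 1:
        raise ValueError("n_syn must be >= 1")
    if q_per_syn < 1:
        raise ValueError("q_per_syn must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    times_ms = rng.normal(center, sd, size=n_syn * q_per_syn)
    if duration is None:
        duration = (center + 5.0 * sd + 10.0 * kin.decay_tau) * 1e-3
    n_samp = int(round(duration / dt))
    idx = np.array([_snap_to_sample(t, dt) for t in times_ms])
    n_clip = int(np.sum((idx < 0) | (idx > n_samp - 1)))
    if n_clip:
        logger.warning("clipped %d release times to the trace window", n_clip)
    idx = np.clip(idx, 0, n_samp - 1)
    trace = _superpose(kin, dt, duration, idx, np.ones(idx.size))
    return trace, times_ms


def normalized_strength(Q: int, R_in: float) -> StrengthNorm:
    """Express stimulus strength as Q * R_in in multiples of 250 MOhm.

    Example: 100 quanta into a 250 MOhm cell and 50 quanta into a 500 MOhm
    cell both give a product of 25,000 Q*MOhm, i.e. 100 equivalents.
    """
    return StrengthNorm(Q=Q, R_in=R_in)


def scale_passive_response(probe_response: Trace, ratio: float) -> Trace:
    """Linearly scale a small passive probe response to a target injection size.

    ``ratio`` is the (negative) amplitude ratio of the target injection over
    the probe injection; scaling preserves the time base and the waveform
    shape (and hence the half-width).
    """
    return probe_response.copy(values=probe_response.values * ratio)
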