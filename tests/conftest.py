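import numpy as np
import pytest

from glica.stim_waveforms import QuantalKinetics, build_quantal_epsc
from glica.trace import Trace


@pytest.fixture
def default_kinetics():
    return QuantalKinetics()


@pytest.fixture
def quantal_epsc():
    return build_quantal_epsc()


def pad_trace(tr: Trace, pre: float = 0.0, post: float = 0.0) -> Trace:
    """Zero-pad a trace on either side (seconds)."""
    n_pre = int(round(pre / tr.dt))
    n_post = int(round(post / tr.dt))
    v = np.concatenate([np.zeros(n_pre), tr.values, np.zeros(n_post)])
    return Trace(values=v, dt=tr.dt, t0=tr.t0, units=tr.units)


@pytest.fixture
def pad():
    return pad_trace


def rc_convolution(inj_pA: np.ndarray, dt_s: float, R_in_MOhm: float,
                   C_m_pF: float, E_rest: float) -> np.ndarray:
    """Analytic convolution oracle for the passive membrane response.

    Exact solution of C dV/dt = -(V-E)/R + I for an input held constant
    over each sampling interval, evaluated at the interval ends: the
    convolution of the input with the kernel R (1-a) a^m, a = exp(-dt/tau).
    """
    n = inj_pA.size
    tau_s = R_in_MOhm * C_m_pF * 1e-6
    a = np.exp(-dt_s / tau_s)
    R_GOhm = R_in_MOhm * 1e-3  # so pA * GOhm = mV
    kernel = R_GOhm * (1.0 - a) * a ** np.arange(n)
    v = np.convolve(inj_pA, kernel)[:n]
    return E_rest + v
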