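"""Voltage-trace metrics and group statistics.

Amplitude and half-width of mock PSPs, normalization against scaled passive
responses, linear passive-peak predictions, train broadening, spikelet
detection, responding-fraction curves, and the statistical tests used for
group comparisons (Fisher exact, paired t, Wilcoxon-Mann-Whitney, Pearson).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from glica.stim_waveforms import StrengthNorm
from glica.trace import Trace

ALPHA = 0.05  # two-sided significance level used throughout


@dataclass(frozen=True)
class PSPMetrics:
    """Summary metrics of one voltage response.

    ``amplitude = peak_Vm - baseline``; half_width is the time (ms) between
    the two half-amplitude crossings, located by linear interpolation.
    ``defined`` is False for flat traces where no crossings exist.
    """

    baseline: float  # mV
    amplitude: float  # mV, signed
    peak_Vm: float  # mV
    half_width: float  # ms (nan when undefined)
    onset_index: int
    defined: bool = True


@dataclass
class TrialRecord:
    """One stimulation trial: strength, voltage peak, calcium outcome."""

    strength: float  # Q*R_in equivalents (multiples of 250 MOhm)
    peak_Vm: float  # mV
    responded: bool | None = None  # set by the detection stage
    dff: float | None = None
    condition: str = "control"


def _half_crossings(values: np.ndarray, level: float,
                    peak_idx: int) -> tuple[float, float] | None:
    """Sub-sample positions of the level crossings bracketing the peak.

    First crossing from the left before the peak, last from the right after
    it; returns None when either side never crosses.
    """
    above = values >= level
    left = None
    for i in range(peak_idx, 0, -1):
        if not above[i - 1]:
            frac = (level - values[i - 1]) / (values[i] - values[i - 1])
            left = i - 1 + frac
            break
    right = None
    for i in range(peak_idx, values.size - 1):
        if not above[i + 1]:
            frac = (values[i] - level) / (values[i] - values[i + 1])
            right = i + frac
            break
    if left is None or right is None:
        return None
    return left, right


def psp_metrics(V: Trace, stim_onset: float,
                baseline_window: float = 0.010) -> PSPMetrics:
    """Compute baseline, amplitude, peak and half-width of a PSP.

    Parameters
    ----------
    V : Trace
        Voltage in mV.
    stim_onset : float
        Stimulus onset time in seconds; the baseline is averaged over
        ``baseline_window`` seconds immediately before it.

    Notes
    -----
    The extremum is searched after the onset; polarity follows the larger
    absolute deflection from baseline, so hyperpolarizing probe responses
    are handled symmetrically. For flat traces the half-width is undefined
    (``defined=False``, ``half_width=nan``).
    """
    i_on = V.index_of(stim_onset)
    i_b0 = max(0, V.index_of(stim_onset - baseline_window))
    if i_b0 >= i_on:
        raise ValueError("baseline window must precede the stimulus onset")
    baseline = float(V.values[i_b0:i_on].mean())
    seg = V.values[i_on:]
    dev = seg - baseline
    k = int(np.argmax(np.abs(dev)))
    sign = 1.0 if dev[k] >= 0 else -1.0
    peak_vm = float(seg[k])
    amplitude = peak_vm - baseline
    cross = _half_crossings(sign * dev, sign * amplitude / 2.0, k)
    if cross is None or amplitude == 0.0:
        return PSPMetrics(baseline=baseline, amplitude=amplitude,
                          peak_Vm=peak_vm, half_width=float("nan"),
                          onset_index=i_on, defined=False)
    left, right = cross
    hw_ms = (right - left) * V.dt * 1e3
    return PSPMetrics(baseline=baseline, amplitude=amplitude,
                      peak_Vm=peak_vm, half_width=hw_ms, onset_index=i_on)


def ratios_vs_passive(active: PSPMetrics,
                      scaled_passive: PSPMetrics) -> tuple[float, float]:
    """Half-width and amplitude ratios of an active PSP over its scaled passive.

    Returns ``(hw_ratio, amp_ratio)``; raises when the passive metrics are
    undefined (flat probe).
    """
    if not scaled_passive.defined:
        raise ValueError("passive metrics undefined; cannot form ratios")
    if not active.defined:
        return float("nan"), active.amplitude / scaled_passive.amplitude
    return (active.half_width / scaled_passive.half_width,
            active.amplitude / scaled_passive.amplitude)


def predict_passive_peak(strength: StrengthNorm,
                         unit_passive_mV_per_equiv: float,
                         E_rest: float = -85.0) -> float:
    """Linear passive prediction of the peak voltage for a given strength.

    ``E_rest + equivalents_250 * unit response``, where the unit response is
    the per-equivalent passive peak depolarization measured from the same
    cell's small probe.
    """
    return E_rest + strength.equivalents_250 * unit_passive_mV_per_equiv


def train_halfwidth_series(V: Trace, onsets: list[float],
                           baseline_window: float = 0.010
                           ) -> tuple[list[float], float]:
    """Per-PSP half-widths in a train and the percent increase last vs first.

    Each PSP is measured on the window from its onset to the next onset
    (the last one runs to the trace end), against the shared baseline taken
    before the first onset. Raises when windows overlap (onsets not sorted).
    """
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("onsets must be strictly increasing")
    i_on0 = V.index_of(onsets[0])
    i_b0 = max(0, V.index_of(onsets[0] - baseline_window))
    if i_b0 >= i_on0:
        raise ValueError("baseline window must precede the first onset")
    baseline = float(V.values[i_b0:i_on0].mean())
    bounds = [V.index_of(t) for t in onsets] + [len(V)]
    widths: list[float] = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        if i1 <= i0:
            raise ValueError("PSP windows overlap")
        seg = V.values[i0:i1] - baseline
        k = int(np.argmax(np.abs(seg)))
        sign = 1.0 if seg[k] >= 0 else -1.0
        cross = _half_crossings(sign * seg, sign * seg[k] / 2.0, k)
        widths.append(float("nan") if cross is None
                      else (cross[1] - cross[0]) * V.dt * 1e3)
    pct = 100.0 * (widths[-1] / widths[0] - 1.0)
    return widths, pct


def detect_spikelets(V: Trace, dvdt_threshold: float = 5.0,
                     min_amplitude: float = 5.0,
                     refractory: float = 0.002
                     ) -> list[tuple[float, float]]:
    """Find fast regenerative events riding on a slow depolarization.

    An event is an upward ``dV/dt`` threshold crossing (mV/ms) followed by a
    local maximum at least ``min_amplitude`` mV above the crossing voltage.
    Defaults (5 mV/ms, 5 mV) are declared conventions.

    Returns a list of ``(time_s, amplitude_mV)`` with the amplitude measured
    relative to the threshold-crossing voltage.
    """
    if V.dt > 1e-4:
        raise ValueError("spikelet detection needs >= 10 kHz sampling")
    dvdt = np.diff(V.values) / (V.dt * 1e3)  # mV/ms
    events: list[tuple[float, float]] = []
    i = 1
    n = dvdt.size
    refr = max(1, int(round(refractory / V.dt)))
    while i < n:
        if dvdt[i] >= dvdt_threshold and dvdt[i - 1] < dvdt_threshold:
            v_cross = V.values[i]
            j = i
            while j + 1 <= n and j + 1 < V.values.size and \
                    V.values[j + 1] >= V.values[j]:
                j += 1
            amp = V.values[j] - v_cross
            if amp >= min_amplitude:
                events.append((V.t0 + i * V.dt, float(amp)))
                i = j + refr
                continue
        i += 1
    return events


def responding_fraction_curve(trials: list[TrialRecord],
                              bin_edges: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Fraction of calcium-responding trials per strength bin and 50% point.

    Returns ``(bin_centers, fractions, strength_at_half)`` where empty bins
    are dropped and the 50% crossing is linearly interpolated between the
    first pair of adjacent (kept) bin centers straddling 0.5;
    ``strength_at_half`` is None when the curve never crosses 0.5.
    """
    edges = np.asarray(bin_edges, float)
    strengths = np.array([t.strength for t in trials])
    responded = np.array([bool(t.responded) for t in trials])
    idx = np.digitize(strengths, edges) - 1
    centers, fracs = [], []
    for b in range(edges.size - 1):
        sel = idx == b
        if not sel.any():
            continue  # empty bin: flagged by omission
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        fracs.append(responded[sel].mean())
    centers_a = np.array(centers)
    fracs_a = np.array(fracs)
    half = None
    for a in range(fracs_a.size - 1):
        f0, f1 = fracs_a[a], fracs_a[a + 1]
        if f0 < 0.5 <= f1:
            half = centers_a[a] + (0.5 - f0) / (f1 - f0) * (
                centers_a[a + 1] - centers_a[a])
            break
        if f0 == 0.5:
            half = float(centers_a[a])
            break
    return centers_a, fracs_a, half


def fisher_exact_2x2(a: int, b: int, c: int, d: int
                     ) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table ``[[a, b], [c, d]]``.

    The p-value sums, over all tables with the same margins, the
    hypergeometric probabilities not exceeding that of the observed table
    (the "sum of <= observed-probability tables" convention). The odds ratio
    is ``ad/bc`` (``inf`` when ``bc = 0`` with ``ad > 0``; ``nan`` when a
    margin is zero).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if min(r1, c1, n - r1, n - c1) == 0:
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return odds, min(p, 1.0)


def compare_groups(x, y, test: str) -> tuple[float, float]:
    """Two-sided group comparison.

    ``test`` is one of ``paired_t`` (equal lengths required), ``wmw``
    (exact for n <= 12 per group, normal approximation above), or
    ``pearson_r2`` (returns R^2 and its p-value).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    if test == "paired_t":
        if x.size != y.size:
            raise ValueError("paired_t requires equal lengths")
        if np.allclose(x, y):
            return 0.0, 1.0
        res = stats.ttest_rel(x, y)
        return float(res.statistic), float(res.pvalue)
    if test == "wmw":
        method = "exact" if max(x.size, y.size) <= 12 else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "pearson_r2":
        r, p = stats.pearsonr(x, y)
        return float(r * r), float(p)
    raise ValueError(f"unknown test {test!r}")
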