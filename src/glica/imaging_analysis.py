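"""Line-scan and frame-scan quantification.

Background subtraction from laser-off lines, spatial averaging into
profiles, sliding-average smoothing, separable Gaussian filtering, dF/F and
dG/R window arithmetic, and exponential decay fitting with nested-model
F-test selection between mono- and bi-exponential forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

from glica.trace import Trace

#: dF/F window conventions (s): F0 averages the 150 ms immediately before
#: the injection; Fpeak averages a 150 ms window starting 100 ms after it.
F0_WINDOW_S = 0.150
PEAK_DELAY_S = 0.100
PEAK_WINDOW_S = 0.150

#: Minimum profile segment length for decay fitting (s).
MIN_DECAY_SEGMENT_S = 7.0

#: Default significance level of the nested F-test selecting the
#: bi-exponential model (not an experimental constant; config key).
DEFAULT_ALPHA_F = 0.01


@dataclass
class LineScan:
    """Time x space fluorescence image for one channel.

    Rows are scan lines (time), columns are positions along the scanned
    segment. ``dark_line_rows`` indexes laser-off rows used for background
    estimation.
    """

    pixels: np.ndarray  # (n_lines, n_pixels)
    line_period: float  # s
    pixel_size: float = 0.1  # um
    dark_line_rows: tuple = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("LineScan pixels must be 2-D (time x space)")
        if self.line_period <= 0:
            raise ValueError("line_period must be > 0")


def subtract_background(ls: LineScan,
                        background: float | None = None) -> LineScan:
    """Subtract a scalar background estimated from laser-off lines.

    The per-channel background is the mean over ``dark_line_rows``; when no
    dark rows exist a config-supplied scalar must be passed. Negative output
    pixels are allowed.
    """
    if ls.dark_line_rows:
        bg = float(ls.pixels[list(ls.dark_line_rows), :].mean())
    elif background is not None:
        bg = float(background)
    else:
        raise ValueError("no dark rows and no configured background value")
    return LineScan(pixels=ls.pixels - bg, line_period=ls.line_period,
                    pixel_size=ls.pixel_size,
                    dark_line_rows=ls.dark_line_rows)


def linescan_profile(ls: LineScan, columns: slice | np.ndarray,
                     exclude_dark: bool = False) -> Trace:
    """Spatially average the selected columns into a fluorescence-vs-time profile."""
    sub = ls.pixels[:, columns]
    if sub.ndim != 2 or sub.shape[1] == 0:
        raise ValueError("empty column selection")
    values = sub.mean(axis=1)
    if exclude_dark and ls.dark_line_rows:
        keep = np.setdiff1d(np.arange(values.size),
                            np.asarray(ls.dark_line_rows))
        values = values[keep]
    return Trace(values=values, dt=ls.line_period, units="au")


def sliding_average(p: Trace, window: int = 5) -> Trace:
    """Centered moving mean with shrinking windows at the edges.

    ``window`` must be odd (the display conventions are 5 or 9 points).
    Edge samples average over the largest centered window that fits, so no
    data is invented at the trace ends where baselines are measured.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be odd and >= 1")
    n = len(p)
    if window > n:
        raise ValueError("window longer than profile")
    half = window // 2
    c = np.concatenate(([0.0], np.cumsum(p.values)))
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (c[hi] - c[lo]) / (hi - lo)
    return p.copy(values=out)


def gaussian_filter2d(ls: LineScan, sigma_t_px: float = 2.0,
                      sigma_x_px: float = 1.0) -> LineScan:
    """Sequential orthogonal 1-D Gaussian filtering of a line-scan image.

    Kernels are normalized to unit sum; the image is reflect-padded. The
    "width" convention is sigma in pixels (time axis first).
    """
    if sigma_t_px < 0 or sigma_x_px < 0:
        raise ValueError("sigmas must be >= 0")
    out = ndimage.gaussian_filter(ls.pixels, sigma=(sigma_t_px, sigma_x_px),
                                  mode="reflect")
    return LineScan(pixels=out, line_period=ls.line_period,
                    pixel_size=ls.pixel_size,
                    dark_line_rows=ls.dark_line_rows)


def df_over_f(p: Trace, stim_onset: float,
              f0_window: float = F0_WINDOW_S,
              peak_delay: float = PEAK_DELAY_S,
              peak_window: float = PEAK_WINDOW_S) -> float:
    """Fractional fluorescence change (Fpeak - F0) / F0 of a profile.

    F0 is the mean over ``f0_window`` seconds immediately before the
    injection onset; Fpeak is the mean over ``peak_window`` seconds starting
    ``peak_delay`` after it. A non-positive F0 raises (it flags a missing or
    bad background subtraction).
    """
    i_on = p.index_of(stim_onset)
    i_f0 = p.index_of(stim_onset - f0_window)
    i_p0 = p.index_of(stim_onset + peak_delay)
    i_p1 = p.index_of(stim_onset + peak_delay + peak_window)
    if i_f0 < 0 or i_p1 > len(p) or i_f0 >= i_on:
        raise ValueError("profile does not cover the dF/F windows")
    f0 = float(p.values[i_f0:i_on].mean())
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0:.3g} <= 0; "
                         "check background subtraction")
    f_peak = float(p.values[i_p0:i_p1].mean())
    return (f_peak - f0) / f0


def dg_over_r(green: np.ndarray, red: np.ndarray, roi: np.ndarray,
              pre_frames: np.ndarray, post_frames: np.ndarray,
              red_background: float = 0.0) -> float:
    """dG/R ratio of a two-channel frame series for one ROI.

    dG is the ROI-mean green fluorescence over the post-stimulus frames
    minus that over the pre-stimulus frames; R is the ROI mean of the
    background-corrected red channel averaged across both frame sets.

    Parameters
    ----------
    green, red : ndarray
        Frame stacks shaped (n_frames, ny, nx).
    roi : ndarray
        Boolean mask (ny, nx).
    pre_frames, post_frames : ndarray
        Disjoint frame index sets before/after the stimulus.
    """
    pre = np.asarray(pre_frames, int)
    post = np.asarray(post_frames, int)
    if np.intersect1d(pre, post).size:
        raise ValueError("pre and post frame sets must be disjoint")
    roi = np.asarray(roi, bool)
    g_pre = green[pre][:, roi].mean()
    g_post = green[post][:, roi].mean()
    both = np.concatenate([pre, post])
    red_avg = red[both].mean(axis=0) - red_background
    r = float(red_avg[roi].mean())
    if r <= 0:
        raise ValueError(f"red normalizer R = {r:.3g} <= 0")
    return float((g_post - g_pre) / r)


@dataclass(frozen=True)
class DecayFit:
    """Result of mono/bi-exponential decay fitting with F-test selection.

    ``weighted_tau`` is the amplitude-weighted time constant
    ``(A1 t1 + A2 t2) / (A1 + A2)`` for the bi-exponential model and simply
    ``tau`` for the mono-exponential one.
    """

    model: str  # "mono" | "bi"
    taus: tuple  # s
    amplitudes: tuple
    offset: float
    weighted_tau: float
    F_statistic: float
    p_F: float
    chosen_by: str
    sse: tuple = field(default=(float("nan"), float("nan")))


def _mono(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _bi(t, a1, t1, a2, t2, c):
    return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + c


def fit_decay(p: Trace, fit_start: float = 0.0,
              alpha_F: float = DEFAULT_ALPHA_F,
              min_segment: float = MIN_DECAY_SEGMENT_S) -> DecayFit:
    """Fit the post-peak decay of a profile with a mono- or bi-exponential.

    Both models are fitted by least squares on the segment from
    ``fit_start`` to the profile end (segment must span at least
    ``min_segment`` seconds); the bi-exponential is accepted when the
    nested-model F-test against the mono fit gives p < ``alpha_F``.
    """
    i0 = p.index_of(fit_start)
    seg = p.values[i0:]
    n = seg.size
    if n * p.dt < min_segment:
        raise ValueError(
            f"decay segment {n * p.dt:.2f} s shorter than required "
            f"{min_segment} s")
    t = np.arange(n) * p.dt
    c0 = float(seg[-max(2, n // 20):].mean())
    a0 = float(seg[0] - c0)
    span = n * p.dt

    try:
        po_m, _ = optimize.curve_fit(
            _mono, t, seg, p0=[a0, span / 4.0, c0],
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as e:
        raise RuntimeError(f"mono-exponential fit failed: {e}") from e
    sse_m = float(np.sum((seg - _mono(t, *po_m)) ** 2))

    try:
        po_b, _ = optimize.curve_fit(
            _bi, t, seg,
            p0=[a0 / 2.0, span / 10.0, a0 / 2.0, span / 2.0, c0],
            bounds=([-np.inf, 1e-6, -np.inf, 1e-6, -np.inf],
                    [np.inf] * 5),
            maxfev=40000)
        sse_b = float(np.sum((seg - _bi(t, *po_b)) ** 2))
    except RuntimeError:
        po_b, sse_b = None, float("inf")

    df_m = n - 3
    df_b = n - 5
    ss_tot = float(np.sum((seg - seg.mean()) ** 2))
    mono_is_perfect = sse_m <= 1e-12 * max(ss_tot, 1e-300)
    if (po_b is not None and not mono_is_perfect
            and sse_b < sse_m and df_b > 0 and sse_b > 0):
        F = ((sse_m - sse_b) / 2.0) / (sse_b / df_b)
        p_F = float(stats.f.sf(F, 2, df_b))
    else:
        F, p_F = 0.0, 1.0

    if p_F < alpha_F and po_b is not None:
        a1, t1, a2, t2, c = po_b
        # report components ordered fast -> slow
        if t1 > t2:
            a1, t1, a2, t2 = a2, t2, a1, t1
        wtau = (a1 * t1 + a2 * t2) / (a1 + a2)
        return DecayFit(model="bi", taus=(float(t1), float(t2)),
                        amplitudes=(float(a1), float(a2)), offset=float(c),
                        weighted_tau=float(wtau), F_statistic=float(F),
                        p_F=p_F, chosen_by=f"F-test alpha={alpha_F}",
                        sse=(sse_m, sse_b))
    a, tau, c = po_m
    return DecayFit(model="mono", taus=(float(tau),),
                    amplitudes=(float(a),), offset=float(c),
                    weighted_tau=float(tau), F_statistic=float(F),
                    p_F=p_F, chosen_by=f"F-test alpha={alpha_F}",
                    sse=(sse_m, sse_b))
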