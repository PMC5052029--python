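"""Scaled-template detection of calcium responses and onset estimation.

At a given alignment the template is fitted to the profile segment by least
squares with two free parameters, scale and offset. The detection criterion
is the fitted scale divided by its standard error, where the standard error
uses the residual standard deviation ``sqrt(SSE / (N - 1))``; a trial is a
response when the criterion strictly exceeds the threshold (3.0 by
convention). Onset estimation resamples the profile to 1 kHz by linear
interpolation, slides a short template along it, and reads the onset from
the lag with the best criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glica.trace import Trace

#: Classification threshold on the detection criterion.
DETECTION_THRESHOLD = 3.0

#: Template lengths (s): full response template and short onset template.
RESPONSE_TEMPLATE_S = 2.5
ONSET_TEMPLATE_S = 1.0

#: Criterion cap for (near-)noiseless fits where SSE -> 0.
CRITERION_CAP = 1e6

#: Resampling rate for onset estimation, Hz.
ONSET_RESAMPLE_HZ = 1000.0


@dataclass(frozen=True)
class Template:
    """Unit-shape response template (peak normalized to 1)."""

    values: np.ndarray
    dt: float  # s

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.size < 2:
            raise ValueError("template needs at least 2 samples")
        if np.ptp(v) == 0:
            raise ValueError("zero-variance template")
        object.__setattr__(self, "values", v)
        peak = np.abs(v).max()
        if not np.isclose(peak, 1.0):
            object.__setattr__(self, "values", v / peak)

    @property
    def length(self) -> float:
        return self.values.size * self.dt


@dataclass(frozen=True)
class DetectionResult:
    """Fit of the template at one alignment.

    ``is_response`` holds iff ``criterion`` strictly exceeds the threshold
    used at classification time.
    """

    best_scale: float
    best_offset: float
    criterion: float
    position: float  # s
    is_response: bool
    onset: float | None = None


def build_template(clear_responses: list[Trace], length: float,
                   dt: float | None = None) -> Template:
    """Average clear-response profiles into a peak-normalized template.

    Profiles must share a common sampling interval (resample first if they
    do not); the pointwise mean is cropped to ``length`` seconds.
    """
    if not clear_responses:
        raise ValueError("need at least one profile")
    dts = {round(p.dt, 12) for p in clear_responses}
    if len(dts) > 1:
        raise ValueError(f"inconsistent sampling intervals: {sorted(dts)}")
    d = clear_responses[0].dt if dt is None else dt
    n = int(round(length / d))
    if any(len(p) < n for p in clear_responses):
        raise ValueError("profile shorter than requested template length")
    mean = np.mean([p.values[:n] for p in clear_responses], axis=0)
    return Template(values=mean, dt=d)


def _fit_scale_offset(segment: np.ndarray, template: np.ndarray
                      ) -> tuple[float, float, float]:
    """Closed-form least-squares fit of ``scale*T + offset`` to a segment.

    Returns (scale, offset, sse).
    """
    n = segment.size
    t_mean = template.mean()
    y_mean = segment.mean()
    stt = float(np.sum((template - t_mean) ** 2))
    if stt == 0:
        raise ValueError("zero-variance template")
    sty = float(np.sum((template - t_mean) * (segment - y_mean)))
    scale = sty / stt
    offset = y_mean - scale * t_mean
    resid = segment - (scale * template + offset)
    sse = float(np.sum(resid ** 2))
    return scale, offset, sse


def cb_fit_and_criterion(p: Trace, T: Template,
                         position: float = 0.0,
                         threshold: float = DETECTION_THRESHOLD
                         ) -> DetectionResult:
    """Fit the template at one alignment and compute the detection criterion.

    The criterion is ``scale / SE`` with ``SE = sqrt(SSE / (N - 1))``; it is
    invariant to adding a constant to the profile and to multiplying it by
    any positive factor, and is capped at ``CRITERION_CAP`` for noiseless
    fits.
    """
    i0 = p.index_of(position)
    n = T.values.size
    if i0 < 0 or i0 + n > len(p):
        raise ValueError("template does not fit within the profile "
                         f"at position {position}")
    seg = p.values[i0:i0 + n]
    scale, offset, sse = _fit_scale_offset(seg, T.values)
    se = np.sqrt(sse / (n - 1))
    if se > 0:
        criterion = scale / se
    else:
        # perfect fit: capped criterion with the sign of the scale,
        # zero for a flat segment (scale 0)
        criterion = np.sign(scale) * np.inf if scale != 0 else 0.0
    criterion = float(np.clip(criterion, -CRITERION_CAP, CRITERION_CAP))
    return DetectionResult(best_scale=scale, best_offset=offset,
                           criterion=criterion, position=position,
                           is_response=criterion > threshold)


def classify_response(p: Trace, T: Template,
                      threshold: float = DETECTION_THRESHOLD,
                      position: float = 0.0) -> bool:
    """Classify a trial: True iff the criterion strictly exceeds ``threshold``.

    Classification is stimulus-aligned (single template position); use
    :func:`onset_time` for the sliding variant.
    """
    return cb_fit_and_criterion(p, T, position, threshold).is_response


def resample_1khz(p: Trace, rate: float = ONSET_RESAMPLE_HZ) -> Trace:
    """Linear-interpolation resampling of a profile onto a 1 kHz grid."""
    dt_new = 1.0 / rate
    t_old = p.times
    t_new = np.arange(p.t0, t_old[-1] + 1e-12, dt_new)
    return Trace(values=np.interp(t_new, t_old, p.values),
                 dt=dt_new, t0=p.t0, units=p.units)


def onset_time(roi_profile: Trace, T_onset: Template,
               threshold: float = DETECTION_THRESHOLD
               ) -> tuple[float | None, DetectionResult | None]:
    """Estimate the response onset by sliding a short template along a profile.

    The profile is resampled to 1 kHz by linear interpolation; at every lag
    (1 ms grid) the template is scaled and offset for an optimal match and
    the criterion computed. The onset is the lag with the maximal criterion,
    provided that criterion exceeds the threshold (ties break to the
    earliest lag). Returns ``(None, None)`` when no lag qualifies.
    """
    if roi_profile.duration <= T_onset.length:
        raise ValueError("profile must be longer than the onset template")
    p = resample_1khz(roi_profile)
    # template resampled onto the same 1 ms grid
    n_t = int(round(T_onset.length * ONSET_RESAMPLE_HZ))
    t_old = np.arange(T_onset.values.size) * T_onset.dt
    t_new = np.arange(n_t) / ONSET_RESAMPLE_HZ
    templ = np.interp(t_new, t_old, T_onset.values)

    best: DetectionResult | None = None
    n = len(p)
    for lag in range(0, n - n_t + 1):
        seg = p.values[lag:lag + n_t]
        try:
            scale, offset, sse = _fit_scale_offset(seg, templ)
        except ValueError:
            continue
        se = np.sqrt(sse / (n_t - 1))
        if se > 0:
            crit = scale / se
        else:
            crit = np.sign(scale) * np.inf if scale != 0 else 0.0
        crit = float(np.clip(crit, -CRITERION_CAP, CRITERION_CAP))
        if crit > threshold and (best is None or crit > best.criterion):
            pos = p.t0 + lag * p.dt
            best = DetectionResult(best_scale=scale, best_offset=offset,
                                   criterion=crit, position=pos,
                                   is_response=True, onset=pos)
    if best is None:
        return None, None
    return best.onset, best
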