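"""Photon-noise-limited two-channel scan-image renderer.

Expected counts per pixel are ``background_offset + photon_budget * F_norm``
where ``F_norm`` is the fluorescence forward model normalized to its
resting level; pixel values are Poisson-distributed (no read noise). The
first ``n_dark_lines`` rows of a line-scan are rendered with the laser off
(background only), mirroring the laser-off background estimation used by
the analysis. A volume/tracer channel is rendered with constant,
calcium-independent brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glica.imaging_analysis import LineScan
from glica.trace import Trace


@dataclass(frozen=True)
class ImagingGeometry:
    """Scan timing, sampling and photon statistics.

    Line rate must fall in the 100-300 Hz acquisition range; frame series
    default to 30 Hz.
    """

    line_period: float = 1.0 / 200.0  # s
    frame_rate: float = 30.0  # Hz
    pixel_size: float = 0.1  # um
    n_pixels: int = 64
    photon_budget: float = 50.0  # expected photons/pixel at baseline
    background_offset: float = 10.0  # counts
    n_dark_lines: int = 20

    def __post_init__(self) -> None:
        rate = 1.0 / self.line_period
        if not (100.0 <= rate <= 300.0):
            raise ValueError(f"line rate {rate:.0f} Hz outside 100-300 Hz")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be > 0")
        if self.n_dark_lines < 0:
            raise ValueError("n_dark_lines must be >= 0")


def _sample_profile(tr: Trace, times: np.ndarray) -> np.ndarray:
    return np.interp(times, tr.times, tr.values)


def render_linescan(F_profiles: dict[int, Trace], geom: ImagingGeometry,
                    n_lines: int, f_rest: float,
                    seed: int | np.random.Generator = 0,
                    noiseless: bool = False,
                    tracer_brightness: float | None = None
                    ) -> dict[str, LineScan]:
    """Render green (calcium) and red (tracer) line-scan channels.

    Parameters
    ----------
    F_profiles : dict
        Map from column index to the fluorescence trace imaged there;
        columns without a profile sit at the resting fluorescence.
    geom : ImagingGeometry
    n_lines : int
        Total rows including the initial dark lines.
    f_rest : float
        Resting fluorescence of the forward model (normalization anchor:
        a pixel at rest receives ``photon_budget`` expected photons).
    seed : int or Generator
    noiseless : bool
        Disable Poisson noise; pixels equal expected counts exactly.
    tracer_brightness : float, optional
        Expected photons/pixel of the red channel (default: photon budget).

    Returns
    -------
    dict with keys ``"green"`` and ``"red"``; dark rows are recorded in
    each LineScan's ``dark_line_rows``.
    """
    if f_rest <= 0:
        raise ValueError("f_rest must be > 0")
    for col in F_profiles:
        if not (0 <= col < geom.n_pixels):
            raise ValueError(f"column {col} outside scan width")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_active = n_lines - geom.n_dark_lines
    if n_active <= 0:
        raise ValueError("n_lines must exceed n_dark_lines")
    t_lines = np.arange(n_active) * geom.line_period

    expected_g = np.full((n_lines, geom.n_pixels),
                         geom.background_offset, dtype=float)
    expected_g[geom.n_dark_lines:, :] += geom.photon_budget
    for col, tr in F_profiles.items():
        f_norm = _sample_profile(tr, t_lines) / f_rest
        expected_g[geom.n_dark_lines:, col] = (
            geom.background_offset + geom.photon_budget * f_norm)

    bright_r = geom.photon_budget if tracer_brightness is None \
        else tracer_brightness
    expected_r = np.full((n_lines, geom.n_pixels),
                         geom.background_offset, dtype=float)
    expected_r[geom.n_dark_lines:, :] += bright_r

    dark = tuple(range(geom.n_dark_lines))
    out = {}
    for name, expected in (("green", expected_g), ("red", expected_r)):
        pix = expected if noiseless else rng.poisson(expected).astype(float)
        out[name] = LineScan(pixels=pix, line_period=geom.line_period,
                             pixel_size=geom.pixel_size, dark_line_rows=dark)
    return out


def render_frameseries(F: Trace, geom: ImagingGeometry,
                       n_frames: int, f_rest: float,
                       shape: tuple[int, int] = (32, 32),
                       roi: np.ndarray | None = None,
                       seed: int | np.random.Generator = 0,
                       noiseless: bool = False
                       ) -> dict[str, np.ndarray]:
    """Render a two-channel frame series (frame x y x x) at ``frame_rate``.

    The ROI pixels follow the fluorescence trace; everything else stays at
    the resting level. The red channel is constant.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ny, nx = shape
    if roi is None:
        roi = np.zeros(shape, bool)
        roi[ny // 3: 2 * ny // 3, nx // 3: 2 * nx // 3] = True
    t_frames = np.arange(n_frames) / geom.frame_rate
    f_norm = _sample_profile(F, t_frames) / f_rest

    expected_g = np.full((n_frames, ny, nx),
                         geom.background_offset + geom.photon_budget, float)
    expected_g[:, roi] = (geom.background_offset
                          + geom.photon_budget * f_norm[:, None])
    expected_r = np.full((n_frames, ny, nx),
                         geom.background_offset + geom.photon_budget, float)
    out = {}
    for name, expected in (("green", expected_g), ("red", expected_r)):
        out[name] = expected if noiseless \
            else rng.poisson(expected).astype(float)
    return out
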