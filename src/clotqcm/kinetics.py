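"""Clot-formation kinetics from baseline-referenced QCM shift curves.

The starred time courses dF*(t) and dG*(t) (shifts re-referenced to the
sample-loading snapshot) rise sigmoidally as fibrin couples to the sensor.
Four parameters summarise each channel:

* max_shift — plateau amplitude dF*_max or dG*_max (Hz);
* R_qcm     — clotting time: first time the curve reaches 10 % of
              max_shift, by linear interpolation between samples (s);
* MRCF      — maximum rate of clot formation: peak of the smoothed first
              derivative (Hz/s);
* TMRCF     — time at which that peak rate occurs (s).

The derivative is a Savitzky-Golay local-cubic estimate (default window
11 samples) with a central-difference fallback for short series.  Noisy
traces warrant a wider window and pre-smoothing before thresholding; see
`extract_kinetics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import NoResponseError
from .spectra import ShiftSeries

__all__ = [
    "ShiftSeries",
    "KineticParams",
    "baseline_reference",
    "max_response",
    "clotting_time",
    "rate_parameters",
    "extract_kinetics",
]

#: fraction of the maximum starred response defining the clotting time
CLOT_THRESHOLD_FRACTION = 0.10


@dataclass(frozen=True)
class KineticParams:
    """Kinetic summary of one starred channel."""

    channel: str
    max_shift: float
    R_qcm: float
    MRCF: float
    TMRCF: float

    def __post_init__(self):
        if self.max_shift < 0:
            raise ValueError("max_shift must be non-negative")
        if self.MRCF < 0:
            raise ValueError("MRCF must be non-negative")


def baseline_reference(dF, dG, t, z_index: int = 0) -> ShiftSeries:
    """Build a ShiftSeries: subtract the z-snapshot to form starred channels.

    The z-snapshot (default: first sample) is the measurement taken just
    after plasma deposition, before clot onset; it carries the viscous
    liquid loading that the starred channels remove.
    """
    return ShiftSeries(t=t, dF=dF, dG=dG, z_index=z_index)


def _smoothed(series: ShiftSeries, channel: str, smooth_window: int | None) -> np.ndarray:
    """Starred channel past the z-snapshot, optionally denoised before
    thresholding.

    The full trace is filtered (local cubic, Savitzky-Golay) and then
    re-referenced to its own smoothed value at the z-snapshot: subtracting
    a single noisy z-sample would imprint that sample's noise on the whole
    starred series as an offset no later smoothing can remove.
    """
    y = series.channel(channel)
    if smooth_window is None or y.size < 5:
        return y[series.z_index :]
    window = min(smooth_window, y.size)
    if window % 2 == 0:
        window -= 1
    if window < 5:
        return y[series.z_index :]
    ys = savgol_filter(y, window_length=window, polyorder=3)
    return ys[series.z_index :] - ys[series.z_index]


def max_response(series: ShiftSeries, channel: str = "f", smooth_window: int | None = None) -> float:
    """Maximum starred response over t >= t[z_index].

    ``smooth_window`` (samples) optionally denoises the trace first, so
    the plateau estimate is not inflated by the extreme noise excursion.
    Raises NoResponseError when the channel never rises above zero.
    """
    peak = float(np.max(_smoothed(series, channel, smooth_window)))
    if peak <= 0:
        raise NoResponseError(f"channel {channel!r} shows no response above the loading baseline")
    return peak


def clotting_time(series: ShiftSeries, channel: str = "f", smooth_window: int | None = None) -> float:
    """R-QCM: first time the starred channel reaches 10 % of its maximum.

    The crossing is located by linear interpolation between the bracketing
    samples, so the result is not quantised to the sampling grid.  On
    noisy traces ``smooth_window`` denoises before thresholding; otherwise
    noise excursions trigger systematically early crossings.
    """
    peak = max_response(series, channel, smooth_window)
    thr = CLOT_THRESHOLD_FRACTION * peak
    t = series.t[series.z_index :]
    y = _smoothed(series, channel, smooth_window)
    idx = np.nonzero(y >= thr)[0]
    if idx.size == 0:
        raise NoResponseError("threshold never crossed")
    i = int(idx[0])
    if i == 0 or y[i] == thr:
        return float(t[i])
    # linear interpolation between (i-1, i)
    frac = (thr - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def rate_parameters(
    series: ShiftSeries, channel: str = "f", smooth_window: int = 11
) -> tuple[float, float]:
    """(MRCF, TMRCF): peak smoothed first derivative and its time.

    Uses a local-cubic Savitzky-Golay derivative over ``smooth_window``
    samples (must fit in the series); series shorter than 5 samples fall
    back to central differences.  Ties in the maximum break to the
    earliest time.  Assumes near-uniform sampling (the filter uses the
    median time step).
    """
    t = series.t[series.z_index :]
    y = series.channel(channel)[series.z_index :]
    n = t.size
    if n < 2:
        raise ValueError("need at least 2 samples for a derivative")
    dt = float(np.median(np.diff(t)))
    window = smooth_window if smooth_window % 2 == 1 else smooth_window - 1
    if n < 5 or window < 5:
        deriv = np.gradient(y, t)
    elif n < window:
        raise ValueError(f"series has {n} samples, shorter than window {window}")
    else:
        # local cubic: an even-order fit's derivative carries a bias from
        # the curve's own cubic term that grows as (k*window)^2
        deriv = savgol_filter(y, window_length=window, polyorder=3, deriv=1, delta=dt)
    # earliest-maximum tie-break, tolerant of float noise in flat regions
    mrcf = float(np.max(deriv))
    tol = 1e-12 * max(1.0, abs(mrcf))
    i = int(np.nonzero(deriv >= mrcf - tol)[0][0])
    return max(mrcf, 0.0), float(t[i])


def extract_kinetics(
    series: ShiftSeries, channel: str = "f", smooth_window: int = 11, presmooth: bool = False
) -> KineticParams:
    """All four kinetic parameters for one channel.

    ``smooth_window`` sizes the derivative filter; with ``presmooth`` the
    same window also denoises the trace for max_shift and R_qcm (sensible
    when the noise is a visible fraction of the response).
    """
    win = smooth_window if presmooth else None
    peak = max_response(series, channel, win)
    r = clotting_time(series, channel, win)
    mrcf, tmrcf = rate_parameters(series, channel, smooth_window)
    name = "frequency" if channel in ("f", "dF", "frequency") else "bandwidth"
    return KineticParams(channel=name, max_shift=peak, R_qcm=r, MRCF=mrcf, TMRCF=tmrcf)
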