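"""Effective elasticity, effective mass density and rigidity factor.

The viscoelastic model converts the in-air-referenced shift curves into a
time-resolved description of the fibrin layer coupled to the sensor:

    c(t)    = dG_z / dG(t)                 plasma viscosity correction
    mu_t(t) = a * (dG(t)**2 - c**2 * dG_z**2)   effective elasticity
    M_t(t)  = b * (dF(t) - c * dF_z)            effective mass density
    RF(t)   = mu_t / M_t                        rigidity factor

with scaling constants a (Hz^-2) and b (Hz^-1).  dF_z and dG_z are the
shifts at the z-snapshot, just after plasma deposition: they carry the
purely viscous liquid loading, so mu_t and M_t are exactly zero there and
RF is a 0/0 that is flagged undefined rather than evaluated.  For a given
clot RF(t) is roughly constant in time, making its plateau mean a
single-number descriptor of fibrin rigidity.

c is evaluated per time point; it equals 1 at the z-snapshot and falls
toward 0 as the clot broadens the resonance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import ShiftSeries

__all__ = ["ViscoConstants", "ViscoSeries", "rigidity_series", "rigidity_summary"]


@dataclass(frozen=True)
class ViscoConstants:
    """Scaling normalisation factors of the viscoelastic model.

    a : Hz^-2, scales effective elasticity (default 2.5e-7)
    b : Hz^-1, scales effective mass density (default 1e-3)
    """

    a: float = 2.5e-7
    b: float = 1e-3

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("scaling constants a, b must be positive")


@dataclass
class ViscoSeries:
    """Time-resolved model outputs; RF is NaN where flagged undefined."""

    t: np.ndarray
    c: np.ndarray
    mu_t: np.ndarray
    M_t: np.ndarray
    RF: np.ndarray
    defined: np.ndarray  # boolean: RF evaluable (|M_t| above the guard)


def rigidity_series(
    series: ShiftSeries, constants: ViscoConstants | None = None, rf_floor: float = 1.0
) -> ViscoSeries:
    """Evaluate the model on every time point of a ShiftSeries.

    Parameters
    ----------
    series
        Shift curves with a valid z-snapshot (dG_z > 0, down-shift-positive
        dF convention).
    constants
        Scaling factors a, b; defaults as documented on ViscoConstants.
    rf_floor
        Net frequency shift (Hz) below which RF is flagged undefined:
        points with |M_t| <= b * rf_floor are NaN in ``RF``.  Guards the
        0/0 at clot onset.

    Raises
    ------
    ValueError
        If dG_z <= 0 or dG(t) <= 0 anywhere (a broadening that vanishes
        has no viscous interpretation).
    """
    k = constants or ViscoConstants()
    if series.dG_z <= 0:
        raise ValueError("dG_z must be positive (liquid loading broadens the peak)")
    if np.any(series.dG <= 0):
        raise ValueError("dG(t) must be positive at every time point")

    c = series.dG_z / series.dG
    mu = k.a * (series.dG**2 - c**2 * series.dG_z**2)
    M = k.b * (series.dF - c * series.dF_z)
    defined = np.abs(M) > k.b * rf_floor
    rf = np.full_like(mu, np.nan)
    np.divide(mu, M, out=rf, where=defined)
    return ViscoSeries(t=series.t.copy(), c=c, mu_t=mu, M_t=M, RF=rf, defined=defined)


def rigidity_summary(
    vs: ViscoSeries, window: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """(mu_t, M_t, RF) scalars over a plateau window.

    mu_t and M_t are means over all window points; RF is the mean of the
    defined RF(t) points.  ``window`` is a (t_start, t_stop) range in
    seconds; by default the last 20 % of the trace, where the clot has
    formed and the trajectory has plateaued.

    Raises ValueError if the window holds fewer than 3 defined RF points.
    """
    if window is None:
        t0 = vs.t[0] + 0.8 * (vs.t[-1] - vs.t[0])
        window = (t0, vs.t[-1])
    lo, hi = window
    in_win = (vs.t >= lo) & (vs.t <= hi)
    if not np.any(in_win):
        raise ValueError("summary window contains no samples")
    ok = in_win & vs.defined
    if np.count_nonzero(ok) < 3:
        raise ValueError("summary window contains fewer than 3 defined RF points")
    return (
        float(np.mean(vs.mu_t[in_win])),
        float(np.mean(vs.M_t[in_win])),
        float(np.mean(vs.RF[ok])),
    )
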