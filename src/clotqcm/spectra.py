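"""Resonance-peak extraction from QCM conductance spectra.

A shear-mode quartz resonator measured with an impedance analyser yields,
per sweep, a conductance-versus-frequency curve with a single peak near the
series resonance.  The peak is modelled as a four-parameter Lorentzian

    G(x) = baseline + amplitude * gamma**2 / ((x - f)**2 + gamma**2)

whose centre ``f`` is the resonant frequency and whose half width at half
maximum ``gamma`` is the bandwidth.  An unloaded sensor sits near 5 MHz with
gamma of a few tens of Hz; liquid loading broadens gamma to the kHz range
and pulls f down by hundreds of Hz.

`fit_resonance` fits one sweep; `track_resonance` chains fits over a time
series and converts the trajectory into in-air-referenced shift curves
(down-shift-positive Delta-f, broadening-positive Delta-Gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, FlatSpectrumError

__all__ = [
    "ConductanceSpectrum",
    "ResonanceState",
    "AirReference",
    "lorentzian",
    "fit_resonance",
    "track_resonance",
]


def lorentzian(x: np.ndarray, f: float, gamma: float, amplitude: float, baseline: float) -> np.ndarray:
    """Four-parameter Lorentzian conductance model."""
    return baseline + amplitude * gamma**2 / ((x - f) ** 2 + gamma**2)


@dataclass(frozen=True)
class ConductanceSpectrum:
    """One conductance sweep around resonance at a given timestamp.

    Parameters
    ----------
    timestamp
        Seconds since activation.
    frequencies
        Strictly increasing sweep frequencies, Hz; at least 8 points.
    conductance
        Non-negative conductance values (arbitrary units), same length.
    """

    timestamp: float
    frequencies: np.ndarray
    conductance: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        cond = np.asarray(self.conductance, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "conductance", cond)
        if freqs.ndim != 1 or freqs.size < 8:
            raise ValueError("spectrum needs at least 8 frequency points")
        if cond.shape != freqs.shape:
            raise ValueError("frequencies and conductance must have the same length")
        if not np.all(np.diff(freqs) > 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass(frozen=True)
class ResonanceState:
    """Fitted Lorentzian parameters of one sweep."""

    f: float
    gamma: float
    amplitude: float
    baseline: float
    fit_rss: float = 0.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class AirReference:
    """Unloaded-sensor resonance: f_air near 5 MHz, gamma_air tens of Hz."""

    f_air: float
    gamma_air: float

    def __post_init__(self):
        if self.gamma_air <= 0:
            raise ValueError("gamma_air must be positive")


@dataclass
class ShiftSeries:
    """In-air-referenced shift time courses with the loading snapshot.

    ``dF`` is the down-shift magnitude f_air - f(t) (mass loading gives
    positive values); ``dG`` is Gamma(t) - gamma_air.  The z-snapshot at
    ``z_index`` is the sample taken just after liquid deposition, before
    clot onset; the starred channels subtract it, so dF_star and dG_star
    are zero there and grow as the clot forms.
    """

    t: np.ndarray
    dF: np.ndarray
    dG: np.ndarray
    z_index: int = 0
    fit_rss: np.ndarray | None = None

    dF_z: float = field(init=False)
    dG_z: float = field(init=False)
    dF_star: np.ndarray = field(init=False)
    dG_star: np.ndarray = field(init=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.dF = np.asarray(self.dF, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        if not (self.t.shape == self.dF.shape == self.dG.shape):
            raise ValueError("t, dF, dG must have the same length")
        if self.t.size == 0:
            raise ValueError("empty series")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not 0 <= self.z_index < self.t.size:
            raise IndexError(f"z_index {self.z_index} out of range for {self.t.size} samples")
        self.dF_z = float(self.dF[self.z_index])
        self.dG_z = float(self.dG[self.z_index])
        self.dF_star = self.dF - self.dF_z
        self.dG_star = self.dG - self.dG_z

    def channel(self, name: str) -> np.ndarray:
        """Starred channel by name: 'f' -> dF_star, 'gamma' -> dG_star."""
        if name in ("f", "dF", "frequency"):
            return self.dF_star
        if name in ("gamma", "dG", "bandwidth"):
            return self.dG_star
        raise KeyError(f"unknown channel {name!r}")


def _initial_guess(freqs: np.ndarray, cond: np.ndarray) -> tuple[float, float, float, float]:
    """Data-driven starting point: peak position, half-max crossing width,
    peak-above-median amplitude, median baseline."""
    n = freqs.size
    # light smoothing so single-sample noise spikes do not set f0;
    # edge-padded so the taper cannot fake an interior maximum
    win = max(3, min(7, n // 4) | 1)
    kernel = np.ones(win) / win
    smooth = np.convolve(np.pad(cond, win // 2, mode="edge"), kernel, mode="valid")
    ipk = int(np.argmax(smooth))
    baseline0 = float(np.median(cond))
    amp0 = float(cond[ipk] - baseline0)
    if amp0 <= 0:
        raise FlatSpectrumError("no conductance peak above the median baseline")
    if ipk == 0 or ipk == n - 1:
        raise FlatSpectrumError("conductance maximum sits on the sweep edge, not an interior peak")
    f0 = float(freqs[ipk])
    half = baseline0 + amp0 / 2.0
    above = cond >= half
    # nearest half-max crossings either side of the peak
    left = ipk
    while left > 0 and above[left - 1]:
        left -= 1
    right = ipk
    while right < n - 1 and above[right + 1]:
        right += 1
    gamma0 = float(freqs[right] - freqs[left]) / 2.0
    if gamma0 <= 0:
        gamma0 = float(freqs[1] - freqs[0])
    return f0, gamma0, amp0, baseline0


def fit_resonance(
    spectrum: ConductanceSpectrum,
    initial_guess: ResonanceState | None = None,
    max_nfev: int = 200,
) -> ResonanceState:
    """Least-squares Lorentzian fit of one conductance sweep.

    Parameters are bounded (f inside the sweep, gamma positive) and the fit
    uses a tight relative tolerance so a noiseless Lorentzian is recovered
    to solver precision regardless of the starting point.

    Raises
    ------
    FlatSpectrumError
        If the sweep has no interior maximum to fit.
    FitError
        If the bounded solver fails to converge.
    """
    freqs = spectrum.frequencies
    cond = spectrum.conductance
    span = freqs[-1] - freqs[0]

    if np.ptp(cond) == 0:
        raise FlatSpectrumError("constant conductance sweep")

    if initial_guess is not None:
        p0 = (initial_guess.f, initial_guess.gamma, initial_guess.amplitude, initial_guess.baseline)
        _initial_guess(freqs, cond)  # still validates peak structure
    else:
        p0 = _initial_guess(freqs, cond)

    # offset frequencies for conditioning: f ~ 5e6 vs gamma ~ 1e1..1e3
    fref = freqs[0]
    x = freqs - fref
    p0 = (min(max(p0[0] - fref, 0.0), span), max(p0[1], 1e-9), max(p0[2], 1e-12), p0[3])

    def residual(p):
        return lorentzian(x, p[0], p[1], p[2], p[3]) - cond

    lo = [0.0, 1e-12, 1e-15, -np.inf]
    hi = [span, 10.0 * span, np.inf, np.inf]
    sol = least_squares(
        residual, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev
    )
    if not sol.success:
        raise FitError(
            f"resonance fit failed: {sol.message}",
            details={"status": sol.status, "nfev": sol.nfev, "cost": float(sol.cost)},
        )
    f, gamma, amp, base = sol.x
    return ResonanceState(
        f=float(f + fref),
        gamma=float(gamma),
        amplitude=float(amp),
        baseline=float(base),
        fit_rss=float(2.0 * sol.cost),
    )


def track_resonance(spectra: Sequence[ConductanceSpectrum], air: AirReference) -> ShiftSeries:
    """Fit each sweep in a time series and build in-air-referenced shifts.

    Delta-f(t) = f_air - f(t)  (down-shift positive: mass loading > 0)
    Delta-Gamma(t) = Gamma(t) - gamma_air

    Any failed fit aborts with the offending timestamp in the message.
    """
    if len(spectra) == 0:
        raise ValueError("no spectra to track")
    ts = np.array([s.timestamp for s in spectra], dtype=float)
    if not np.all(np.diff(ts) > 0):
        raise ValueError("spectrum timestamps must be strictly increasing")
    f = np.empty(len(spectra))
    g = np.empty(len(spectra))
    rss = np.empty(len(spectra))
    for i, spec in enumerate(spectra):
        try:
            state = fit_resonance(spec)
        except (FlatSpectrumError, FitError) as err:
            raise type(err)(f"fit failed at t={spec.timestamp:g} s: {err}") from err
        f[i], g[i], rss[i] = state.f, state.gamma, state.fit_rss
    return ShiftSeries(t=ts, dF=air.f_air - f, dG=g - air.gamma_air, fit_rss=rss)
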