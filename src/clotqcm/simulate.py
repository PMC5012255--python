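"""Synthetic inputs with known ground truth.

Three generators mirror the three kinds of raw data the analysis consumes:

1. sigmoidal clot-formation shift curves (logistic by default, so every
   kinetic parameter has a closed form; Gompertz available for asymmetric
   traces) sitting on a liquid-loading plateau, with additive Gaussian
   noise;
2. conductance-spectrum time series realising those curves as Lorentzian
   peaks that the resonance tracker can round-trip;
3. crossed-rectangular-grating fibre-network images with exact porosity,
   density and diameter.

All generators are seed-deterministic: the same seed reproduces the same
arrays, and changing only the seed changes only the noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fibres import FibreImage, FibreMetrics
from .kinetics import KineticParams
from .spectra import AirReference, ConductanceSpectrum, ShiftSeries, lorentzian

__all__ = [
    "ClotSimParams",
    "NetworkSimParams",
    "simulate_shift_series",
    "simulate_spectra",
    "simulate_network_image",
]


@dataclass(frozen=True)
class ClotSimParams:
    """Sigmoidal clot-curve parameters.

    dF_z, dG_z: liquid-loading plateau shifts (Hz); A_f, A_g: clot
    amplitudes (Hz); k: rate (1/s); t0: midpoint (s); duration, dt (s);
    noise_sd: additive Gaussian noise (Hz); shape: 'logistic' or
    'gompertz'.
    """

    dF_z: float = 700.0
    dG_z: float = 1000.0
    A_f: float = 2000.0
    A_g: float = 2000.0
    k: float = 0.02
    t0: float = 400.0
    duration: float = 1200.0
    dt: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    shape: str = "logistic"

    def __post_init__(self):
        if self.dG_z <= 0:
            raise ValueError("dG_z must be positive")
        if self.A_f < 0 or self.A_g < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.k <= 0 or self.dt <= 0:
            raise ValueError("k and dt must be positive")
        if self.duration <= self.t0:
            raise ValueError("duration must exceed the midpoint t0")
        if self.shape not in ("logistic", "gompertz"):
            raise ValueError(f"unknown curve shape {self.shape!r}")


@dataclass(frozen=True)
class NetworkSimParams:
    """Crossed-grating fibre-network image parameters.

    width_px: fibre width; period_px: fibre spacing; angle_deg: grating
    orientation; pixel_size_nm: physical calibration; image_size_px:
    square image side; noise_sd: additive Gaussian grey-level noise;
    blur_px: Gaussian blur sigma.
    """

    width_px: float = 3.0
    period_px: float = 10.0
    angle_deg: float = 0.0
    pixel_size_nm: float = 25.0
    image_size_px: int = 256
    noise_sd: float = 0.0
    blur_px: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.width_px < self.period_px:
            raise ValueError("require 1 <= width_px < period_px")
        if self.image_size_px < 64:
            raise ValueError("image_size_px must be >= 64")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")


def _sigmoid(t: np.ndarray, k: float, t0: float, shape: str) -> np.ndarray:
    if shape == "logistic":
        return 1.0 / (1.0 + np.exp(-k * (t - t0)))
    return np.exp(-np.exp(-k * (t - t0)))  # gompertz


def _truth_kinetics(channel: str, A: float, k: float, t0: float, shape: str) -> KineticParams:
    """Closed-form kinetic parameters of the noiseless sigmoid."""
    if shape == "logistic":
        r = t0 - math.log(9.0) / k  # crosses 0.1*A
        mrcf = A * k / 4.0
    else:
        r = t0 - math.log(math.log(10.0)) / k
        mrcf = A * k / math.e
    return KineticParams(channel=channel, max_shift=A, R_qcm=r, MRCF=mrcf, TMRCF=t0)


def simulate_shift_series(p: ClotSimParams) -> tuple[ShiftSeries, dict[str, KineticParams]]:
    """Generate a noisy sigmoidal ShiftSeries and its closed-form truth.

    dF(t) = dF_z + A_f * sigmoid(t) + noise, dG(t) analogous.  The returned
    truth dict has entries 'frequency' and 'bandwidth' holding the exact
    KineticParams (max = A, R at the 10 % crossing, MRCF and TMRCF from the
    sigmoid derivative).
    """
    rng = np.random.default_rng(p.seed)
    t = np.arange(0.0, p.duration + p.dt / 2, p.dt)
    s = _sigmoid(t, p.k, p.t0, p.shape)
    dF = p.dF_z + p.A_f * s + rng.normal(0.0, p.noise_sd, t.size)
    dG = p.dG_z + p.A_g * s + rng.normal(0.0, p.noise_sd, t.size)
    series = ShiftSeries(t=t, dF=dF, dG=dG, z_index=0)
    truth = {
        "frequency": _truth_kinetics("frequency", p.A_f, p.k, p.t0, p.shape),
        "bandwidth": _truth_kinetics("bandwidth", p.A_g, p.k, p.t0, p.shape),
    }
    return series, truth


def simulate_spectra(
    series: ShiftSeries,
    air: AirReference,
    sweep_span: float,
    n_points: int = 201,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    baseline: float = 0.0,
) -> list[ConductanceSpectrum]:
    """Render a ShiftSeries as Lorentzian conductance sweeps.

    Each time point becomes a sweep of ``n_points`` over ``sweep_span`` Hz
    centred on the trajectory, with peak at f = f_air - dF(t) and width
    gamma = gamma_air + dG(t).  The span must cover every peak with at
    least one linewidth of margin on both sides, so the fitter always sees
    the full half-maximum region.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8 (minimum fittable sweep)")
    rng = np.random.default_rng(seed)
    f_t = air.f_air - series.dF
    g_t = air.gamma_air + series.dG
    lo_needed = float(np.min(f_t - g_t))
    hi_needed = float(np.max(f_t + g_t))
    if hi_needed - lo_needed > sweep_span:
        raise ValueError(
            f"sweep_span {sweep_span:g} Hz too small: trajectory needs "
            f">= {hi_needed - lo_needed:g} Hz"
        )
    centre = 0.5 * (lo_needed + hi_needed)
    freqs = np.linspace(centre - sweep_span / 2, centre + sweep_span / 2, n_points)
    spectra = []
    for i, ts in enumerate(series.t):
        cond = lorentzian(freqs, f_t[i], g_t[i], amplitude, baseline)
        cond = cond + rng.normal(0.0, noise_sd, n_points)
        spectra.append(ConductanceSpectrum(timestamp=float(ts), frequencies=freqs, conductance=cond))
    return spectra


def simulate_network_image(p: NetworkSimParams) -> tuple[FibreImage, FibreMetrics]:
    """Crossed rectangular grating image and its exact metrics.

    Two orthogonal sets of bright bars (width w, period P) on a dark
    background, rotated by ``angle_deg``, optionally blurred and noised.
    Ground truth: F_Por = (1 - w/P)^2, F_Dens = 1/(P * pixel_size),
    F_Diam = w * pixel_size.
    """
    n = p.image_size_px
    yy, xx = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    th = np.deg2rad(p.angle_deg)
    u = xx * np.cos(th) + yy * np.sin(th)
    v = -xx * np.sin(th) + yy * np.cos(th)
    bars = (np.mod(u, p.period_px) < p.width_px) | (np.mod(v, p.period_px) < p.width_px)
    img = np.where(bars, 200.0, 50.0)
    if p.blur_px > 0:
        img = ndimage.gaussian_filter(img, sigma=p.blur_px)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        img = img + rng.normal(0.0, p.noise_sd, img.shape)
    w_over_p = p.width_px / p.period_px
    f_dens = 1.0 / p.period_px / p.pixel_size_nm * 1000.0  # cycles/um
    truth = FibreMetrics(
        F_Por=(1.0 - w_over_p) ** 2,
        F_Dens=f_dens,
        F_Diam=p.width_px * p.pixel_size_nm,
        peak_freq_px=1.0 / p.period_px,
    )
    return FibreImage(pixels=img, pixel_size=p.pixel_size_nm), truth
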