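import numpy as np
import pytest

from clotqcm import (
    AirReference,
    ConductanceSpectrum,
    ShiftSeries,
    lorentzian,
)


def make_spectrum(
    f=5_000_000.0,
    gamma=30.0,
    amplitude=1.0,
    baseline=0.0,
    half_span=300.0,
    step=1.0,
    noise_sd=0.0,
    seed=0,
    timestamp=0.0,
    centre=None,
):
    """Noiseless or seeded-noise Lorentzian sweep around the peak."""
    centre = f if centre is None else centre
    freqs = np.arange(centre - half_span, centre + half_span + step / 2, step)
    cond = lorentzian(freqs, f, gamma, amplitude, baseline)
    if noise_sd > 0:
        cond = cond + np.random.default_rng(seed).normal(0.0, noise_sd, freqs.size)
    return ConductanceSpectrum(timestamp=timestamp, frequencies=freqs, conductance=cond)


def logistic_series(A_f=2000.0, A_g=2000.0, k=0.02, t0=400.0, dF_z=700.0, dG_z=1000.0,
                    duration=1200.0, dt=1.0):
    """Noiseless logistic clot curve on a liquid-loading plateau."""
    t = np.arange(0.0, duration + dt / 2, dt)
    s = 1.0 / (1.0 + np.exp(-k * (t - t0)))
    return ShiftSeries(t=t, dF=dF_z + A_f * s, dG=dG_z + A_g * s, z_index=0)


@pytest.fixture
def air():
    return AirReference(f_air=5_000_000.0, gamma_air=30.0)
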