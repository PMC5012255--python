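"""Fibrin-network image metrics: filtering, binarization, porosity,
radial power spectrum, fibre density and the grating diameter identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clotqcm import (
    DegenerateThresholdError,
    FibreImage,
    FibreMetrics,
    NetworkSimParams,
    binarize_mean,
    fibre_density,
    fibre_metrics,
    porosity,
    radial_power_spectrum,
    simulate_network_image,
    structure_filter,
)


def grating(width=3, period=10, n=250, pixel_size=25.0):
    img, _ = simulate_network_image(
        NetworkSimParams(width_px=width, period_px=period, image_size_px=n,
                         pixel_size_nm=pixel_size)
    )
    return img


class TestStructureFilter:
    def test_constant_image_unchanged(self):
        img = FibreImage(np.full((64, 64), 7.0), 25.0)
        out = structure_filter(img)
        assert np.allclose(out.pixels, 7.0, atol=1e-10)

    def test_checkerboard_removed_constant_kept(self):
        """The single-pixel checkerboard lives at the Nyquist corner
        (wavelength sqrt(2) < 2 px) and dies at the 2 px cutoff."""
        n = 64
        yy, xx = np.indices((n, n))
        img = FibreImage(10.0 + ((-1.0) ** (xx + yy)), 25.0)
        out = structure_filter(img, min_size_px=2)
        assert np.allclose(out.pixels, 10.0, atol=1e-9)

    def test_long_wavelength_sinusoid_passes(self):
        n = 100
        x = np.arange(n)
        img = FibreImage(5.0 + np.sin(2 * np.pi * x / 10.0)[None, :] * np.ones((n, 1)), 25.0)
        out = structure_filter(img, min_size_px=2)
        assert np.allclose(out.pixels, img.pixels, atol=1e-6)

    def test_mean_preserved(self):
        rng = np.random.default_rng(3)
        img = FibreImage(rng.uniform(0, 255, (64, 64)), 25.0)
        out = structure_filter(img, min_size_px=3)
        assert out.pixels.mean() == pytest.approx(img.pixels.mean(), abs=1e-9)

    def test_cutoff_larger_than_image_raises(self):
        img = FibreImage(np.zeros((64, 64)), 25.0)
        with pytest.raises(ValueError):
            structure_filter(img, min_size_px=64)


class TestBinarize:
    def test_half_and_half(self):
        px = np.zeros((64, 64))
        px[:, 32:] = 1.0
        b = binarize_mean(FibreImage(px, 25.0))
        assert np.all(b[:, :32] == -1) and np.all(b[:, 32:] == 1)

    def test_codomain_is_plus_minus_one(self):
        rng = np.random.default_rng(0)
        b = binarize_mean(FibreImage(rng.uniform(0, 255, (40, 40)), 25.0))
        assert set(np.unique(b)) <= {-1, 1}

    def test_linear_ramp_splits_near_half(self):
        n = 256
        px = np.tile(np.linspace(0, 255, n), (n, 1))
        b = binarize_mean(FibreImage(px, 25.0))
        assert porosity(b) == pytest.approx(0.5, abs=1.0 / n)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateThresholdError):
            binarize_mean(FibreImage(np.full((32, 32), 3.0), 25.0))


class TestPorosity:
    def test_all_bright_is_zero(self):
        assert porosity(np.ones((32, 32), dtype=np.int8)) == 0.0

    def test_checkerboard_is_half(self):
        yy, xx = np.indices((32, 32))
        b = np.where((xx + yy) % 2 == 0, 1, -1)
        assert porosity(b) == 0.5

    def test_crossed_grating_closed_form(self):
        b = binarize_mean(grating(width=3, period=10, n=250))
        assert porosity(b) == pytest.approx(0.49, abs=0.01)

    def test_porosity_plus_bright_fraction_is_one(self):
        rng = np.random.default_rng(1)
        b = binarize_mean(FibreImage(rng.uniform(0, 1, (50, 50)), 25.0))
        bright = np.count_nonzero(b == 1) / b.size
        assert porosity(b) + bright == 1.0


class TestRadialSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        n = 64
        x = np.arange(n)
        img = np.sin(2 * np.pi * x / 8.0)[None, :] * np.ones((n, 1))
        spec = radial_power_spectrum(img)
        peak_bin = int(np.argmax(spec.power[1:])) + 1
        assert spec.freq[peak_bin] == pytest.approx(0.125, abs=1.0 / n)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(7)
        img = rng.normal(0, 1, (128, 128))
        spec = radial_power_spectrum(img, window="none")
        total_mean = np.sum(spec.power * spec.count) / np.sum(spec.count)
        ok = spec.count >= 30
        dev = np.abs(spec.power[ok] - total_mean)
        tol = 3.0 * total_mean / np.sqrt(spec.count[ok])
        assert np.mean(dev <= tol) > 0.95  # 3-sd band, allowing CLT tails

    def test_parseval_partition(self):
        rng = np.random.default_rng(11)
        img = rng.normal(0, 1, (64, 96))
        spec = radial_power_spectrum(img, window="none")
        power = np.abs(np.fft.fft2(img)) ** 2
        total_non_dc = power.sum() - power[0, 0]
        assert np.sum(spec.power * spec.count) == pytest.approx(total_non_dc, rel=1e-12)


class TestFibreDensity:
    def test_grating_fundamental(self):
        b = binarize_mean(grating(width=3, period=10, n=250))
        spec = radial_power_spectrum(b)
        f_dens, peak, flags = fibre_density(spec, pixel_size=25.0)
        assert peak == pytest.approx(0.1, abs=1.0 / 250)
        assert f_dens == pytest.approx(4.0, abs=4.0 / 25)  # one-bin slack
        assert "weak_peak" not in flags

    def test_pixel_size_scale_linearity(self):
        b = binarize_mean(grating(width=3, period=10, n=250))
        spec = radial_power_spectrum(b)
        d25, _, _ = fibre_density(spec, pixel_size=25.0)
        d50, _, _ = fibre_density(spec, pixel_size=50.0)
        assert d50 == pytest.approx(d25 / 2)

    def test_white_noise_flagged(self):
        rng = np.random.default_rng(5)
        img = rng.normal(0, 1, (128, 128))
        spec = radial_power_spectrum(np.sign(img))
        _, _, flags = fibre_density(spec, pixel_size=25.0)
        assert "weak_peak" in flags


class TestFibreMetrics:
    def test_grating_identity_recovers_width(self):
        m = fibre_metrics(grating(width=3, period=10, n=250, pixel_size=25.0))
        assert m.F_Diam == pytest.approx(75.0, abs=8.0)  # 3 px +/- edge effects
        assert m.F_Por == pytest.approx(0.49, abs=0.02)
        assert m.F_Dens == pytest.approx(4.0, abs=0.2)

    def test_stored_fields_satisfy_diameter_identity(self):
        m = fibre_metrics(grating())
        assert m.F_Diam == pytest.approx((1 - np.sqrt(m.F_Por)) / m.F_Dens * 1000, rel=1e-12)

    def test_table_style_identity(self):
        """The diameter identity applied to measured porosity/density pairs."""
        for f_por, f_dens, f_diam in [(0.518, 1.72, 163.0), (0.561, 2.12, 118.0)]:
            m = FibreMetrics(F_Por=f_por, F_Dens=f_dens,
                             F_Diam=(1 - np.sqrt(f_por)) / f_dens * 1000,
                             peak_freq_px=0.05)
            assert m.F_Diam == pytest.approx(f_diam, abs=0.5)

    @given(gain=st.floats(0.2, 5.0), offset=st.floats(-50.0, 50.0))
    @settings(max_examples=10, deadline=None)
    def test_invariant_to_affine_intensity_rescaling(self, gain, offset):
        img = grating(width=4, period=16, n=128)
        scaled = FibreImage(gain * img.pixels + offset, img.pixel_size)
        a = fibre_metrics(img)
        b = fibre_metrics(scaled)
        assert b.F_Por == pytest.approx(a.F_Por, abs=1e-12)
        assert b.F_Dens == pytest.approx(a.F_Dens, rel=1e-12)

    def test_density_decreases_with_period(self):
        dens = [fibre_metrics(grating(width=3, period=p, n=240)).F_Dens
                for p in (8, 12, 16, 24)]
        assert all(a > b for a, b in zip(dens, dens[1:]))

    def test_rotation_tolerance(self):
        """Radial averaging makes the metrics nearly orientation-free."""
        m0 = fibre_metrics(grating(width=3, period=10, n=256))
        img37, _ = simulate_network_image(
            NetworkSimParams(width_px=3, period_px=10, angle_deg=37.0, image_size_px=256)
        )
        m37 = fibre_metrics(img37)
        assert m37.F_Dens == pytest.approx(m0.F_Dens, rel=0.10)
        assert m37.F_Diam == pytest.approx(m0.F_Diam, rel=0.10)


def test_fibre_image_invariants():
    with pytest.raises(ValueError):
        FibreImage(np.zeros((16, 64)), 25.0)
    with pytest.raises(ValueError):
        FibreImage(np.zeros((64, 64)), -1.0)
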