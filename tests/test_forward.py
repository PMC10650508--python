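import numpy as np
import pytest

from pamnet.forward import (
    NoiseSpec,
    add_noise,
    complex_wavenumber,
    particle_velocity,
    point_source_pressure,
    simulate_rf,
)
from pamnet.geometry import MediumProperties, PointSource


WATER = MediumProperties()


def test_complex_wavenumber_values():
    k = complex_wavenumber(612e3, WATER)
    assert k.real == pytest.approx(2 * np.pi * 612e3 / 1500.0)  # 2563.54 rad/m
    assert k.real == pytest.approx(2563.54, abs=0.01)
    assert k.imag == pytest.approx(-4.32e-4)
    k1 = complex_wavenumber(1000e3, WATER)
    assert k1.real == pytest.approx(4188.79, abs=0.01)


def test_complex_wavenumber_lossless_limit():
    lossless = MediumProperties(attenuation=1e-30)
    k = complex_wavenumber(500e3, lossless)
    assert abs(k.imag) < 1e-20


def test_complex_wavenumber_rejects_nonpositive_frequency():
    with pytest.raises(ValueError):
        complex_wavenumber(0.0, WATER)


class TestPointSourcePressure:
    src = PointSource(position=(0.0, 0.0, 0.0), frequency=612e3)

    def test_inverse_distance_law(self):
        lossless = MediumProperties(attenuation=1e-30)
        k = complex_wavenumber(612e3, lossless)
        p1 = point_source_pressure(self.src, np.array([0, 0, 0.02]), k, lossless)
        p2 = point_source_pressure(self.src, np.array([0, 0, 0.04]), k, lossless)
        assert abs(p1) == pytest.approx(2 * abs(p2), rel=1e-12)

    def test_magnitude_hand_value(self):
        # |p| = (f/c) * rho*c / R at negligible attenuation, unit strength
        lossless = MediumProperties(attenuation=1e-30)
        k = complex_wavenumber(612e3, lossless)
        p = point_source_pressure(self.src, np.array([0, 0, 0.04]), k, lossless)
        expected = (612e3 / 1500.0) * 1000.0 * 1500.0 / 0.04
        assert abs(p) == pytest.approx(expected, rel=1e-12)
        assert abs(p) == pytest.approx(1.53e10, rel=1e-2)

    def test_attenuation_monotone(self):
        k = complex_wavenumber(612e3, WATER)
        rs = np.linspace(0.01, 0.1, 20)
        vals = [abs(point_source_pressure(self.src, np.array([0, 0, r]), k, WATER)) * r
                for r in rs]
        assert np.all(np.diff(vals) < 0)

    def test_singularity(self):
        k = complex_wavenumber(612e3, WATER)
        with pytest.raises(ZeroDivisionError):
            point_source_pressure(self.src, np.array([0.0, 0.0, 0.0]), k, WATER)


class TestParticleVelocity:
    src = PointSource(position=(0.0, 0.0, 0.0), frequency=612e3)

    def test_symbolic_formula(self):
        """Direct evaluation of the printed expression at R = 0.01 m."""
        k = complex_wavenumber(612e3, WATER)
        R = 0.01
        expected = (1j * k / (2 * np.pi)) * np.exp(-1j * k * R) / R * (1 - 1j * k * R)
        got = particle_velocity(self.src, np.array([0, 0, R]), k, WATER)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_strength(self):
        k = complex_wavenumber(612e3, WATER)
        pt = np.array([0, 0, 0.03])
        u1 = particle_velocity(self.src, pt, k, WATER)
        src3 = PointSource(position=(0, 0, 0), frequency=612e3, strength=3.0)
        assert particle_velocity(src3, pt, k, WATER) == pytest.approx(3 * u1, rel=1e-12)

    def test_velocity_pressure_ratio_strength_free(self):
        k = complex_wavenumber(612e3, WATER)
        pt = np.array([0.001, 0.002, 0.03])
        for s in (1.0, 7.5):
            src = PointSource(position=(0, 0, 0), frequency=612e3, strength=s)
            ratio = (particle_velocity(src, pt, k, WATER)
                     / point_source_pressure(src, pt, k, WATER))
            if s == 1.0:
                base = ratio
        assert ratio == pytest.approx(base, rel=1e-12)


class TestSimulateRF:
    def test_raw_length_is_5600(self, f612):
        medium, array, _, freq = f612
        src = [PointSource(position=(0, 0, 0.04), frequency=freq)]
        rf = simulate_rf(src, array, medium)
        assert rf.n_t == 5600
        assert rf.sampling_rate == 40e6

    def test_center_channel_symmetry(self, f612):
        medium, array, _, freq = f612
        src = [PointSource(position=(0, 0, 0.04), frequency=freq)]
        rf = simulate_rf(src, array, medium, duration=20e-6)
        quad = [rf.samples[:, 7, 7], rf.samples[:, 7, 8],
                rf.samples[:, 8, 7], rf.samples[:, 8, 8]]
        for q in quad[1:]:
            assert np.allclose(q, quad[0], rtol=1e-9, atol=1e-9 * np.abs(quad[0]).max())

    def test_rms_decays_with_lateral_distance(self, f612):
        medium, array, _, freq = f612
        src = [PointSource(position=(0, 0, 0.04), frequency=freq)]
        rf = simulate_rf(src, array, medium, duration=20e-6)
        rms = np.sqrt(np.mean(rf.samples**2, axis=0))
        center = rms[7:9, 7:9].mean()
        corner = rms[0, 0]
        assert corner < center

    def test_linearity_in_sources(self, f612):
        medium, array, _, freq = f612
        s1 = PointSource(position=(0.001, -0.002, 0.038), frequency=freq)
        s2 = PointSource(position=(-0.003, 0.002, 0.042), frequency=freq)
        both = simulate_rf([s1, s2], array, medium, duration=10e-6)
        a = simulate_rf([s1], array, medium, duration=10e-6)
        b = simulate_rf([s2], array, medium, duration=10e-6)
        scale = np.abs(both.samples).max()
        assert np.allclose(both.samples, a.samples + b.samples,
                           rtol=1e-12, atol=1e-12 * scale)

    def test_spectral_purity(self, f612):
        medium, array, _, freq = f612
        src = [PointSource(position=(0.002, 0.001, 0.04), frequency=freq)]
        rf = simulate_rf(src, array, medium, duration=50e-6)
        spec = np.abs(np.fft.rfft(rf.samples[:, 3, 11]))
        freqs = np.fft.rfftfreq(rf.n_t, 1 / rf.sampling_rate)
        assert abs(freqs[np.argmax(spec)] - freq) <= freqs[1]

    def test_subelement_convergence(self, f612):
        """At sufficient sub-element density, halving the spacing changes
        channel RMS by <0.5% (discretization convergence)."""
        from dataclasses import replace

        medium, array, _, freq = f612
        src = [PointSource(position=(0.004, 0.004, 0.036), frequency=freq)]
        coarse = replace(array, sub_points_per_wavelength=16)
        fine = replace(array, sub_points_per_wavelength=32)
        rf_a = simulate_rf(src, coarse, medium, duration=10e-6)
        rf_b = simulate_rf(src, fine, medium, duration=10e-6)
        rms_a = np.sqrt(np.mean(rf_a.samples**2, axis=0))
        rms_b = np.sqrt(np.mean(rf_b.samples**2, axis=0))
        assert np.max(np.abs(rms_a - rms_b) / rms_b) < 0.005

    def test_empty_source_list(self, f612):
        medium, array, _, _ = f612
        rf = simulate_rf([], array, medium, duration=1e-6)
        assert np.all(rf.samples == 0)

    def test_mixed_frequencies_rejected(self, f612):
        medium, array, _, freq = f612
        srcs = [PointSource(position=(0, 0, 0.04), frequency=freq),
                PointSource(position=(0, 0, 0.05), frequency=2 * freq)]
        with pytest.raises(NotImplementedError):
            simulate_rf(srcs, array, medium, duration=1e-6)


class TestAddNoise:
    def _rf(self, f612, duration=140e-6):
        medium, array, _, freq = f612
        src = [PointSource(position=(0.001, 0, 0.04), frequency=freq)]
        return simulate_rf(src, array, medium, duration=duration)

    def test_zero_spread_realizes_minus4(self, f612):
        rf = self._rf(f612)
        _, info = add_noise(rf, NoiseSpec(relative_std=0.0, seed=1))
        dev = info["realized_snr_db"] - (-4.0)
        # finite-record noise-power estimate: std = (10/ln10) sqrt(2/N) dB
        sigma = 10 / np.log(10) * np.sqrt(2 / rf.n_t)
        assert abs(dev.mean()) < 4 * sigma / np.sqrt(dev.size)
        assert np.abs(dev).max() < 5 * sigma  # max over 256 channels

    def test_seed_determinism(self, f612):
        rf = self._rf(f612, duration=20e-6)
        a, _ = add_noise(rf, NoiseSpec(seed=3))
        b, _ = add_noise(rf, NoiseSpec(seed=3))
        assert np.array_equal(a.samples, b.samples)

    def test_zero_signal_channel_rejected(self, f612):
        medium, array, _, _ = f612
        from pamnet.forward import RFRecord

        rf = RFRecord(samples=np.zeros((100, 16, 16)), sampling_rate=40e6)
        with pytest.raises(ValueError):
            add_noise(rf, NoiseSpec(seed=0))
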