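"""Ray-acoustics RF synthesis and calibrated noise injection.

A continuous-wave point source of strength u*ds produces, at distance R in a
lossy medium with complex wavenumber k = w/c - j*alpha, the complex pressure

    p = j*k*rho*c/(2*pi) * exp(-j*k*R)/R * (u*ds)

(the single-source form of the Rayleigh-Sommerfeld integral).  The receiver
array samples the real part of p * exp(j*w*t) at 40 MHz; each element face is
averaged over its point-like sub-elements.  Channel noise is white Gaussian,
calibrated per element to a target SNR drawn from a normal distribution in dB.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import MediumProperties, PointSource, ReceiverArray


class SingularFieldError(ZeroDivisionError):
    """Field requested at the source position (R = 0)."""


@dataclass(frozen=True)
class RFRecord:
    """Real-valued channel data, shape (n_t, n_y, n_x), with sampling metadata.

    ``start_time`` is the time of sample 0 relative to the (eternal, steady
    state) source phase reference; trimming shifts it.  Stage flags track the
    conditioning pipeline.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    stages: tuple[str, ...] = ("raw",)

    def __post_init__(self) -> None:
        if self.samples.ndim != 3:
            raise ValueError("RF samples must have shape (n_t, n_y, n_x)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    @property
    def n_t(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_t / self.sampling_rate

    def with_stage(self, samples: np.ndarray, stage: str, *, start_time: float | None = None) -> "RFRecord":
        return replace(
            self,
            samples=samples,
            stages=self.stages + (stage,),
            start_time=self.start_time if start_time is None else start_time,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Per-element SNR calibration for additive white Gaussian noise.

    Each element draws a target SNR from Normal(mean_snr_db,
    relative_std * |mean_snr_db|) dB; noise power is then set from the
    element's own signal power.
    """

    mean_snr_db: float = -4.0
    relative_std: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_std < 0:
            raise ValueError("relative_std must be >= 0")

    @property
    def snr_std_db(self) -> float:
        return self.relative_std * abs(self.mean_snr_db)


def complex_wavenumber(frequency: float, medium: MediumProperties) -> complex:
    """k = 2*pi*f/c - j*alpha (rad/m); imaginary part encodes absorption."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    return 2.0 * np.pi * frequency / medium.sound_speed - 1j * medium.attenuation


def _distances(source: PointSource, field_points: np.ndarray) -> np.ndarray:
    r = np.linalg.norm(np.asarray(field_points, dtype=float) - np.asarray(source.position), axis=-1)
    if np.any(r == 0):
        raise SingularFieldError("field point coincides with the source")
    return r


def point_source_pressure(
    source: PointSource,
    field_points: np.ndarray,
    k: complex,
    medium: MediumProperties,
) -> np.ndarray:
    """Complex CW pressure phasor at one or more field points (broadcasts)."""
    r = _distances(source, field_points)
    amp = 1j * k * medium.density * medium.sound_speed / (2.0 * np.pi)
    phasor = source.strength * np.exp(1j * source.phase)
    return amp * np.exp(-1j * k * r) / r * phasor


def particle_velocity(
    source: PointSource,
    field_points: np.ndarray,
    k: complex,
    medium: MediumProperties,
) -> np.ndarray:
    """Longitudinal particle-velocity phasor, u = jk/(2pi) e^{-jkR}/R uds (1 - jkR)."""
    r = _distances(source, field_points)
    phasor = source.strength * np.exp(1j * source.phase)
    return (1j * k / (2.0 * np.pi)) * np.exp(-1j * k * r) / r * phasor * (1.0 - 1j * k * r)


def channel_phasors(
    sources: list[PointSource],
    array: ReceiverArray,
    medium: MediumProperties,
) -> np.ndarray:
    """(n_y, n_x) complex pressure phasor per element (sub-element averaged)."""
    if not sources:
        return np.zeros((array.n_y, array.n_x), dtype=complex)
    freq = sources[0].frequency
    wavelength = medium.sound_speed / freq
    pts = array.sub_element_positions(wavelength)  # (ny, nx, s, 3)
    k = complex_wavenumber(freq, medium)
    total = np.zeros(pts.shape[:-1], dtype=complex)
    for src in sources:
        total += point_source_pressure(src, pts, k, medium)
    return total.mean(axis=-1)


def simulate_rf(
    sources: list[PointSource],
    array: ReceiverArray,
    medium: MediumProperties,
    duration: float = 140e-6,
    sampling_rate: float = 40e6,
) -> RFRecord:
    """Synthesize steady-state CW channel data for equal-frequency sources.

    Channel (a, b) at t_n = n / f_s holds Re{ P_ab * exp(j*w*t_n) } where
    P_ab sums the sub-element-averaged pressure phasors of all sources.
    Propagation delay enters through the exp(-j*k*R) phase of each phasor.
    """
    n_t = duration * sampling_rate
    if abs(n_t - round(n_t)) > 1e-6:
        raise ValueError("duration * sampling_rate must be an integer sample count")
    n_t = int(round(n_t))
    if sources:
        freqs = {s.frequency for s in sources}
        if len(freqs) > 1:
            raise NotImplementedError("mixed source frequencies are unsupported")
        omega = sources[0].omega
    else:
        omega = 0.0
    phasors = channel_phasors(sources, array, medium)  # (ny, nx)
    t = np.arange(n_t) / sampling_rate
    wave = np.exp(1j * omega * t)  # (n_t,)
    samples = np.real(wave[:, None, None] * phasors[None, :, :])
    return RFRecord(samples=samples.astype(np.float64), sampling_rate=sampling_rate)


def draw_channel_snr_db(spec: NoiseSpec, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Per-element target SNRs in dB."""
    return rng.normal(spec.mean_snr_db, spec.snr_std_db, size=shape)


def add_noise(rf: RFRecord, spec: NoiseSpec) -> tuple[RFRecord, dict]:
    """Add white Gaussian noise per channel at a drawn target SNR.

    Returns the noisy record and an info dict with the drawn target SNRs, the
    realized SNRs (known signal vs. realized noise power), and the noise
    component itself, all keyed for calibration checks.
    """
    sig = rf.samples
    p_sig = np.mean(sig**2, axis=0)  # (ny, nx)
    if np.any(p_sig <= 0):
        raise ValueError("zero-power channel: SNR is undefined")
    rng = np.random.default_rng(spec.seed)
    snr_db = draw_channel_snr_db(spec, p_sig.shape, rng)
    p_noise = p_sig / 10.0 ** (snr_db / 10.0)
    noise = rng.standard_normal(sig.shape) * np.sqrt(p_noise)[None, :, :]
    realized = 10.0 * np.log10(p_sig / np.mean(noise**2, axis=0))
    noisy = rf.with_stage(sig + noise, "noisy")
    info = {"target_snr_db": snr_db, "realized_snr_db": realized, "noise": noise}
    return noisy, info
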