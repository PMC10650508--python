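"""Channel-data conditioning between simulation and beamforming/learning.

Band-pass filtering around the source frequency, temporal trimming to the
delay-spread-plus-integration window, whole-frame z-score normalization of
network inputs, and the square-root/max target transform of beamformed
intensity volumes.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .forward import RFRecord
from .geometry import MediumProperties, ROIGrid, ReceiverArray
from .tea import BeamformedVolume, compute_delays

#: lower band edge floor when center - half_bandwidth would be nonpositive
_MIN_BAND_EDGE_HZ = 10e3


def butterworth_sos(center: float, half_bandwidth: float, sampling_rate: float,
                    order: int = 6) -> np.ndarray:
    """Second-order sections of the band-pass conditioning filter.

    ``order`` is the Butterworth prototype order (the usual naming for
    band-pass designs; the transfer function has 2*order poles).
    A nonpositive lower edge (possible for the 256 kHz preset with the
    default 300 kHz half-bandwidth) is clamped to 10 kHz, preserving the
    pass region around the carrier.
    """
    lo = center - half_bandwidth
    hi = center + half_bandwidth
    if lo <= 0:
        lo = _MIN_BAND_EDGE_HZ
    if hi >= sampling_rate / 2:
        raise ValueError("upper band edge reaches Nyquist")
    return signal.butter(order, [lo, hi], btype="bandpass",
                         fs=sampling_rate, output="sos")


def bandpass_filter(rf: RFRecord, center: float, half_bandwidth: float = 300e3,
                    order: int = 6) -> RFRecord:
    """Apply the same causal Butterworth band-pass to every channel.

    A single causal pass (not zero-phase): the common group delay cancels in
    the relative delays used by beamforming on trimmed records.
    """
    sos = butterworth_sos(center, half_bandwidth, rf.sampling_rate, order)
    filtered = signal.sosfilt(sos, rf.samples, axis=0)
    return rf.with_stage(np.asarray(filtered), "filtered")


def trim_window(array: ReceiverArray, grid: ROIGrid, medium: MediumProperties,
                sampling_rate: float, integration_time: float) -> tuple[int, int]:
    """First and last raw sample indices retained by temporal trimming.

    The window runs from the minimum to the maximum voxel-element delay plus
    the integration time: floor(fs * min_delay) .. ceil(fs * (max_delay + T)).
    """
    delays = compute_delays(grid, array, medium).delays
    i0 = int(np.floor(sampling_rate * delays.min()))
    i1 = int(np.ceil(sampling_rate * (delays.max() + integration_time)))
    return i0, i1


def trim_rf(rf: RFRecord, array: ReceiverArray, grid: ROIGrid,
            medium: MediumProperties, integration_time: float = 20e-6) -> RFRecord:
    """Trim the record to the information-bearing window, updating start_time.

    The updated ``start_time`` makes downstream beamforming with the same
    absolute delay table exact: the beamformer subtracts it, which turns
    absolute delays into relative ones.
    """
    i0, i1 = trim_window(array, grid, medium, rf.sampling_rate, integration_time)
    if i1 >= rf.n_t:
        raise ValueError(
            f"record of {rf.n_t} samples does not cover the trim window [{i0}, {i1}]"
        )
    return rf.with_stage(
        rf.samples[i0 : i1 + 1],
        "trimmed",
        start_time=rf.start_time + i0 / rf.sampling_rate,
    )


def zscore(rf: RFRecord) -> RFRecord:
    """Normalize the whole frame (all channels jointly) to mean 0, std 1.

    Per-frame rather than per-channel scaling preserves the inter-channel
    amplitude ratios that encode spherical spreading.
    """
    x = rf.samples
    if x.size <= 1:
        raise ValueError("z-score needs more than one sample")
    std = x.std()
    if std == 0:
        raise ValueError("z-score undefined for a constant record")
    return rf.with_stage((x - x.mean()) / std, "normalized")


def target_transform(volume: BeamformedVolume | np.ndarray) -> np.ndarray:
    """sqrt(intensity) scaled so its maximum is exactly 1 (pressure-like units)."""
    inten = volume.intensity if isinstance(volume, BeamformedVolume) else np.asarray(volume)
    if np.any(inten < 0):
        raise ValueError("intensity volume must be nonnegative")
    root = np.sqrt(inten)
    peak = root.max()
    if peak <= 0:
        raise ValueError("all-zero volume has no normalization scale")
    return root / peak
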