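"""Time exposure acoustics (TEA) beamforming.

Ground-truth image formation for passive acoustic mapping: each channel is
scaled by the spherical-spreading factor |R_i|, delayed by the time of flight
|R_i|/c, and summed over the array; the voxel intensity is the integral of
the squared beamformed signal over the integration window,

    I(r) = integral_0^T [ sum_i |R_i| p_i(t + |R_i|/c) ]^2 dt ,

discretized as a Riemann sum over round(T * f_s) samples starting at the
record origin.  Fractional sample delays are linearly interpolated
(nearest-sample lookup is available for cross-checks against naive
implementations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import RFRecord
from .geometry import MediumProperties, ROIGrid, ReceiverArray


@dataclass(frozen=True)
class DelayTable:
    """Per (voxel, element) propagation geometry.

    distances, delays: arrays of shape (n_voxels, n_elements), with voxels
    flattened in grid index order (x fastest ordering of ``ROIGrid.voxel_centers``)
    and elements flattened row-major over (n_y, n_x).
    """

    distances: np.ndarray
    delays: np.ndarray
    grid: ROIGrid

    def __post_init__(self) -> None:
        if np.any(self.distances <= 0):
            raise ValueError("all voxel-element distances must be positive")


@dataclass(frozen=True)
class BeamformedVolume:
    """Nonnegative intensity on the reconstruction grid with its window."""

    intensity: np.ndarray
    grid: ROIGrid
    window: tuple[float, float]
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if self.intensity.shape != self.grid.shape:
            raise ValueError("intensity shape does not match the grid")
        if np.any(self.intensity < 0):
            raise ValueError("beamformed intensity must be nonnegative")


def compute_delays(grid: ROIGrid, array: ReceiverArray, medium: MediumProperties) -> DelayTable:
    """Euclidean voxel-to-element distances and water time-of-flight delays."""
    voxels = grid.voxel_centers().reshape(-1, 3)
    elements = array.element_centers().reshape(-1, 3)
    dist = np.linalg.norm(voxels[:, None, :] - elements[None, :, :], axis=-1)
    return DelayTable(distances=dist, delays=dist / medium.sound_speed, grid=grid)


def tea_beamform(
    rf: RFRecord,
    delays: DelayTable,
    integration_time: float = 20e-6,
    distance_weighting: bool = True,
    interpolation: str = "linear",
    voxel_chunk: int = 4096,
    provenance: dict | None = None,
) -> BeamformedVolume:
    """Delay, scale, sum, square and integrate the channel data per voxel.

    The record's ``start_time`` is honored: a trimmed record beamformed with
    its (implicitly relative) delays reproduces the untrimmed result exactly.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    fs = rf.sampling_rate
    n_int = int(round(integration_time * fs))
    if n_int < 1:
        raise ValueError("integration window shorter than one sample")
    x = rf.samples.reshape(rf.n_t, -1)  # (n_t, E)
    n_vox, n_elem = delays.delays.shape
    if x.shape[1] != n_elem:
        raise ValueError("element count mismatch between record and delay table")

    base = (delays.delays - rf.start_time) * fs  # fractional sample offsets (V, E)
    if interpolation == "nearest":
        base = np.round(base)
    i0 = np.floor(base).astype(np.int64)
    frac = (base - i0).astype(np.float64)
    if np.any(i0 < 0) or np.any(i0 + n_int >= rf.n_t):
        raise ValueError(
            "record does not cover the delay + integration window for every voxel"
        )
    weights = delays.distances if distance_weighting else np.ones_like(delays.distances)

    dt = 1.0 / fs
    out = np.empty(n_vox, dtype=np.float64)
    steps = np.arange(n_int)
    for v0 in range(0, n_vox, voxel_chunk):
        v1 = min(n_vox, v0 + voxel_chunk)
        beam = np.zeros((v1 - v0, n_int), dtype=np.float64)
        for e in range(n_elem):
            col = x[:, e]
            idx = i0[v0:v1, e][:, None] + steps[None, :]
            s = col[idx]
            f = frac[v0:v1, e][:, None]
            if interpolation == "linear":
                s = (1.0 - f) * s + f * col[idx + 1]
            beam += weights[v0:v1, e][:, None] * s
        out[v0:v1] = np.sum(beam * beam, axis=1) * dt
    intensity = out.reshape(delays.grid.shape)
    t_o = 0.0
    return BeamformedVolume(
        intensity=intensity,
        grid=delays.grid,
        window=(t_o, t_o + n_int * dt),
        provenance=provenance,
    )
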