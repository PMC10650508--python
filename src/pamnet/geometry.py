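"""Shared geometry and medium configuration for passive acoustic mapping.

Defines the water medium, the planar 16x16 receiver matrix, the cubic
reconstruction grid, and continuous-wave point sources, together with the
three preset acquisition configurations (256 kHz, 612 kHz, 1 MHz) that the
simulation and beamforming stages share.

Coordinate convention: right-handed, array plane at z = 0 centered on the
origin, reconstruction cube centered on the array axis at (0, 0, L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised for unknown presets or inconsistent geometry parameters."""


@dataclass(frozen=True)
class MediumProperties:
    """Homogeneous propagation medium (water by default).

    Parameters
    ----------
    sound_speed : float
        Longitudinal speed of sound in m/s.
    density : float
        Mass density in kg/m^3.
    attenuation : float
        Amplitude attenuation coefficient in Np/m.
    """

    sound_speed: float = 1500.0
    density: float = 1000.0
    attenuation: float = 4.32e-4

    def __post_init__(self) -> None:
        if self.sound_speed <= 0 or self.density <= 0 or self.attenuation <= 0:
            raise ConfigurationError("medium properties must be strictly positive")


@dataclass(frozen=True)
class ReceiverArray:
    """Planar matrix receiver in the z = 0 plane, centered on the origin.

    Element size equals the pitch (contiguous square elements, one wavelength
    center-to-center).  Each element face is subdivided into a uniform square
    grid of point-like sub-elements, at least ``sub_points_per_wavelength``
    per wavelength per axis; the element signal is the arithmetic mean over
    its sub-elements so that units do not depend on the subdivision density.
    """

    n_x: int = 16
    n_y: int = 16
    pitch: float = 2.48e-3
    element_size: float | None = None
    sub_points_per_wavelength: int = 4

    def __post_init__(self) -> None:
        if self.element_size is None:
            object.__setattr__(self, "element_size", self.pitch)
        if self.n_x < 1 or self.n_y < 1 or self.pitch <= 0:
            raise ConfigurationError("invalid receiver array geometry")
        if self.element_size > self.pitch * (1 + 1e-12):
            raise ConfigurationError("element_size must not exceed pitch")
        if self.sub_points_per_wavelength < 1:
            raise ConfigurationError("sub_points_per_wavelength must be >= 1")

    @property
    def n_elements(self) -> int:
        return self.n_x * self.n_y

    def element_centers(self) -> np.ndarray:
        """(n_y, n_x, 3) element-center coordinates, symmetric about the origin."""
        xs = (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * self.pitch
        ys = (np.arange(self.n_y) - (self.n_y - 1) / 2.0) * self.pitch
        gx, gy = np.meshgrid(xs, ys, indexing="xy")
        out = np.zeros((self.n_y, self.n_x, 3))
        out[..., 0] = gx
        out[..., 1] = gy
        return out

    def n_sub_per_axis(self, wavelength: float) -> int:
        """Sub-element count per axis for a given acoustic wavelength."""
        n = int(np.ceil(self.sub_points_per_wavelength * self.element_size / wavelength))
        return max(n, 1)

    def sub_element_offsets(self, wavelength: float) -> np.ndarray:
        """(n_sub^2, 3) offsets of sub-element centers relative to an element center."""
        n = self.n_sub_per_axis(wavelength)
        step = self.element_size / n
        coords = (np.arange(n) - (n - 1) / 2.0) * step
        ox, oy = np.meshgrid(coords, coords, indexing="xy")
        out = np.zeros((n * n, 3))
        out[:, 0] = ox.ravel()
        out[:, 1] = oy.ravel()
        return out

    def sub_element_positions(self, wavelength: float) -> np.ndarray:
        """(n_y, n_x, n_sub^2, 3) absolute sub-element coordinates."""
        return self.element_centers()[:, :, None, :] + self.sub_element_offsets(wavelength)[None, None, :, :]


@dataclass(frozen=True)
class ROIGrid:
    """Cubic reconstruction grid centered on the array axis.

    ``n_per_axis`` voxel centers span ``side_length`` so that the extreme
    centers sit exactly at +-side_length/2 laterally; the cube center is at
    axial distance ``axial_distance`` from the array plane.
    """

    axial_distance: float = 0.04
    side_length: float = 10e-3
    voxel_pitch: float = 0.25e-3
    n_per_axis: int | None = None

    def __post_init__(self) -> None:
        expected = int(round(self.side_length / self.voxel_pitch)) + 1
        if self.n_per_axis is None:
            object.__setattr__(self, "n_per_axis", expected)
        elif self.n_per_axis != expected:
            raise ConfigurationError(
                f"n_per_axis {self.n_per_axis} inconsistent with side/voxel ({expected})"
            )
        if self.axial_distance <= 0:
            raise ConfigurationError("axial_distance must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_per_axis, self.n_per_axis, self.n_per_axis)

    def axis_coords(self, axis: str) -> np.ndarray:
        """Voxel-center coordinates along 'x', 'y' (lateral) or 'z' (axial)."""
        half = self.side_length / 2.0
        c = np.linspace(-half, half, self.n_per_axis)
        if axis in ("x", "y"):
            return c
        if axis == "z":
            return c + self.axial_distance
        raise ValueError(f"unknown axis {axis!r}")

    def voxel_centers(self) -> np.ndarray:
        """(n, n, n, 3) voxel-center coordinates, index order (x, y, z)."""
        x = self.axis_coords("x")
        y = self.axis_coords("y")
        z = self.axis_coords("z")
        gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([-self.side_length / 2, -self.side_length / 2,
                       self.axial_distance - self.side_length / 2])
        return lo, lo + self.side_length


@dataclass(frozen=True)
class PointSource:
    """Monochromatic continuous-wave point emitter.

    ``strength`` is the source strength u*ds (normal surface velocity times
    radiating area); all generated sources share unit strength since volumes
    are max-normalized downstream.
    """

    position: tuple[float, float, float]
    frequency: float
    strength: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ConfigurationError("source frequency must be positive")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency


#: Preset acquisition configurations: frequency (Hz), pitch (m), axial distance (m).
_PRESETS: dict[str, tuple[float, float, float]] = {
    "f256": (256e3, 5.8e-3, 0.06),
    "f612": (612e3, 2.48e-3, 0.04),
    "f1000": (1000e3, 1.5e-3, 0.02),
}


def preset_config(
    name: str,
) -> tuple[MediumProperties, ReceiverArray, ROIGrid, float]:
    """Return (medium, array, grid, source frequency) for a named preset.

    Presets pair the receiver pitch with roughly one acoustic wavelength and
    place the 10 mm reconstruction cube at 6 / 4 / 2 cm axial distance for
    256 / 612 / 1000 kHz respectively.
    """
    try:
        freq, pitch, dist = _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    medium = MediumProperties()
    array = ReceiverArray(pitch=pitch)
    grid = ROIGrid(axial_distance=dist)
    return medium, array, grid, freq


def load_config(path) -> dict:
    """Load a YAML acquisition configuration.

    Recognized keys (all optional, falling back to the f612 preset):
    ``medium{c, rho, alpha}``, ``array{n, pitch, element_size, ppwl}``,
    ``roi{distance, side, voxel}``, ``source{freq, n_min, n_max}``, ``seed``.
    Returns a dict with medium, array, grid, source frequency, the source
    count range, and the seed.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    med = raw.get("medium", {})
    medium = MediumProperties(
        sound_speed=med.get("c", 1500.0),
        density=med.get("rho", 1000.0),
        attenuation=med.get("alpha", 4.32e-4),
    )
    arr = raw.get("array", {})
    n = arr.get("n", 16)
    array = ReceiverArray(
        n_x=n, n_y=n,
        pitch=arr.get("pitch", 2.48e-3),
        element_size=arr.get("element_size"),
        sub_points_per_wavelength=arr.get("ppwl", 4),
    )
    roi = raw.get("roi", {})
    grid = ROIGrid(
        axial_distance=roi.get("distance", 0.04),
        side_length=roi.get("side", 10e-3),
        voxel_pitch=roi.get("voxel", 0.25e-3),
    )
    src = raw.get("source", {})
    return {
        "medium": medium,
        "array": array,
        "grid": grid,
        "frequency": src.get("freq", 612e3),
        "n_sources": (src.get("n_min", 1), src.get("n_max", 5)),
        "seed": raw.get("seed", 0),
    }


def random_sources(
    n: int,
    grid: ROIGrid,
    rng: np.random.Generator,
    frequency: float,
) -> list[PointSource]:
    """Draw ``n`` equal-strength CW sources uniformly inside the ROI cube."""
    if not 1 <= n <= 5:
        raise ValueError(f"source count must be in 1..5, got {n}")
    lo, hi = grid.bounds()
    pos = rng.uniform(lo, hi, size=(n, 3))
    return [PointSource(position=tuple(p), frequency=frequency) for p in pos]
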