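"""Dataset generation, persistence, and configuration plumbing.

A *profile* freezes every pipeline parameter (sampling, record length,
integration window, grid resolution, noise, filtering, network input
length) for one preset geometry.  The full-scale profile reproduces the
study conditions (40 MHz, 140 us records, 20 us integration, 41^3 grid,
2000/25/500 split); the desk profile is a 1-CPU scale-down (8 MHz, 50 us,
5 us, 21^3 grid) used by the test suite.

Archives are single HDF5 files:  /frames/<id>/{rf_trimmed, target} plus
optional intermediate stages, per-frame attributes (sources, seed, split),
and a /manifest JSON attribute holding the parameter snapshot.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import h5py
import numpy as np

from .forward import NoiseSpec, RFRecord, add_noise, simulate_rf
from .geometry import (
    MediumProperties,
    PointSource,
    ROIGrid,
    ReceiverArray,
    preset_config,
    random_sources,
)
from .preprocess import bandpass_filter, target_transform, trim_rf, zscore
from .tea import compute_delays, tea_beamform


@dataclass(frozen=True)
class PipelineProfile:
    """Complete parameter snapshot for one acquisition configuration."""

    preset: str = "f612"
    sampling_rate: float = 40e6
    duration: float = 140e-6
    integration_time: float = 20e-6
    grid_n: int = 41
    input_length: int = 1521
    half_bandwidth: float = 300e3
    filter_order: int = 6
    noise_mean_snr_db: float = -4.0
    noise_relative_std: float = 0.3
    n_sources_min: int = 1
    n_sources_max: int = 5

    def geometry(self) -> tuple[MediumProperties, ReceiverArray, ROIGrid, float]:
        medium, array, grid, freq = preset_config(self.preset)
        if self.grid_n != grid.n_per_axis:
            pitch = grid.side_length / (self.grid_n - 1)
            grid = ROIGrid(axial_distance=grid.axial_distance,
                           side_length=grid.side_length, voxel_pitch=pitch)
        return medium, array, grid, freq


def full_profile(preset: str = "f612") -> PipelineProfile:
    return PipelineProfile(preset=preset)


def desk_profile(preset: str = "f612") -> PipelineProfile:
    """Scaled-down profile for single-CPU runs (coarser grid, shorter records)."""
    return PipelineProfile(
        preset=preset,
        sampling_rate=8e6,
        duration=50e-6,
        integration_time=5e-6,
        grid_n=21,
        input_length=168,
    )


@dataclass(frozen=True)
class FrameRecord:
    frame_id: int
    seed: int
    split: str
    sources: tuple[tuple[float, float, float], ...]
    n_sources: int


@dataclass(frozen=True)
class DatasetManifest:
    profile: PipelineProfile
    global_seed: int
    frames: tuple[FrameRecord, ...]

    def split_ids(self, split: str) -> list[int]:
        return [f.frame_id for f in self.frames if f.split == split]

    def to_json(self) -> str:
        return json.dumps({
            "profile": asdict(self.profile),
            "global_seed": self.global_seed,
            "frames": [asdict(f) for f in self.frames],
        })

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        raw = json.loads(text)
        frames = tuple(
            FrameRecord(
                frame_id=f["frame_id"], seed=f["seed"], split=f["split"],
                sources=tuple(tuple(s) for s in f["sources"]),
                n_sources=f["n_sources"],
            )
            for f in raw["frames"]
        )
        return cls(profile=PipelineProfile(**raw["profile"]),
                   global_seed=raw["global_seed"], frames=frames)


def frame_seed(global_seed: int, frame_id: int) -> int:
    """Counter-based per-frame seed, independently reproducible."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(frame_id,))
    return int(ss.generate_state(1)[0] % (2**31))


def synthesize_frame(profile: PipelineProfile, seed: int, *,
                     n_sources: int | None = None, noisy: bool = True):
    """Run the forward pipeline for one frame.

    Returns a dict with the source list and the RF record at every stage,
    the beamformed target volume, and the network-ready input tensor.
    """
    medium, array, grid, freq = profile.geometry()
    rng = np.random.default_rng(seed)
    if n_sources is None:
        n_sources = int(rng.integers(profile.n_sources_min, profile.n_sources_max + 1))
    sources = random_sources(n_sources, grid, rng, freq)
    rf_raw = simulate_rf(sources, array, medium,
                         duration=profile.duration,
                         sampling_rate=profile.sampling_rate)
    if noisy:
        spec = NoiseSpec(mean_snr_db=profile.noise_mean_snr_db,
                         relative_std=profile.noise_relative_std,
                         seed=seed)
        rf_noisy, noise_info = add_noise(rf_raw, spec)
    else:
        rf_noisy, noise_info = rf_raw, None
    rf_filt = bandpass_filter(rf_noisy, center=freq,
                              half_bandwidth=profile.half_bandwidth,
                              order=profile.filter_order)
    rf_trim = trim_rf(rf_filt, array, grid, medium,
                      integration_time=profile.integration_time)
    delays = compute_delays(grid, array, medium)
    volume = tea_beamform(rf_filt, delays,
                          integration_time=profile.integration_time,
                          provenance={"seed": seed,
                                      "sources": [s.position for s in sources]})
    target = target_transform(volume)
    return {
        "sources": sources,
        "rf_raw": rf_raw,
        "rf_noisy": rf_noisy,
        "rf_filtered": rf_filt,
        "rf_trimmed": rf_trim,
        "volume": volume,
        "target": target,
        "noise_info": noise_info,
        "grid": grid,
        "frequency": freq,
    }


def network_input(rf_trimmed: RFRecord, input_length: int) -> np.ndarray:
    """Z-score the trimmed record and fit it to the network input length.

    Records longer than the configured length are cropped at the tail;
    shorter ones are zero-padded at the tail (after z-scoring, so the pad
    does not disturb the normalization of the signal itself).
    """
    z = zscore(rf_trimmed).samples.astype(np.float32)
    n_t = z.shape[0]
    if n_t >= input_length:
        return z[:input_length]
    out = np.zeros((input_length, *z.shape[1:]), dtype=np.float32)
    out[:n_t] = z
    return out


def generate_dataset(path, profile: PipelineProfile, *, n_train: int = 2000,
                     n_val: int = 25, n_test: int = 500, seed: int = 0,
                     store_intermediate: bool = False,
                     val_sources: int | None = None) -> DatasetManifest:
    """Synthesize and persist a complete train/val/test archive.

    ``val_sources`` optionally pins the validation frames to a fixed source
    count (single-source validation is the common desk-scale monitoring
    choice).
    """
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    frames = []
    with h5py.File(path, "w") as h5:
        grp = h5.create_group("frames")
        for fid, split in enumerate(splits):
            s = frame_seed(seed, fid)
            pin = val_sources if (split == "val" and val_sources) else None
            frame = synthesize_frame(profile, s, n_sources=pin)
            g = grp.create_group(str(fid))
            g.create_dataset("rf_trimmed", data=frame["rf_trimmed"].samples,
                             dtype="f4")
            g["rf_trimmed"].attrs["start_time"] = frame["rf_trimmed"].start_time
            g["rf_trimmed"].attrs["sampling_rate"] = frame["rf_trimmed"].sampling_rate
            g.create_dataset("target", data=frame["target"], dtype="f4")
            if store_intermediate:
                for stage in ("rf_raw", "rf_noisy", "rf_filtered"):
                    g.create_dataset(stage, data=frame[stage].samples, dtype="f4")
            g.attrs["seed"] = s
            g.attrs["split"] = split
            g.attrs["sources"] = np.array([src.position for src in frame["sources"]])
            frames.append(FrameRecord(
                frame_id=fid, seed=s, split=split,
                sources=tuple(src.position for src in frame["sources"]),
                n_sources=len(frame["sources"]),
            ))
        manifest = DatasetManifest(profile=profile, global_seed=seed,
                                   frames=tuple(frames))
        h5.attrs["manifest"] = manifest.to_json()
    return manifest


def load_manifest(path) -> DatasetManifest:
    with h5py.File(path, "r") as h5:
        return DatasetManifest.from_json(h5.attrs["manifest"])


def load_dataset(path, split: str):
    """Yield (network input, target volume) pairs for one split, in manifest order."""
    manifest = load_manifest(path)
    ids = manifest.split_ids(split)
    if not ids:
        raise ValueError(f"split {split!r} is empty or unknown")
    profile = manifest.profile
    with h5py.File(path, "r") as h5:
        for fid in ids:
            g = h5["frames"][str(fid)]
            rf = RFRecord(
                samples=g["rf_trimmed"][...].astype(np.float64),
                sampling_rate=float(g["rf_trimmed"].attrs["sampling_rate"]),
                start_time=float(g["rf_trimmed"].attrs["start_time"]),
                stages=("raw", "noisy", "filtered", "trimmed"),
            )
            yield network_input(rf, profile.input_length), g["target"][...].astype(np.float32)


def export_nifti(volume, grid: ROIGrid, path) -> None:
    """Write an intensity volume as NIfTI-1 with true voxel spacing (mm)."""
    import nibabel as nib

    pitch_mm = grid.voxel_pitch * 1e3
    affine = np.diag([pitch_mm, pitch_mm, pitch_mm, 1.0])
    half = grid.side_length / 2 * 1e3
    affine[:3, 3] = [-half, -half, grid.axial_distance * 1e3 - half]
    data = volume.intensity if hasattr(volume, "intensity") else np.asarray(volume)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
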