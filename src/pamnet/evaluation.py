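"""Image-quality metrics, source counting, and paired statistics.

Per-frame metrics: PSNR, NRMSE, SSIM (see :mod:`pamnet.nn.losses`), peak
sidelobe ratio, image SNR, localization error and main-lobe radii.  Source
counting thresholds the intensity volume at -3 dB of its peak and counts
26-connected components.  Aggregate comparisons use the exact two-sided
sign test and one-vs-rest confusion rates per source count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

PSNR_INF_SENTINEL = float("inf")

#: -3 dB applied on intensity: cutoff fraction of the peak
DB3_FRACTION = 10.0 ** (-3.0 / 10.0)

#: 26-neighborhood connectivity for contiguous-volume labeling
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SourceDetectionResult:
    threshold_db: float
    count: int
    labels: np.ndarray
    peak_locations: np.ndarray  # (count, 3) voxel indices of per-component peaks
    peak_intensities: np.ndarray
    main_lobe_label: int  # label of the component containing the global max


@dataclass
class ImageQualityReport:
    ssim: float = np.nan
    psnr: float = np.nan
    nrmse: float = np.nan
    pslr: float = np.nan
    image_snr: float = np.nan
    localization_error_mm: float = np.nan
    lobe_radii_mm: tuple[float, float, float] = (np.nan, np.nan, np.nan)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("ssim", "psnr", "nrmse", "pslr", "image_snr", "localization_error_mm")}
        d["lobe_short1_mm"], d["lobe_short2_mm"], d["lobe_long_mm"] = self.lobe_radii_mm
        return d


@dataclass(frozen=True)
class PairedComparison:
    """Frame-aligned metric pairs with a sign test on their differences."""

    target: np.ndarray
    predicted: np.ndarray
    p_value: float
    median_difference: float
    iqr: float

    @classmethod
    def from_pairs(cls, target, predicted) -> "PairedComparison":
        target = np.asarray(target, dtype=float)
        predicted = np.asarray(predicted, dtype=float)
        if target.shape != predicted.shape:
            raise ValueError("paired metric lists must align")
        diff = predicted - target
        q1, med, q3 = np.percentile(diff, [25, 50, 75])
        return cls(target, predicted, sign_test(diff), float(med), float(q3 - q1))


def _check_volumes(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError("volume shape mismatch")
    return truth, pred


def mse(truth: np.ndarray, pred: np.ndarray) -> float:
    truth, pred = _check_volumes(truth, pred)
    return float(np.mean((truth - pred) ** 2))


def psnr(truth: np.ndarray, pred: np.ndarray) -> float:
    """20*log10(I_max / sqrt(MSE)) in dB; identical volumes give +inf."""
    truth, pred = _check_volumes(truth, pred)
    peak = truth.max()
    if peak <= 0:
        raise ValueError("reference volume must have positive maximum")
    err = mse(truth, pred)
    if err == 0:
        return PSNR_INF_SENTINEL
    return float(20.0 * np.log10(peak / np.sqrt(err)))


def nrmse(truth: np.ndarray, pred: np.ndarray) -> float:
    """sqrt(MSE) / (I_max - I_min) of the reference volume."""
    truth, pred = _check_volumes(truth, pred)
    rng = truth.max() - truth.min()
    if rng <= 0:
        raise ValueError("flat reference volume: NRMSE undefined")
    return float(np.sqrt(mse(truth, pred)) / rng)


def count_sources(volume: np.ndarray, threshold_db: float = -3.0) -> SourceDetectionResult:
    """Count contiguous -3 dB regions of an intensity volume.

    The volume is binarized at max * 10^(threshold_db/10) and 26-connected
    components are labeled; each component's peak voxel and intensity are
    reported, along with the component holding the global maximum.
    """
    volume = np.asarray(volume, dtype=float)
    peak = volume.max()
    if peak <= 0:
        raise ValueError("cannot count sources in a nonpositive volume")
    mask = volume >= peak * 10.0 ** (threshold_db / 10.0)
    labels, count = ndimage.label(mask, structure=_STRUCTURE)
    locs = np.zeros((count, 3), dtype=int)
    peaks = np.zeros(count)
    for k in range(1, count + 1):
        flat = np.where(labels.ravel() == k)[0]
        best = flat[np.argmax(volume.ravel()[flat])]
        locs[k - 1] = np.unravel_index(best, volume.shape)
        peaks[k - 1] = volume.ravel()[best]
    main = int(labels[np.unravel_index(np.argmax(volume), volume.shape)])
    return SourceDetectionResult(
        threshold_db=threshold_db, count=int(count), labels=labels,
        peak_locations=locs, peak_intensities=peaks, main_lobe_label=main,
    )


def pslr(volume: np.ndarray, detection: SourceDetectionResult) -> float:
    """Peak sidelobe ratio: highest intensity outside the main lobe / peak."""
    volume = np.asarray(volume, dtype=float)
    outside = volume[detection.labels != detection.main_lobe_label]
    if outside.size == 0:
        return 0.0
    return float(outside.max() / volume.max())


def image_snr(volume: np.ndarray, wavelength: float, detection: SourceDetectionResult,
              voxel_pitch: float) -> float:
    """Peak intensity over background standard deviation.

    Background voxels lie more than one wavelength from the main-lobe peak;
    distances use physical units (``voxel_pitch`` and ``wavelength`` in the
    same unit).
    """
    volume = np.asarray(volume, dtype=float)
    main = detection.peak_locations[detection.main_lobe_label - 1]
    idx = np.indices(volume.shape)
    dist = np.sqrt(((idx - main.reshape(3, 1, 1, 1)) ** 2).sum(axis=0)) * voxel_pitch
    background = volume[dist > wavelength]
    if background.size == 0:
        raise ValueError("exclusion radius leaves no background voxels")
    sd = background.std()
    if sd == 0:
        raise ValueError("zero-variance background")
    return float(volume.max() / sd)


def _argmax_with_tie_warning(volume: np.ndarray) -> np.ndarray:
    flat = volume.ravel()
    best = flat.argmax()
    if np.count_nonzero(flat == flat[best]) > 1:
        warnings.warn("argmax tie broken by lowest linear index")
    return np.array(np.unravel_index(best, volume.shape))


def localization_error(truth: np.ndarray, pred: np.ndarray, voxel_pitch_mm: float) -> float:
    """Euclidean distance (mm) between the peak voxels of two volumes."""
    truth, pred = _check_volumes(truth, pred)
    a = _argmax_with_tie_warning(truth)
    b = _argmax_with_tie_warning(pred)
    return float(np.linalg.norm((a - b) * voxel_pitch_mm))


def _axis_halfwidth(profile: np.ndarray, center: int, cutoff: float) -> float:
    """Half-extent (in voxel units) of the above-cutoff run through ``center``,
    with linear interpolation of the crossing on each side."""
    n = len(profile)
    # walk right
    right = float(n - 1 - center)
    for i in range(center, n - 1):
        if profile[i + 1] < cutoff:
            right = i - center + (profile[i] - cutoff) / (profile[i] - profile[i + 1])
            break
    left = float(center)
    for i in range(center, 0, -1):
        if profile[i - 1] < cutoff:
            left = center - i + (profile[i] - cutoff) / (profile[i] - profile[i - 1])
            break
    return (left + right) / 2.0


def main_lobe_radii(volume: np.ndarray, detection: SourceDetectionResult,
                    voxel_pitch_mm: float) -> tuple[float, float, float]:
    """-3 dB half-widths (mm) along x, y (short axes) and z (long axis).

    Profiles run through the main-lobe peak; the crossing of the -3 dB
    intensity cutoff is located by linear interpolation between voxels.
    A single-voxel lobe yields zeros with a warning.
    """
    volume = np.asarray(volume, dtype=float)
    peak_idx = detection.peak_locations[detection.main_lobe_label - 1]
    lobe_size = np.count_nonzero(detection.labels == detection.main_lobe_label)
    if lobe_size <= 1:
        warnings.warn("degenerate single-voxel main lobe; radii reported as 0")
        return (0.0, 0.0, 0.0)
    cutoff = volume.max() * DB3_FRACTION
    radii = []
    for axis in range(3):
        sl = list(peak_idx)
        sl[axis] = slice(None)
        profile = volume[tuple(sl)]
        radii.append(_axis_halfwidth(profile, int(peak_idx[axis]), cutoff) * voxel_pitch_mm)
    return tuple(radii)


def sign_test(differences) -> float:
    """Exact two-sided binomial test on the signs of paired differences."""
    d = np.asarray(differences, dtype=float)
    pos = int(np.sum(d > 0))
    neg = int(np.sum(d < 0))
    if pos + neg == 0:
        raise ValueError("sign test needs at least one nonzero difference")
    return float(stats.binomtest(pos, pos + neg, 0.5, alternative="two-sided").pvalue)


def confusion_report(true_counts, pred_counts, classes=range(1, 6)) -> dict[int, dict[str, float]]:
    """One-vs-rest detection rates per source-count class.

    For class k, a frame is positive when its count equals k.  Rates are
    TPR = TP/(TP+FN), FPR = FP/(FP+TN), TNR, FNR; a class never present in
    the truth yields NaN TPR/FNR.
    """
    t = np.asarray(true_counts, dtype=int)
    p = np.asarray(pred_counts, dtype=int)
    if t.shape != p.shape:
        raise ValueError("count lists must have equal length")
    out: dict[int, dict[str, float]] = {}
    for k in classes:
        tp = int(np.sum((t == k) & (p == k)))
        fn = int(np.sum((t == k) & (p != k)))
        fp = int(np.sum((t != k) & (p == k)))
        tn = int(np.sum((t != k) & (p != k)))
        out[k] = {
            "TPR": tp / (tp + fn) if tp + fn else np.nan,
            "FNR": fn / (tp + fn) if tp + fn else np.nan,
            "FPR": fp / (fp + tn) if fp + tn else np.nan,
            "TNR": tn / (fp + tn) if fp + tn else np.nan,
        }
    return out


def quality_report(truth: np.ndarray, pred: np.ndarray, voxel_pitch_mm: float,
                   wavelength_mm: float) -> ImageQualityReport:
    """Bundle all per-frame metrics for one (target, prediction) pair."""
    from .nn.losses import ssim3d

    truth, pred = _check_volumes(truth, pred)
    det = count_sources(pred)
    return ImageQualityReport(
        ssim=ssim3d(truth, pred),
        psnr=psnr(truth, pred),
        nrmse=nrmse(truth, pred),
        pslr=pslr(pred, det),
        image_snr=image_snr(pred, wavelength_mm, det, voxel_pitch_mm),
        localization_error_mm=localization_error(truth, pred, voxel_pitch_mm),
        lobe_radii_mm=main_lobe_radii(pred, det, voxel_pitch_mm),
    )
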