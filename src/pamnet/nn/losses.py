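"""Composite SSIM + L1 loss for volumetric reconstruction.

The structural similarity index is computed with a 3D Gaussian window
(size 11 voxels, sigma 1.5 voxels by default).  Local means, variances and
the covariance are obtained by normalized zero-padded Gaussian filtering:
the raw zero-padded correlation is divided, voxel-wise, by the local window
mass, so border voxels see a properly renormalized window and constant
inputs have exact local means everywhere.  The per-voxel SSIM map

    S = (2 mu_x mu_y + C1)(2 cov_xy + C2) /
        ((mu_x^2 + mu_y^2 + C1)(var_x + var_y + C2))

is averaged over all voxels.  Stabilizers default to C1 = (0.01 D)^2,
C2 = (0.03 D)^2 with data range D = 1 (volumes are max-normalized).

The training loss is  w_ssim * (1 - SSIM) + w_l1 * L1  with the weights
renormalized to sum to one; analytic gradients with respect to the
prediction are provided for both terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d


@dataclass(frozen=True)
class LossConfig:
    ssim_weight: float = 0.84
    l1_weight: float = 0.16
    window_size: int = 11
    window_sigma: float = 1.5
    c1: float = 0.01**2
    c2: float = 0.03**2

    def __post_init__(self) -> None:
        if self.window_size % 2 != 1:
            raise ValueError("SSIM window size must be odd")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("stabilizers must be positive")
        if self.ssim_weight < 0 or self.l1_weight < 0 or (self.ssim_weight + self.l1_weight) <= 0:
            raise ValueError("loss weights must be nonnegative and not both zero")

    @property
    def normalized_weights(self) -> tuple[float, float]:
        t = self.ssim_weight + self.l1_weight
        return self.ssim_weight / t, self.l1_weight / t


def gaussian_window(size: int, sigma: float) -> np.ndarray:
    """1D Gaussian taps, unit sum; the 3D window is the separable product."""
    half = (size - 1) / 2.0
    x = np.arange(size) - half
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return (w / w.sum()).astype(np.float64)


class _GaussianFilter3d:
    """Normalized zero-padded separable Gaussian filtering and its adjoint."""

    def __init__(self, shape: tuple[int, int, int], cfg: LossConfig):
        self.taps = gaussian_window(cfg.window_size, cfg.window_sigma)
        self.shape = shape
        self.mass = self._raw(np.ones(shape))  # local window mass, (0, 1]

    def _raw(self, x: np.ndarray) -> np.ndarray:
        y = np.asarray(x, dtype=np.float64)
        for axis in range(3):
            y = correlate1d(y, self.taps, axis=axis, mode="constant", cval=0.0)
        return y

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self._raw(x) / self.mass

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        # F = D^-1 A with A symmetric (zero padding, symmetric taps), so
        # F^T y = A (y / mass)
        return self._raw(np.asarray(y, dtype=np.float64) / self.mass)


_FILTER_CACHE: dict[tuple, _GaussianFilter3d] = {}


def _filter_for(shape, cfg: LossConfig) -> _GaussianFilter3d:
    key = (shape, cfg.window_size, cfg.window_sigma)
    if key not in _FILTER_CACHE:
        _FILTER_CACHE[key] = _GaussianFilter3d(shape, cfg)
    return _FILTER_CACHE[key]


def _ssim_terms(pred: np.ndarray, truth: np.ndarray, cfg: LossConfig):
    f = _filter_for(pred.shape, cfg)
    mx = f.apply(pred)
    my = f.apply(truth)
    mxx = f.apply(pred * pred)
    myy = f.apply(truth * truth)
    mxy = f.apply(pred * truth)
    var_x = mxx - mx * mx
    var_y = myy - my * my
    cov = mxy - mx * my
    a1 = 2.0 * mx * my + cfg.c1
    a2 = 2.0 * cov + cfg.c2
    b1 = mx * mx + my * my + cfg.c1
    b2 = var_x + var_y + cfg.c2
    s = (a1 * a2) / (b1 * b2)
    return f, mx, my, a1, a2, b1, b2, s


def ssim3d(a: np.ndarray, b: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Mean 3D Gaussian-window SSIM between two volumes."""
    cfg = cfg or LossConfig()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("ssim3d expects two 3D volumes of identical shape")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("ssim3d inputs must be finite")
    *_, s = _ssim_terms(a, b, cfg)
    return float(s.mean())


def ssim3d_with_grad(pred: np.ndarray, truth: np.ndarray, cfg: LossConfig):
    """Mean SSIM and its gradient with respect to ``pred``."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.ndim != 3:
        raise ValueError("expected two 3D volumes of identical shape")
    f, mx, my, a1, a2, b1, b2, s = _ssim_terms(pred, truth, cfg)
    n = pred.size
    g = 1.0 / n  # d(mean S)/dS per voxel
    inv_b1b2 = 1.0 / (b1 * b2)
    # partials of S with respect to the filtered moments
    d_mu = g * (
        2.0 * my * a2 * inv_b1b2          # via A1
        - 2.0 * my * a1 * inv_b1b2        # via cov in A2 (d cov/d mu_x = -mu_y)
        - s / b1 * 2.0 * mx               # via B1
        + s / b2 * 2.0 * mx               # via var_x in B2 (d var/d mu_x = -2 mu_x)
    )
    d_mxx = g * (-s / b2)                 # via var_x
    d_mxy = g * (2.0 * a1 * inv_b1b2)     # via cov
    grad = f.adjoint(d_mu) + 2.0 * pred * f.adjoint(d_mxx) + truth * f.adjoint(d_mxy)
    return float(s.mean()), grad


def l1_loss(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute voxel difference."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(a - b)))


def l1_with_grad(pred: np.ndarray, truth: np.ndarray):
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    diff = pred - truth
    return float(np.mean(np.abs(diff))), np.sign(diff) / pred.size


def combined_loss(pred: np.ndarray, truth: np.ndarray, cfg: LossConfig | None = None) -> float:
    """w_ssim * (1 - SSIM) + w_l1 * L1, weights renormalized to sum to 1."""
    cfg = cfg or LossConfig()
    ws, wl = cfg.normalized_weights
    total = 0.0
    if ws > 0:
        total += ws * (1.0 - ssim3d(pred, truth, cfg))
    if wl > 0:
        total += wl * l1_loss(pred, truth)
    return total


def combined_loss_with_grad(pred: np.ndarray, truth: np.ndarray, cfg: LossConfig):
    ws, wl = cfg.normalized_weights
    loss = 0.0
    grad = np.zeros_like(np.asarray(pred, dtype=np.float64))
    if ws > 0:
        s, gs = ssim3d_with_grad(pred, truth, cfg)
        loss += ws * (1.0 - s)
        grad -= ws * gs
    if wl > 0:
        l, gl = l1_with_grad(pred, truth)
        loss += wl * l
        grad += wl * gl
    return loss, grad
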