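"""Adam training loop for the reconstruction network.

Mirrors the published configuration: Adam at learning rate 3e-4, L2 penalty
1e-3 on convolution weights, batch size 5, composite 0.84*SSIM + 0.16*L1
loss on max-normalized outputs.  Desk-scale runs use the same loop with a
smaller network and dataset and a shorter schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import LossConfig, combined_loss_with_grad, l1_loss, ssim3d
from .network import ReconstructionNetwork


@dataclass
class TrainConfig:
    learning_rate: float = 3e-4
    l2_penalty: float = 1e-3
    batch_size: int = 5
    epochs: int = 300
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0 or self.l2_penalty < 0:
            raise ValueError("training hyperparameters must be positive")


class Adam:
    """Adam with an L2 penalty added to the gradients of decaying parameters."""

    def __init__(self, params, lr, l2=0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.l2 > 0 and p.decay:
                g = g + self.l2 * p.value
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


class TrainingDiverged(RuntimeError):
    pass


def _as_arrays(dataset):
    xs, ys = zip(*dataset)
    return np.asarray(xs, dtype=np.float32), np.asarray(ys, dtype=np.float32)


def evaluate_model(model, dataset, loss_cfg: LossConfig):
    """Mean combined loss / SSIM / NRMSE-style L1 over (rf, target) pairs."""
    from ..evaluation import nrmse

    xs, ys = _as_arrays(dataset)
    losses, ssims, nrmses = [], [], []
    for i in range(0, len(xs), 8):
        pred = model.forward(xs[i : i + 8], training=False)
        for p, t in zip(pred, ys[i : i + 8]):
            losses.append(float(np.mean(combined_loss_with_grad(p, t, loss_cfg)[0])))
            ssims.append(ssim3d(p, t, loss_cfg))
            nrmses.append(nrmse(t, p) if t.max() > t.min() else np.nan)
    return {
        "loss": float(np.mean(losses)),
        "ssim": float(np.mean(ssims)),
        "nrmse": float(np.nanmean(nrmses)),
    }


def train(
    model: ReconstructionNetwork,
    dataset,
    cfg: TrainConfig,
    val_dataset=None,
    verbose: bool = False,
):
    """Train in place; returns a per-epoch history dict.

    ``dataset`` and ``val_dataset`` are sequences of (rf_input, target
    volume) pairs with shapes matching the model spec.  The best-validation
    parameter state (by combined loss) is restored at the end when a
    validation set is supplied.
    """
    xs, ys = _as_arrays(dataset)
    if len(xs) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg.learning_rate, cfg.l2_penalty)
    history = {"epoch": [], "train_loss": [], "train_ssim": [],
               "val_loss": [], "val_ssim": [], "val_nrmse": []}
    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(xs))
        ep_loss, ep_ssim, n_batches = 0.0, 0.0, 0
        for b0 in range(0, len(order), cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            xb, yb = xs[idx], ys[idx]
            model.zero_grad()
            pred = model.forward(xb, training=True)
            grads = np.empty_like(pred, dtype=np.float64)
            batch_loss = 0.0
            batch_ssim = 0.0
            for k in range(len(idx)):
                loss_k, grad_k = combined_loss_with_grad(pred[k], yb[k], cfg.loss)
                batch_loss += loss_k
                batch_ssim += ssim3d(pred[k], yb[k], cfg.loss)
                grads[k] = grad_k
            batch_loss /= len(idx)
            batch_ssim /= len(idx)
            if not np.isfinite(batch_loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {b0 // cfg.batch_size}"
                )
            model.backward(grads / len(idx))
            opt.step()
            ep_loss += batch_loss
            ep_ssim += batch_ssim
            n_batches += 1
        history["epoch"].append(epoch)
        history["train_loss"].append(ep_loss / n_batches)
        history["train_ssim"].append(ep_ssim / n_batches)
        if val_dataset:
            stats = evaluate_model(model, val_dataset, cfg.loss)
            history["val_loss"].append(stats["loss"])
            history["val_ssim"].append(stats["ssim"])
            history["val_nrmse"].append(stats["nrmse"])
            if stats["loss"] < best[0]:
                best = (stats["loss"], model.get_state())
        else:
            history["val_loss"].append(np.nan)
            history["val_ssim"].append(np.nan)
            history["val_nrmse"].append(np.nan)
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {history['train_loss'][-1]:.4f}"
                f"  ssim {history['train_ssim'][-1]:.4f}"
                f"  val_ssim {history['val_ssim'][-1]:.4f}"
            )
    if val_dataset and best[1] is not None:
        model.set_state(best[1])
    return history
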