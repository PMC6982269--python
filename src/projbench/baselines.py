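"""Corroborating projections: PCA and a bottleneck autoencoder.

Both serve as sanity checks for a structure-less data set: if neither the
variance-maximizing linear projection (PCA) nor a nonlinear 2-neuron
bottleneck autoencoder shows subgroups, an apparent cluster structure in a
stochastic embedding of the same data is suspect.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .datasets import DataSet
from .projection import Projection

__all__ = ["AutoencoderConfig", "pca_project", "autoencoder_project"]


def pca_project(data: DataSet) -> Projection:
    """Project onto the top-2 principal components.

    Deterministic including sign: each component is flipped so its
    largest-magnitude loading is positive.
    """
    x = data.points
    if x.shape[0] <= 2:
        raise ValueError("need n > 2")
    if x.shape[1] < 2:
        raise ValueError("need D >= 2")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise ValueError("data has zero variance")
    top2 = evecs[:, :2].copy()
    for j in range(2):
        lead = np.argmax(np.abs(top2[:, j]))
        if top2[lead, j] < 0:
            top2[:, j] = -top2[:, j]
    return Projection(
        coords=xc @ top2,
        method="pca",
        config={"explained_variance": evals[:2].tolist(),
                "total_variance": float(evals.sum())},
    )


@dataclass
class AutoencoderConfig:
    """Feedforward autoencoder with logistic-sigmoid units and a 2-neuron
    bottleneck (default architecture D-5-2-5-D)."""

    layer_sizes: Optional[Sequence[int]] = None  # filled from D at fit time
    activation: str = "logistic_sigmoid"
    epochs: int = 500
    learning_rate: float = 0.05
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation != "logistic_sigmoid":
            raise ValueError("only logistic_sigmoid is supported")
        if self.layer_sizes is not None:
            sizes = list(self.layer_sizes)
            if len(sizes) < 3 or min(sizes) < 1:
                raise ValueError("invalid layer sizes")
            if sizes[len(sizes) // 2] != 2:
                raise ValueError("bottleneck (middle layer) must have width 2")

    def resolved_sizes(self, d: int) -> list[int]:
        if self.layer_sizes is None:
            return [d, 5, 2, 5, d]
        sizes = list(self.layer_sizes)
        if sizes[0] != d or sizes[-1] != d:
            raise ValueError("first/last layer must equal the data dimension")
        return sizes


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Autoencoder:
    """Minimal MLP trained to reconstruct its input (squared error)."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        for w, b in zip(self.weights, self.biases):
            acts.append(_sigmoid(acts[-1] @ w + b))
        return acts

    def loss(self, x: np.ndarray) -> float:
        recon = self.forward(x)[-1]
        return float(0.5 * np.mean(np.sum((recon - x) ** 2, axis=1)))

    def gradients(self, x: np.ndarray):
        """Backprop of the mean squared reconstruction error over a batch."""
        acts = self.forward(x)
        m = x.shape[0]
        delta = (acts[-1] - x) * acts[-1] * (1.0 - acts[-1]) / m
        grads_w, grads_b = [], []
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w.append(acts[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * acts[layer] * (
                    1.0 - acts[layer]
                )
        return grads_w[::-1], grads_b[::-1]

    def step(self, x: np.ndarray, lr: float) -> None:
        gw, gb = self.gradients(x)
        for w, b, dw, db in zip(self.weights, self.biases, gw, gb):
            w -= lr * dw
            b -= lr * db


def _minmax_scale(x: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> np.ndarray:
    """Per-column min-max scaling into [lo, hi] (sigmoid outputs cannot
    reach 0 or 1, so targets must stay strictly inside)."""
    mn, mx = x.min(axis=0), x.max(axis=0)
    span = np.where(mx > mn, mx - mn, 1.0)
    scaled = lo + (hi - lo) * (x - mn) / span
    scaled[:, mx == mn] = 0.5 * (lo + hi)
    return scaled


def autoencoder_project(
    data: DataSet, config: Optional[AutoencoderConfig] = None
) -> Projection:
    """Train a bottleneck autoencoder and return the 2-D bottleneck codes."""
    cfg = config or AutoencoderConfig()
    sizes = cfg.resolved_sizes(data.dim)
    rng = np.random.default_rng(cfg.seed)
    x = _minmax_scale(data.points)
    net = _Autoencoder(sizes, rng)
    initial_loss = net.loss(x)
    n = x.shape[0]
    epoch_losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            net.step(x[order[start : start + cfg.batch_size]], cfg.learning_rate)
        loss = net.loss(x)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"autoencoder diverged (learning_rate={cfg.learning_rate})"
            )
        epoch_losses.append(loss)
    bottleneck_layer = len(sizes) // 2
    codes = net.forward(x)[bottleneck_layer]
    return Projection(
        coords=codes,
        method="autoencoder",
        config={
            **asdict(cfg),
            "layer_sizes": sizes,
            "initial_loss": initial_loss,
            "epoch_losses": epoch_losses,
        },
        seed=cfg.seed,
        final_objective=epoch_losses[-1],
    )
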