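"""Exact t-distributed stochastic neighbor embedding (t-SNE).

High-dimensional pairwise similarities are Gaussian with a per-point
bandwidth sigma_i calibrated so that the Shannon entropy of the conditional
neighbor distribution equals log2(perplexity); conditionals are symmetrized
into a joint distribution P.  Low-dimensional similarities Q use a Student-t
kernel with one degree of freedom, which keeps moderately distant points
from being crushed together in the plane.  The embedding minimizes the
(asymmetric) Kullback-Leibler divergence KL(P || Q) by gradient descent
with momentum, adaptive per-coordinate gains and an early-exaggeration
phase — the reference optimizer schedule that classic CPU implementations
(including the R "tsne" package) share.

Everything here is exact O(n^2); no tree or interpolation approximations.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .datasets import DataSet
from .projection import Projection

__all__ = [
    "AffinityMatrix",
    "TsneConfig",
    "highdim_affinities",
    "lowdim_affinities",
    "kl_divergence",
    "tsne_gradient",
    "tsne_embed",
]

# floor applied to affinities inside objective/gradient evaluation, so that
# log(0) never occurs; stored matrices stay exactly normalized
AFFINITY_FLOOR = 1e-12


@dataclass
class AffinityMatrix:
    """A symmetric joint probability matrix over point pairs.

    kind is "highdim_P" (Gaussian, perplexity-calibrated) or "lowdim_Q"
    (Student-t).  Entries are >= 0 with zero diagonal and grand sum 1.
    """

    probs: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.kind not in ("highdim_P", "lowdim_Q"):
            raise ValueError(f"unknown affinity kind {self.kind!r}")
        self.validate()

    def validate(self) -> None:
        p = self.probs
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("affinity matrix must be square")
        if np.any(p < 0):
            raise ValueError("negative affinity")
        if np.any(np.diag(p) != 0):
            raise ValueError("diagonal must be exactly zero")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("affinities must sum to 1 within 1e-9")
        if np.max(np.abs(p - p.T)) > 1e-12:
            raise ValueError("affinity matrix must be symmetric")


@dataclass
class TsneConfig:
    """Optimizer and model settings; defaults follow the classic reference
    schedule (perplexity 30, lr 100, momentum 0.5 -> 0.8 at iteration 250,
    early exaggeration x4 for 100 iterations, optional PCA pre-reduction to
    ``initial_dims`` input dimensions)."""

    perplexity: float = 30.0
    initial_dims: int = 30
    max_iter: int = 1000
    learning_rate: float = 100.0
    momentum_initial: float = 0.5
    momentum_final: float = 0.8
    momentum_switch_iter: int = 250
    early_exaggeration_factor: float = 4.0
    early_exaggeration_iters: int = 100
    min_gain: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perplexity <= 1:
            raise ValueError("perplexity must be > 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        for m in (self.momentum_initial, self.momentum_final):
            if not (0 <= m < 1):
                raise ValueError("momenta must lie in [0, 1)")
        if self.learning_rate <= 0 or self.early_exaggeration_factor <= 0:
            raise ValueError("learning_rate and exaggeration must be > 0")


# ---------------------------------------------------------------------------
# affinities
# ---------------------------------------------------------------------------

def _row_entropy_bits(sq_dists: np.ndarray, sigma: float) -> tuple[float, np.ndarray]:
    """Shannon entropy (bits) and probabilities of one conditional row."""
    w = np.exp(-sq_dists / (2.0 * sigma * sigma))
    total = w.sum()
    if total <= 0:
        # all mass collapsed numerically; entropy 0, point mass on argmin
        p = np.zeros_like(w)
        p[np.argmin(sq_dists)] = 1.0
        return 0.0, p
    p = w / total
    nz = p > 0
    h = -np.sum(p[nz] * np.log2(p[nz]))
    return h, p


def _calibrate_row(
    sq_dists: np.ndarray,
    perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 50,
    sigma_bounds: tuple[float, float] = (1e-20, 1e20),
) -> np.ndarray:
    """Bisection in log(sigma) for one point's conditional distribution."""
    target = np.log2(perplexity)
    lo, hi = (np.log(b) for b in sigma_bounds)
    best_p = None
    best_err = np.inf
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        h, p = _row_entropy_bits(sq_dists, np.exp(mid))
        err = h - target
        if abs(err) < best_err:
            best_err, best_p = abs(err), p
        if abs(err) < tol:
            return p
        if err > 0:  # entropy too high -> shrink sigma
            hi = mid
        else:
            lo = mid
    warnings.warn(
        f"perplexity calibration did not reach tolerance {tol:g} "
        f"(residual {best_err:.2e}); using best sigma found",
        RuntimeWarning,
        stacklevel=2,
    )
    return best_p


def highdim_affinities(points: np.ndarray, perplexity: float) -> AffinityMatrix:
    """Perplexity-calibrated, symmetrized Gaussian joint probabilities P."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not (1 < perplexity < n):
        raise ValueError("require 1 < perplexity < n")
    d2 = squareform(pdist(points, "sqeuclidean"))
    cond = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        others = idx != i
        cond[i, others] = _calibrate_row(d2[i, others], perplexity)
    p = (cond + cond.T) / (2.0 * n)
    np.fill_diagonal(p, 0.0)
    p /= p.sum()  # renormalize away symmetrization round-off
    return AffinityMatrix(probs=p, kind="highdim_P")


def lowdim_affinities(coords: np.ndarray) -> AffinityMatrix:
    """Student-t (1 d.o.f.) joint probabilities Q over embedding pairs."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    num = 1.0 / (1.0 + squareform(pdist(coords, "sqeuclidean")))
    np.fill_diagonal(num, 0.0)
    q = num / num.sum()
    return AffinityMatrix(probs=q, kind="lowdim_Q")


def kl_divergence(P: AffinityMatrix, Q: AffinityMatrix) -> float:
    """KL(P || Q) = sum_{i != j} p_ij log(p_ij / q_ij), natural log.

    Terms with p_ij = 0 contribute nothing; q is floored at 1e-12 so the
    objective stays finite.
    """
    p, q = P.probs, Q.probs
    if p.shape != q.shape:
        raise ValueError("shape mismatch between P and Q")
    mask = p > 0
    return float(
        np.sum(p[mask] * np.log(p[mask] / np.maximum(q[mask], AFFINITY_FLOOR)))
    )


# ---------------------------------------------------------------------------
# gradient and optimizer
# ---------------------------------------------------------------------------

def tsne_gradient(p: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Analytic gradient of KL(P||Q) w.r.t. the embedding coordinates:
    dC/dy_i = 4 sum_j (p_ij - q_ij) (1 + |y_i - y_j|^2)^-1 (y_i - y_j)."""
    num = 1.0 / (1.0 + squareform(pdist(coords, "sqeuclidean")))
    np.fill_diagonal(num, 0.0)
    q = np.maximum(num / num.sum(), AFFINITY_FLOOR)
    np.fill_diagonal(q, 0.0)
    w = (p - q) * num
    # grad_i = 4 * (sum_j w_ij * (y_i - y_j))
    return 4.0 * (w.sum(axis=1)[:, None] * coords - w @ coords)


def _pca_reduce(x: np.ndarray, n_components: int) -> np.ndarray:
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / max(x.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    return xc @ evecs[:, order]


def tsne_embed(data: DataSet, config: Optional[TsneConfig] = None) -> Projection:
    """Embed a data set into the plane by exact t-SNE gradient descent."""
    cfg = config or TsneConfig()
    x = data.points
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points")
    if cfg.perplexity >= n:
        raise ValueError("perplexity must be < n")
    if x.shape[1] > cfg.initial_dims:
        x = _pca_reduce(x, cfg.initial_dims)

    p_mat = highdim_affinities(x, cfg.perplexity).probs
    rng = np.random.default_rng(cfg.seed)
    y = rng.normal(0.0, 1e-2, size=(n, 2))  # sd 1e-2 -> variance 1e-4
    dy = np.zeros_like(y)
    gains = np.ones_like(y)

    p_aff = AffinityMatrix(p_mat, "highdim_P")
    p_run = p_mat * cfg.early_exaggeration_factor
    objective_trace: list[tuple[int, float]] = []

    def record(it: int) -> None:
        objective_trace.append(
            (it, kl_divergence(p_aff, lowdim_affinities(y)))
        )

    for it in range(cfg.max_iter):
        if it == cfg.early_exaggeration_iters:
            p_run = p_mat
            record(it)
        grad = tsne_gradient(p_run, y)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(
                f"NaN/Inf in t-SNE gradient at iteration {it} "
                f"(learning_rate={cfg.learning_rate})"
            )
        momentum = (
            cfg.momentum_initial
            if it < cfg.momentum_switch_iter
            else cfg.momentum_final
        )
        same_sign = np.sign(dy) == np.sign(grad)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        np.clip(gains, cfg.min_gain, None, out=gains)
        dy = momentum * dy - cfg.learning_rate * gains * grad
        y = y + dy
        y = y - y.mean(axis=0)
        if it >= cfg.max_iter - 100:
            record(it + 1)

    final_kl = objective_trace[-1][1] if objective_trace else kl_divergence(
        p_aff, lowdim_affinities(y)
    )
    return Projection(
        coords=y,
        method="tsne",
        config={**asdict(cfg), "objective_trace": objective_trace},
        seed=cfg.seed,
        final_objective=final_kl,
    )
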