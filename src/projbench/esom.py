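"""Emergent self-organizing map (ESOM) training and projection.

An ESOM is a Kohonen map with thousands of neurons — many more than the
expected number of clusters — so that cluster structure *emerges* as
macro-scale patterns (ridges, valleys) on the lattice instead of being
forced into one-neuron-per-cluster prototypes.  Training uses the online
SOM rule

    w_i <- w_i + eta(t) * h(bmu, i, r(t)) * (x - w_i)

with a Gaussian neighborhood kernel h over lattice distance and per-epoch
linear decay of both the learning rate eta and the kernel radius r.  The
default lattice is a 50 x 80 torus: wraparound edges avoid the artificial
border clusters that planar maps produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import DataSet

__all__ = [
    "EsomGrid",
    "TrainingSchedule",
    "BmuAssignment",
    "init_grid",
    "grid_distance_sq",
    "best_matching_unit",
    "train_esom",
    "project_bmus",
    "mean_quantization_error",
]

EMERGENT_MIN_NEURONS = 1000


@dataclass
class EsomGrid:
    """A rows x cols lattice of D-dimensional neuron weight vectors."""

    weights: np.ndarray  # shape (rows, cols, D)
    topology: str = "toroidal"
    trained: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError("weights must have shape (rows, cols, D)")
        if self.rows * self.cols < 2:
            raise ValueError("grid must have at least 2 neurons")
        if self.topology not in ("toroidal", "planar"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights contain NaN/Inf")
        if self.rows * self.cols < EMERGENT_MIN_NEURONS:
            warnings.warn(
                f"grid has only {self.rows * self.cols} neurons; emergent "
                f"structure needs >= {EMERGENT_MIN_NEURONS}",
                UserWarning,
                stacklevel=2,
            )

    @property
    def rows(self) -> int:
        return self.weights.shape[0]

    @property
    def cols(self) -> int:
        return self.weights.shape[1]

    @property
    def dim(self) -> int:
        return self.weights.shape[2]


@dataclass
class TrainingSchedule:
    """Per-epoch linear decay of learning rate and Gaussian kernel radius.

    Defaults (20 epochs, eta 0.5 -> 0.1, radius 24 -> 2) suit the 50 x 80
    default lattice: the initial radius spans roughly half the smaller
    lattice dimension so early epochs order the map globally, late epochs
    fine-tune locally.  The final radius of 2 keeps the converged map
    locally smooth; driving it to 1 lets the map fold sharply, which etches
    spurious ridges into the U-matrix where a cluster's band touches itself.
    """

    epochs: int = 20
    lr_start: float = 0.5
    lr_end: float = 0.1
    radius_start: float = 24.0
    radius_end: float = 2.0
    neighborhood_kernel: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.lr_end <= self.lr_start <= 1):
            raise ValueError("require 0 < lr_end <= lr_start <= 1")
        if not (1 <= self.radius_end <= self.radius_start):
            raise ValueError("require radius_start >= radius_end >= 1")
        if self.neighborhood_kernel != "gaussian":
            raise ValueError("only the gaussian kernel is supported")


@dataclass
class BmuAssignment:
    """Best-matching-unit coordinates and quantization error per point."""

    rows: np.ndarray
    cols: np.ndarray
    quantization_errors: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.quantization_errors = np.asarray(
            self.quantization_errors, dtype=float
        )


def init_grid(
    data: DataSet,
    rows: int = 50,
    cols: int = 80,
    seed: int = 0,
    topology: str = "toroidal",
) -> EsomGrid:
    """Initialize neuron weights uniformly within the per-column data range."""
    if data.n < 1:
        raise ValueError("data must be nonempty")
    rng = np.random.default_rng(seed)
    lo = data.points.min(axis=0)
    hi = data.points.max(axis=0)
    weights = rng.uniform(lo, hi, size=(rows, cols, data.dim))
    return EsomGrid(
        weights=weights,
        topology=topology,
        trained=False,
        provenance={"init_seed": seed, "data_name": data.name},
    )


def grid_distance_sq(
    r1: int, c1: int, r2: int, c2: int, rows: int, cols: int, topology: str
) -> float:
    """Squared lattice distance between two neurons, wrapping on a torus."""
    dr = abs(r1 - r2)
    dc = abs(c1 - c2)
    if topology == "toroidal":
        dr = min(dr, rows - dr)
        dc = min(dc, cols - dc)
    return float(dr * dr + dc * dc)


def best_matching_unit(grid: EsomGrid, x: np.ndarray) -> tuple[int, int]:
    """Index of the neuron closest to x; ties break to the first neuron in
    row-major order."""
    x = np.asarray(x, dtype=float)
    if x.shape != (grid.dim,):
        raise ValueError(f"query must be a vector of length {grid.dim}")
    flat = grid.weights.reshape(-1, grid.dim)
    d2 = np.einsum("nd,nd->n", flat, flat) - 2.0 * flat @ x + x @ x
    idx = int(np.argmin(d2))
    return idx // grid.cols, idx % grid.cols


def _base_kernel(rows: int, cols: int, radius: float, topology: str) -> np.ndarray:
    """Gaussian kernel values for a BMU at (0, 0); on a torus this single
    table serves every BMU position via a roll."""
    dr = np.arange(rows)
    dc = np.arange(cols)
    if topology == "toroidal":
        dr = np.minimum(dr, rows - dr)
        dc = np.minimum(dc, cols - dc)
    g2 = dr[:, None] ** 2 + dc[None, :] ** 2
    return np.exp(-g2 / (2.0 * radius * radius))


def _epoch_value(start: float, end: float, epoch: int, epochs: int) -> float:
    if epochs == 1:
        return start
    return start + (end - start) * epoch / (epochs - 1)


def train_esom(
    data: DataSet, grid: EsomGrid, schedule: Optional[TrainingSchedule] = None
) -> EsomGrid:
    """Online ESOM training; returns a new trained grid.

    Each epoch presents all points in a fresh seeded random order; every
    neuron is updated toward the current point, weighted by the Gaussian
    kernel over lattice distance to the BMU.  Reproducible bit-for-bit for
    fixed (data, grid, schedule).
    """
    sched = schedule or TrainingSchedule()
    if data.dim != grid.dim:
        raise ValueError("data dimension does not match grid")
    rng = np.random.default_rng(sched.seed)
    w = grid.weights.copy()
    rows, cols, dim = w.shape
    flat = w.reshape(-1, dim)
    x_all = data.points

    for epoch in range(sched.epochs):
        eta = _epoch_value(sched.lr_start, sched.lr_end, epoch, sched.epochs)
        radius = _epoch_value(
            sched.radius_start, sched.radius_end, epoch, sched.epochs
        )
        kernel0 = _base_kernel(rows, cols, radius, grid.topology)
        if grid.topology != "toroidal":
            row_idx = np.arange(rows)
            col_idx = np.arange(cols)
        order = rng.permutation(data.n)
        for i in order:
            x = x_all[i]
            d2 = (
                np.einsum("nd,nd->n", flat, flat) - 2.0 * flat @ x + x @ x
            )
            bmu = int(np.argmin(d2))
            br, bc = bmu // cols, bmu % cols
            if grid.topology == "toroidal":
                h = np.roll(np.roll(kernel0, br, axis=0), bc, axis=1)
            else:
                g2 = (row_idx - br)[:, None] ** 2 + (col_idx - bc)[None, :] ** 2
                h = np.exp(-g2 / (2.0 * radius * radius))
            w += (eta * h)[:, :, None] * (x - w)
        if not np.all(np.isfinite(w)):
            raise FloatingPointError(
                f"NaN/Inf in weights after epoch {epoch} "
                f"(eta={eta:.3g}, radius={radius:.3g})"
            )

    return EsomGrid(
        weights=w,
        topology=grid.topology,
        trained=True,
        provenance={
            **grid.provenance,
            "schedule": {
                "epochs": sched.epochs,
                "lr": [sched.lr_start, sched.lr_end],
                "radius": [sched.radius_start, sched.radius_end],
                "seed": sched.seed,
            },
        },
    )


def project_bmus(grid: EsomGrid, data: DataSet) -> BmuAssignment:
    """BMU lattice position and quantization error for every data point."""
    if data.dim != grid.dim:
        raise ValueError("data dimension does not match grid")
    flat = grid.weights.reshape(-1, grid.dim)
    d = cdist(data.points, flat)
    idx = d.argmin(axis=1)
    qe = d[np.arange(data.n), idx]
    return BmuAssignment(
        rows=idx // grid.cols, cols=idx % grid.cols, quantization_errors=qe
    )


def mean_quantization_error(grid: EsomGrid, data: DataSet) -> float:
    """Mean distance from each point to its BMU weight — a SOM fit statistic."""
    return float(project_bmus(grid, data).quantization_errors.mean())
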