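"""U-matrix, P-matrix and U*-matrix landscapes over a trained ESOM.

The U-matrix assigns each neuron the summed data-space distance from its
weight vector to the weights of its immediate lattice neighbors: high
"ridges" mark places where the map stretches across empty data space, i.e.
cluster boundaries.  The P-matrix instead measures data density around each
neuron's weight (points within a radius).  The U*-matrix damps U-heights in
dense regions — where apparent walls cannot be real cluster borders — and
keeps them in sparse regions, which sharpens density-based separations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .datasets import DataSet
from .esom import BmuAssignment, EsomGrid

__all__ = [
    "HeightMatrix",
    "compute_umatrix",
    "compute_pmatrix",
    "pareto_radius",
    "compute_ustar",
    "write_height_matrix",
    "read_height_matrix",
    "render_landscape",
]

# 8-neighborhood offsets on the rectangular lattice
_OFFSETS_8 = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]
_OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclass
class HeightMatrix:
    """A nonnegative landscape (kind U, P or Ustar) over an ESOM lattice."""

    heights: np.ndarray
    kind: str
    topology: str = "toroidal"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.kind not in ("U", "P", "Ustar"):
            raise ValueError(f"unknown height kind {self.kind!r}")
        if self.heights.ndim != 2:
            raise ValueError("heights must be 2-D")
        if np.any(self.heights < 0):
            raise ValueError("heights must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


def compute_umatrix(grid: EsomGrid, neighborhood: int = 8) -> HeightMatrix:
    """Per-neuron sum of weight distances to immediate lattice neighbors."""
    if neighborhood == 8:
        offsets = _OFFSETS_8
    elif neighborhood == 4:
        offsets = _OFFSETS_4
    else:
        raise ValueError("neighborhood must be 4 or 8")
    if not grid.trained:
        warnings.warn(
            "computing a U-matrix on an untrained grid", UserWarning,
            stacklevel=2,
        )
    w = grid.weights
    rows, cols = grid.rows, grid.cols
    heights = np.zeros((rows, cols))
    for dr, dc in offsets:
        shifted = np.roll(np.roll(w, -dr, axis=0), -dc, axis=1)
        dist = np.linalg.norm(shifted - w, axis=2)
        if grid.topology == "planar":
            valid = np.ones((rows, cols), dtype=bool)
            if dr == -1:
                valid[0, :] = False
            elif dr == 1:
                valid[-1, :] = False
            if dc == -1:
                valid[:, 0] = False
            elif dc == 1:
                valid[:, -1] = False
            dist = np.where(valid, dist, 0.0)
        heights += dist
    return HeightMatrix(
        heights=heights,
        kind="U",
        topology=grid.topology,
        params={"neighborhood": neighborhood},
    )


def pareto_radius(data: DataSet, seed: int = 0, max_sample: int = 2000) -> float:
    """Density radius heuristic: 20th percentile of pairwise distances of a
    (seeded) subsample of at most ``max_sample`` points."""
    pts = data.points
    if pts.shape[0] > max_sample:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(pts.shape[0], max_sample, replace=False)]
    d = pdist(pts)
    return float(np.percentile(d, 20))


def compute_pmatrix(
    grid: EsomGrid,
    data: DataSet,
    radius: Union[float, str] = "auto",
    seed: int = 0,
) -> HeightMatrix:
    """Per-neuron count of data points within ``radius`` of its weight.

    ``radius="auto"`` uses :func:`pareto_radius` (20th percentile of sampled
    pairwise data distances).
    """
    if data.dim != grid.dim:
        raise ValueError("data dimension does not match grid")
    if radius == "auto":
        r = pareto_radius(data, seed=seed)
    else:
        r = float(radius)
        if r <= 0:
            raise ValueError("radius must be > 0")
    flat = grid.weights.reshape(-1, grid.dim)
    counts = np.zeros(flat.shape[0])
    chunk = max(1, int(2e7) // max(data.n, 1))
    for start in range(0, flat.shape[0], chunk):
        d = cdist(flat[start : start + chunk], data.points)
        counts[start : start + chunk] = (d <= r).sum(axis=1)
    return HeightMatrix(
        heights=counts.reshape(grid.rows, grid.cols),
        kind="P",
        topology=grid.topology,
        params={"radius": r},
    )


def compute_ustar(U: HeightMatrix, P: HeightMatrix) -> HeightMatrix:
    """U* = U * f(P): damp walls where the data are dense.

    f is linear with f = 1 at the P median and f = 0 at the P maximum,
    clipped to [0, 1].  If median equals maximum (uniform density) f == 1
    and U* == U.
    """
    if U.kind != "U" or P.kind != "P":
        raise ValueError("expected kinds U and P")
    if U.shape != P.shape:
        raise ValueError("shape mismatch between U and P")
    p = P.heights
    med, mx = float(np.median(p)), float(p.max())
    if mx == med:
        f = np.ones_like(p)
    else:
        f = np.clip((mx - p) / (mx - med), 0.0, 1.0)
    return HeightMatrix(
        heights=U.heights * f,
        kind="Ustar",
        topology=U.topology,
        params={"p_median": med, "p_max": mx},
    )


def write_height_matrix(H: HeightMatrix, path_base: str | Path) -> Path:
    """Persist a landscape as a CSV grid plus a JSON sidecar holding kind,
    parameters, topology and a checksum of the CSV bytes."""
    import hashlib
    import json

    path_base = Path(path_base)
    csv_path = path_base.with_suffix(".csv")
    np.savetxt(csv_path, H.heights, delimiter=",")
    sidecar = {
        "kind": H.kind,
        "topology": H.topology,
        "params": H.params,
        "sha256": hashlib.sha256(csv_path.read_bytes()).hexdigest(),
    }
    path_base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_height_matrix(path_base: str | Path) -> HeightMatrix:
    """Load a landscape written by :func:`write_height_matrix`."""
    import json

    path_base = Path(path_base)
    heights = np.loadtxt(path_base.with_suffix(".csv"), delimiter=",",
                         ndmin=2)
    sidecar = json.loads(path_base.with_suffix(".json").read_text())
    return HeightMatrix(
        heights=heights,
        kind=sidecar["kind"],
        topology=sidecar["topology"],
        params=sidecar["params"],
    )


def render_landscape(
    H: HeightMatrix,
    assignment: Optional[BmuAssignment] = None,
    labels: Optional[np.ndarray] = None,
    tile: Optional[bool] = None,
    ax=None,
):
    """Topographic rendering of a height landscape with optional BMU markers.

    Toroidal landscapes are tiled 2 x 2 by default so structures crossing
    the wrap are visually continuous.  Returns ``(fig, display)`` where
    ``display`` is the (possibly tiled) matrix actually drawn.
    """
    import matplotlib.pyplot as plt

    if tile is None:
        tile = H.topology == "toroidal"
    display = H.heights
    if tile:
        display = np.tile(display, (2, 2))
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 8 * display.shape[0] / display.shape[1]))
    else:
        fig = ax.figure
    ax.imshow(display, cmap="terrain", interpolation="nearest")
    if assignment is not None:
        reps = 2 if tile else 1
        rows, cols = H.shape
        if labels is not None:
            colors = np.asarray(labels)
        else:
            colors = "k"
        for ti in range(reps):
            for tj in range(reps):
                ax.scatter(
                    assignment.cols + tj * cols,
                    assignment.rows + ti * rows,
                    c=colors,
                    s=6,
                    cmap="tab10",
                    edgecolors="none",
                )
    ax.set_title(f"{H.kind}-matrix")
    ax.set_xticks([])
    ax.set_yticks([])
    return fig, display
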