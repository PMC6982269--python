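"""Synthetic benchmark data sets for projection / subgroup-detection studies.

All generators return a :class:`DataSet`.  The collection mirrors the
classic stress tests used to probe 2-D projection methods:

* a structure-less "golf ball" (points spread evenly on a sphere) that any
  honest projection must show as a single homogeneous cloud,
* FCPS-style sets (Chainlink, EngyTime, Lsun) that each break a specific
  class of projection/clustering algorithms,
* a 2-D four-mode Gaussian mixture emulating an SS/CD45 flow-cytometry
  scatter plot.

Every stochastic generator takes an explicit integer seed and owns a single
``numpy.random.Generator``; no global RNG state is touched.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DataSet",
    "generate_golfball",
    "sphere_neighbor_degrees",
    "generate_chainlink",
    "generate_engytime",
    "generate_lsun",
    "generate_facs_gmm",
    "write_dataset",
    "read_dataset",
]


@dataclass
class DataSet:
    """An n x D point matrix with optional ground-truth class labels.

    Parameters
    ----------
    points
        Real matrix of shape (n, D).  Must be finite.
    labels
        Optional integer vector of length n; class ids are 0-based and
        ``-1`` marks an unlabeled point.  ``None`` for structure-less sets.
    name
        Short identifier, used in file names and reports.
    provenance
        Generator name, parameters and seed — enough to regenerate the set.
    """

    points: np.ndarray
    labels: Optional[np.ndarray] = None
    name: str = "dataset"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D array (n, D)")
        n, d = self.points.shape
        if n < 1 or d < 1:
            raise ValueError("need n >= 1 and D >= 1")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain NaN/Inf")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must equal number of points")
            if np.any(self.labels < -1):
                raise ValueError("labels must be >= -1")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


# ---------------------------------------------------------------------------
# golf ball: geodesic icosahedral sphere
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere icosahedron: 12 vertices, 20 triangular faces."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=int,
    )
    return verts, faces


def generate_golfball(subdivision_frequency: int = 20) -> DataSet:
    """Points spread almost-equidistantly on the unit sphere ("golf ball").

    The construction is the icosahedral geodesic subdivision at frequency
    ``nu``: each of the 20 icosahedron faces is split into ``nu**2`` small
    triangles and every vertex is projected onto the unit sphere, giving
    ``10 * nu**2 + 2`` points.  All but the 12 original icosahedron vertices
    have six nearest neighbors at (approximately) equal distance; the 12
    exceptional vertices have five.  The default frequency 20 yields 4002
    points.  Deterministic — no randomness involved.
    """
    nu = int(subdivision_frequency)
    if nu < 1:
        raise ValueError("subdivision_frequency must be >= 1")
    verts, faces = _icosahedron()
    pts = []
    for a, b, c in faces:
        va, vb, vc = verts[a], verts[b], verts[c]
        for i in range(nu + 1):
            for j in range(nu + 1 - i):
                k = nu - i - j
                p = (i * va + j * vb + k * vc) / nu
                pts.append(p)
    pts = np.asarray(pts)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # shared edges/vertices are emitted once per adjacent face; deduplicate
    uniq = np.unique(np.round(pts, 9), axis=0)
    expected = 10 * nu * nu + 2
    if uniq.shape[0] != expected:  # pragma: no cover - construction guard
        raise RuntimeError(
            f"geodesic construction produced {uniq.shape[0]} points, "
            f"expected {expected}"
        )
    uniq /= np.linalg.norm(uniq, axis=1, keepdims=True)
    return DataSet(
        points=uniq,
        labels=None,
        name="golfball",
        provenance={"generator": "golfball", "subdivision_frequency": nu},
    )


def sphere_neighbor_degrees(points: np.ndarray) -> np.ndarray:
    """Nearest-neighbor count per point for a convex point cloud on a sphere.

    Neighbors are read from the convex hull triangulation (the Delaunay
    triangulation of the sphere), which is tolerance-free: on a geodesic
    sphere it yields exactly 12 points with 5 neighbors (the icosahedron
    vertices) and 6 for every other point.  Distances to those neighbors
    are only approximately equal — exact equidistance is geometrically
    impossible beyond the icosahedron itself.
    """
    from scipy.spatial import ConvexHull

    points = np.asarray(points, dtype=float)
    hull = ConvexHull(points)
    degree_sets: list[set] = [set() for _ in range(points.shape[0])]
    for a, b, c in hull.simplices:
        degree_sets[a].update((b, c))
        degree_sets[b].update((a, c))
        degree_sets[c].update((a, b))
    return np.array([len(s) for s in degree_sets], dtype=int)


# ---------------------------------------------------------------------------
# FCPS-style sets
# ---------------------------------------------------------------------------

def generate_chainlink(
    n_per_ring: int = 500, noise_sd: float = 0.05, seed: int = 0
) -> DataSet:
    """Two interlocked unit circles in 3-D (distance-separated clusters).

    Ring 0 lies in the XY plane centered at the origin; ring 1 lies in the
    XZ plane centered at (1, 0, 0), so the rings interlock like chain links.
    Angles are sampled uniformly; isotropic Gaussian jitter of standard
    deviation ``noise_sd`` is added.  With ``noise_sd=0`` the minimal
    distance between the rings is exactly 1 (each ring passes through the
    other's center).
    """
    if n_per_ring < 3:
        raise ValueError("n_per_ring must be >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t0 = rng.uniform(0.0, 2 * np.pi, n_per_ring)
    t1 = rng.uniform(0.0, 2 * np.pi, n_per_ring)
    ring0 = np.column_stack([np.cos(t0), np.sin(t0), np.zeros(n_per_ring)])
    ring1 = np.column_stack(
        [1.0 + np.cos(t1), np.zeros(n_per_ring), np.sin(t1)]
    )
    pts = np.vstack([ring0, ring1])
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    labels = np.repeat([0, 1], n_per_ring)
    return DataSet(
        points=pts,
        labels=labels,
        name="chainlink",
        provenance={
            "generator": "chainlink",
            "n_per_ring": n_per_ring,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def _stratified_counts(n_total: int, n_groups: int) -> np.ndarray:
    """Split n_total into n_groups near-equal counts (remainder to the first)."""
    base = n_total // n_groups
    counts = np.full(n_groups, base, dtype=int)
    counts[: n_total - base * n_groups] += 1
    return counts


# EngyTime: equal-weight 2-D mixture where the clusters differ by density,
# not by a gap — the classic failure case for purely distance-based readings.
_ENGYTIME_MEANS = (np.array([1.3, 1.3]), np.array([0.0, 0.0]))
_ENGYTIME_COVS = (
    np.array([[0.09, 0.0], [0.0, 0.09]]),          # tight, circular
    np.array([[1.0, 0.5], [0.5, 1.0]]),            # broad, correlated
)


def generate_engytime(n_total: int = 4096, seed: int = 0) -> DataSet:
    """Two overlapping 2-D Gaussians separated by density contrast only."""
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    rng = np.random.default_rng(seed)
    counts = _stratified_counts(n_total, 2)
    parts, labels = [], []
    for comp, (mean, cov, cnt) in enumerate(
        zip(_ENGYTIME_MEANS, _ENGYTIME_COVS, counts)
    ):
        parts.append(rng.multivariate_normal(mean, cov, size=cnt))
        labels.append(np.full(cnt, comp, dtype=int))
    return DataSet(
        points=np.vstack(parts),
        labels=np.concatenate(labels),
        name="engytime",
        provenance={"generator": "engytime", "n_total": n_total, "seed": seed},
    )


# Lsun geometry: two uniform strips forming an "L" plus a Gaussian "sun",
# all three separated by clear gaps.
_LSUN_STRIP0 = ((0.0, 3.0), (0.0, 0.6))     # x-range, y-range (horizontal bar)
_LSUN_STRIP1 = ((0.0, 0.6), (1.8, 4.8))     # vertical bar, 1.2 above the base
_LSUN_BALL_MEAN = np.array([4.0, 4.0])
_LSUN_BALL_SD = 0.25


def generate_lsun(n_total: int = 400, seed: int = 0) -> DataSet:
    """Three well-separated 2-D clusters: two uniform strips and a ball."""
    if n_total < 3:
        raise ValueError("n_total must be >= 3")
    rng = np.random.default_rng(seed)
    counts = _stratified_counts(n_total, 3)
    (x0, y0), (x1, y1) = _LSUN_STRIP0, _LSUN_STRIP1
    strip0 = np.column_stack(
        [rng.uniform(*x0, counts[0]), rng.uniform(*y0, counts[0])]
    )
    strip1 = np.column_stack(
        [rng.uniform(*x1, counts[1]), rng.uniform(*y1, counts[1])]
    )
    ball = rng.normal(_LSUN_BALL_MEAN, _LSUN_BALL_SD, size=(counts[2], 2))
    labels = np.repeat([0, 1, 2], counts)
    return DataSet(
        points=np.vstack([strip0, strip1, ball]),
        labels=labels,
        name="lsun",
        provenance={"generator": "lsun", "n_total": n_total, "seed": seed},
    )


# ---------------------------------------------------------------------------
# FACS surrogate: 2-D four-mode Gaussian mixture (SS vs CD45)
# ---------------------------------------------------------------------------

# Default modes sketch the canonical SS/CD45 leukocyte landscape:
# lymphocytes (low SS, high CD45), two adjacent mononuclear modes close
# enough to merge under a poor projection, and granulocytes (high SS).
_FACS_MEANS = np.array(
    [[1.0, 4.0], [2.0, 3.4], [2.6, 2.9], [4.0, 1.5]]
)
_FACS_COVS = np.array(
    [
        [[0.09, 0.0], [0.0, 0.09]],
        [[0.12, 0.0], [0.0, 0.12]],
        [[0.12, 0.0], [0.0, 0.12]],
        [[0.30, 0.0], [0.0, 0.20]],
    ]
)
_FACS_WEIGHTS = np.array([0.30, 0.25, 0.20, 0.25])


def generate_facs_gmm(
    n_total: int = 5000,
    seed: int = 0,
    means: Optional[np.ndarray] = None,
    covs: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> DataSet:
    """2-D Gaussian mixture emulating an SS/CD45 flow-cytometry scatter.

    Four visibly distinct but adjacent modes by default; two of them sit
    close enough that a poor projection merges them into one apparent
    group.  Dimensions are named "SS" and "CD45" in the provenance.
    """
    if n_total < 4:
        raise ValueError("n_total must be >= 4")
    means = _FACS_MEANS if means is None else np.asarray(means, dtype=float)
    covs = _FACS_COVS if covs is None else np.asarray(covs, dtype=float)
    weights = (
        _FACS_WEIGHTS if weights is None else np.asarray(weights, dtype=float)
    )
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("component weights must sum to 1 within 1e-9")
    if not (len(means) == len(covs) == len(weights)):
        raise ValueError("means, covs and weights must have equal length")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n_total, p=weights)
    pts = np.empty((n_total, 2))
    for c in range(len(weights)):
        idx = np.flatnonzero(comp == c)
        if idx.size:
            pts[idx] = rng.multivariate_normal(
                means[c], covs[c], size=idx.size
            )
    return DataSet(
        points=pts,
        labels=comp,
        name="facs_gmm",
        provenance={
            "generator": "facs_gmm",
            "n_total": n_total,
            "seed": seed,
            "columns": ["SS", "CD45"],
            "weights": weights.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# CSV fixtures with manifest
# ---------------------------------------------------------------------------

def write_dataset(ds: DataSet, directory: str | Path, sep: str = ",") -> Path:
    """Write a data set as CSV (header row, optional 'label' column) plus a
    JSON manifest recording provenance and a checksum of the CSV bytes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = ds.provenance.get(
        "columns", [f"x{i + 1}" for i in range(ds.dim)]
    )
    frame = pd.DataFrame(ds.points, columns=list(cols))
    if ds.labels is not None:
        frame["label"] = ds.labels
    csv_path = directory / f"{ds.name}.csv"
    frame.to_csv(csv_path, sep=sep, index=False)
    digest = hashlib.sha256(csv_path.read_bytes()).hexdigest()
    manifest = {"name": ds.name, "provenance": ds.provenance, "sha256": digest}
    (directory / f"{ds.name}.manifest.json").write_text(
        json.dumps(manifest, indent=2)
    )
    return csv_path


def read_dataset(
    path: str | Path, label_column: str = "label", sep: str = ","
) -> DataSet:
    """Read a CSV written by :func:`write_dataset` (or any compatible CSV)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=sep)
    labels = None
    if label_column in frame.columns:
        labels = frame.pop(label_column).to_numpy(dtype=int)
    return DataSet(
        points=frame.to_numpy(dtype=float),
        labels=labels,
        name=path.stem,
        provenance={"source": str(path)},
    )
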