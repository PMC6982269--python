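"""Projection quality metrics: trustworthiness and continuity.

Trustworthiness penalizes *forward* projection errors — points that look
like neighbors in the embedding but are not neighbors in the original
space; continuity penalizes *backward* errors — original neighbors that the
embedding pulls apart.  Both follow the rank-based definition of Venna &
Kaski and map to [0, 1], with 1 for a projection that preserves all
k-neighborhoods.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .datasets import DataSet
from .projection import Projection
from .readout import ClusterReadout, label_agreement

__all__ = [
    "QualityReport",
    "rank_matrix",
    "trustworthiness",
    "continuity",
    "make_report",
    "write_reports",
]


def rank_matrix(points: np.ndarray) -> np.ndarray:
    """rank[i, j] = rank of j among i's neighbors by distance in ``points``
    (1 = nearest; ties broken by point index; diagonal set to 0)."""
    d = squareform(pdist(points))
    n = d.shape[0]
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")  # index tie-break
    ranks = np.empty((n, n), dtype=int)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, n + 1)[None, :]
    np.fill_diagonal(ranks, 0)
    return ranks


def _neighbor_sets(ranks: np.ndarray, k: int) -> np.ndarray:
    return ranks <= k  # boolean n x n: j in kNN(i)


def _penalty(ranks_src: np.ndarray, in_dst: np.ndarray, in_src: np.ndarray,
             k: int) -> float:
    """Sum over i of (rank_src(i,j) - k) for j in kNN_dst(i) \\ kNN_src(i)."""
    intruders = in_dst & ~in_src
    return float(np.sum((ranks_src - k)[intruders]))


def _normalizer(n: int, k: int) -> float:
    return 2.0 / (n * k * (2.0 * n - 3.0 * k - 1.0))


def trustworthiness(X: np.ndarray, Y: np.ndarray, k: int = 12) -> float:
    """1 minus the normalized rank penalty of embedding-only neighbors."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n = X.shape[0]
    if not 1 <= k < n / 2:
        raise ValueError("require 1 <= k < n/2")
    ranks_x = rank_matrix(X)
    in_x = _neighbor_sets(ranks_x, k)
    in_y = _neighbor_sets(rank_matrix(Y), k)
    return 1.0 - _normalizer(n, k) * _penalty(ranks_x, in_y, in_x, k)


def continuity(X: np.ndarray, Y: np.ndarray, k: int = 12) -> float:
    """Mirror image of trustworthiness: penalizes original-space neighbors
    missing from the embedding neighborhood, ranked in the embedding."""
    return trustworthiness(Y, X, k)


@dataclass
class QualityReport:
    """Per-(dataset, method, seed) record of projection quality."""

    dataset: str
    method: str
    seed: Optional[int] = None
    k: int = 12
    trustworthiness: Optional[float] = None
    continuity: Optional[float] = None
    kl: Optional[float] = None
    n_clusters: Optional[int] = None
    ari: Optional[float] = None
    misassignment_rate: Optional[float] = None
    runtime_s: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("trustworthiness", "continuity"):
            v = getattr(self, name)
            if v is not None and not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QualityReport":
        return cls(**json.loads(text))


def write_reports(reports, jsonl_path, csv_path=None) -> None:
    """Persist a collection of reports as JSON lines and, optionally, a CSV
    summary table."""
    from pathlib import Path

    import pandas as pd

    reports = list(reports)
    Path(jsonl_path).write_text(
        "".join(r.to_json() + "\n" for r in reports)
    )
    if csv_path is not None:
        pd.DataFrame([asdict(r) for r in reports]).drop(
            columns=["extras"]
        ).to_csv(csv_path, index=False)


def make_report(
    dataset: DataSet,
    projection: Optional[Projection] = None,
    readout: Optional[ClusterReadout] = None,
    k: int = 12,
    runtime_s: Optional[float] = None,
) -> QualityReport:
    """Assemble a quality report; fields without a source stay ``None``."""
    method = "unknown"
    seed = None
    trust = cont = kl = None
    if projection is not None:
        if projection.n != dataset.n:
            raise ValueError("projection size does not match dataset")
        method = projection.method
        seed = projection.seed
        trust = trustworthiness(dataset.points, projection.coords, k)
        cont = continuity(dataset.points, projection.coords, k)
        if projection.method == "tsne":
            kl = projection.final_objective
    n_clusters = ari = mis = None
    if readout is not None:
        if len(readout.point_labels) != dataset.n:
            raise ValueError("readout size does not match dataset")
        if projection is None:
            method = readout.method
        n_clusters = readout.n_clusters
        if dataset.labels is not None:
            agree = label_agreement(readout, dataset.labels)
            ari = agree["ari"]
            mis = agree["misassignment_rate"]
    return QualityReport(
        dataset=dataset.name,
        method=method,
        seed=seed,
        k=k,
        trustworthiness=trust,
        continuity=cont,
        kl=kl,
        n_clusters=n_clusters,
        ari=ari,
        misassignment_rate=mis,
        runtime_s=runtime_s,
    )
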