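"""Shared container for 2-D embeddings produced by any projection method."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Projection", "write_projection", "read_projection"]


@dataclass
class Projection:
    """An n x 2 embedding with provenance.

    ``final_objective`` carries the method's terminal loss where one exists
    (KL divergence for t-SNE, reconstruction MSE for the autoencoder); it is
    ``None`` for closed-form methods such as PCA.
    """

    coords: np.ndarray
    method: str
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None
    final_objective: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain NaN/Inf")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def write_projection(proj: Projection, path: str | Path) -> Path:
    """Write coordinates as CSV with columns id, y1, y2."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "id": np.arange(proj.n),
            "y1": proj.coords[:, 0],
            "y2": proj.coords[:, 1],
        }
    )
    frame.to_csv(path, index=False)
    return path


def read_projection(path: str | Path, method: str = "file") -> Projection:
    frame = pd.read_csv(path)
    return Projection(
        coords=frame[["y1", "y2"]].to_numpy(dtype=float), method=method
    )
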