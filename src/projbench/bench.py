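"""Benchmark harness: multi-seed stability, method comparison, tuning study.

Reproduces the evaluation protocol of the projection-bias study: run a
projection method repeatedly with different seeds on a benchmark set, read
off the number of apparent clusters automatically, and quantify how the
readout disperses across seeds (a structure-less set read as >1 cluster on
some seeds is a spurious-structure signal).  A hyperparameter tuning study
checks whether settings tuned to one data set transfer to another.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import datasets as ds
from .baselines import AutoencoderConfig, autoencoder_project, pca_project
from .esom import TrainingSchedule, init_grid, project_bmus, train_esom
from .matrices import compute_pmatrix, compute_umatrix, compute_ustar
from .projection import Projection
from .quality import make_report
from .readout import ClusterReadout, density_clusters_2d, watershed_clusters
from .tsne import TsneConfig, tsne_embed

__all__ = [
    "BenchmarkSpec",
    "DATASET_GENERATORS",
    "make_dataset",
    "run_single",
    "run_stability_study",
    "run_method_comparison",
    "run_tuning_study",
    "crossover_flags",
]

log = logging.getLogger("projbench.bench")

DATASET_GENERATORS: dict[str, Callable[..., ds.DataSet]] = {
    "golfball": lambda seed=0, **kw: ds.generate_golfball(**kw),
    "chainlink": lambda seed=0, **kw: ds.generate_chainlink(seed=seed, **kw),
    "engytime": lambda seed=0, **kw: ds.generate_engytime(seed=seed, **kw),
    "lsun": lambda seed=0, **kw: ds.generate_lsun(seed=seed, **kw),
    "facs_gmm": lambda seed=0, **kw: ds.generate_facs_gmm(seed=seed, **kw),
}

KNOWN_METHODS = ("tsne", "pca", "autoencoder", "esom_u", "esom_ustar")


@dataclass
class BenchmarkSpec:
    """One benchmark cell: a data set, a method, seeds and readout settings."""

    dataset: str
    method: str
    dataset_params: dict = field(default_factory=dict)
    method_params: dict = field(default_factory=dict)
    seeds: Sequence[int] = (0,)
    readout_params: dict = field(default_factory=dict)
    data_seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dataset not in DATASET_GENERATORS:
            raise ValueError(f"unknown dataset {self.dataset!r}")
        if self.method not in KNOWN_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.seeds) < 1:
            raise ValueError("need at least one seed")


def make_dataset(name: str, params: Optional[dict] = None, seed: int = 0) -> ds.DataSet:
    return DATASET_GENERATORS[name](seed=seed, **(params or {}))


def _zscore(data: ds.DataSet) -> ds.DataSet:
    sd = data.points.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return ds.DataSet(
        points=(data.points - data.points.mean(axis=0)) / sd,
        labels=data.labels,
        name=data.name,
        provenance={**data.provenance, "zscored": True},
    )


def _run_esom(
    data: ds.DataSet, method: str, params: dict, seed: int, readout_params: dict
) -> tuple[ClusterReadout, dict]:
    params = dict(params)
    rows = params.pop("rows", 50)
    cols = params.pop("cols", 80)
    zscore = params.pop("zscore", False)
    sched = TrainingSchedule(seed=seed, **params)
    fit_data = _zscore(data) if zscore else data
    grid = init_grid(fit_data, rows=rows, cols=cols, seed=seed)
    grid = train_esom(fit_data, grid, sched)
    assignment = project_bmus(grid, fit_data)
    u = compute_umatrix(grid)
    if method == "esom_ustar":
        p = compute_pmatrix(grid, fit_data, radius="auto", seed=seed)
        height = compute_ustar(u, p)
    else:
        height = u
    readout = watershed_clusters(height, assignment, **readout_params)
    return readout, {"rows": rows, "cols": cols, "epochs": sched.epochs}


def _run_projection(
    data: ds.DataSet, method: str, params: dict, seed: int
) -> Projection:
    if method == "tsne":
        return tsne_embed(data, TsneConfig(seed=seed, **params))
    if method == "pca":
        return pca_project(data)
    if method == "autoencoder":
        return autoencoder_project(data, AutoencoderConfig(seed=seed, **params))
    raise ValueError(f"unknown projection method {method!r}")


def run_single(
    spec: BenchmarkSpec, seed: int, quality_k: Optional[int] = 12
) -> dict:
    """Execute one (dataset, method, seed) cell and return a summary row."""
    data = make_dataset(spec.dataset, spec.dataset_params, seed=spec.data_seed)
    t0 = time.perf_counter()
    row: dict = {
        "dataset": spec.dataset,
        "method": spec.method,
        "seed": seed,
        "n": data.n,
        "error": "",
        "n_clusters": None,
        "ari": None,
        "misassignment_rate": None,
        "trustworthiness": None,
        "continuity": None,
        "kl": None,
    }
    try:
        if spec.method.startswith("esom"):
            readout, meta = _run_esom(
                data, spec.method, spec.method_params, seed, spec.readout_params
            )
            report = make_report(data, readout=readout)
            row.update(meta)
        else:
            proj = _run_projection(data, spec.method, spec.method_params, seed)
            readout = density_clusters_2d(proj, **spec.readout_params)
            if quality_k is not None and quality_k < data.n / 2:
                report = make_report(data, projection=proj, readout=readout,
                                     k=quality_k)
            else:
                report = make_report(data, readout=readout)
        row.update(
            n_clusters=report.n_clusters,
            ari=report.ari,
            misassignment_rate=report.misassignment_rate,
            trustworthiness=report.trustworthiness,
            continuity=report.continuity,
            kl=report.kl,
        )
    except Exception as exc:  # per-row failure must not kill a study
        log.warning("run failed (%s/%s seed=%d): %s",
                    spec.dataset, spec.method, seed, exc)
        row["error"] = f"{type(exc).__name__}: {exc}"
    row["runtime_s"] = time.perf_counter() - t0
    row["provenance"] = repr(
        {
            "dataset_params": spec.dataset_params,
            "method_params": spec.method_params,
            "readout_params": spec.readout_params,
            "data_seed": spec.data_seed,
        }
    )
    return row


def run_stability_study(
    spec: BenchmarkSpec, quality_k: Optional[int] = 12
) -> pd.DataFrame:
    """One row per seed plus dispersion bookkeeping in ``DataFrame.attrs``.

    ``attrs["distinct_cluster_counts"]`` holds the sorted set of observed
    cluster counts — its size is the seed-instability signal.
    """
    rows = [run_single(spec, seed, quality_k=quality_k) for seed in spec.seeds]
    table = pd.DataFrame(rows)
    ok = table[table["error"] == ""]
    counts = sorted(int(c) for c in ok["n_clusters"].dropna().unique())
    table.attrs["distinct_cluster_counts"] = counts
    table.attrs["modal_n_clusters"] = (
        int(ok["n_clusters"].mode().iloc[0]) if len(ok) else None
    )
    return table


def run_method_comparison(
    specs: Iterable[BenchmarkSpec],
    output_dir: Optional[str | Path] = None,
    quality_k: Optional[int] = 12,
) -> pd.DataFrame:
    """Cross product over the given specs; one summary row per run."""
    frames = []
    for spec in specs:
        log.info("running %s x %s (%d seeds)", spec.dataset, spec.method,
                 len(spec.seeds))
        frames.append(run_stability_study(spec, quality_k=quality_k))
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["dataset", "method", "seed", "n", "n_clusters", "error"]
        )
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "summary.csv", index=False)
        with open(out / "reports.jsonl", "w") as fh:
            for row in table.to_dict(orient="records"):
                fh.write(json.dumps(row, default=str) + "\n")
    return table


def crossover_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Flag hyperparameter cells that read dataset A correctly but B wrongly.

    Expects columns: cell (hashable id), dataset, n_clusters, true_clusters,
    skipped.  Returns one row per cell with correctness per dataset and the
    crossover flag (evidence that tuning does not transfer).
    """
    out = []
    for cell, grp in table.groupby("cell", sort=True):
        rec: dict = {"cell": cell}
        names = list(grp["dataset"])
        correct = {}
        for _, r in grp.iterrows():
            correct[r["dataset"]] = (
                (not r.get("skipped", False))
                and r["n_clusters"] == r["true_clusters"]
            )
        if len(names) >= 2:
            a, b = names[0], names[1]
            rec["correct_a"] = bool(correct[a])
            rec["correct_b"] = bool(correct[b])
            rec["crossover"] = bool(correct[a] and not correct[b])
        out.append(rec)
    return pd.DataFrame(out)


def run_tuning_study(
    dataset_a: ds.DataSet,
    dataset_b: ds.DataSet,
    hyper_grid: Sequence[dict],
    seed: int = 0,
    readout_params: Optional[dict] = None,
    base_config: Optional[dict] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """t-SNE hyperparameter grid (perplexity, initial_dims) on two data sets.

    Returns (per-run table, crossover table).  Grid cells where perplexity
    is infeasible (>= n) for a data set are skipped and flagged.
    """
    readout_params = readout_params or {}
    base_config = base_config or {}
    rows = []
    for cell_id, cell in enumerate(hyper_grid):
        for name, data in (("a", dataset_a), ("b", dataset_b)):
            truth = (
                len(np.unique(data.labels[data.labels >= 0]))
                if data.labels is not None
                else 1
            )
            rec = {
                "cell": cell_id,
                "dataset": f"{name}:{data.name}",
                "perplexity": cell.get("perplexity"),
                "initial_dims": cell.get("initial_dims"),
                "true_clusters": truth,
                "skipped": False,
                "n_clusters": None,
            }
            if cell.get("perplexity", 30) >= data.n:
                rec["skipped"] = True
                rows.append(rec)
                continue
            cfg = TsneConfig(seed=seed, **{**base_config, **cell})
            proj = tsne_embed(data, cfg)
            readout = density_clusters_2d(proj, **readout_params)
            rec["n_clusters"] = readout.n_clusters
            rec["kl"] = proj.final_objective
            rows.append(rec)
    table = pd.DataFrame(rows)
    return table, crossover_flags(table)
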