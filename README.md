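# projbench

Stress-testing toolkit for 2-D projection methods used in subgroup
discovery on high-dimensional, cytometry-like data.

Dimensionality-reduction scatter plots drive gating and subgroup calls in
computational cytometry (and, increasingly, transcriptomics). But a
projection can *invent* structure: run t-SNE twice on perfectly homogeneous
data and you may get two different "cluster" pictures. `projbench` is built
for methodologists and analysts who want to quantify that risk. It
provides:

* **Exact t-SNE**, written from first principles: per-point Gaussian
  bandwidths σᵢ calibrated by entropy so that
  `H(p(·|i)) = log₂(perplexity)`, Student-t low-dimensional affinities
  `q_ij ∝ (1+‖y_i−y_j‖²)⁻¹`, and gradient descent on the asymmetric
  Kullback–Leibler divergence `KL(P‖Q) = Σ_{i≠j} p_ij log(p_ij/q_ij)`.
* **Emergent self-organizing maps (ESOM)**: online Kohonen learning
  `Δw = η(t)·h(bmu, i, r(t))·(x − w)` on a 50×80 toroidal lattice, read out
  through **U-matrix** (summed weight distances to lattice neighbors —
  ridges mark cluster borders), **P-matrix** (data density at each neuron)
  and **U\*-matrix** (density-damped U) landscapes.
* **Synthetic benchmarks** with ground truth by construction: a 4002-point
  geodesic-sphere "golf ball" (guaranteed structure-less), Chainlink,
  EngyTime and Lsun in the style of the Fundamental Clustering Problems
  Suite, and a four-mode SS/CD45 Gaussian-mixture FACS surrogate.
* **Automatic cluster readouts** (watershed flooding of U*-landscapes;
  self-calibrated DBSCAN on scatters), **quality metrics**
  (trustworthiness/continuity), PCA and bottleneck-autoencoder baselines,
  and a **multi-seed benchmark harness** with a hyperparameter cross-over
  study.

See `docs/methods.md` for the full model descriptions, parameter defaults
and design rationale.

## Worked example

Does the ESOM/U* readout see the golf ball as the single homogeneous cloud
it is, while t-SNE's answer depends on the seed?

```python
import projbench as pb

data = pb.generate_golfball(10)          # reduced golf ball: 1002 points

# ESOM -> U* landscape -> watershed readout, two seeds
for seed in (1, 2):
    grid = pb.init_grid(data, 50, 80, seed=seed)
    grid = pb.train_esom(data, grid, pb.TrainingSchedule(seed=seed))
    asg  = pb.project_bmus(grid, data)
    u    = pb.compute_umatrix(grid)
    p    = pb.compute_pmatrix(grid, data, "auto", seed=seed)
    ro   = pb.watershed_clusters(pb.compute_ustar(u, p), asg)
    print(f"ESOM/U* seed={seed}: {ro.n_clusters} cluster(s)")

# default t-SNE on the same data, two seeds
for seed in (1, 2):
    proj = pb.tsne_embed(data, pb.TsneConfig(seed=seed))
    ro   = pb.density_clusters_2d(proj)
    print(f"t-SNE   seed={seed}: {ro.n_clusters} cluster(s), "
          f"KL={proj.final_objective:.3f}")
```

Output:

```
ESOM/U* seed=1: 1 cluster(s)
ESOM/U* seed=2: 1 cluster(s)
t-SNE   seed=1: 1 cluster(s), KL=0.847
t-SNE   seed=2: 2 cluster(s), KL=0.829
```

The ESOM/U* pipeline reports one cluster on both seeds — correct, the data
have no subgroups. t-SNE converges to a different local minimum per seed
(the KL values differ) and the seed-2 embedding splits the homogeneous
sphere into two apparent groups: projection-induced structure, not data
structure. On the labeled benchmarks the same pipeline recovers the true
counts (3 on Lsun, 2 on Chainlink, 2 on EngyTime) as the modal readout
across seeds; the density-separated EngyTime boundary sits at the automatic
readout's detection limit, so its per-seed readout fluctuates and only the
modal value is stable (see `docs/methods.md`, Known limitations).

## Command line

```bash
projbench tsne --input data.csv --perplexity 30 --seed 42 --output proj.csv
projbench esom train --input data.csv --rows 50 --cols 80 --epochs 20 \
    --seed 42 --output grid.npz
projbench esom project --grid grid.npz --input data.csv --output bmus.csv
projbench bench --config bench.yaml     # datasets x methods x seeds study
```

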