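# Methods

`projbench` stress-tests 2-D projection methods used for subgroup discovery
in high-dimensional cytometry-like data. It pairs a stochastic,
neighborhood-focusing embedding (t-SNE) with a topology-preserving
alternative (an emergent self-organizing map read out through U-matrix
landscapes), runs both on synthetic benchmarks whose ground truth is known
by construction, and quantifies when each method invents, merges or splits
subgroups.

## t-SNE

High-dimensional affinities are conditional Gaussians
`p(j|i) ∝ exp(−‖x_i−x_j‖² / 2σ_i²)` with the per-point bandwidth σ_i chosen
so the Shannon entropy of `p(·|i)` equals `log2(perplexity)`. The
calibration is a bisection in log σ over σ ∈ [1e−20, 1e20], at most 50
iterations, entropy tolerance 1e−5 bits; an unreachable target (possible
only in degenerate neighborhoods, e.g. a single neighbor) produces a
warning and the best bandwidth found. Conditionals are symmetrized to the
joint `p_ij = (p(j|i)+p(i|j)) / 2n`. Low-dimensional affinities use the
Student-t kernel with one degree of freedom,
`q_ij ∝ (1+‖y_i−y_j‖²)^{-1}`, normalized over all pairs. The objective is
the asymmetric Kullback–Leibler divergence `KL(P‖Q) = Σ p_ij log(p_ij/q_ij)`
(natural log); `q` is floored at 1e−12 inside the objective and gradient so
`log 0` never occurs, while the stored affinity matrices remain exactly
normalized (the matrix invariants — symmetry, zero diagonal, grand sum 1 —
are enforced at construction).

The optimizer is plain gradient descent with the classic reference
schedule: learning rate 100, momentum 0.5 switching to 0.8 at iteration
250, per-coordinate adaptive gains (×1.2 on sign agreement via +0.2, ×0.8
otherwise, floored at 0.01), early exaggeration ×4 for the first 100 of
1000 iterations, initialization `y ~ N(0, 1e−4)` from the run seed, and
optional PCA pre-reduction to `initial_dims` (default 30; skipped when the
data have fewer dimensions). Everything is exact O(n²) — no Barnes–Hut or
interpolation — because every benchmark here has n ≤ ~5000. The embedding
is deterministic given (data, config, seed); across seeds it is not, which
is exactly the property the stability study measures.

## ESOM and the U/P/U* landscapes

The ESOM is a Kohonen map on a 50×80 toroidal lattice (4000 neurons — an
order of magnitude more than any expected cluster count, so structure can
emerge as multi-neuron patterns). Weights initialize uniformly inside the
per-column data range. Training is online: per epoch every point is
presented in a fresh seeded order, its best-matching unit (BMU) is the
weight-nearest neuron (ties to the first in row-major order), and all
neurons move by

    Δw = η(t) · exp(−g² / 2r(t)²) · (x − w)

where g is the wrapped lattice distance to the BMU. Both η (0.5 → 0.1) and
r (24 → 2) decay linearly per epoch over 20 epochs. Two deliberate
choices:

* **Toroidal topology.** Wraparound removes lattice borders; on planar maps
  border compression fabricates peripheral clusters. Planar remains
  available via configuration.
* **Final radius 2, not 1.** With r(end)=1 the converged map can fold
  sharply enough that a single cluster's lattice band touches itself across
  a crease; the crease shows up as a high U-ridge inside one cluster and
  the readout splits it. r(end)=2 keeps the map locally smooth; we observed
  markedly more stable cluster counts on the ring-shaped benchmark at this
  setting while the separated-cluster benchmarks were unaffected.

The **U-matrix** assigns each neuron the sum of data-space distances from
its weight to its 8 lattice neighbors (4-neighborhood available); ridges
mark jumps across empty data space. The **P-matrix** counts data points
within a radius of each neuron's weight; the default radius is the 20th
percentile of pairwise distances in a seeded subsample of ≤2000 points
(counts, not kernel densities, for testability). The **U\*-matrix** damps
U-heights where the data are dense: `u*(i) = u(i)·f(p(i))` with f linear,
f=1 at the P median, f=0 at the P maximum, clipped to [0,1] (f≡1 when
median = max). Dense regions cannot host real cluster borders, so their
apparent walls are suppressed; sparse regions keep theirs.

## Automatic cluster readouts

The original workflow counts clusters by eye; reproducible evaluation needs
a deterministic stand-in, so two parameter-light readouts are defined.

**Watershed on landscapes.** An immersion watershed (ascending sweep,
union-find, toroidal 8-connectivity) partitions the landscape into basins
and records the minimal saddle height between every adjacent basin pair.
Basins then merge bottom-up while the *dynamics* of the weakest wall —
saddle height minus the shallower basin's floor — is below
`depth_frac × (max(H) − min(H))`. depth_frac defaults to 0.15: on
constructed profiles a wall must rise at least 15% of the total relief
above a basin floor to count as real, which merges the shallow rumple of a
homogeneous landscape while preserving the deep walls of genuinely
separated clusters. Points inherit their BMU's basin; basins holding fewer
than `min_cluster_frac` (2%) of points are absorbed across their lowest
saddle. A perfectly flat landscape is one cluster by definition.

**Density clustering of scatters.** DBSCAN on the 2-D coordinates with
`min_samples = k = max(5, round(0.5·√n))` and eps at the knee (maximum
chord gap) of the sorted k-distance curve; clusters below 2% of points are
demoted to noise. Deterministic given coordinates, and invariant to rigid
motions of the embedding since only inter-point distances enter.

**Agreement scores.** Adjusted Rand index over non-noise points, plus a
misassignment rate from Hungarian matching of clusters to classes (the
fraction of non-noise points outside matched cells). With a single cluster
against two classes this degenerates to ARI 0 and misassignment = minority
fraction, as it should.

## Quality metrics

Trustworthiness and continuity follow the rank-based Venna–Kaski
definitions: trustworthiness penalizes points that enter a k-neighborhood
only in the embedding (penalty = their high-dimensional rank excess over
k), continuity penalizes original neighbors the embedding expels (ranked in
the embedding), both normalized to [0,1]. Rank ties break by point index —
immaterial for continuous data. Default k = 12, roughly twice the lattice
neighborhood scale of the geodesic benchmark; k is configurable everywhere.

## Baselines

PCA projects centered data onto the top-2 eigenvectors of the covariance,
with signs fixed so each component's largest-magnitude loading is positive.
The autoencoder is a D-5-2-5-D feedforward net, logistic sigmoid on every
layer, trained by seeded mini-batch backpropagation on squared
reconstruction error; inputs are min-max scaled into [0.1, 0.9] because
sigmoid outputs cannot reach 0/1. Defaults: 500 epochs, learning rate 0.05,
batch 32. The 2-neuron bottleneck activations are the projection.

## Synthetic benchmarks — what they emulate and what they do not

* **Golf ball** (default 4002 points): icosahedral geodesic subdivision of
  the unit sphere at frequency ν (count 10ν²+2; ν=20 by default). This is
  the unique standard construction matching both the count and the
  "six nearest neighbors" description: every point except the 12 original
  icosahedron vertices (which have 5) has exactly 6 lattice neighbors, read
  tolerance-free off the convex hull. Neighbor distances are only
  *approximately* equal (within ~18% per point) — exact equidistance of
  4000+ points on a sphere is geometrically impossible. Deterministic, no
  seed. It emulates "structure-less" data with a hard guarantee of no
  subgroups.
* **Chainlink** (2×500): two unit circles in orthogonal planes, centers
  offset by 1 so the rings interlock; uniform angles, Gaussian jitter
  (sd 0.05). The minimal inter-ring distance is exactly 1 at zero noise —
  distance-separated, not linearly separable.
* **EngyTime** (4096): equal-weight 2-D Gaussian mixture, one tight
  circular component (sd 0.3) at (1.3, 1.3) and one broad correlated
  component at the origin; supports overlap, so the boundary is visible in
  density, not distance.
* **Lsun** (400): two uniform strips forming an "L" plus a Gaussian ball,
  all with clear gaps — the easy, distance-separated case.
* **FACS surrogate** (5000): a four-mode 2-D Gaussian mixture over
  dimensions named SS and CD45, sketching the canonical leukocyte scatter;
  two mononuclear modes sit close enough to merge under a poor projection.
  Means, covariances and weights are configuration, documented surrogates
  for the real patient data this toolkit deliberately does not ship.

These sets share the *topology* and density contrasts of their archetypes,
not exact coordinates. They are clean, low-dimensional and free of the
spillover, compensation artifacts, heavy tails and batch effects of real
cytometry, so passing benchmarks here demonstrates correct behavior of the
projections and readouts on known structure — not performance on real
patient data.

## Benchmark harness

The stability study runs one (dataset, method) cell across a seed list and
reports per-seed cluster counts, ARI, trustworthiness/continuity and KL,
plus the set of distinct cluster counts observed — the dispersion of that
set across seeds is the spurious-structure signal for a structure-less
input. The method comparison crosses datasets × methods; failures flag
their row and the run continues. The tuning study evaluates a
(perplexity, initial_dims) grid on two data sets and flags *crossover*
cells — settings that read data set A correctly while misreading B —
operationalizing the observation that t-SNE tuning does not transfer
between data sets. Infeasible cells (perplexity ≥ n) are skipped and
flagged. Benchmark-scale runs use a reduced golf ball (ν=10, 1002 points)
and exact t-SNE; ν=20 is the full-scale profile.

## Numerical and edge-case conventions

* Affinity floors (1e−12) only inside objective/gradient; stored matrices
  exactly normalized (grand sum within 1e−9, symmetry within 1e−12).
* BMU and watershed ties break to the first index in row-major order.
* Watershed on a flat landscape returns one cluster, not an error; a P
  landscape with median = max leaves U* = U.
* DBSCAN eps falls back to the smallest positive k-distance when the knee
  lands on zero; all-coincident coordinates are a single cluster.
* NaN/Inf anywhere in gradients or weights aborts with a diagnostic naming
  the iteration/epoch and learning rate.
* Every stochastic routine takes one explicit integer seed and owns a
  single `numpy.random.Generator`; nothing touches global RNG state.

## Known limitations

* Exact t-SNE is O(n²) memory and time; ~20k points is a practical ceiling.
* The watershed depth_frac (0.15) and the DBSCAN k-rule are heuristics
  calibrated on these benchmark families; density boundaries whose relative
  relief sits near depth_frac are at the detection limit. On EngyTime-like
  data a *single* ESOM run reads one or two clusters with roughly even
  odds — only the modal count across several seeds is a meaningful readout
  there, whereas distance-separated clusters (Lsun, Chainlink) and the
  homogeneous control are read stably per run.
* The P-matrix uses hard counts; for very small data sets the landscape is
  step-valued.
* The autoencoder is a faithful small-net reconstruction baseline, not a
  competitive modern autoencoder; with default epochs it may underfit data
  needing a strongly nonlinear code.
* FCS file ingestion is out of scope; input is CSV/TSV.
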