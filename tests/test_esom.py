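"""ESOM lattice, BMU search and training against brute-force oracles."""

import warnings

import numpy as np
import pytest

import projbench as pb
from projbench.esom import _base_kernel, grid_distance_sq


def brute_force_bmu(grid, x):
    best = None
    for r in range(grid.rows):
        for c in range(grid.cols):
            d = np.linalg.norm(grid.weights[r, c] - x)
            if best is None or d < best[0]:
                best = (d, r, c)
    return best[1], best[2]


def brute_force_wrap_distance_sq(r1, c1, r2, c2, rows, cols):
    """Shortest wrapped lattice distance by scanning all nine images."""
    best = np.inf
    for dr in (-rows, 0, rows):
        for dc in (-cols, 0, cols):
            d = (r1 - r2 + dr) ** 2 + (c1 - c2 + dc) ** 2
            best = min(best, d)
    return best


@pytest.fixture
def small_grid():
    data = pb.generate_lsun(60, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pb.init_grid(data, rows=6, cols=6, seed=2), data


class TestInitGrid:
    def test_default_grid_is_50x80(self):
        data = pb.generate_lsun(30, seed=0)
        grid = pb.init_grid(data, seed=0)
        assert grid.rows * grid.cols == 4000

    def test_weights_within_data_range(self, small_grid):
        grid, data = small_grid
        lo, hi = data.points.min(axis=0), data.points.max(axis=0)
        assert np.all(grid.weights >= lo) and np.all(grid.weights <= hi)

    def test_deterministic(self):
        data = pb.generate_lsun(30, seed=0)
        a = pb.init_grid(data, seed=5)
        b = pb.init_grid(data, seed=5)
        assert np.array_equal(a.weights, b.weights)

    def test_small_grids_warn_not_error(self):
        data = pb.generate_lsun(30, seed=0)
        with pytest.warns(UserWarning, match="emergent"):
            pb.init_grid(data, rows=5, cols=5, seed=0)


class TestBmu:
    def test_exact_weight_match(self, small_grid):
        grid, _ = small_grid
        x = grid.weights[3, 5].copy()
        assert pb.best_matching_unit(grid, x) == (3, 5)

    def test_nearer_neuron_wins(self):
        grid = pb.EsomGrid(
            weights=np.array([[[0.0], [10.0]]]), topology="planar"
        )
        assert pb.best_matching_unit(grid, np.array([1.0])) == (0, 0)

    def test_matches_exhaustive_scan(self, small_grid):
        grid, _ = small_grid
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.uniform(-1, 6, size=grid.dim)
            assert pb.best_matching_unit(grid, x) == brute_force_bmu(grid, x)

    def test_dimension_mismatch_rejected(self, small_grid):
        grid, _ = small_grid
        with pytest.raises(ValueError):
            pb.best_matching_unit(grid, np.zeros(grid.dim + 1))


class TestGridDistance:
    def test_toroidal_wraparound_against_oracle(self):
        rows, cols = 5, 7
        for r1 in range(rows):
            for c1 in range(cols):
                for r2 in range(rows):
                    for c2 in range(cols):
                        got = grid_distance_sq(
                            r1, c1, r2, c2, rows, cols, "toroidal"
                        )
                        ref = brute_force_wrap_distance_sq(
                            r1, c1, r2, c2, rows, cols
                        )
                        assert got == ref
                        # symmetry
                        assert got == grid_distance_sq(
                            r2, c2, r1, c1, rows, cols, "toroidal"
                        )

    def test_base_kernel_consistent_with_distance(self):
        rows, cols, radius = 5, 7, 2.5
        k = _base_kernel(rows, cols, radius, "toroidal")
        for r in range(rows):
            for c in range(cols):
                g2 = grid_distance_sq(0, 0, r, c, rows, cols, "toroidal")
                assert k[r, c] == pytest.approx(
                    np.exp(-g2 / (2 * radius**2)), rel=1e-12
                )


class TestTraining:
    def test_single_point_contraction(self):
        data = pb.DataSet(points=np.array([[2.0, -1.0]]), name="one")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            grid = pb.init_grid(data, rows=4, cols=4, seed=1)
            grid.weights += np.random.default_rng(0).normal(
                0, 1, grid.weights.shape
            )
            dists = []
            g = grid
            for epoch in range(5):
                g = pb.train_esom(
                    data, g,
                    pb.TrainingSchedule(
                        epochs=1, radius_start=1.0, radius_end=1.0, seed=0
                    ),
                )
                r, c = pb.best_matching_unit(g, data.points[0])
                dists.append(np.linalg.norm(g.weights[r, c] - data.points[0]))
        assert all(b < a for a, b in zip(dists, dists[1:]))

    def test_one_step_hand_update(self):
        """One update on a 2x2 torus, eta=0.5, radius=1: every neuron moves
        by eta * exp(-g^2/2) * (x - w), evaluated by hand."""
        weights = np.array(
            [[[0.0, 0.0], [1.0, 0.0]], [[0.0, 1.0], [1.0, 1.0]]]
        )
        x = np.array([0.2, 0.1])
        data = pb.DataSet(points=x[None, :], name="single")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            grid = pb.EsomGrid(weights=weights.copy(), topology="toroidal")
            sched = pb.TrainingSchedule(
                epochs=1, lr_start=0.5, lr_end=0.5,
                radius_start=1.0, radius_end=1.0, seed=0,
            )
            trained = pb.train_esom(data, grid, sched)
        # BMU is (0,0); wrapped lattice distances g^2: 0, 1, 1, 2
        g2 = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}
        for (r, c), g in g2.items():
            h = np.exp(-g / 2.0)
            expected = weights[r, c] + 0.5 * h * (x - weights[r, c])
            assert np.allclose(trained.weights[r, c], expected, atol=1e-12)
        # BMU moved exactly halfway toward the point
        assert np.allclose(trained.weights[0, 0], 0.5 * x, atol=1e-12)

    def test_reproducible_bit_for_bit(self, two_blob_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            grid = pb.init_grid(two_blob_dataset, rows=10, cols=12, seed=4)
            sched = pb.TrainingSchedule(epochs=3, radius_start=5, seed=4)
            a = pb.train_esom(two_blob_dataset, grid, sched)
            b = pb.train_esom(two_blob_dataset, grid, sched)
        assert np.array_equal(a.weights, b.weights)

    def test_two_blobs_occupy_disjoint_grid_regions(
        self, two_blob_dataset, trained_blob_grid
    ):
        _, trained = trained_blob_grid
        asg = pb.project_bmus(trained, two_blob_dataset)
        flat = asg.rows * trained.cols + asg.cols
        neurons0 = set(flat[two_blob_dataset.labels == 0])
        neurons1 = set(flat[two_blob_dataset.labels == 1])
        assert not neurons0 & neurons1

    @pytest.mark.parametrize(
        "make",
        [
            lambda: pb.generate_golfball(5),
            lambda: pb.generate_chainlink(100, seed=3),
            lambda: pb.generate_lsun(200, seed=3),
        ],
        ids=["golfball", "chainlink", "lsun"],
    )
    def test_training_reduces_quantization_error(self, make):
        data = make()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            grid = pb.init_grid(data, rows=20, cols=25, seed=7)
            trained = pb.train_esom(
                data, grid,
                pb.TrainingSchedule(
                    epochs=10, radius_start=5, radius_end=1, seed=7
                ),
            )
        before = pb.mean_quantization_error(grid, data)
        after = pb.mean_quantization_error(trained, data)
        assert after < before


class TestProjectBmus:
    def test_zero_qe_for_points_equal_to_weights(self, trained_blob_grid):
        _, trained = trained_blob_grid
        sub = trained.weights[2:5, 3:6].reshape(-1, trained.dim)
        data = pb.DataSet(points=sub, name="weights_subset")
        asg = pb.project_bmus(trained, data)
        assert np.allclose(asg.quantization_errors, 0.0, atol=1e-12)

    def test_permutation_equivariance(self, two_blob_dataset, trained_blob_grid):
        _, trained = trained_blob_grid
        asg = pb.project_bmus(trained, two_blob_dataset)
        perm = np.random.default_rng(1).permutation(two_blob_dataset.n)
        permuted = pb.DataSet(
            points=two_blob_dataset.points[perm], name="permuted"
        )
        asg_p = pb.project_bmus(trained, permuted)
        assert np.array_equal(asg_p.rows, asg.rows[perm])
        assert np.array_equal(asg_p.cols, asg.cols[perm])

    def test_matches_bruteforce_oracle(self, small_grid):
        grid, data = small_grid
        asg = pb.project_bmus(grid, data)
        for i in range(0, data.n, 7):
            assert (asg.rows[i], asg.cols[i]) == brute_force_bmu(
                grid, data.points[i]
            )

    def test_dimension_mismatch_rejected(self, small_grid):
        grid, _ = small_grid
        bad = pb.DataSet(points=np.zeros((3, grid.dim + 2)), name="bad")
        with pytest.raises(ValueError):
            pb.project_bmus(grid, bad)
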