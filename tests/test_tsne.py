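"""t-SNE affinities, objective and optimizer against independent oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

import projbench as pb
from projbench.tsne import AffinityMatrix, tsne_gradient


def grid_search_affinities(points, perplexity, n_grid=20001):
    """Independent oracle: solve each sigma_i by dense grid search over
    log-spaced bandwidths, then symmetrize exactly as the contract states."""
    points = np.asarray(points, float)
    n = len(points)
    d2 = squareform(pdist(points, "sqeuclidean"))
    target = np.log2(perplexity)
    sigmas = np.logspace(-8, 8, n_grid)
    cond = np.zeros((n, n))
    for i in range(n):
        others = np.arange(n) != i
        best, best_p = np.inf, None
        for s in sigmas:
            w = np.exp(-d2[i, others] / (2 * s * s))
            if w.sum() <= 0:
                continue
            p = w / w.sum()
            nz = p > 0
            h = -np.sum(p[nz] * np.log2(p[nz]))
            if abs(h - target) < best:
                best, best_p = abs(h - target), p
        cond[i, others] = best_p
    p = (cond + cond.T) / (2 * n)
    np.fill_diagonal(p, 0.0)
    return p / p.sum()


class TestHighdimAffinities:
    def test_two_points_forced_to_half(self):
        # with a single neighbor the entropy target is unreachable; the
        # contract is a warning plus the best bandwidth found
        with pytest.warns(RuntimeWarning, match="calibration"):
            p = pb.highdim_affinities(np.array([[0.0], [5.0]]), 1.5).probs
        assert p[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert p[1, 0] == pytest.approx(0.5, abs=1e-12)

    def test_three_equidistant_points_uniform(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        p = pb.highdim_affinities(pts, 2.0).probs
        off = p[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1 / 6, atol=1e-9)

    def test_five_point_line_matches_grid_search_oracle(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.0], [10.0]])
        ours = pb.highdim_affinities(pts, 2.0).probs
        oracle = grid_search_affinities(pts, 2.0)
        assert np.allclose(ours, oracle, atol=1e-4)

    def test_row_entropies_hit_perplexity_target(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.0], [10.0]])
        p = pb.highdim_affinities(pts, 2.0).probs
        # recover conditionals: p_cond rows were entropy-calibrated
        n = len(pts)
        d2 = squareform(pdist(pts, "sqeuclidean"))
        # re-run the internal calibration through the public result is not
        # possible; check the conditional construction directly instead
        from projbench.tsne import _calibrate_row

        for i in range(n):
            others = np.arange(n) != i
            cond = _calibrate_row(d2[i, others], 2.0)
            h = -np.sum(cond[cond > 0] * np.log2(cond[cond > 0]))
            assert h == pytest.approx(np.log2(2.0), abs=1e-4)

    def test_rejects_bad_perplexity(self):
        pts = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            pb.highdim_affinities(pts, 5.0)

    def test_invariants_on_random_data(self):
        pts = np.random.default_rng(1).normal(size=(20, 3))
        aff = pb.highdim_affinities(pts, 5.0)
        aff.validate()  # symmetric, normalized, zero diagonal


class TestLowdimAffinities:
    def test_two_points(self):
        q = pb.lowdim_affinities(np.array([[0.0, 0.0], [3.0, 4.0]])).probs
        assert q[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_equilateral_triangle_uniform(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        q = pb.lowdim_affinities(pts).probs
        assert np.allclose(q[~np.eye(3, dtype=bool)], 1 / 6, atol=1e-12)

    def test_collinear_points_exact_rational_values(self):
        # kernel for points 0,1,2,3 on a line: k(d^2) = 1/(1+d^2)
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        k = {1: Fraction(1, 2), 4: Fraction(1, 5), 9: Fraction(1, 10)}
        pairs = {
            (0, 1): k[1], (1, 2): k[1], (2, 3): k[1],
            (0, 2): k[4], (1, 3): k[4], (0, 3): k[9],
        }
        total = 2 * sum(pairs.values())
        q = pb.lowdim_affinities(pts).probs
        for (i, j), kv in pairs.items():
            expected = float(kv / total)
            assert q[i, j] == pytest.approx(expected, rel=1e-12)
            assert q[j, i] == pytest.approx(expected, rel=1e-12)


class TestKlDivergence:
    def test_identity_is_zero(self):
        pts = np.random.default_rng(2).normal(size=(8, 2))
        q = pb.lowdim_affinities(pts)
        assert pb.kl_divergence(
            AffinityMatrix(q.probs, "highdim_P"), q
        ) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy(self):
        p = np.array([[0.0, 0.4], [0.6, 0.0]])
        p = (p + p.T) / 2  # symmetrize -> 0.5/0.5
        q = np.array([[0.0, 0.3], [0.3, 0.0]])
        q = q / q.sum()
        P = AffinityMatrix(p, "highdim_P")
        Q = AffinityMatrix(q, "lowdim_Q")
        expected = 2 * 0.5 * np.log(0.5 / 0.5)  # equals 0 here
        assert pb.kl_divergence(P, Q) == pytest.approx(expected, abs=1e-12)
        # asymmetric q
        q2 = np.array([[0.0, 0.2], [0.8, 0.0]])
        # not symmetric -> construct via direct summation oracle on floored q
        expected2 = 0.5 * np.log(0.5 / 0.2) + 0.5 * np.log(0.5 / 0.8)
        s = sum(
            p[i][j] * np.log(p[i][j] / q2[i][j])
            for i in range(2)
            for j in range(2)
            if i != j
        )
        assert s == pytest.approx(expected2)

    def test_shape_mismatch_rejected(self):
        a = pb.lowdim_affinities(np.zeros((3, 2)) + np.arange(3)[:, None])
        b = pb.lowdim_affinities(np.zeros((4, 2)) + np.arange(4)[:, None])
        with pytest.raises(ValueError):
            pb.kl_divergence(AffinityMatrix(a.probs, "highdim_P"), b)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegativity_gibbs(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(7, 3))
        y = rng.normal(size=(7, 2))
        P = AffinityMatrix(
            pb.highdim_affinities(x, 3.0).probs, "highdim_P"
        )
        Q = pb.lowdim_affinities(y)
        assert pb.kl_divergence(P, Q) >= -1e-12


class TestGradientAndEmbedding:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 4))
        y = rng.normal(size=(10, 2))
        p = pb.highdim_affinities(x, 4.0).probs
        grad = tsne_gradient(p, y)

        def objective(flat):
            q = pb.lowdim_affinities(flat.reshape(10, 2))
            return pb.kl_divergence(AffinityMatrix(p, "highdim_P"), q)

        eps = 1e-6
        flat = y.ravel().copy()
        for idx in range(flat.size):
            up, dn = flat.copy(), flat.copy()
            up[idx] += eps
            dn[idx] -= eps
            fd = (objective(up) - objective(dn)) / (2 * eps)
            assert grad.ravel()[idx] == pytest.approx(
                fd, rel=1e-4, abs=1e-7
            )

    def test_embedding_deterministic_under_seed(self):
        data = pb.generate_lsun(60, seed=4)
        cfg = pb.TsneConfig(perplexity=10, max_iter=60, seed=11)
        a = pb.tsne_embed(data, cfg)
        b = pb.tsne_embed(data, cfg)
        assert np.array_equal(a.coords, b.coords)
        assert a.final_objective == b.final_objective

    def test_two_cluster_toy_beats_random_layouts(self):
        rng = np.random.default_rng(5)
        pts = np.vstack(
            [
                rng.normal(0.0, 0.3, size=(100, 5)),
                rng.normal(4.0, 0.3, size=(100, 5)),
            ]
        )
        data = pb.DataSet(points=pts, name="two_blobs_5d")
        proj = pb.tsne_embed(
            data, pb.TsneConfig(perplexity=20, max_iter=300, seed=1)
        )
        P = AffinityMatrix(
            pb.highdim_affinities(pts, 20.0).probs, "highdim_P"
        )
        random_kls = []
        for s in range(100):
            layout = np.random.default_rng(s).normal(size=(200, 2))
            random_kls.append(
                pb.kl_divergence(P, pb.lowdim_affinities(layout))
            )
        assert proj.final_objective < min(random_kls)

    def test_objective_tail_non_increasing(self):
        data = pb.generate_lsun(80, seed=6)
        proj = pb.tsne_embed(
            data, pb.TsneConfig(perplexity=15, max_iter=250, seed=2)
        )
        trace = dict(proj.config["objective_trace"])
        tail = [v for it, v in sorted(trace.items()) if it >= 150]
        for earlier, later in zip(tail, tail[1:]):
            assert later <= earlier + 1e-3

    def test_objective_after_exaggeration_improves(self):
        data = pb.generate_lsun(80, seed=8)
        cfg = pb.TsneConfig(perplexity=15, max_iter=300, seed=3)
        proj = pb.tsne_embed(data, cfg)
        trace = dict(proj.config["objective_trace"])
        assert proj.final_objective <= trace[cfg.early_exaggeration_iters]

    def test_rejects_tiny_datasets_and_big_perplexity(self):
        data = pb.generate_lsun(12, seed=0)
        with pytest.raises(ValueError):
            pb.tsne_embed(data, pb.TsneConfig(perplexity=12, max_iter=5))
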