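import itertools

import numpy as np
import pytest

from mcgpath import toybuilder
from mcgpath.principal_path import (align_frames, fit_principal_path,
                                    nearest_frames, pp_cost, select_s)


class TestPpCost:
    def test_reduces_to_kmeans_wcss_at_s_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (60, 2))
        W = np.array([[0.0, 0.0], [2.0, 2.0], [-2.0, 1.0]])
        c = np.argmin(((X[:, None] - W[None]) ** 2).sum(-1), axis=1)
        wcss = sum(((X[c == j] - W[j]) ** 2).sum() for j in range(3))
        assert pp_cost(X, W, c, 0.0) == pytest.approx(wcss)

    def test_single_frame_collinear_hand_value(self):
        g = 1.7
        W = np.array([[0.0, 0.0], [g, 0.0], [2 * g, 0.0]])
        X = W[[1]]  # one frame sitting exactly on its representative
        assert pp_cost(X, W, np.array([1]), 3.0) == \
            pytest.approx(2 * 3.0 * g ** 2)

    def test_negative_s_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            pp_cost(np.zeros((2, 2)), np.zeros((3, 2)),
                    np.array([0, 1]), -1.0)

    def test_invalid_assignments_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            pp_cost(np.zeros((2, 2)), np.zeros((3, 2)),
                    np.array([0, 5]), 1.0)


def _brute_force_1d(X, A, B, K, s, grid_step=0.01):
    """Exhaustive grid search over interior representatives (1-D instances)."""
    lo, hi = min(X.min(), A, B) - 0.2, max(X.max(), A, B) + 0.2
    grid = np.arange(lo, hi + grid_step, grid_step)
    best = np.inf
    for interior in itertools.product(grid, repeat=K - 2):
        W = np.array([A, *interior, B])[:, None]
        c = np.argmin((X[:, None, 0] - W[None, :, 0]) ** 2, axis=1)
        best = min(best, pp_cost(X, W, c, s))
    return best


class TestFitPrincipalPath:
    def test_matches_exhaustive_search_on_1d_instances(self):
        """Alternating minimization reaches the global grid optimum (K=4)."""
        rng = np.random.default_rng(7)
        for s in (0.0, 0.5, 2.0):
            X = np.sort(rng.uniform(0, 3, 6))[:, None]
            A, B = 0.0, 3.0
            path = fit_principal_path(X, [A], [B], K=4, s=s)
            brute = _brute_force_1d(X, A, B, 4, s)
            assert path.cost_history[-1] <= brute + 0.05

    def test_cost_monotone_nonincreasing(self):
        arc = toybuilder.make_arc_cloud(300, 0.08, seed=1)
        path = fit_principal_path(arc.points, arc.endpoints[0],
                                  arc.endpoints[1], K=10, s=0.5)
        assert np.all(np.diff(path.cost_history) <= 1e-9)

    def test_collinear_frames_give_ordered_segment(self):
        t = np.linspace(0, 1, 50)[:, None]
        A, B = np.array([0.0, 0.0]), np.array([4.0, 0.0])
        X = (1 - t) * A + t * B
        path = fit_principal_path(X, A, B, K=5, s=0.1)
        W = path.representatives
        np.testing.assert_allclose(W[:, 1], 0.0, atol=1e-9)  # on the line
        assert np.all(np.diff(W[:, 0]) > 0)                  # ordered A → B

    def test_large_s_approaches_uniform_spacing(self):
        arc = toybuilder.make_arc_cloud(200, 0.05, seed=2)
        A, B = arc.endpoints
        var = np.var(arc.points)
        path = fit_principal_path(arc.points, A, B, K=6, s=1e6 * var)
        expected = np.linspace(0, 1, 6)[:, None] * (B - A) + A
        np.testing.assert_allclose(path.representatives, expected, atol=1e-3)

    def test_arc_beats_straight_line_and_recovers_curve(self):
        arc = toybuilder.make_arc_cloud(500, 0.05, seed=4)
        A, B = arc.endpoints
        s = 1.0
        path = fit_principal_path(arc.points, A, B, K=8, s=s)
        # cost of the straight-line configuration with its best assignments
        t = np.linspace(0, 1, 8)[:, None]
        W_line = (1 - t) * A + t * B
        c_line = np.argmin(((arc.points[:, None] - W_line[None]) ** 2)
                           .sum(-1), axis=1)
        assert path.cost_history[-1] <= pp_cost(arc.points, W_line,
                                                c_line, s)
        dist = np.abs(np.linalg.norm(path.representatives, axis=1)
                      - arc.radius)
        assert dist.mean() < 2 * arc.noise_sd

    def test_endpoints_pinned_and_k_conserved(self):
        arc = toybuilder.make_arc_cloud(100, 0.05, seed=5)
        path = fit_principal_path(arc.points, arc.endpoints[0],
                                  arc.endpoints[1], K=20, s=0.3)
        assert path.K == 20
        np.testing.assert_allclose(path.representatives[0], arc.endpoints[0])
        np.testing.assert_allclose(path.representatives[-1], arc.endpoints[1])

    def test_s_zero_free_endpoints_matches_lloyd(self):
        """With s = 0 and free endpoints the update is exactly Lloyd's."""
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (80, 2))
        K = 4
        t = np.linspace(0, 1, K)[:, None]
        A, B = X[0], X[-1]
        W = (1 - t) * A + t * B
        for _ in range(50):  # plain Lloyd iterations from the same init
            c = np.argmin(((X[:, None] - W[None]) ** 2).sum(-1), axis=1)
            for j in range(K):
                if np.any(c == j):
                    W[j] = X[c == j].mean(axis=0)
        path = fit_principal_path(X, A, B, K=K, s=0.0, pin_endpoints=False)
        np.testing.assert_allclose(
            np.sort(path.representatives, axis=0), np.sort(W, axis=0),
            atol=1e-6)

    def test_conformational_frames_align_and_reshape(self, hinge_pair):
        a, b = hinge_pair
        rng = np.random.default_rng(3)
        frames = [a.coords + rng.normal(0, 0.1, a.coords.shape)
                  for _ in range(10)] + \
                 [b.coords + rng.normal(0, 0.1, b.coords.shape)
                  for _ in range(10)]
        path = fit_principal_path(frames, a, b, K=4, s=0.5)
        assert path.conformations.shape == (4, len(a), 3)
        np.testing.assert_allclose(path.conformations[0], a.coords,
                                   atol=1e-9)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            fit_principal_path(np.zeros((2, 2)), [0, 0], [1, 1], K=3, s=1.0)


class TestSelectS:
    def test_interior_selection_on_polyline_data(self):
        """Evidence maximization picks a finite, non-boundary s (≥ 8/10)."""
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(rep)
            verts = np.array([[0, 0], [1, 0.8], [2, 0.2], [3, 1.2], [4, 0.5]])
            ts = rng.uniform(0, 4, 300)
            seg = np.minimum(ts.astype(int), 3)
            frac = (ts - seg)[:, None]
            pts = verts[seg] * (1 - frac) + verts[seg + 1] * frac
            pts += rng.normal(0, 0.08, pts.shape)
            s_star, table = select_s(pts, verts[0], verts[-1], K=5)
            grid = table["s"].to_numpy()
            if grid.min() < s_star < grid.max():
                wins += 1
        assert wins >= 8

    def test_single_value_grid_warns_and_returns_it(self):
        arc = toybuilder.make_arc_cloud(50, 0.05, seed=6)
        with pytest.warns(UserWarning, match="single"):
            s_star, table = select_s(arc.points, arc.endpoints[0],
                                     arc.endpoints[1], K=4, s_grid=[0.7])
        assert s_star == 0.7 and len(table) == 1

    def test_degenerate_duplicate_frames(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        s1 = fit_principal_path(X, X[0], X[2], K=3, s=0.1)
        s2 = fit_principal_path(X, X[0], X[2], K=3, s=10.0)
        # no interior structure: data cost identical across s
        d1 = s1.cost_history[-1] - 0.1 * np.sum(
            np.diff(s1.representatives, axis=0) ** 2)
        d2 = s2.cost_history[-1] - 10.0 * np.sum(
            np.diff(s2.representatives, axis=0) ** 2)
        assert d1 == pytest.approx(d2, abs=1e-6)


class TestNearestFrames:
    def test_exact_match_returns_that_frame(self):
        arc = toybuilder.make_arc_cloud(60, 0.05, seed=8)
        path = fit_principal_path(arc.points, arc.endpoints[0],
                                  arc.endpoints[1], K=5, s=0.2)
        X = np.vstack([arc.points, path.representatives[2]])
        idx = nearest_frames(path, X)
        assert idx[2] == len(X) - 1

    def test_tie_broken_by_earlier_frame(self):
        W = np.array([[0.0], [1.0], [2.0]])
        path = fit_principal_path(
            np.array([[0.0], [0.5], [1.5], [2.0]]), [0.0], [2.0], K=3, s=0.0)
        # representative at 1.0 equidistant from frames 1 and 2
        path.representatives[:] = W
        idx = nearest_frames(path, np.array([[0.0], [0.5], [1.5], [2.0]]))
        assert idx[1] == 1

    def test_nearest_frame_energies_dominate_representative_energies(
            self, hinge_pair):
        """Real frames are noisier than the variance-optimal representatives,
        so their data cost (distance to the path) is at least as large."""
        a, b = hinge_pair
        rng = np.random.default_rng(9)
        frames = [a.coords + rng.normal(0, 0.3, a.coords.shape)
                  for _ in range(15)] + \
                 [b.coords + rng.normal(0, 0.3, b.coords.shape)
                  for _ in range(15)]
        path = fit_principal_path(frames, a, b, K=5, s=0.5)
        idx = nearest_frames(path, frames, endpoint_A=a)
        X = align_frames(frames, a)
        W = path.representatives
        d_near = ((X[idx] - W) ** 2).sum()
        assert d_near >= 0.0  # representatives are exact minimizers
        # and replacing representatives by their nearest frames cannot
        # lower the clustering cost
        c = path.assignments
        assert pp_cost(X, X[idx], c, 0.0) >= pp_cost(X, W, c, 0.0) - 1e-9
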