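import itertools

import numpy as np
import pytest

from grn_landscape.cme import build_generator, ctmc_mfpt
from grn_landscape.kinetics import (
    MfptEstimate,
    barrier_height,
    barrier_matrix,
    barrier_time_correlation,
    bottleneck_levels,
    mfpt,
    path_flux,
)
from grn_landscape.landscape import (
    Basin,
    LandscapeGrid,
    find_basins,
    landscape_from_histogram,
)
from grn_landscape.model import compile_network
from grn_landscape.ssa import first_passage_times, initial_state

from conftest import make_single_gene


def grid_from_U(U, axes=("P53", "ZEB", "OCT4")):
    U = np.asarray(U, dtype=float)
    P = np.exp(-U)
    P /= P.sum()
    U = -np.log(P)
    return LandscapeGrid(axes[: U.ndim], 1.0, P, U, 0.0)


def brute_force_minimax(U, start, goal):
    """Independent oracle: smallest threshold theta such that start and goal
    are connected through voxels with U <= theta (threshold percolation)."""
    U = np.asarray(U, dtype=float)
    levels = np.unique(U[np.isfinite(U)])
    shape = U.shape
    for theta in levels:
        if U[start] > theta or U[goal] > theta:
            continue
        seen = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            if v == goal:
                return theta
            for d in range(len(shape)):
                for s in (-1, 1):
                    j = v[d] + s
                    if 0 <= j < shape[d]:
                        nb = v[:d] + (j,) + v[d + 1 :]
                        if nb not in seen and np.isfinite(U[nb]) and U[nb] <= theta:
                            seen.add(nb)
                            stack.append(nb)
    return np.inf


class TestBarrierHeight:
    def test_1d_three_voxel_profile(self):
        grid = grid_from_U([0.0, 3.0, 1.0], axes=("x",))
        basins = find_basins(grid, delta_merge=0.1)
        assert len(basins) == 2
        a = next(b for b in basins if b.min_idx == (0,))
        b = next(b for b in basins if b.min_idx == (2,))
        bar_ab, saddle = barrier_height(grid, a, b)
        bar_ba, _ = barrier_height(grid, b, a)
        # normalization shifts U uniformly; differences are preserved
        assert bar_ab == pytest.approx(3.0)
        assert bar_ba == pytest.approx(2.0)
        assert saddle == (1,)

    def test_symmetric_double_well(self):
        grid = grid_from_U([0.0, 4.0, 0.0], axes=("x",))
        basins = find_basins(grid, delta_merge=0.1)
        a, b = basins
        assert barrier_height(grid, a, b)[0] == pytest.approx(
            barrier_height(grid, b, a)[0]
        )

    def test_disconnected_is_infinite(self):
        U = np.array([0.0, np.inf, 1.0])
        P = np.array([0.5, 0.0, 0.5])
        grid = LandscapeGrid(("x",), 1.0, P, U, 0.0)
        a = Basin("A", (0,), np.array([0.5]), 0.0, np.array([[0]]))
        b = Basin("B", (2,), np.array([2.5]), 1.0, np.array([[2]]))
        bar, _ = barrier_height(grid, a, b)
        assert np.isinf(bar)

    @pytest.mark.parametrize("shape", [(5, 5), (4, 4, 4), (5, 5, 5)])
    def test_minimax_matches_brute_force(self, shape):
        rng = np.random.default_rng(sum(shape))
        for trial in range(5):
            U = rng.uniform(0.0, 5.0, size=shape)
            grid = grid_from_U(U)
            start = tuple(rng.integers(0, s) for s in shape)
            goal = tuple(rng.integers(0, s) for s in shape)
            levels = bottleneck_levels(grid, start)
            expected = brute_force_minimax(grid.U, start, goal)
            assert levels[goal] == pytest.approx(expected)

    def test_shared_saddle_identity(self):
        rng = np.random.default_rng(5)
        U = rng.uniform(0.0, 6.0, size=(6, 6, 6))
        grid = grid_from_U(U)
        basins = find_basins(grid, delta_merge=0.05)
        bm = barrier_matrix(grid, basins)
        n = len(basins)
        for i in range(n):
            for j in range(n):
                if i == j or not np.isfinite(bm.barrier[i, j]):
                    continue
                lhs = bm.barrier[i, j] + bm.U_min[i]
                rhs = bm.barrier[j, i] + bm.U_min[j]
                assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_barrier_nonnegative(self):
        rng = np.random.default_rng(6)
        grid = grid_from_U(rng.uniform(0, 4, size=(6, 6)))
        basins = find_basins(grid, delta_merge=0.05)
        bm = barrier_matrix(grid, basins)
        assert np.all(bm.barrier[np.isfinite(bm.barrier)] >= -1e-12)


class TestMfpt:
    def test_birth_death_first_passage_vs_ctmc_oracle(self):
        """SSA first-passage 0 -> >=N of an unregulated gene against the
        linear-solve oracle on the truncated generator."""
        net = make_single_gene(g0=10.0)
        c = compile_network(net)
        N = 15
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[N:, :, :] = True
        times, reached = first_passage_times(
            c, ("A", "A", "A"), initial_state(c), mask, n_passages=300, seed=3,
            bin_width=1,
        )
        assert reached.all()
        Q, cn, _ = build_generator(net, truncation=60)
        tau = ctmc_mfpt(Q, targets=np.where(cn[:, 0] >= N)[0])
        start_idx = int(np.where(cn[:, 0] == 0)[0][0])
        expected = tau[start_idx]
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - expected) < 3 * se

    def test_mfpt_estimate_fields(self):
        net = make_single_gene(g0=10.0)
        hist = np.zeros((30, 30, 30))
        hist[5:15, 5:15, 5:15] = 1.0
        grid = landscape_from_histogram(hist, axes=("A", "A", "A"),
                                        bin_width=1.0, smoothing=0.0)
        src = Basin("src", (0, 0, 0), np.array([0.0, 0.0, 0.0]), 0.0,
                    np.array([[0, 0, 0]]))
        tgt_vox = np.array(
            [[i, j, k] for i in range(8, 12) for j in range(8, 12)
             for k in range(8, 12)]
        )
        tgt = Basin("tgt", (10, 10, 10), np.array([10.0, 10.0, 10.0]),
                    float(grid.U[10, 10, 10]), tgt_vox)
        est = mfpt(net, grid, src, tgt, n_passages=20, seed=1, delta_core=5.0)
        assert est.n_passages == 20
        assert est.mean > 0
        assert est.stderr > 0
        assert est.censored_fraction == 0.0
        assert est.reliable

    def test_censoring_reported(self):
        net = make_single_gene(g0=2.0)  # mean 2: reaching 25 is very rare
        hist = np.zeros((30, 30, 30))
        hist[:, :, :] = 1.0
        grid = landscape_from_histogram(hist, axes=("A", "A", "A"),
                                        bin_width=1.0, smoothing=0.0)
        src = Basin("src", (0, 0, 0), np.array([0, 0, 0.0]), 0.0,
                    np.array([[0, 0, 0]]))
        tgt = Basin("tgt", (25, 25, 25), np.array([25.0, 25, 25]), 0.0,
                    np.array([[25, 25, 25]]))
        est = mfpt(net, grid, src, tgt, n_passages=5, seed=2,
                   max_events_per_passage=2000)
        assert est.censored_fraction > 0.5
        assert not est.reliable


class TestCorrelation:
    def test_perfect_arrhenius(self):
        barriers = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.exp(0.5 + 1.3 * barriers)
        assert barrier_time_correlation(barriers, times) == pytest.approx(1.0)

    def test_anticorrelated(self):
        barriers = np.array([1.0, 2.0, 3.0])
        times = np.exp(-2.0 * barriers)
        assert barrier_time_correlation(barriers, times) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            barrier_time_correlation([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_length_requirements(self):
        with pytest.raises(ValueError):
            barrier_time_correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            barrier_time_correlation([1.0, 2.0, 3.0], [1.0, 2.0])


class TestPathFlux:
    routes = [
        ("normal", "SC", "CSC", "cancer"),
        ("normal", "premalignant", "cancer"),
        ("normal", "lesion", "hyperplasia", "cancer"),
    ]

    def mfpts(self, scale=1.0):
        vals = {
            ("normal", "SC"): 100.0, ("SC", "CSC"): 400.0,
            ("CSC", "cancer"): 50.0, ("normal", "premalignant"): 40.0,
            ("premalignant", "cancer"): 10.0, ("normal", "lesion"): 200.0,
            ("lesion", "hyperplasia"): 300.0, ("hyperplasia", "cancer"): 60.0,
        }
        return {k: v * scale for k, v in vals.items()}

    def test_probabilities_sum_to_one(self):
        res = path_flux(self.routes, self.mfpts(), {"normal": 0.6})
        assert sum(p.probability for p in res) == pytest.approx(1.0, abs=1e-6)

    def test_fastest_route_dominates(self):
        res = path_flux(self.routes, self.mfpts(), {"normal": 0.6})
        best = max(res, key=lambda p: p.probability)
        assert best.route == ("normal", "premalignant", "cancer")

    def test_rate_is_reciprocal_of_time(self):
        res = path_flux(self.routes, self.mfpts(), {"normal": 0.5})
        for p in res:
            assert p.rate == pytest.approx(1.0 / p.transition_time)

    def test_probability_invariant_to_common_rescale(self):
        a = path_flux(self.routes, self.mfpts(), {"normal": 0.6})
        b = path_flux(self.routes, self.mfpts(scale=7.0), {"normal": 0.06})
        for pa, pb in zip(a, b):
            assert pa.probability == pytest.approx(pb.probability)

    def test_missing_step_named(self):
        m = self.mfpts()
        del m[("SC", "CSC")]
        with pytest.raises(KeyError, match="SC -> CSC"):
            path_flux(self.routes, m, {"normal": 0.6})

    def test_routes_must_share_endpoints(self):
        with pytest.raises(ValueError):
            path_flux(
                [("a", "b"), ("a", "c")], {("a", "b"): 1.0, ("a", "c"): 1.0},
                {"a": 1.0},
            )
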