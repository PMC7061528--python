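"""Barrier heights, mean first-passage times, their correlation, and
flux decomposition of multi-step basin routes.

Barriers are minimax-path saddles on the discretized potential: the barrier
from A to B is the smallest-over-paths maximum U along any support path
between the two minima, minus U at A's minimum.  Transition times are
simulated first-passage times of the exact jump process.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .landscape import Basin, LandscapeGrid
from .model import CompiledNetwork, NetworkSpec
from .ssa import SystemState, _as_compiled, first_passage_times, initial_state

__all__ = [
    "BarrierResult",
    "BarrierMatrix",
    "MfptEstimate",
    "PathResult",
    "barrier_height",
    "bottleneck_levels",
    "barrier_matrix",
    "mfpt",
    "barrier_time_correlation",
    "path_flux",
]


@dataclass(frozen=True)
class BarrierResult:
    barrier: float
    saddle_idx: tuple[int, ...]
    saddle_U: float


@dataclass
class BarrierMatrix:
    labels: list[str]
    barrier: np.ndarray          # (n, n), barrier[i, j] = height from i to j
    saddle_U: np.ndarray         # (n, n) U at the connecting saddle
    U_min: np.ndarray            # (n,)

    def get(self, a: str, b: str) -> float:
        return float(self.barrier[self.labels.index(a), self.labels.index(b)])


@dataclass
class MfptEstimate:
    source: str
    target: str
    mean: float
    stderr: float
    n_passages: int
    censored_fraction: float = 0.0

    @property
    def reliable(self) -> bool:
        return self.censored_fraction <= 0.10


@dataclass
class PathResult:
    route: tuple[str, ...]
    transition_time: float       # sum of step MFPTs
    rate: float                  # reciprocal of the transition time
    flux: float                  # stationary source probability x rate
    probability: float           # flux normalized over the declared routes


def bottleneck_levels(grid: LandscapeGrid, start_idx: tuple[int, ...]) -> np.ndarray:
    """Minimax (bottleneck) U level from ``start_idx`` to every support voxel.

    levels[v] is the lowest possible value of (maximum U along a 6-connected
    support path from start to v); +inf for disconnected voxels."""
    U = grid.U
    shape = U.shape
    levels = np.full(shape, np.inf)
    start = tuple(start_idx)
    if not np.isfinite(U[start]):
        raise ValueError("start voxel outside landscape support")
    levels[start] = U[start]
    heap = [(U[start], start)]
    ndim = len(shape)
    while heap:
        lev, vox = heapq.heappop(heap)
        if lev > levels[vox]:
            continue
        for d in range(ndim):
            for step_ in (-1, 1):
                j = vox[d] + step_
                if not 0 <= j < shape[d]:
                    continue
                nb = vox[:d] + (j,) + vox[d + 1 :]
                u = U[nb]
                if not np.isfinite(u):
                    continue
                cand = lev if lev > u else u
                if cand < levels[nb]:
                    levels[nb] = cand
                    heapq.heappush(heap, (cand, nb))
    return levels


def barrier_height(
    grid: LandscapeGrid, basin_a: Basin, basin_b: Basin
) -> tuple[float, tuple[int, ...]]:
    """Barrier from A to B: U(minimax saddle) - U_min(A), plus the saddle
    voxel.  Returns (inf, A's minimum) if the basins are disconnected."""
    levels = bottleneck_levels(grid, basin_a.min_idx)
    lev = levels[basin_b.min_idx]
    if not np.isfinite(lev):
        return np.inf, basin_a.min_idx
    barrier = float(lev - basin_a.U_min)
    saddle_idx = _saddle_on_path(grid, basin_a.min_idx, basin_b.min_idx, levels)
    return barrier, saddle_idx


def _saddle_on_path(grid, start, goal, levels) -> tuple[int, ...]:
    """Walk back from goal to start along non-increasing bottleneck levels,
    returning the voxel achieving the path maximum of U."""
    U = grid.U
    shape = U.shape
    vox = tuple(goal)
    best = vox
    visited = {vox}
    while vox != tuple(start):
        nxt = None
        for d in range(len(shape)):
            for step_ in (-1, 1):
                j = vox[d] + step_
                if not 0 <= j < shape[d]:
                    continue
                nb = vox[:d] + (j,) + vox[d + 1 :]
                if nb in visited or not np.isfinite(U[nb]):
                    continue
                if levels[nb] <= levels[vox] + 1e-12:
                    if nxt is None or levels[nb] < levels[nxt]:
                        nxt = nb
        if nxt is None:
            break
        visited.add(nxt)
        vox = nxt
        if U[vox] > U[best]:
            best = vox
    return best


def barrier_matrix(grid: LandscapeGrid, basins: Sequence[Basin]) -> BarrierMatrix:
    """All ordered-pair barriers via one bottleneck search per basin."""
    labels = [b.label for b in basins]
    n = len(basins)
    barrier = np.full((n, n), np.inf)
    saddle_U = np.full((n, n), np.inf)
    u_min = np.array([b.U_min for b in basins])
    for i, a in enumerate(basins):
        levels = bottleneck_levels(grid, a.min_idx)
        for j, b in enumerate(basins):
            if i == j:
                barrier[i, j] = 0.0
                saddle_U[i, j] = a.U_min
                continue
            lev = levels[b.min_idx]
            if np.isfinite(lev):
                barrier[i, j] = lev - a.U_min
                saddle_U[i, j] = lev
    return BarrierMatrix(labels, barrier, saddle_U, u_min)


def _basin_core_mask(
    grid: LandscapeGrid, basin: Basin, delta_core: float
) -> np.ndarray:
    mask = np.zeros(grid.P.shape, dtype=bool)
    sel = grid.U[tuple(basin.voxels.T)] <= basin.U_min + delta_core
    mask[tuple(basin.voxels[sel].T)] = True
    return mask


def _occupancy_probability(c: CompiledNetwork, r: int, n: float) -> float:
    m = int(c.site_m[r])
    if n < m:
        return 0.0
    if m == 1:
        comb = n
    elif m == 2:
        comb = n * (n - 1) / 2.0
    else:
        comb = n * (n - 1) * (n - 2) * (n - 3) / 6.0
    xeq = c.site_f[r] / c.site_h[r]
    return comb / (comb + xeq)


def start_state_for(
    network: NetworkSpec | CompiledNetwork,
    grid: LandscapeGrid,
    basin: Basin,
    iterations: int = 200,
) -> SystemState:
    """SSA start state at a basin minimum: axis species pinned to the minimum
    coordinates, non-axis species relaxed to their quasi-stationary mean-field
    level given those coordinates, all sites unbound."""
    c = _as_compiled(network)
    axis_idx = {c.species_index(a): grid.axes.index(a) for a in grid.axes}
    x = np.array([c.g0[s] / c.k[s] for s in range(c.n_species)])
    for s, d in axis_idx.items():
        x[s] = basin.min_coords[d]
    for _ in range(iterations):
        g = c.g0.copy()
        for r in range(c.n_sites):
            p = _occupancy_probability(c, r, x[c.site_source[r]])
            g[c.site_target[r]] *= (1.0 - p) + p * c.site_lam[r]
        for s in range(c.n_species):
            if s not in axis_idx:
                x[s] += 0.2 * (g[s] / c.k[s] - x[s])
    n0 = [int(round(v)) for v in x]
    return initial_state(c, n0)


def mfpt(
    network: NetworkSpec | CompiledNetwork,
    grid: LandscapeGrid,
    source: Basin,
    target: Basin,
    n_passages: int = 10,
    seed: int = 0,
    delta_core: float = 1.0,
    max_events_per_passage: int = 500_000_000,
    start: SystemState | None = None,
) -> MfptEstimate:
    """Mean first-passage time from the source minimum into the target basin
    core (voxels with U <= U_min(target) + delta_core), by independent SSA
    runs.  Censored passages (event budget hit) are excluded from the mean
    and reported as a censoring fraction."""
    if n_passages < 1:
        raise ValueError("n_passages must be >= 1")
    c = _as_compiled(network)
    mask = _basin_core_mask(grid, target, delta_core)
    if start is None:
        start = start_state_for(c, grid, source)
    times, reached = first_passage_times(
        c,
        grid.axes,
        start,
        mask,
        n_passages,
        seed=seed,
        bin_width=int(grid.bin_width),
        max_events_per_passage=max_events_per_passage,
    )
    ok = times[reached]
    censored = 1.0 - reached.mean()
    if len(ok) == 0:
        return MfptEstimate(source.label, target.label, np.inf, np.inf, 0, 1.0)
    stderr = float(ok.std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else np.inf
    return MfptEstimate(
        source.label, target.label, float(ok.mean()), stderr, int(len(ok)),
        float(censored),
    )


def barrier_time_correlation(
    barriers: Sequence[float], mfpts: Sequence[float]
) -> float:
    """Pearson correlation of barrier height against ln(transition time)."""
    barriers = np.asarray(barriers, dtype=float)
    mfpts = np.asarray(mfpts, dtype=float)
    if len(barriers) != len(mfpts):
        raise ValueError("paired lists required")
    if len(barriers) < 3:
        raise ValueError("at least 3 pairs required")
    log_t = np.log(mfpts)
    if np.std(barriers) == 0 or np.std(log_t) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(barriers, log_t)
    return float(r)


def path_flux(
    routes: Sequence[Sequence[str]],
    mfpts: Mapping[tuple[str, str], float],
    basin_probabilities: Mapping[str, float],
) -> list[PathResult]:
    """Flux decomposition over alternative routes sharing source and target.

    Per route: transition time = sum of step MFPTs, rate = 1/time, flux =
    stationary source-basin probability x rate, probability = flux normalized
    over the given routes."""
    routes = [tuple(r) for r in routes]
    if not routes:
        raise ValueError("no routes given")
    src = routes[0][0]
    dst = routes[0][-1]
    for r in routes:
        if r[0] != src or r[-1] != dst:
            raise ValueError("routes must share source and destination")
    results = []
    for r in routes:
        total = 0.0
        for a, b in zip(r[:-1], r[1:]):
            if (a, b) not in mfpts:
                raise KeyError(f"missing MFPT for step {a} -> {b}")
            total += float(mfpts[(a, b)])
        rate = 1.0 / total
        flux = basin_probabilities[src] * rate
        results.append(PathResult(r, total, rate, flux, 0.0))
    z = sum(p.flux for p in results)
    for p in results:
        p.probability = p.flux / z
    return results
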