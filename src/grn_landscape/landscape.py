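"""Probability landscape U = -ln P over a marginal of selected species,
basin detection by watershed on the discretized potential, and labeling of
basins with the seven cell-state signatures.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .ssa import Trajectory

__all__ = [
    "LandscapeGrid",
    "Basin",
    "STATE_SIGNATURES",
    "estimate_landscape",
    "landscape_from_histogram",
    "find_basins",
    "label_basins",
    "project_landscape",
]

# per-axis qualitative levels (P53, ZEB, OCT4): 0 = low, 1 = intermediate, 2 = high
STATE_SIGNATURES: dict[str, tuple[int, int, int]] = {
    "normal": (2, 0, 0),
    "premalignant": (1, 1, 0),
    "cancer": (0, 2, 0),
    "SC": (2, 0, 2),
    "CSC": (1, 1, 1),
    "lesion": (0, 0, 0),
    "hyperplasia": (0, 0, 2),
}

DEFAULT_AXES = ("P53", "ZEB", "OCT4")

# default absolute low|intermediate|high cuts (copy numbers) per axis,
# tuned to the shipped default network's attractor positions
DEFAULT_THRESHOLDS: tuple[tuple[float, float], ...] = (
    (110.0, 160.0),   # P53
    (100.0, 330.0),   # ZEB
    (100.0, 200.0),   # OCT4
)


@dataclass
class LandscapeGrid:
    """Binned steady-state probability P and potential U = -ln P."""

    axes: tuple[str, ...]
    bin_width: float
    P: np.ndarray               # sums to 1 over the grid
    U: np.ndarray               # -ln P where P > 0, +inf elsewhere
    bandwidth: float = 0.0      # gaussian smoothing sigma, in bins

    @property
    def support(self) -> np.ndarray:
        return self.P > 0

    def coords(self, idx: Sequence[int]) -> np.ndarray:
        """Bin-center coordinates (copy-number units) of a voxel index."""
        return (np.asarray(idx) + 0.5) * self.bin_width

    def voxel_of(self, coords: Sequence[float]) -> tuple[int, ...]:
        idx = np.floor(np.asarray(coords, dtype=float) / self.bin_width).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.P.shape) - 1)
        return tuple(int(i) for i in idx)


@dataclass
class Basin:
    label: str                  # one of the seven states, or "unassigned"
    min_idx: tuple[int, ...]
    min_coords: np.ndarray
    U_min: float
    voxels: np.ndarray          # (n_voxels, ndim) indices of the catchment
    probability: float = 0.0

    def member_mask(self, shape: tuple[int, ...]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[tuple(self.voxels.T)] = True
        return mask


def _finalize(P: np.ndarray, axes, bin_width, bandwidth) -> LandscapeGrid:
    total = P.sum()
    if total <= 0:
        raise ValueError("empty landscape: no probability mass")
    P = P / total
    if bandwidth > 0:
        P = gaussian_filter(P, sigma=bandwidth, mode="constant")
        P = P / P.sum()
    with np.errstate(divide="ignore"):
        U = np.where(P > 0, -np.log(np.where(P > 0, P, 1.0)), np.inf)
    return LandscapeGrid(tuple(axes), float(bin_width), P, U, float(bandwidth))


def estimate_landscape(
    ensemble: Sequence[Trajectory],
    axes: Sequence[str] = DEFAULT_AXES,
    bin_width: float = 5.0,
    smoothing: float = 1.0,
    n_bins: int = 96,
) -> LandscapeGrid:
    """Landscape from pooled post-burn-in trajectory records.

    Records are uniformly thinned, so each carries equal time weight; the
    histogram is therefore the time-weighted occupancy of the ensemble.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    cols = [ensemble[0].species.index(a) for a in axes]
    chunks = []
    for traj in ensemble:
        _, counts = traj.post_burn_in()
        if len(counts):
            chunks.append(counts[:, cols])
    if not chunks:
        raise ValueError("no post-burn-in records in ensemble")
    data = np.concatenate(chunks, axis=0)
    edges = [np.arange(n_bins + 1) * bin_width] * len(cols)
    clipped = np.minimum(data, n_bins * bin_width - 0.5)
    P, _ = np.histogramdd(clipped, bins=edges)
    return _finalize(P, axes, bin_width, smoothing)


def landscape_from_histogram(
    hist: np.ndarray,
    axes: Sequence[str] = DEFAULT_AXES,
    bin_width: float = 5.0,
    smoothing: float = 1.0,
) -> LandscapeGrid:
    """Landscape from a precomputed time-weighted occupancy histogram (the
    fast path used with the jitted dwell-time accumulator)."""
    return _finalize(np.asarray(hist, dtype=float), axes, bin_width, smoothing)


def _neighbors(idx: tuple[int, ...], shape: tuple[int, ...]):
    for d in range(len(shape)):
        for step in (-1, 1):
            j = idx[d] + step
            if 0 <= j < shape[d]:
                yield idx[:d] + (j,) + idx[d + 1 :]


def find_basins(grid: LandscapeGrid, delta_merge: float = 0.5) -> list[Basin]:
    """Watershed decomposition of the potential into basins of attraction.

    Support voxels are visited in ascending U (immersion); a voxel with no
    previously assigned neighbor seeds a new basin, otherwise it drains to
    the basin of its lowest assigned neighbor.  Minima whose depth below
    their lowest connecting saddle is less than ``delta_merge`` are merged
    into the neighbor across that saddle.
    """
    U = grid.U
    shape = U.shape
    support = np.argwhere(np.isfinite(U))
    if len(support) == 0:
        raise ValueError("flat/empty landscape")
    order = np.argsort(U[tuple(support.T)], kind="stable")
    voxels = [tuple(v) for v in support[order]]

    assign: dict[tuple[int, ...], int] = {}
    minima: list[tuple[int, ...]] = []
    saddle: dict[tuple[int, int], float] = {}

    for vox in voxels:
        owner = -1
        best_u = np.inf
        touching: set[int] = set()
        for nb in _neighbors(vox, shape):
            b = assign.get(nb)
            if b is None:
                continue
            touching.add(b)
            if U[nb] < best_u:
                best_u = U[nb]
                owner = b
        if owner < 0:
            owner = len(minima)
            minima.append(vox)
        else:
            for b in touching:
                if b != owner:
                    key = (min(b, owner), max(b, owner))
                    if key not in saddle or U[vox] < saddle[key]:
                        saddle[key] = float(U[vox])
        assign[vox] = owner

    # persistence merging of shallow minima
    parent = list(range(len(minima)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def merged_saddles() -> dict[tuple[int, int], float]:
        out: dict[tuple[int, int], float] = {}
        for (a, b), u in saddle.items():
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            key = (min(ra, rb), max(ra, rb))
            if key not in out or u < out[key]:
                out[key] = u
        return out

    while True:
        sd = merged_saddles()
        best = None
        for (a, b), u in sd.items():
            ua, ub = U[minima[a]], U[minima[b]]
            shallow, deep = (a, b) if ua >= ub else (b, a)
            persistence = u - U[minima[shallow]]
            if persistence < delta_merge and (best is None or persistence < best[0]):
                best = (persistence, shallow, deep)
        if best is None:
            break
        _, shallow, deep = best
        parent[find(shallow)] = find(deep)

    roots = sorted({find(i) for i in range(len(minima))})
    relabel = {r: i for i, r in enumerate(roots)}
    members: list[list[tuple[int, ...]]] = [[] for _ in roots]
    for vox, b in assign.items():
        members[relabel[find(b)]].append(vox)

    basins = []
    for i, r in enumerate(roots):
        vox_arr = np.array(members[i], dtype=int)
        min_idx = minima[r]
        prob = float(grid.P[tuple(vox_arr.T)].sum())
        basins.append(
            Basin(
                label="unassigned",
                min_idx=min_idx,
                min_coords=grid.coords(min_idx),
                U_min=float(U[min_idx]),
                voxels=vox_arr,
                probability=prob,
            )
        )
    basins.sort(key=lambda b: b.U_min)
    return basins


def _tertile_thresholds(grid: LandscapeGrid) -> list[tuple[float, float]]:
    """Per-axis (low|intermediate, intermediate|high) cuts: tertile points of
    the support range of the landscape."""
    out = []
    support = np.argwhere(grid.support)
    for d in range(grid.P.ndim):
        lo = (support[:, d].min() + 0.5) * grid.bin_width
        hi = (support[:, d].max() + 0.5) * grid.bin_width
        out.append((lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0))
    return out


def _level(value: float, cuts: tuple[float, float]) -> int:
    if value < cuts[0]:
        return 0
    if value < cuts[1]:
        return 1
    return 2


def label_basins(
    basins: Sequence[Basin],
    grid: LandscapeGrid,
    thresholds: Sequence[tuple[float, float]] | None = None,
    mode: str = "exact",
) -> list[Basin]:
    """Assign the seven state labels by matching each basin minimum's
    low/intermediate/high pattern over (P53, ZEB, OCT4).

    In the default "exact" mode a basin must land exactly on a signature;
    unmatched minima stay "unassigned" and duplicate matches go to the
    deeper basin.  In "nearest" mode every still-unlabeled basin is then
    also considered for the remaining signatures by Manhattan distance in
    level space (used by the pipeline to place states whose reconstructed
    position is adjacent to, rather than on, the published pattern).
    """
    if grid.axes != DEFAULT_AXES:
        ax_perm = [grid.axes.index(a) for a in DEFAULT_AXES if a in grid.axes]
    else:
        ax_perm = [0, 1, 2]
    cuts = list(thresholds) if thresholds is not None else _tertile_thresholds(grid)
    by_sig = {sig: name for name, sig in STATE_SIGNATURES.items()}
    claimed: dict[str, Basin] = {}
    ordered = sorted(basins, key=lambda b: b.U_min)
    sigs = {}
    for b in ordered:
        b.label = "unassigned"
        sig = tuple(_level(b.min_coords[d], cuts[d]) for d in ax_perm)
        sigs[id(b)] = sig
        name = by_sig.get(sig)
        if name is not None and name not in claimed:
            b.label = name
            claimed[name] = b
    if mode == "nearest":
        for b in ordered:
            if b.label != "unassigned":
                continue
            sig = sigs[id(b)]
            options = [
                (sum(abs(s - t) for s, t in zip(sig, target)), name)
                for name, target in STATE_SIGNATURES.items()
                if name not in claimed
            ]
            if options:
                dist, name = min(options)
                if dist <= 2:
                    b.label = name
                    claimed[name] = b
    elif mode != "exact":
        raise ValueError(f"unknown labeling mode {mode!r}")
    return list(basins)


def project_landscape(grid: LandscapeGrid, axis_pair: Sequence[str]) -> LandscapeGrid:
    """Marginalize P over the axes not in ``axis_pair`` and recompute U."""
    keep = [grid.axes.index(a) for a in axis_pair]
    if len(keep) != 2:
        raise ValueError("axis_pair must name two grid axes")
    drop = tuple(d for d in range(grid.P.ndim) if d not in keep)
    P2 = grid.P.sum(axis=drop)
    if keep[0] > keep[1]:
        P2 = P2.T
    with np.errstate(divide="ignore"):
        U2 = np.where(P2 > 0, -np.log(np.where(P2 > 0, P2, 1.0)), np.inf)
    return LandscapeGrid(
        tuple(axis_pair), grid.bin_width, P2, U2, grid.bandwidth
    )
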