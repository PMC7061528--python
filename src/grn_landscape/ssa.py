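"""Exact (Gillespie) stochastic simulation of the coupled copy-number +
binding-site occupancy jump process.

Two implementations share the same reaction layout: a pure-Python reference
(`propensity_vector` / `step`) used by the test oracles, and jitted kernels
(`simulate`, `ensemble`, `pooled_histogram`, `first_passage_times`) used for
production runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .model import CompiledNetwork, NetworkSpec, ParameterSet, compile_network

__all__ = [
    "SystemState",
    "Trajectory",
    "ReactionEvent",
    "initial_state",
    "propensity_vector",
    "step",
    "simulate",
    "ensemble",
    "pooled_histogram",
    "first_passage_times",
    "spawn_seeds",
]

_MAX_EVENTS = np.iinfo(np.int64).max


@dataclass
class SystemState:
    """Free copy numbers per species plus per-site occupancy flags."""

    copy_numbers: np.ndarray  # (S,) int64, free (unsequestered) copies
    occupancy: np.ndarray     # (R,) uint8
    time: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(self.copy_numbers.copy(), self.occupancy.copy(), self.time)


@dataclass(frozen=True)
class ReactionEvent:
    kind: str                  # synthesis | degradation | binding | unbinding
    index: int                 # species index (synthesis/degradation) or site index
    propensity: float


@dataclass
class Trajectory:
    species: tuple[str, ...]
    times: np.ndarray          # (n_records,) strictly increasing, starts at 0
    counts: np.ndarray         # (n_records, S) free copy numbers
    occupancy: np.ndarray      # (n_records, R)
    rng_seed: int
    burn_in: float = 0.0
    n_events: int = 0
    t_end: float = 0.0

    def post_burn_in(self) -> tuple[np.ndarray, np.ndarray]:
        keep = self.times >= self.burn_in
        return self.times[keep], self.counts[keep]


def initial_state(
    compiled: CompiledNetwork, copy_numbers: Sequence[int] | None = None
) -> SystemState:
    n = np.zeros(compiled.n_species, dtype=np.int64)
    if copy_numbers is not None:
        n[:] = np.asarray(copy_numbers, dtype=np.int64)
    occ = np.zeros(compiled.n_sites, dtype=np.uint8)
    return SystemState(n, occ)


def _as_compiled(network: NetworkSpec | CompiledNetwork) -> CompiledNetwork:
    if isinstance(network, CompiledNetwork):
        return network
    return compile_network(network)


def _synthesis_rates(c: CompiledNetwork, occupancy: np.ndarray) -> np.ndarray:
    syn = np.empty(c.n_species)
    _kernels.compute_syn.py_func(
        c.g0, c.site_lam, occupancy, c.tgt_ptr, c.tgt_sites, syn
    )
    return syn


def propensity_vector(
    state: SystemState,
    network: NetworkSpec | CompiledNetwork,
    params: ParameterSet | None = None,
) -> list[tuple[ReactionEvent, float]]:
    """All reaction channels and their current propensities (reference path).

    Degradation uses free copies only; a bound site's binding channel is 0 and
    its unbinding channel equals its unbinding rate f.
    """
    c = _as_compiled(network)
    n = state.copy_numbers
    occ = state.occupancy
    if np.any(n < 0):
        raise ValueError("negative copy number")
    syn = _synthesis_rates(c, occ)
    out: list[tuple[ReactionEvent, float]] = []
    for s in range(c.n_species):
        out.append((ReactionEvent("synthesis", s, syn[s]), syn[s]))
    for s in range(c.n_species):
        rate = c.k[s] * n[s]
        out.append((ReactionEvent("degradation", s, rate), rate))
    for r in range(c.n_sites):
        if occ[r]:
            rate = 0.0
        else:
            x = int(n[c.site_source[r]])
            m = int(c.site_m[r])
            h = c.site_h[r]
            if x < m:
                rate = 0.0
            elif m == 1:
                rate = h * x
            elif m == 2:
                rate = h * x * (x - 1) / 2.0
            else:
                rate = h * x * (x - 1) * (x - 2) * (x - 3) / 6.0
        out.append((ReactionEvent("binding", r, rate), rate))
    for r in range(c.n_sites):
        rate = float(c.site_f[r]) if occ[r] else 0.0
        out.append((ReactionEvent("unbinding", r, rate), rate))
    return out


def step(
    state: SystemState,
    network: NetworkSpec | CompiledNetwork,
    params: ParameterSet | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SystemState, float]:
    """One exact SSA step (reference path).  Raises at an absorbing state."""
    c = _as_compiled(network)
    rng = rng if rng is not None else np.random.default_rng()
    channels = propensity_vector(state, c)
    rates = np.array([rate for _, rate in channels])
    total = rates.sum()
    if total <= 0:
        raise RuntimeError("absorbing state: total propensity is zero")
    wait = rng.exponential(1.0 / total)
    j = int(np.searchsorted(np.cumsum(rates), rng.random() * total))
    event, _ = channels[j]
    new = state.copy()
    if event.kind == "synthesis":
        new.copy_numbers[event.index] += 1
    elif event.kind == "degradation":
        new.copy_numbers[event.index] -= 1
    elif event.kind == "binding":
        new.copy_numbers[c.site_source[event.index]] -= c.site_m[event.index]
        new.occupancy[event.index] = 1
    else:
        new.copy_numbers[c.site_source[event.index]] += c.site_m[event.index]
        new.occupancy[event.index] = 0
    new.time = state.time + wait
    return new, wait


def save_trajectories_h5(path: str, trajectories: Sequence[Trajectory]) -> None:
    """Store an ensemble in one HDF5 container with per-run metadata."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["n_runs"] = len(trajectories)
        for i, tr in enumerate(trajectories):
            g = fh.create_group(f"run{i:04d}")
            g.create_dataset("times", data=tr.times)
            g.create_dataset("counts", data=tr.counts)
            g.create_dataset("occupancy", data=tr.occupancy)
            g.attrs["species"] = list(tr.species)
            g.attrs["seed"] = tr.rng_seed
            g.attrs["burn_in"] = tr.burn_in
            g.attrs["n_events"] = tr.n_events
            g.attrs["t_end"] = tr.t_end


def load_trajectories_h5(path: str) -> list[Trajectory]:
    import h5py

    out = []
    with h5py.File(path, "r") as fh:
        for key in sorted(k for k in fh.keys() if k.startswith("run")):
            g = fh[key]
            out.append(
                Trajectory(
                    species=tuple(g.attrs["species"]),
                    times=g["times"][...],
                    counts=g["counts"][...],
                    occupancy=g["occupancy"][...],
                    rng_seed=int(g.attrs["seed"]),
                    burn_in=float(g.attrs["burn_in"]),
                    n_events=int(g.attrs["n_events"]),
                    t_end=float(g.attrs["t_end"]),
                )
            )
    return out


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds (uint32) for trajectory kernels."""
    return np.random.SeedSequence(master_seed).generate_state(n)


def _kernel_args(c: CompiledNetwork):
    return (
        c.g0, c.k, c.site_source, c.site_target, c.site_m,
        c.site_h, c.site_f, c.site_lam, c.tgt_ptr, c.tgt_sites,
    )


def simulate(
    network: NetworkSpec | CompiledNetwork,
    params: ParameterSet | None = None,
    t_max: float = 100.0,
    seed: int = 0,
    record_every: float = 1.0,
    init: SystemState | None = None,
    burn_in: float = 0.0,
) -> Trajectory:
    """One reproducible trajectory with records thinned at ``record_every``."""
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    c = _as_compiled(network)
    state = init.copy() if init is not None else initial_state(c)
    n_records = int(np.floor(t_max / record_every)) + 1
    rec_n = np.zeros((n_records, c.n_species), dtype=np.int64)
    rec_b = np.zeros((n_records, c.n_sites), dtype=np.uint8)
    kseed = int(spawn_seeds(seed, 1)[0])
    _, _, t_end, n_events, n_rec = _kernels.ssa_trajectory(
        *_kernel_args(c),
        state.copy_numbers, state.occupancy,
        float(t_max), kseed, float(record_every), rec_n, rec_b, _MAX_EVENTS,
    )
    times = np.arange(n_rec) * record_every
    return Trajectory(
        species=c.species,
        times=times,
        counts=rec_n[:n_rec],
        occupancy=rec_b[:n_rec],
        rng_seed=seed,
        burn_in=burn_in,
        n_events=int(n_events),
        t_end=float(t_end),
    )


def ensemble(
    network: NetworkSpec | CompiledNetwork,
    params: ParameterSet | None = None,
    n_runs: int = 1,
    t_max: float = 100.0,
    burn_in: float = 0.0,
    seed: int = 0,
    record_every: float = 1.0,
    init: SystemState | None = None,
) -> list[Trajectory]:
    """Independent trajectories with child seeds spawned from ``seed``."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    c = _as_compiled(network)
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    out = []
    for i, child in enumerate(seeds):
        child_seed = int(child.generate_state(1)[0])
        traj = simulate(
            c, params, t_max=t_max, seed=child_seed,
            record_every=record_every, init=init, burn_in=burn_in,
        )
        out.append(traj)
    return out


def pooled_histogram(
    network: NetworkSpec | CompiledNetwork,
    axes: Sequence[str],
    t_max: float,
    n_runs: int = 1,
    burn_in: float = 0.0,
    seed: int = 0,
    bin_width: int = 5,
    n_bins: int = 96,
    init: SystemState | None = None,
) -> tuple[np.ndarray, float, int]:
    """Time-weighted 3D occupancy histogram over ``axes``, pooled across an
    ensemble (the fast path feeding the landscape estimator).

    Returns (hist, total_weighted_time, total_events)."""
    c = _as_compiled(network)
    if len(axes) != 3:
        raise ValueError("exactly three axis species required")
    a0, a1, a2 = (c.species_index(a) for a in axes)
    hist = np.zeros((n_bins, n_bins, n_bins))
    seeds = spawn_seeds(seed, n_runs)
    total_events = 0
    for i in range(n_runs):
        state = init.copy() if init is not None else initial_state(c)
        _, _, _, ev = _kernels.ssa_histogram(
            *_kernel_args(c),
            state.copy_numbers, state.occupancy,
            float(t_max), float(burn_in), int(seeds[i]),
            a0, a1, a2, int(bin_width), hist, _MAX_EVENTS,
        )
        total_events += int(ev)
    return hist, float(hist.sum()), total_events


def first_passage_times(
    network: NetworkSpec | CompiledNetwork,
    axes: Sequence[str],
    start: SystemState,
    target_mask: np.ndarray,
    n_passages: int,
    seed: int = 0,
    bin_width: int = 5,
    max_events_per_passage: int = 500_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """First-passage times of independent runs from ``start`` into the voxel
    set ``target_mask`` (3D bool over axes//bin_width).

    Returns (times, reached) arrays of length n_passages; censored runs carry
    the elapsed time at budget exhaustion and reached=False."""
    c = _as_compiled(network)
    a0, a1, a2 = (c.species_index(a) for a in axes)
    seeds = spawn_seeds(seed, n_passages)
    times = np.empty(n_passages)
    reached = np.zeros(n_passages, dtype=bool)
    mask = np.ascontiguousarray(target_mask)
    for i in range(n_passages):
        t, _, ok = _kernels.ssa_first_passage(
            *_kernel_args(c),
            start.copy_numbers, start.occupancy, int(seeds[i]),
            a0, a1, a2, int(bin_width), mask, int(max_events_per_passage),
        )
        times[i] = t
        reached[i] = bool(ok)
    return times, reached
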