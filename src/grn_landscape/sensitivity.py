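"""One-at-a-time sensitivity of landscape topography to regulation strength.

Each scan multiplies a single regulation's binding rate by a scale factor,
re-runs the simulate -> landscape -> basins -> barriers pipeline with a
fixed seed ladder, and tracks six barrier heights: premalignant<->cancer,
normal<->premalignant, and normal<->SC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import barrier_matrix
from .landscape import find_basins, label_basins, landscape_from_histogram
from .model import NetworkSpec, compile_network
from .ssa import pooled_histogram

__all__ = [
    "SimulationBudget",
    "SensitivityScan",
    "TRACKED_PAIRS",
    "tracked_barriers",
    "scan_regulation",
    "rank_regulations",
    "p53_nonmonotonicity_probe",
]

TRACKED_PAIRS: tuple[tuple[str, str], ...] = (
    ("premalignant", "cancer"),
    ("cancer", "premalignant"),
    ("normal", "premalignant"),
    ("premalignant", "normal"),
    ("normal", "SC"),
    ("SC", "normal"),
)


@dataclass(frozen=True)
class SimulationBudget:
    """Knobs of one landscape evaluation inside a scan point."""

    t_max: float = 1500.0
    n_runs: int = 8
    burn_in: float = 50.0
    bin_width: int = 5
    n_bins: int = 96
    smoothing: float = 1.0
    delta_merge: float = 0.5
    axes: tuple[str, str, str] = ("P53", "ZEB", "OCT4")
    thresholds: tuple[tuple[float, float], ...] | None = None
    label_mode: str = "nearest"
    min_basin_probability: float = 1e-3


@dataclass
class SensitivityScan:
    regulation_id: str
    scales: list[float]
    barriers: pd.DataFrame   # index: scale; columns: "A->B" tracked pairs
    deltas: pd.DataFrame     # barriers minus the scale-1.0 row

    def max_abs_delta(self) -> float:
        off = self.deltas.drop(index=1.0, errors="ignore")
        vals = off.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        return float(np.max(np.abs(vals))) if len(vals) else 0.0


def tracked_barriers(
    network: NetworkSpec,
    budget: SimulationBudget,
    seed: int,
    pairs: Sequence[tuple[str, str]] = TRACKED_PAIRS,
    return_labels: bool = False,
):
    """Run the landscape pipeline once and read off the tracked barriers.

    Pairs whose basins are absent come back as NaN; with
    ``return_labels=True`` the set of labeled basins found is also
    returned, so callers can distinguish a vanished basin from a
    disconnected pair."""
    c = compile_network(network)
    hist, _, _ = pooled_histogram(
        c,
        budget.axes,
        t_max=budget.t_max,
        n_runs=budget.n_runs,
        burn_in=budget.burn_in,
        seed=seed,
        bin_width=budget.bin_width,
        n_bins=budget.n_bins,
    )
    grid = landscape_from_histogram(
        hist, budget.axes, budget.bin_width, budget.smoothing
    )
    candidates = [
        b
        for b in find_basins(grid, budget.delta_merge)
        if b.probability >= budget.min_basin_probability
    ]
    basins = label_basins(
        candidates, grid, budget.thresholds, mode=budget.label_mode
    )
    labeled = {b.label: b for b in basins if b.label != "unassigned"}
    out: dict[tuple[str, str], float] = {}
    needed = {l for p in pairs for l in p}
    present = [labeled[l] for l in needed if l in labeled]
    bm = barrier_matrix(grid, present) if present else None
    for a, b in pairs:
        if bm is not None and a in labeled and b in labeled:
            out[(a, b)] = bm.get(a, b)
        else:
            out[(a, b)] = float("nan")
    if return_labels:
        return out, set(labeled)
    return out


def scan_regulation(
    network: NetworkSpec,
    regulation_id: str,
    scales: Sequence[float],
    budget: SimulationBudget | None = None,
    seed: int = 0,
    pairs: Sequence[tuple[str, str]] = TRACKED_PAIRS,
) -> SensitivityScan:
    """Barriers of the tracked pairs at each strength scale of one regulation.

    The same seed ladder is reused at every scale so scale-1.0 deltas are
    exactly zero and cross-scale differences are not pure reseeding noise.
    """
    scales = sorted(float(s) for s in scales)
    if 1.0 not in scales:
        raise ValueError("scales must include 1.0 (the baseline)")
    if any(s < 0.5 or s > 2.0 for s in scales):
        raise ValueError("scales outside [0.5, 2.0] are not supported")
    network.regulation(regulation_id)  # raises KeyError if absent
    budget = budget or SimulationBudget()
    cols = [f"{a}->{b}" for a, b in pairs]
    rows = {}
    for s in scales:
        net_s = network.with_strength(regulation_id, s)
        vals = tracked_barriers(net_s, budget, seed, pairs)
        rows[s] = [vals[p] for p in pairs]
    barriers = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    barriers.index.name = "scale"
    deltas = barriers - barriers.loc[1.0]
    return SensitivityScan(regulation_id, scales, barriers, deltas)


def rank_regulations(scans: Sequence[SensitivityScan]) -> list[tuple[str, float]]:
    """Order regulations by the maximum |barrier delta| across tracked pairs
    and non-unit scales; ties broken lexicographically by regulation id."""
    scale_sets = {tuple(s.scales) for s in scans}
    if len(scale_sets) > 1:
        raise ValueError("scans must share a common scale set")
    scored = [(s.regulation_id, s.max_abs_delta()) for s in scans]
    return sorted(scored, key=lambda t: (-t[1], t[0]))


def p53_nonmonotonicity_probe(
    network: NetworkSpec,
    scales: Sequence[float] = (0.9, 1.0, 1.1, 1.2, 1.3),
    budget: SimulationBudget | None = None,
    seed: int = 0,
    noise_threshold: float = 0.3,
    scan: SensitivityScan | None = None,
) -> pd.DataFrame:
    """Delta trajectory of the normal<->premalignant barriers across scales
    of the P53 self-activation, with a saturation flag where successive
    deltas fall below the noise threshold."""
    if scan is None:
        scan = scan_regulation(
            network,
            "P53->P53",
            scales,
            budget=budget,
            seed=seed,
            pairs=(("normal", "premalignant"), ("premalignant", "normal")),
        )
    table = scan.deltas.copy()
    diffs = table.diff().abs()
    table["saturated"] = (diffs < noise_threshold).all(axis=1) & ~diffs.isna().any(
        axis=1
    )
    return table
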