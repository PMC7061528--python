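"""End-to-end orchestration: simulate -> landscape -> basins -> barriers ->
MFPT -> flux (-> sensitivity), from a single config, with deterministic
seed derivation and a provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import barrier_matrix, mfpt, path_flux
from .landscape import (
    DEFAULT_AXES,
    DEFAULT_THRESHOLDS,
    find_basins,
    label_basins,
    landscape_from_histogram,
)
from .model import NetworkSpec, compile_network, default_network, load_network
from .sensitivity import SimulationBudget, scan_regulation
from .ssa import pooled_histogram

__all__ = ["RunConfig", "RunManifest", "run_all", "FORWARD_ROUTES", "REVERSE_ROUTES"]

FORWARD_ROUTES = (
    ("normal", "SC", "CSC", "cancer"),
    ("normal", "premalignant", "cancer"),
    ("normal", "lesion", "hyperplasia", "cancer"),
)
REVERSE_ROUTES = (
    ("cancer", "CSC", "SC", "normal"),
    ("cancer", "premalignant", "normal"),
    ("cancer", "hyperplasia", "lesion", "normal"),
)


@dataclass
class RunConfig:
    network: str | None = None          # path to a network YAML; None = shipped default
    out_dir: str = "run"
    seed: int = 0
    # simulation budget
    t_max: float = 3000.0
    n_runs: int = 20
    burn_in: float = 100.0
    # landscape
    axes: tuple[str, str, str] = DEFAULT_AXES
    bin_width: int = 5
    n_bins: int = 96
    smoothing: float = 1.0
    delta_merge: float = 0.5
    thresholds: tuple[tuple[float, float], ...] = DEFAULT_THRESHOLDS
    label_mode: str = "nearest"
    min_basin_probability: float = 1e-3
    # kinetics
    delta_core: float = 1.0
    n_passages: int = 8
    max_events_per_passage: int = 200_000_000
    mfpt_pairs: str = "routes"          # "routes" or "all"
    run_flux: bool = True
    # sensitivity
    run_sensitivity: bool = False
    sensitivity_regulations: tuple[str, ...] = ("miR200-|ZEB", "OCT4->OCT4", "P53->P53")
    sensitivity_scales: tuple[float, ...] = (0.7, 1.0, 1.3, 1.5)
    sensitivity_t_max: float = 1000.0
    sensitivity_n_runs: int = 6

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        if cfg.thresholds is not None:
            cfg.thresholds = tuple(tuple(t) for t in cfg.thresholds)
        cfg.axes = tuple(cfg.axes)
        cfg.sensitivity_regulations = tuple(cfg.sensitivity_regulations)
        cfg.sensitivity_scales = tuple(float(s) for s in cfg.sensitivity_scales)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _network_for(cfg: RunConfig) -> NetworkSpec:
    if cfg.network is None:
        return default_network()
    return load_network(cfg.network)


def run_all(cfg: RunConfig, resume: bool = True) -> RunManifest:
    """Execute all applicable stages in dependency order.

    Stage outputs live under cfg.out_dir; a stage is skipped on rerun when
    its outputs exist and the config hash is unchanged.  The manifest
    records per-stage wall time and output hashes.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest_path = out / "manifest.json"
    old = None
    if resume and manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            old = None
        if old is not None and old.get("config_hash") != chash:
            old = None
    manifest = RunManifest(chash, __version__, cfg.seed)
    network = _network_for(cfg)
    compiled = compile_network(network)

    def stage(name: str, outputs: list[str], fn) -> dict[str, Path]:
        paths = {o: out / o for o in outputs}
        if (
            old is not None
            and name in old.get("stages", {})
            and all(p.exists() for p in paths.values())
        ):
            manifest.stages[name] = old["stages"][name] | {"cached": True}
            return paths
        t0 = time.time()
        fn(paths)
        manifest.stages[name] = {
            "wall_seconds": round(time.time() - t0, 3),
            "outputs": {o: _file_hash(p) for o, p in paths.items()},
            "cached": False,
        }
        manifest.save(manifest_path)
        return paths

    # ---- simulate ----------------------------------------------------
    def do_sim(paths):
        hist, total_time, events = pooled_histogram(
            compiled,
            cfg.axes,
            t_max=cfg.t_max,
            n_runs=cfg.n_runs,
            burn_in=cfg.burn_in,
            seed=cfg.seed,
            bin_width=cfg.bin_width,
            n_bins=cfg.n_bins,
        )
        np.save(paths["histogram.npy"], hist)
        (out / "simulate.json").write_text(
            json.dumps({"events": events, "weighted_time": total_time, "seed": cfg.seed})
        )

    sim = stage("simulate", ["histogram.npy"], do_sim)
    hist = np.load(sim["histogram.npy"])
    grid = landscape_from_histogram(hist, cfg.axes, cfg.bin_width, cfg.smoothing)

    # ---- basins ------------------------------------------------------
    basins = [
        b
        for b in find_basins(grid, cfg.delta_merge)
        if b.probability >= cfg.min_basin_probability
    ]
    basins = label_basins(basins, grid, thresholds=cfg.thresholds, mode=cfg.label_mode)
    labeled = {b.label: b for b in basins if b.label != "unassigned"}

    def do_basins(paths):
        rows = [
            {
                "label": b.label,
                cfg.axes[0]: b.min_coords[0],
                cfg.axes[1]: b.min_coords[1],
                cfg.axes[2]: b.min_coords[2],
                "U_min": b.U_min,
                "probability": b.probability,
            }
            for b in sorted(basins, key=lambda b: b.U_min)
        ]
        pd.DataFrame(rows).to_csv(paths["basins.tsv"], sep="\t", index=False)

    stage("basins", ["basins.tsv"], do_basins)

    # ---- barriers ----------------------------------------------------
    ordered = sorted(labeled.values(), key=lambda b: b.U_min)
    bm = barrier_matrix(grid, ordered) if ordered else None

    def do_barriers(paths):
        pd.DataFrame(bm.barrier, index=bm.labels, columns=bm.labels).to_csv(
            paths["barriers.tsv"], sep="\t"
        )

    if bm is not None:
        stage("barriers", ["barriers.tsv"], do_barriers)

    # ---- MFPT --------------------------------------------------------
    if cfg.mfpt_pairs == "all":
        pairs = [
            (a, b) for a in labeled for b in labeled if a != b
        ]
    else:
        pairs = sorted(
            {
                (a, b)
                for route in FORWARD_ROUTES + REVERSE_ROUTES
                for a, b in zip(route[:-1], route[1:])
                if a in labeled and b in labeled
            }
        )
    mfpt_estimates = {}

    def do_mfpt(paths):
        rows = []
        for i, (a, b) in enumerate(pairs):
            est = mfpt(
                compiled,
                grid,
                labeled[a],
                labeled[b],
                n_passages=cfg.n_passages,
                seed=cfg.seed + 1000 + i,
                delta_core=cfg.delta_core,
                max_events_per_passage=cfg.max_events_per_passage,
            )
            mfpt_estimates[(a, b)] = est
            rows.append(
                {
                    "source": a,
                    "target": b,
                    "mfpt": est.mean,
                    "stderr": est.stderr,
                    "n_passages": est.n_passages,
                    "censored_fraction": est.censored_fraction,
                }
            )
        pd.DataFrame(rows).to_csv(paths["mfpt.tsv"], sep="\t", index=False)

    if pairs:
        mf = stage("mfpt", ["mfpt.tsv"], do_mfpt)
        if not mfpt_estimates:  # stage was cached: reload
            df = pd.read_csv(mf["mfpt.tsv"], sep="\t")
            for _, r in df.iterrows():
                mfpt_estimates[(r["source"], r["target"])] = r["mfpt"]

    # ---- flux --------------------------------------------------------
    def do_flux(paths):
        times = {
            k: (v.mean if hasattr(v, "mean") and not isinstance(v, float) else float(v))
            for k, v in mfpt_estimates.items()
        }
        probs = {b.label: b.probability for b in labeled.values()}
        result = {}
        for name, routes in (("forward", FORWARD_ROUTES), ("reverse", REVERSE_ROUTES)):
            usable = [
                r
                for r in routes
                if all((a, b) in times and np.isfinite(times[(a, b)])
                       for a, b in zip(r[:-1], r[1:]))
            ]
            if not usable:
                result[name] = {"error": "no route has a complete MFPT chain"}
                continue
            out_routes = path_flux(usable, times, probs)
            result[name] = [
                {
                    "route": list(p.route),
                    "transition_time": p.transition_time,
                    "rate": p.rate,
                    "flux": p.flux,
                    "probability": p.probability,
                }
                for p in out_routes
            ]
        paths["flux.json"].write_text(json.dumps(result, indent=2))

    if cfg.run_flux and mfpt_estimates:
        stage("flux", ["flux.json"], do_flux)

    # ---- sensitivity -------------------------------------------------
    def do_sens(paths):
        budget = SimulationBudget(
            t_max=cfg.sensitivity_t_max,
            n_runs=cfg.sensitivity_n_runs,
            burn_in=cfg.burn_in,
            bin_width=cfg.bin_width,
            n_bins=cfg.n_bins,
            smoothing=cfg.smoothing,
            delta_merge=cfg.delta_merge,
            axes=cfg.axes,
            thresholds=cfg.thresholds,
            label_mode=cfg.label_mode,
            min_basin_probability=cfg.min_basin_probability,
        )
        frames = []
        for reg_id in cfg.sensitivity_regulations:
            scan = scan_regulation(
                network, reg_id, cfg.sensitivity_scales, budget=budget, seed=cfg.seed
            )
            long = scan.barriers.reset_index().melt(
                id_vars="scale", var_name="pair", value_name="barrier"
            )
            long["delta"] = scan.deltas.reset_index().melt(
                id_vars="scale", var_name="pair", value_name="delta"
            )["delta"]
            long.insert(0, "regulation", reg_id)
            frames.append(long)
        pd.concat(frames).to_csv(paths["sensitivity.tsv"], sep="\t", index=False)

    if cfg.run_sensitivity:
        stage("sensitivity", ["sensitivity.tsv"], do_sens)

    manifest.save(manifest_path)
    return manifest
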