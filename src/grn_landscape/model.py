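"""Regulatory network declaration, validation and per-reaction rate laws.

The model is a set of genes (proteins or microRNAs, treated identically in
the reaction formalism) plus signed regulations.  Each regulation defines
exactly one binding site on its target gene.  Binding of a multimer of the
source species to that site rescales the target's synthesis rate by a fold
factor (``lambda_a`` for activation, ``lambda_r`` for repression) and
sequesters ``m`` copies of the source species until unbinding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "GeneNode",
    "Regulation",
    "ParameterSet",
    "NetworkSpec",
    "CompiledNetwork",
    "default_network",
    "validate",
    "synthesis_rate",
    "binding_propensity",
    "unbinding_rate",
    "load_network",
    "save_network",
    "compile_network",
]

ACTIVATION = "activation"
REPRESSION = "repression"
_ALLOWED_MULTIMER = (1, 2, 4)
_ALLOWED_KINDS = ("protein", "microRNA")


@dataclass(frozen=True)
class GeneNode:
    """A synthesized/degraded species (protein or microRNA)."""

    name: str
    kind: str = "protein"
    g0: float = 50.0
    k: float = 1.0


@dataclass(frozen=True)
class Regulation:
    """A single binding site on ``target`` occupied by an ``m``-mer of ``source``.

    ``h``, ``f`` and ``lam`` default to the global values implied by the
    parameter set (``h_a``/``h_r``, ``k*omega``, ``lambda_a``/``lambda_r``)
    when left as ``None``.  ``strength_scale`` multiplies the binding rate and
    is the knob turned by sensitivity scans.
    """

    source: str
    target: str
    sign: str
    m: int = 2
    h: float | None = None
    f: float | None = None
    lam: float | None = None
    strength_scale: float = 1.0

    @property
    def id(self) -> str:
        arrow = "->" if self.sign == ACTIVATION else "-|"
        return f"{self.source}{arrow}{self.target}"


@dataclass(frozen=True)
class ParameterSet:
    """Global kinetic parameters; per-regulation values may override them.

    ``volume`` is the mass-action system-size constant for multimer binding:
    the propensity of an order-m binding reaction carries a 1/volume**(m-1)
    concentration normalization.  At the default volume = 1 the propensities
    are the bare printed formulas (h*n(n-1)/2 etc.).
    """

    k: float = 1.0
    g0: float = 50.0
    lambda_a: float = 8.0
    lambda_r: float = 0.5
    h_a: float = 2.0
    h_r: float = 1.875
    omega: float = 1000.0
    volume: float = 1.0

    @property
    def f(self) -> float:
        """Unbinding rate, tied to the adiabaticity ratio: f = k * omega."""
        return self.k * self.omega

    @property
    def xeq_a(self) -> float:
        return self.f / self.h_a

    @property
    def xeq_r(self) -> float:
        return self.f / self.h_r


@dataclass
class NetworkSpec:
    nodes: list[GeneNode]
    regulations: list[Regulation]
    params: ParameterSet = field(default_factory=ParameterSet)

    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def node(self, name: str) -> GeneNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def regulation(self, reg_id: str) -> Regulation:
        for r in self.regulations:
            if r.id == reg_id:
                return r
        raise KeyError(reg_id)

    def sites_on(self, target: str) -> list[Regulation]:
        """Binding sites on ``target``, in declaration order."""
        return [r for r in self.regulations if r.target == target]

    def with_strength(self, reg_id: str, scale: float) -> "NetworkSpec":
        """Copy of the network with one regulation's strength_scale replaced."""
        regs = [
            replace(r, strength_scale=scale) if r.id == reg_id else r
            for r in self.regulations
        ]
        if not any(r.id == reg_id for r in self.regulations):
            raise KeyError(reg_id)
        return NetworkSpec(list(self.nodes), regs, self.params)


def reg_h(reg: Regulation, params: ParameterSet) -> float:
    if reg.h is not None:
        return reg.h
    return params.h_a if reg.sign == ACTIVATION else params.h_r


def reg_f(reg: Regulation, params: ParameterSet) -> float:
    return reg.f if reg.f is not None else params.k * params.omega


def reg_lambda(reg: Regulation, params: ParameterSet) -> float:
    if reg.lam is not None:
        return reg.lam
    return params.lambda_a if reg.sign == ACTIVATION else params.lambda_r


# --------------------------------------------------------------------------
# The shipped default wiring: 6 nodes, 16 regulations (7 activations, 9
# repressions).  The direct P53 -| OCT4 repression and the repressive sign
# of OCT4 -| miR145 follow the effective-regulation chains spelled out in
# the circuit description (e.g. mutual OCT4/ZEB activation runs through
# OCT4 -| miR145 -| ZEB).  Multimer order is per regulation: microRNA
# repressors bind as dimers, protein regulators as tetramers.
_DEFAULT_EDGES: list[tuple[str, str, str, int]] = [
    ("miR200", "ZEB", REPRESSION, 2),
    ("P53", "miR200", ACTIVATION, 4),
    ("P53", "miR145", ACTIVATION, 4),
    ("P53", "MDM2", ACTIVATION, 4),
    ("miR145", "ZEB", REPRESSION, 2),
    ("miR145", "OCT4", REPRESSION, 2),
    ("miR145", "MDM2", REPRESSION, 2),
    ("ZEB", "miR200", REPRESSION, 4),
    ("ZEB", "miR145", REPRESSION, 4),
    ("ZEB", "ZEB", ACTIVATION, 4),
    ("OCT4", "miR200", ACTIVATION, 4),
    ("OCT4", "miR145", REPRESSION, 2),
    ("MDM2", "P53", REPRESSION, 4),
    ("OCT4", "OCT4", ACTIVATION, 4),
    ("P53", "P53", ACTIVATION, 4),
    ("P53", "OCT4", REPRESSION, 2),
]

_DEFAULT_NODES: list[tuple[str, str]] = [
    ("P53", "protein"),
    ("MDM2", "protein"),
    ("ZEB", "protein"),
    ("OCT4", "protein"),
    ("miR145", "microRNA"),
    ("miR200", "microRNA"),
]

DEFAULT_VOLUME = 50.0


def default_network(
    omega: float = 1000.0, volume: float = DEFAULT_VOLUME
) -> NetworkSpec:
    """The shipped 6-node / 16-regulation circuit with default kinetics."""
    params = ParameterSet(omega=omega, volume=volume)
    nodes = [GeneNode(name, kind, params.g0, params.k) for name, kind in _DEFAULT_NODES]
    regs = [
        Regulation(src, tgt, sign, m=m) for src, tgt, sign, m in _DEFAULT_EDGES
    ]
    return NetworkSpec(nodes, regs, params)


def validate(network: NetworkSpec) -> list[str]:
    """Return human-readable invariant violations (empty list means valid)."""
    problems: list[str] = []
    names = [n.name for n in network.nodes]
    seen: set[str] = set()
    for n in network.nodes:
        if n.name in seen:
            problems.append(f"duplicate node name {n.name!r}")
        seen.add(n.name)
        if n.kind not in _ALLOWED_KINDS:
            problems.append(f"node {n.name!r}: unknown kind {n.kind!r}")
        if not n.g0 > 0:
            problems.append(f"node {n.name!r}: g0 must be > 0 (got {n.g0})")
        if not n.k > 0:
            problems.append(f"node {n.name!r}: k must be > 0 (got {n.k})")
    p = network.params
    for attr in ("k", "g0", "h_a", "h_r", "omega"):
        if not getattr(p, attr) > 0:
            problems.append(f"parameter {attr} must be > 0")
    if not p.lambda_a > 1:
        problems.append(f"lambda_a must be > 1 (got {p.lambda_a})")
    if not 0 < p.lambda_r < 1:
        problems.append(f"lambda_r must be in (0, 1) (got {p.lambda_r})")
    for r in network.regulations:
        if r.source not in names:
            problems.append(f"regulation {r.id}: unknown source {r.source!r}")
        if r.target not in names:
            problems.append(f"regulation {r.id}: unknown target {r.target!r}")
        if r.sign not in (ACTIVATION, REPRESSION):
            problems.append(f"regulation {r.id}: unknown sign {r.sign!r}")
        if r.m not in _ALLOWED_MULTIMER:
            problems.append(f"regulation {r.id}: multimer order must be 1, 2 or 4")
        if r.h is not None and not r.h > 0:
            problems.append(f"regulation {r.id}: h must be > 0")
        if r.f is not None and not r.f > 0:
            problems.append(f"regulation {r.id}: f must be > 0")
        if not r.strength_scale > 0:
            problems.append(f"regulation {r.id}: strength_scale must be > 0")
        lam = r.lam
        if lam is not None:
            if r.sign == ACTIVATION and not lam > 1:
                problems.append(f"regulation {r.id}: activation fold must be > 1")
            if r.sign == REPRESSION and not 0 < lam < 1:
                problems.append(f"regulation {r.id}: repression fold must be in (0, 1)")
    return problems


def synthesis_rate(
    gene: GeneNode,
    sites: Sequence[Regulation],
    occupancy: Sequence[int],
    params: ParameterSet,
) -> float:
    """Synthesis rate of ``gene`` given its sites' bound/unbound pattern.

    Every bound activating site multiplies the base rate by the activation
    fold, every bound repressing site by the repression fold; an n-site gene
    therefore has 2**n distinct synthesis rates.
    """
    if len(occupancy) != len(sites):
        raise ValueError(
            f"occupancy length {len(occupancy)} != number of sites {len(sites)}"
        )
    rate = gene.g0
    for reg, occ in zip(sites, occupancy):
        if occ:
            rate *= reg_lambda(reg, params)
    return rate


def binding_propensity(reg: Regulation, n: int, params: ParameterSet) -> float:
    """Propensity of the multimer-binding reaction at ``n`` free source copies.

    Monomer: h*n; dimer: h*n(n-1)/2; tetramer: h*n(n-1)(n-2)(n-3)/6 (the
    tetramer divisor is 6, as printed in the source model, not 4!).  Always 0
    when fewer than ``m`` copies are available.
    """
    if n < 0:
        raise ValueError(f"copy number must be non-negative, got {n}")
    if n < reg.m:
        return 0.0
    h = reg_h(reg, params) * reg.strength_scale / params.volume ** (reg.m - 1)
    if reg.m == 1:
        return h * n
    if reg.m == 2:
        return h * n * (n - 1) / 2.0
    if reg.m == 4:
        return h * n * (n - 1) * (n - 2) * (n - 3) / 6.0
    raise ValueError(f"unsupported multimer order {reg.m}")


def unbinding_rate(reg: Regulation, params: ParameterSet) -> float:
    """Unbinding propensity of a bound site (f = k * omega unless overridden)."""
    return reg_f(reg, params)


# --------------------------------------------------------------------------
# Config file I/O

def _params_from_dict(d: dict) -> ParameterSet:
    keys = {"k", "g0", "lambda_a", "lambda_r", "h_a", "h_r", "omega", "volume"}
    unknown = set(d) - keys
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ParameterSet(**{k: float(v) for k, v in d.items()})


def network_from_dict(doc: dict) -> NetworkSpec:
    params = _params_from_dict(doc.get("params", {}))
    nodes = [
        GeneNode(
            name=str(n["name"]),
            kind=str(n.get("kind", "protein")),
            g0=float(n.get("g0", params.g0)),
            k=float(n.get("k", params.k)),
        )
        for n in doc["nodes"]
    ]
    regs = []
    for r in doc["regulations"]:
        regs.append(
            Regulation(
                source=str(r["source"]),
                target=str(r["target"]),
                sign=str(r["sign"]),
                m=int(r.get("m", 2)),
                h=None if r.get("h") is None else float(r["h"]),
                f=None if r.get("f") is None else float(r["f"]),
                lam=None if r.get("lam") is None else float(r["lam"]),
                strength_scale=float(r.get("strength_scale", 1.0)),
            )
        )
    return NetworkSpec(nodes, regs, params)


def network_to_dict(network: NetworkSpec) -> dict:
    p = network.params
    return {
        "params": {
            "k": p.k,
            "g0": p.g0,
            "lambda_a": p.lambda_a,
            "lambda_r": p.lambda_r,
            "h_a": p.h_a,
            "h_r": p.h_r,
            "omega": p.omega,
            "volume": p.volume,
        },
        "nodes": [
            {"name": n.name, "kind": n.kind, "g0": n.g0, "k": n.k}
            for n in network.nodes
        ],
        "regulations": [
            {
                "source": r.source,
                "target": r.target,
                "sign": r.sign,
                "m": r.m,
                **({"h": r.h} if r.h is not None else {}),
                **({"f": r.f} if r.f is not None else {}),
                **({"lam": r.lam} if r.lam is not None else {}),
                **(
                    {"strength_scale": r.strength_scale}
                    if r.strength_scale != 1.0
                    else {}
                ),
            }
            for r in network.regulations
        ],
    }


def load_network(path: str) -> NetworkSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    net = network_from_dict(doc)
    problems = validate(net)
    if problems:
        raise ValueError("invalid network config:\n" + "\n".join(problems))
    return net


def save_network(network: NetworkSpec, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(network), fh, sort_keys=False)


def default_network_path() -> str:
    return str(resources.files("grn_landscape.data") / "default_network.yaml")


# --------------------------------------------------------------------------
# Array form consumed by the simulation kernels

@dataclass(frozen=True)
class CompiledNetwork:
    """Flat array view of a NetworkSpec for the jitted SSA kernels."""

    species: tuple[str, ...]
    g0: np.ndarray          # (S,) base synthesis rates
    k: np.ndarray           # (S,) degradation rates
    site_source: np.ndarray  # (R,) species index
    site_target: np.ndarray  # (R,) species index
    site_m: np.ndarray      # (R,) multimer order
    site_h: np.ndarray      # (R,) binding rate incl. strength_scale
    site_f: np.ndarray      # (R,) unbinding rate
    site_lam: np.ndarray    # (R,) synthesis fold when bound
    tgt_ptr: np.ndarray     # (S+1,) CSR offsets into tgt_sites
    tgt_sites: np.ndarray   # sites grouped by target species

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.site_source)

    def species_index(self, name: str) -> int:
        return self.species.index(name)


def compile_network(network: NetworkSpec) -> CompiledNetwork:
    problems = validate(network)
    if problems:
        raise ValueError("invalid network:\n" + "\n".join(problems))
    p = network.params
    names = tuple(n.name for n in network.nodes)
    idx = {n: i for i, n in enumerate(names)}
    regs = network.regulations
    site_source = np.array([idx[r.source] for r in regs], dtype=np.int64)
    site_target = np.array([idx[r.target] for r in regs], dtype=np.int64)
    site_m = np.array([r.m for r in regs], dtype=np.int64)
    site_h = np.array(
        [reg_h(r, p) * r.strength_scale / p.volume ** (r.m - 1) for r in regs]
    )
    site_f = np.array([reg_f(r, p) for r in regs])
    site_lam = np.array([reg_lambda(r, p) for r in regs])
    order = []
    ptr = [0]
    for s in range(len(names)):
        order.extend(i for i in range(len(regs)) if site_target[i] == s)
        ptr.append(len(order))
    return CompiledNetwork(
        species=names,
        g0=np.array([n.g0 for n in network.nodes]),
        k=np.array([n.k for n in network.nodes]),
        site_source=site_source,
        site_target=site_target,
        site_m=site_m,
        site_h=site_h,
        site_f=site_f,
        site_lam=site_lam,
        tgt_ptr=np.array(ptr, dtype=np.int64),
        tgt_sites=np.array(order, dtype=np.int64),
    )
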