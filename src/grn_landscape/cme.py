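"""Direct linear-algebra solution of the truncated master equation.

Only meant for test-scale systems (a few species, a couple of binding
sites): every state (copy-number vector up to a truncation, occupancy bits)
is enumerated, the generator assembled sparsely, and the stationary vector
solved for exactly.  Serves as the independent oracle against which the
Gillespie engine is validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import CompiledNetwork, NetworkSpec
from .ssa import _as_compiled

__all__ = ["CmeSolution", "build_generator", "solve_cme_reference", "ctmc_mfpt"]

_MAX_STATES = 200_000


@dataclass
class CmeSolution:
    probabilities: np.ndarray      # (n_states,)
    copy_numbers: np.ndarray       # (n_states, S)
    occupancy: np.ndarray          # (n_states, R)
    boundary_mass: float           # probability sitting at the truncation edge

    def marginal(self, species_index: int) -> np.ndarray:
        """Stationary marginal over one species' copy number."""
        n_max = int(self.copy_numbers[:, species_index].max())
        out = np.zeros(n_max + 1)
        np.add.at(out, self.copy_numbers[:, species_index], self.probabilities)
        return out


def _enumerate_states(c: CompiledNetwork, trunc: np.ndarray):
    radix = [int(t) + 1 for t in trunc] + [2] * c.n_sites
    n_states = int(np.prod(radix))
    if n_states > _MAX_STATES:
        raise ValueError(f"state space too large to enumerate ({n_states})")
    grids = np.indices(radix).reshape(len(radix), n_states).T
    copy_numbers = grids[:, : c.n_species].astype(np.int64)
    occupancy = grids[:, c.n_species :].astype(np.uint8)
    strides = np.ones(len(radix), dtype=np.int64)
    for i in range(len(radix) - 2, -1, -1):
        strides[i] = strides[i + 1] * radix[i + 1]
    return copy_numbers, occupancy, strides, n_states


def _binding_rate(h: float, m: int, x: int) -> float:
    if x < m:
        return 0.0
    if m == 1:
        return h * x
    if m == 2:
        return h * x * (x - 1) / 2.0
    return h * x * (x - 1) * (x - 2) * (x - 3) / 6.0


def build_generator(
    network: NetworkSpec | CompiledNetwork,
    truncation: int | Sequence[int],
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Row-convention generator Q (Q[i, j] = rate of i -> j, rows sum to 0)
    of the truncated process, plus the state enumeration.

    Synthesis at the truncation edge and unbinding that would push a species
    past it are dropped (reflecting truncation)."""
    c = _as_compiled(network)
    trunc = np.broadcast_to(np.asarray(truncation, dtype=np.int64), (c.n_species,))
    copy_numbers, occupancy, strides, n_states = _enumerate_states(c, trunc)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    syn_cache: dict[bytes, np.ndarray] = {}
    S, R = c.n_species, c.n_sites

    for i in range(n_states):
        n = copy_numbers[i]
        b = occupancy[i]
        key = b.tobytes()
        syn = syn_cache.get(key)
        if syn is None:
            syn = np.array(
                [
                    c.g0[t]
                    * np.prod(
                        [
                            c.site_lam[r]
                            for r in c.tgt_sites[c.tgt_ptr[t] : c.tgt_ptr[t + 1]]
                            if b[r]
                        ]
                    )
                    for t in range(S)
                ]
            )
            syn_cache[key] = syn
        for s in range(S):
            if n[s] < trunc[s] and syn[s] > 0:
                rows.append(i)
                cols.append(i + strides[s])
                vals.append(float(syn[s]))
            if n[s] > 0:
                rows.append(i)
                cols.append(i - strides[s])
                vals.append(float(c.k[s] * n[s]))
        for r in range(R):
            src = int(c.site_source[r])
            m = int(c.site_m[r])
            if b[r]:
                if n[src] + m <= trunc[src]:
                    rows.append(i)
                    cols.append(i + m * strides[src] - strides[S + r])
                    vals.append(float(c.site_f[r]))
            else:
                rate = _binding_rate(float(c.site_h[r]), m, int(n[src]))
                if rate > 0:
                    rows.append(i)
                    cols.append(i - m * strides[src] + strides[S + r])
                    vals.append(rate)

    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states)).tocsr()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=1)).ravel())
    return Q.tocsr(), copy_numbers, occupancy


def solve_cme_reference(
    network: NetworkSpec | CompiledNetwork,
    truncation: int | Sequence[int],
    boundary_tol: float = 1e-4,
) -> CmeSolution:
    """Stationary distribution of the truncated generator (testing oracle)."""
    c = _as_compiled(network)
    Q, copy_numbers, occupancy = build_generator(c, truncation)
    n_states = Q.shape[0]
    # stationary p solves p Q = 0 with sum(p) = 1
    A = Q.T.tolil()
    A[0, :] = 1.0
    rhs = np.zeros(n_states)
    rhs[0] = 1.0
    p = spla.spsolve(A.tocsr(), rhs)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    trunc = np.broadcast_to(np.asarray(truncation, dtype=np.int64), (c.n_species,))
    at_edge = (copy_numbers == trunc[None, :]).any(axis=1)
    boundary_mass = float(p[at_edge].sum())
    if boundary_mass > boundary_tol:
        warnings.warn(
            f"truncation too small: boundary mass {boundary_mass:.2e} exceeds "
            f"{boundary_tol:.0e}",
            stacklevel=2,
        )
    return CmeSolution(p, copy_numbers, occupancy, boundary_mass)


def ctmc_mfpt(Q: np.ndarray | sp.spmatrix, targets: Sequence[int]) -> np.ndarray:
    """Mean first-passage times to ``targets`` for a row-convention generator.

    Solves Q_AA tau = -1 over the non-target states; returns tau for all
    states (0 at targets).  Used as the brute-force oracle for simulated
    first-passage estimates."""
    Q = sp.csr_matrix(Q)
    n = Q.shape[0]
    targets = np.asarray(list(targets), dtype=np.int64)
    keep = np.ones(n, dtype=bool)
    keep[targets] = False
    idx = np.where(keep)[0]
    sub = Q[idx][:, idx]
    tau_sub = spla.spsolve(sub.tocsc(), -np.ones(len(idx)))
    tau = np.zeros(n)
    tau[idx] = tau_sub
    return tau
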