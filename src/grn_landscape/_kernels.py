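"""Jitted inner loops for the exact stochastic simulation.

Reaction index layout inside a propensity vector of length 2*S + 2*R
(S species, R binding sites):

    [0, S)          synthesis per species
    [S, 2S)         degradation per species (free copies only)
    [2S, 2S+R)      binding per site (zero while bound)
    [2S+R, 2S+2R)   unbinding per site (zero while unbound)

Binding sequesters ``m`` copies of the source species; unbinding releases
them.  The synthesis rate of a gene is recomputed exactly (product over its
bound sites) after every flip to avoid multiplicative float drift.
"""

import numpy as np
from numba import njit

__all__ = ["ssa_histogram", "ssa_trajectory", "ssa_first_passage", "compute_syn"]


@njit(cache=True)
def compute_syn(g0, lam, bound, tgt_ptr, tgt_sites, syn):
    S = g0.shape[0]
    for t in range(S):
        prod = g0[t]
        for q in range(tgt_ptr[t], tgt_ptr[t + 1]):
            r = tgt_sites[q]
            if bound[r] == 1:
                prod *= lam[r]
        syn[t] = prod


@njit(cache=True, inline="always")
def _fill_prop(n, bound, syn, kdeg, src, m, h, f, prop):
    S = n.shape[0]
    R = src.shape[0]
    tot = 0.0
    for s in range(S):
        prop[s] = syn[s]
        prop[S + s] = kdeg[s] * n[s]
        tot += prop[s] + prop[S + s]
    for r in range(R):
        if bound[r] == 1:
            pb = 0.0
            pu = f[r]
        else:
            x = n[src[r]]
            mm = m[r]
            if x < mm:
                pb = 0.0
            elif mm == 1:
                pb = h[r] * x
            elif mm == 2:
                pb = h[r] * x * (x - 1) * 0.5
            else:
                pb = h[r] * x * (x - 1) * (x - 2) * (x - 3) / 6.0
            pu = 0.0
        prop[2 * S + r] = pb
        prop[2 * S + R + r] = pu
        tot += pb + pu
    return tot


@njit(cache=True, inline="always")
def _apply(j, n, bound, syn, g0, lam, src, tgt, m, tgt_ptr, tgt_sites):
    S = n.shape[0]
    R = src.shape[0]
    if j < S:
        n[j] += 1
        return j
    if j < 2 * S:
        n[j - S] -= 1
        return j - S
    r = j - 2 * S
    if r < R:
        n[src[r]] -= m[r]
        bound[r] = 1
    else:
        r -= R
        n[src[r]] += m[r]
        bound[r] = 0
    t = tgt[r]
    prod = g0[t]
    for q in range(tgt_ptr[t], tgt_ptr[t + 1]):
        s2 = tgt_sites[q]
        if bound[s2] == 1:
            prod *= lam[s2]
    syn[t] = prod
    return src[r]


@njit(cache=True, inline="always")
def _select(prop, tot, nrx):
    u = np.random.random() * tot
    c = 0.0
    for idx in range(nrx):
        c += prop[idx]
        if u <= c:
            return idx
    return nrx - 1


@njit(cache=True)
def ssa_histogram(
    g0, kdeg, src, tgt, m, h, f, lam, tgt_ptr, tgt_sites,
    n0, bound0, t_max, burn_in, seed,
    a0, a1, a2, bin_width, hist, max_events,
):
    """Run SSA to t_max, accumulating post-burn-in dwell time into ``hist``
    (3D, indexed by copy number // bin_width of axis species a0, a1, a2,
    top bin clipped).  Returns (n, bound, t_end, n_events)."""
    np.random.seed(seed)
    S = g0.shape[0]
    R = src.shape[0]
    nrx = 2 * S + 2 * R
    n = n0.copy()
    bound = bound0.copy()
    syn = np.empty(S)
    compute_syn(g0, lam, bound, tgt_ptr, tgt_sites, syn)
    prop = np.empty(nrx)
    nb0, nb1, nb2 = hist.shape
    t = 0.0
    events = 0
    while events < max_events:
        tot = _fill_prop(n, bound, syn, kdeg, src, m, h, f, prop)
        if tot <= 0.0:
            break
        t_new = t + np.random.exponential(1.0) / tot
        lo = t if t > burn_in else burn_in
        hi = t_new if t_new < t_max else t_max
        if hi > lo:
            i0 = n[a0] // bin_width
            i1 = n[a1] // bin_width
            i2 = n[a2] // bin_width
            if i0 >= nb0:
                i0 = nb0 - 1
            if i1 >= nb1:
                i1 = nb1 - 1
            if i2 >= nb2:
                i2 = nb2 - 1
            hist[i0, i1, i2] += hi - lo
        if t_new >= t_max:
            t = t_max
            break
        j = _select(prop, tot, nrx)
        _apply(j, n, bound, syn, g0, lam, src, tgt, m, tgt_ptr, tgt_sites)
        t = t_new
        events += 1
    return n, bound, t, events


@njit(cache=True)
def ssa_trajectory(
    g0, kdeg, src, tgt, m, h, f, lam, tgt_ptr, tgt_sites,
    n0, bound0, t_max, seed, record_every, rec_n, rec_bound, max_events,
):
    """Run SSA recording the state at multiples of record_every.

    rec_n: (n_records, S) int64 output; rec_bound: (n_records, R) uint8.
    Record i holds the state at time i * record_every.  Returns
    (n, bound, t_end, n_events, n_recorded)."""
    np.random.seed(seed)
    S = g0.shape[0]
    R = src.shape[0]
    nrx = 2 * S + 2 * R
    n = n0.copy()
    bound = bound0.copy()
    syn = np.empty(S)
    compute_syn(g0, lam, bound, tgt_ptr, tgt_sites, syn)
    prop = np.empty(nrx)
    n_records = rec_n.shape[0]
    t = 0.0
    events = 0
    next_rec = 0
    while events < max_events:
        tot = _fill_prop(n, bound, syn, kdeg, src, m, h, f, prop)
        if tot <= 0.0:
            break
        t_new = t + np.random.exponential(1.0) / tot
        while next_rec < n_records and next_rec * record_every <= t_new:
            if next_rec * record_every > t_max:
                break
            for s in range(S):
                rec_n[next_rec, s] = n[s]
            for r in range(R):
                rec_bound[next_rec, r] = bound[r]
            next_rec += 1
        if t_new >= t_max:
            t = t_max
            break
        j = _select(prop, tot, nrx)
        _apply(j, n, bound, syn, g0, lam, src, tgt, m, tgt_ptr, tgt_sites)
        t = t_new
        events += 1
    return n, bound, t, events, next_rec


@njit(cache=True)
def ssa_first_passage(
    g0, kdeg, src, tgt, m, h, f, lam, tgt_ptr, tgt_sites,
    n0, bound0, seed, a0, a1, a2, bin_width, target_mask, max_events,
):
    """Run SSA until the (a0, a1, a2) voxel enters ``target_mask``.

    Returns (first_passage_time, n_events, reached) where reached is 0 for a
    censored run (event budget exhausted)."""
    np.random.seed(seed)
    S = g0.shape[0]
    R = src.shape[0]
    nrx = 2 * S + 2 * R
    n = n0.copy()
    bound = bound0.copy()
    syn = np.empty(S)
    compute_syn(g0, lam, bound, tgt_ptr, tgt_sites, syn)
    prop = np.empty(nrx)
    nb0, nb1, nb2 = target_mask.shape
    t = 0.0
    events = 0
    while events < max_events:
        tot = _fill_prop(n, bound, syn, kdeg, src, m, h, f, prop)
        if tot <= 0.0:
            break
        t += np.random.exponential(1.0) / tot
        j = _select(prop, tot, nrx)
        changed = _apply(j, n, bound, syn, g0, lam, src, tgt, m, tgt_ptr, tgt_sites)
        events += 1
        if changed == a0 or changed == a1 or changed == a2:
            i0 = n[a0] // bin_width
            i1 = n[a1] // bin_width
            i2 = n[a2] // bin_width
            if i0 >= nb0:
                i0 = nb0 - 1
            if i1 >= nb1:
                i1 = nb1 - 1
            if i2 >= nb2:
                i2 = nb2 - 1
            if target_mask[i0, i1, i2]:
                return t, events, 1
    return t, events, 0
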