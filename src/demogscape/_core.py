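"""Numba kernels for the structured-coalescent simulator.

Everything here works on plain arrays so it can be jitted; the friendly
interfaces live in :mod:`demogscape.coalescent`. Time runs backward from the
present in generations. Demes are indexed 0 (north) and 1 (south); after the
divergence time all lineages sit in deme 0, whose size becomes the ancestral
size.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sim_genealogy", "sim_path_stats", "branch_sfs",
           "leaf_sets", "poisson_mutations"]


@njit(cache=True)
def sim_genealogy(seed, n1, n2, starts, two_n, migs, t_div, two_n_anc):
    """Simulate one genealogy under a two-deme piecewise-constant history.

    Parameters are raw arrays: ``starts`` (epoch start times, ``starts[0]==0``,
    strictly increasing, all < ``t_div``), ``two_n[e, d]`` the number of gene
    copies (2N for diploid sizes) in deme ``d`` during epoch ``e``, and
    ``migs[e, d, f]`` the backward per-generation rate at which a lineage in
    deme ``d`` jumps to deme ``f``. Coalescence in a deme with ``k`` lineages
    occurs at rate ``k(k-1)/2 / two_n``. Returns ``(parent, node_time)`` for
    the ``2(n1+n2)-1`` nodes; leaves ``0..n1-1`` were sampled in deme 0 and
    ``n1..n1+n2-1`` in deme 1. Parents always have larger indices than their
    children (nodes are created in time order).
    """
    np.random.seed(seed)
    n = n1 + n2
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)

    act = np.empty(n, dtype=np.int64)
    deme = np.empty(n, dtype=np.int64)  # deme of act[i]
    for i in range(n):
        act[i] = i
        deme[i] = 0 if i < n1 else 1
    n_act = n
    k0 = n1
    k1 = n2

    t = 0.0
    epoch = 0
    n_epochs = starts.shape[0]
    nxt = n  # next internal node id
    merged = t_div <= 0.0
    if merged:
        for i in range(n_act):
            deme[i] = 0
        k0 = n_act
        k1 = 0

    while n_act > 1:
        if merged:
            rc0 = k0 * (k0 - 1) * 0.5 / two_n_anc
            rc1 = 0.0
            rm0 = 0.0
            rm1 = 0.0
            boundary = np.inf
        else:
            rc0 = k0 * (k0 - 1) * 0.5 / two_n[epoch, 0]
            rc1 = k1 * (k1 - 1) * 0.5 / two_n[epoch, 1]
            rm0 = k0 * migs[epoch, 0, 1]
            rm1 = k1 * migs[epoch, 1, 0]
            if epoch + 1 < n_epochs:
                boundary = starts[epoch + 1]
                if boundary > t_div:
                    boundary = t_div
            else:
                boundary = t_div
        total = rc0 + rc1 + rm0 + rm1

        if total > 0.0:
            w = np.random.exponential(1.0 / total)
        else:
            w = np.inf
        if t + w >= boundary:
            t = boundary
            if not merged and t >= t_div:
                merged = True
                for i in range(n_act):
                    deme[i] = 0
                k0 = n_act
                k1 = 0
            else:
                epoch += 1
            continue
        t += w

        u = np.random.random() * total
        if u < rc0 + rc1:
            d = 0 if u < rc0 else 1
            kd = k0 if d == 0 else k1
            # choose an unordered pair among the kd lineages of deme d
            a = np.int64(np.random.random() * kd)
            b = np.int64(np.random.random() * (kd - 1))
            if b >= a:
                b += 1
            ia = -1
            ib = -1
            seen = 0
            for i in range(n_act):
                if deme[i] == d:
                    if seen == a:
                        ia = i
                    if seen == b:
                        ib = i
                    seen += 1
            parent[act[ia]] = nxt
            parent[act[ib]] = nxt
            node_time[nxt] = t
            act[ia] = nxt
            nxt += 1
            act[ib] = act[n_act - 1]
            deme[ib] = deme[n_act - 1]
            n_act -= 1
            if d == 0:
                k0 -= 1
            else:
                k1 -= 1
        else:
            d = 0 if u < rc0 + rc1 + rm0 else 1
            kd = k0 if d == 0 else k1
            a = np.int64(np.random.random() * kd)
            seen = 0
            for i in range(n_act):
                if deme[i] == d:
                    if seen == a:
                        deme[i] = 1 - d
                        break
                    seen += 1
            if d == 0:
                k0 -= 1
                k1 += 1
            else:
                k0 += 1
                k1 -= 1

    return parent, node_time


@njit(cache=True)
def sim_path_stats(seed, n1, n2, starts, two_n, migs, t_div, two_n_anc,
                   cell_lo):
    """Simulate one genealogy under the reference model while recording the
    sufficient statistics of the path law on a fixed time partition.

    ``cell_lo`` are increasing cell lower bounds (``cell_lo[0] == 0``; the
    last cell is unbounded) chosen to contain every epoch boundary and
    candidate divergence time of interest. ``stats[c]`` holds, for cell
    ``c``: the integrals A0 = int k0(k0-1)/2 dt, A1, X = int k0*k1 dt,
    B0 = int k0 dt, B1; and the event counts C0, C1 (same-deme
    coalescences), CC (cross-deme coalescences, possible once the reference
    has merged), M01 and M10 (migrations). The log path density of ANY
    two-deme history that is piecewise constant on the partition — and that
    merges no earlier than the reference and allows no migration after the
    reference merger — is linear in these statistics, which makes exact
    importance reweighting over a parameter grid a single matrix product.

    Returns ``(parent, node_time, stats)``; demes keep their labels after
    the reference merger so the statistics remain meaningful for models
    that merge later (a cross-deme ancestor is labelled deme 0).
    """
    np.random.seed(seed)
    n = n1 + n2
    n_nodes = 2 * n - 1
    n_cells = cell_lo.shape[0]
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)
    stats = np.zeros((n_cells, 10), dtype=np.float64)

    act = np.empty(n, dtype=np.int64)
    deme = np.empty(n, dtype=np.int64)
    for i in range(n):
        act[i] = i
        deme[i] = 0 if i < n1 else 1
    n_act = n
    k0 = n1
    k1 = n2

    t = 0.0
    ci = 0  # current cell index
    epoch = 0
    n_epochs = starts.shape[0]
    nxt_node = n
    merged = t_div <= 0.0

    while n_act > 1:
        if merged:
            total = n_act * (n_act - 1) * 0.5 / two_n_anc
            rc0 = total
            rc1 = 0.0
            rm0 = 0.0
            rm1 = 0.0
            boundary = np.inf
        else:
            rc0 = k0 * (k0 - 1) * 0.5 / two_n[epoch, 0]
            rc1 = k1 * (k1 - 1) * 0.5 / two_n[epoch, 1]
            rm0 = k0 * migs[epoch, 0, 1]
            rm1 = k1 * migs[epoch, 1, 0]
            if epoch + 1 < n_epochs:
                boundary = starts[epoch + 1]
                if boundary > t_div:
                    boundary = t_div
            else:
                boundary = t_div
            total = rc0 + rc1 + rm0 + rm1

        if total > 0.0:
            w = np.random.exponential(1.0 / total)
        else:
            w = np.inf
        t_next = t + w
        if t_next >= boundary:
            t_next = boundary

        # spread the waiting interval across partition cells
        cur = t
        while cur < t_next:
            hi = cell_lo[ci + 1] if ci + 1 < n_cells else np.inf
            seg_end = t_next if t_next < hi else hi
            dt = seg_end - cur
            stats[ci, 0] += k0 * (k0 - 1) * 0.5 * dt
            stats[ci, 1] += k1 * (k1 - 1) * 0.5 * dt
            stats[ci, 2] += k0 * k1 * dt
            stats[ci, 3] += k0 * dt
            stats[ci, 4] += k1 * dt
            cur = seg_end
            if cur >= hi:
                ci += 1

        if t_next >= boundary:
            t = boundary
            if not merged and boundary >= t_div:
                merged = True
            else:
                epoch += 1
            continue
        t = t_next

        u = np.random.random() * total
        if u < rc0 + rc1:
            if merged:
                a = np.int64(np.random.random() * n_act)
                b = np.int64(np.random.random() * (n_act - 1))
                if b >= a:
                    b += 1
                ia, ib = a, b
            else:
                d = 0 if u < rc0 else 1
                kd = k0 if d == 0 else k1
                a = np.int64(np.random.random() * kd)
                b = np.int64(np.random.random() * (kd - 1))
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                seen = 0
                for i in range(n_act):
                    if deme[i] == d:
                        if seen == a:
                            ia = i
                        if seen == b:
                            ib = i
                        seen += 1
            d1 = deme[ia]
            d2 = deme[ib]
            if d1 == d2:
                stats[ci, 5 + d1] += 1.0
                if d1 == 0:
                    k0 -= 1
                else:
                    k1 -= 1
            else:
                stats[ci, 7] += 1.0
                k1 -= 1  # cross-deme ancestor labelled deme 0
            parent[act[ia]] = nxt_node
            parent[act[ib]] = nxt_node
            node_time[nxt_node] = t
            act[ia] = nxt_node
            deme[ia] = d1 if d1 == d2 else 0
            nxt_node += 1
            act[ib] = act[n_act - 1]
            deme[ib] = deme[n_act - 1]
            n_act -= 1
        else:
            d = 0 if u < rc0 + rc1 + rm0 else 1
            kd = k0 if d == 0 else k1
            a = np.int64(np.random.random() * kd)
            seen = 0
            for i in range(n_act):
                if deme[i] == d:
                    if seen == a:
                        deme[i] = 1 - d
                        break
                    seen += 1
            stats[ci, 8 + d] += 1.0
            if d == 0:
                k0 -= 1
                k1 += 1
            else:
                k0 += 1
                k1 -= 1

    return parent, node_time, stats


@njit(cache=True)
def branch_sfs(parent, node_time, n1, n2, out):
    """Accumulate branch length onto joint leaf-count classes.

    ``out[i, j]`` gains the total length of branches subtending exactly ``i``
    deme-0 leaves and ``j`` deme-1 leaves. Multiplying by the per-locus
    mutation rate gives the expected unfolded joint SFS contribution of this
    genealogy (the mutational expectation, taken analytically).
    """
    n_nodes = parent.shape[0]
    n = n1 + n2
    leaf0 = np.zeros(n_nodes, dtype=np.int64)
    leaf1 = np.zeros(n_nodes, dtype=np.int64)
    for l in range(n):
        if l < n1:
            leaf0[l] = 1
        else:
            leaf1[l] = 1
    for j in range(n_nodes - 1):
        p = parent[j]
        leaf0[p] += leaf0[j]
        leaf1[p] += leaf1[j]
        out[leaf0[j], leaf1[j]] += node_time[p] - node_time[j]


@njit(cache=True)
def leaf_sets(parent, n):
    """Boolean matrix ``below[v, l]``: leaf ``l`` descends from node ``v``."""
    n_nodes = parent.shape[0]
    below = np.zeros((n_nodes, n), dtype=np.bool_)
    for l in range(n):
        below[l, l] = True
    for j in range(n_nodes - 1):
        p = parent[j]
        for l in range(n):
            if below[j, l]:
                below[p, l] = True
    return below


@njit(cache=True)
def poisson_mutations(seed, parent, node_time, theta_per_branch_unit):
    """Number of mutations per branch: Poisson(rate * branch length).

    Branch ``j`` connects node ``j`` to ``parent[j]``; the root row is zero.
    """
    n_nodes = parent.shape[0]
    np.random.seed(seed)
    muts = np.zeros(n_nodes, dtype=np.int64)
    for j in range(n_nodes - 1):
        blen = node_time[parent[j]] - node_time[j]
        muts[j] = np.random.poisson(theta_per_branch_unit * blen)
    return muts
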