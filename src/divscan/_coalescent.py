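"""Structured two-population coalescent engine.

Backward-in-time continuous-time coalescent for two demes ("brown" = deme 0,
"ferox" = deme 1) that merge into an ancestral population at ``tdiv``
generations.  A single epoch boundary ``t2`` splits the divergence period:
symmetric migration runs at rate ``mig_recent`` (per lineage per generation)
for t < t2 and at ``mig_ancient`` for t2 <= t < tdiv, and an instantaneous
admixture pulse can fire at t2 (each deme-0 lineage jumps to deme 1 with
probability ``pulse_01`` and vice versa — the backward view of a forward
admixture event).  All six divergence scenarios (SI, IM, AM, SC, IMchange,
SCadm) are epoch/pulse configurations of this single machine.

Time is measured in generations; ``ne_*`` are diploid effective sizes, so a
pair of haploid lineages in a deme of size N coalesces at rate 1/(2N).

Two jit-compiled kernels:

- :func:`accumulate_branch_cells` — expected branch length subtending each
  (i, j) joint-sample-count class, the Monte-Carlo ingredient of the
  expected joint SFS.
- :func:`simulate_mutation_masks` — per-locus genealogies with leaf-set
  bitmasks and infinite-sites Poisson mutation, the ingredient of the
  synthetic ddRAD dataset generator.

The two kernels deliberately share no code path beyond this module's event
logic written twice: agreement of the realised SFS of one with the expected
SFS of the other is itself a test invariant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["accumulate_branch_cells", "simulate_mutation_masks", "MAX_HAPLOIDS"]

#: leaf sets are int64 bitmasks, so at most 63 haploid samples per simulation
MAX_HAPLOIDS = 63


@njit(cache=True)
def accumulate_branch_cells(
    n1,
    n2,
    ne_b,
    ne_f,
    ne_anc,
    tdiv,
    t2,
    mig_recent,
    mig_ancient,
    pulse_01,
    pulse_10,
    n_sims,
    seed,
):
    """Monte-Carlo E[branch length] per joint descendant class.

    Returns a float64 array of shape (n1+1, n2+1): mean total branch length
    (generations) subtending exactly i deme-0 and j deme-1 samples, averaged
    over ``n_sims`` independent genealogies of n1 + n2 haploid lineages.
    """
    np.random.seed(seed)
    n = n1 + n2
    out = np.zeros((n1 + 1) * (n2 + 1), dtype=np.float64)
    deme = np.empty(n, dtype=np.int8)
    ci = np.empty(n, dtype=np.int32)
    cj = np.empty(n, dtype=np.int32)
    # a lineage's (ci, cj) class is constant over its lifetime, so branch
    # length is accrued once per merge (t - born) rather than per event
    born = np.empty(n, dtype=np.float64)

    for _ in range(n_sims):
        for x in range(n1):
            deme[x] = 0
            ci[x] = 1
            cj[x] = 0
        for x in range(n2):
            deme[n1 + x] = 1
            ci[n1 + x] = 0
            cj[n1 + x] = 1
        born[:] = 0.0
        k = n
        k0 = n1
        t = 0.0
        pulsed = t2 <= 0.0
        merged = tdiv <= 0.0
        if merged:
            for x in range(n):
                deme[x] = 0
            k0 = n

        while k > 1:
            if merged:
                rc0 = k * (k - 1) / (4.0 * ne_anc)
                rc1 = 0.0
                rm = 0.0
                boundary = np.inf
            else:
                k1 = k - k0
                rc0 = k0 * (k0 - 1) / (4.0 * ne_b)
                rc1 = k1 * (k1 - 1) / (4.0 * ne_f)
                m = mig_recent if not pulsed else mig_ancient
                rm = m * k
                boundary = t2 if not pulsed else tdiv
            total = rc0 + rc1 + rm

            if total > 0.0:
                dt = np.random.exponential(1.0 / total)
            else:
                dt = np.inf
            if t + dt >= boundary:
                t = boundary
                if not pulsed:
                    pulsed = True
                    if pulse_01 > 0.0 or pulse_10 > 0.0:
                        for x in range(k):
                            u = np.random.random()
                            if deme[x] == 0:
                                if u < pulse_01:
                                    deme[x] = 1
                            else:
                                if u < pulse_10:
                                    deme[x] = 0
                        k0 = 0
                        for x in range(k):
                            if deme[x] == 0:
                                k0 += 1
                else:
                    merged = True
                    for x in range(k):
                        deme[x] = 0
                    k0 = k
                continue
            t += dt

            u = np.random.random() * total
            if u < rc0 + rc1:
                d = 0 if u < rc0 else 1
                if merged:
                    kd = k
                else:
                    kd = k0 if d == 0 else k - k0
                a = np.random.randint(kd)
                b = np.random.randint(kd - 1)
                if b >= a:
                    b += 1
                # map within-deme ranks to lineage indices
                if not merged:
                    ia = -1
                    ib = -1
                    r = 0
                    for x in range(k):
                        if deme[x] == d:
                            if r == a:
                                ia = x
                            if r == b:
                                ib = x
                            r += 1
                else:
                    ia = a
                    ib = b
                out[ci[ia] * (n2 + 1) + cj[ia]] += t - born[ia]
                out[ci[ib] * (n2 + 1) + cj[ib]] += t - born[ib]
                ci[ia] += ci[ib]
                cj[ia] += cj[ib]
                born[ia] = t
                deme[ib] = deme[k - 1]
                ci[ib] = ci[k - 1]
                cj[ib] = cj[k - 1]
                born[ib] = born[k - 1]
                k -= 1
                if d == 0:
                    k0 -= 1
            else:
                x = np.random.randint(k)
                if deme[x] == 0:
                    deme[x] = 1
                    k0 -= 1
                else:
                    deme[x] = 0
                    k0 += 1

    out /= n_sims
    return out.reshape((n1 + 1, n2 + 1))


@njit(cache=True)
def simulate_mutation_masks(
    n1,
    n2,
    ne_b,
    ne_f,
    ne_anc,
    tdiv,
    t2,
    mig_recent,
    mig_ancient,
    pulse_01,
    pulse_10,
    n_loci,
    mu_locus,
    seed,
):
    """Simulate ``n_loci`` independent genealogies and drop mutations.

    Each locus is non-recombining; mutations arrive on each branch at rate
    ``mu_locus`` (per-locus per-generation, i.e. per-site mu times locus
    length) under infinite sites.  Returns ``(locus_idx, leaf_mask, count)``
    where ``leaf_mask[m]`` is an int64 bitmask over the n1 + n2 haploid
    samples carrying the derived allele of mutation ``m`` (deme-0 samples
    occupy bits 0..n1-1).  Arrays are over-allocated; only ``count`` entries
    are valid.
    """
    np.random.seed(seed)
    n = n1 + n2
    cap = n_loci * 8 + 1024
    mut_locus = np.empty(cap, dtype=np.int64)
    mut_mask = np.empty(cap, dtype=np.int64)
    nm_total = 0

    # per-genealogy node bookkeeping: n leaves + (n - 1) internal nodes
    deme = np.empty(n, dtype=np.int8)
    node_of = np.empty(n, dtype=np.int32)  # active lineage -> node id
    mask = np.empty(2 * n, dtype=np.int64)
    birth = np.empty(2 * n, dtype=np.float64)
    death = np.empty(2 * n, dtype=np.float64)

    for locus in range(n_loci):
        for x in range(n):
            deme[x] = 0 if x < n1 else 1
            node_of[x] = x
            mask[x] = np.int64(1) << x
            birth[x] = 0.0
        next_node = n
        k = n
        t = 0.0
        pulsed = t2 <= 0.0
        merged = tdiv <= 0.0
        if merged:
            for x in range(n):
                deme[x] = 0

        while k > 1:
            if merged:
                k0 = k
                rc0 = k0 * (k0 - 1) / (4.0 * ne_anc)
                rc1 = 0.0
                rm = 0.0
                boundary = np.inf
            else:
                k0 = 0
                for x in range(k):
                    if deme[x] == 0:
                        k0 += 1
                k1 = k - k0
                rc0 = k0 * (k0 - 1) / (4.0 * ne_b)
                rc1 = k1 * (k1 - 1) / (4.0 * ne_f)
                m = mig_recent if not pulsed else mig_ancient
                rm = m * k
                boundary = t2 if not pulsed else tdiv
            total = rc0 + rc1 + rm

            if total > 0.0:
                dt = np.random.exponential(1.0 / total)
            else:
                dt = np.inf
            if t + dt >= boundary:
                t = boundary
                if not pulsed:
                    pulsed = True
                    if pulse_01 > 0.0 or pulse_10 > 0.0:
                        for x in range(k):
                            u = np.random.random()
                            if deme[x] == 0:
                                if u < pulse_01:
                                    deme[x] = 1
                            else:
                                if u < pulse_10:
                                    deme[x] = 0
                else:
                    merged = True
                    for x in range(k):
                        deme[x] = 0
                continue
            t += dt

            u = np.random.random() * total
            if u < rc0 + rc1:
                d = 0 if u < rc0 else 1
                if merged:
                    kd = k
                else:
                    kd = k0 if d == 0 else k - k0
                a = np.random.randint(kd)
                b = np.random.randint(kd - 1)
                if b >= a:
                    b += 1
                if not merged:
                    ia = -1
                    ib = -1
                    r = 0
                    for x in range(k):
                        if deme[x] == d:
                            if r == a:
                                ia = x
                            if r == b:
                                ib = x
                            r += 1
                else:
                    ia = a
                    ib = b
                na = node_of[ia]
                nb = node_of[ib]
                death[na] = t
                death[nb] = t
                mask[next_node] = mask[na] | mask[nb]
                birth[next_node] = t
                node_of[ia] = next_node
                next_node += 1
                deme[ib] = deme[k - 1]
                node_of[ib] = node_of[k - 1]
                k -= 1
            else:
                x = np.random.randint(k)
                deme[x] = 1 - deme[x]

        # root = node_of[0]; every other created node carries mutations
        root = node_of[0]
        for nd in range(next_node):
            if nd == root:
                continue
            span = death[nd] - birth[nd]
            nm = np.random.poisson(mu_locus * span)
            for _ in range(nm):
                if nm_total < cap:
                    mut_locus[nm_total] = locus
                    mut_mask[nm_total] = mask[nd]
                    nm_total += 1

    return mut_locus[:nm_total], mut_mask[:nm_total], nm_total
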