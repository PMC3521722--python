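"""Numba kernels for the serial coalescent and GSM mutation simulator.

The kernels use numba's internal RNG, seeded explicitly per call (or per
locus) so that runs are replayable from integer seeds handed down by the
caller's ``numpy.random.Generator``.

Node layout: for n gene copies, tips are nodes ``0..n-1`` (grouped by
temporal sample, in sample order) and internal nodes ``n..2n-2`` are created
in coalescence order, so every node's parent has a larger index; the root is
node ``2n-2``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1.0e308


@njit(cache=True)
def _seed(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _sim_tree(sample_times, sample_counts, breaks, sizes, parent, node_time):
    """Serial Kingman coalescent under piecewise-constant diploid Ne.

    Lineages enter at their sample times (generations before present);
    while k lineages are active the pairwise-coalescence rate is
    k(k-1)/(4N) per generation.  Waiting times are exponential within an
    epoch and censored at epoch boundaries and sample-injection times
    (piecewise-exponential across boundaries).  Fills ``parent`` and
    ``node_time`` in place.
    """
    ns = sample_counts.shape[0]
    n = 0
    for i in range(ns):
        n += sample_counts[i]
    total = 2 * n - 1
    for i in range(total):
        parent[i] = -1
        node_time[i] = 0.0

    tip_start = np.empty(ns + 1, np.int64)
    tip_start[0] = 0
    for i in range(ns):
        tip_start[i + 1] = tip_start[i] + sample_counts[i]
    order = np.argsort(sample_times)

    active = np.empty(n, np.int64)
    k = 0
    si = 0
    nb = breaks.shape[0]
    ei = 0
    t = sample_times[order[0]]
    next_node = n
    while True:
        while si < ns and sample_times[order[si]] <= t:
            s = order[si]
            for tip in range(tip_start[s], tip_start[s + 1]):
                active[k] = tip
                node_time[tip] = sample_times[s]
                k += 1
            si += 1
        if k <= 1:
            if si < ns:
                t = sample_times[order[si]]
                continue
            break
        while ei < nb and t >= breaks[ei]:
            ei += 1
        rate = k * (k - 1) / (4.0 * sizes[ei])
        w = np.random.exponential(1.0 / rate)
        tb = INF
        if si < ns:
            tb = sample_times[order[si]]
        if ei < nb and breaks[ei] < tb:
            tb = breaks[ei]
        if t + w < tb:
            t = t + w
            i = np.random.randint(0, k)
            a = active[i]
            active[i] = active[k - 1]
            k -= 1
            j = np.random.randint(0, k)
            b = active[j]
            parent[a] = next_node
            parent[b] = next_node
            node_time[next_node] = t
            active[j] = next_node
            next_node += 1
        else:
            t = tb
    return n


@njit(cache=True)
def _drop_mutations(parent, node_time, n_tips, mu, p_gsm, founder, lo, hi, alleles):
    """Generalized stepwise mutations down a genealogy.

    Mutation counts per branch are Poisson(mu * branch length); each
    mutation steps the repeat count by +-s with s >= 1 geometric with
    parameter p_gsm (p_gsm = 0 degenerates to the strict single-step SMM);
    sizes are reflected at the state bounds [lo, hi].  Writes tip allele
    sizes into ``alleles``.
    """
    total = parent.shape[0]
    state = np.empty(total, np.int64)
    state[total - 1] = founder
    for node in range(total - 2, -1, -1):
        a = state[parent[node]]
        bl = node_time[parent[node]] - node_time[node]
        m = np.random.poisson(mu * bl)
        for _ in range(m):
            s = np.random.geometric(1.0 - p_gsm)
            if np.random.random() < 0.5:
                s = -s
            a += s
            while a < lo or a > hi:
                if a < lo:
                    a = 2 * lo - a
                else:
                    a = 2 * hi - a
        state[node] = a
    for i in range(n_tips):
        alleles[i] = state[i]


@njit(cache=True)
def k_sim_tree(seed, sample_times, sample_counts, breaks, sizes, parent, node_time):
    np.random.seed(seed)
    return _sim_tree(sample_times, sample_counts, breaks, sizes, parent, node_time)


@njit(cache=True)
def k_drop_mutations(seed, parent, node_time, n_tips, mu, p_gsm, founder, lo, hi, alleles):
    np.random.seed(seed)
    _drop_mutations(parent, node_time, n_tips, mu, p_gsm, founder, lo, hi, alleles)


@njit(cache=True)
def k_sim_locus(seed, sample_times, sample_counts, breaks, sizes, mu, p_gsm,
                founder, lo, hi, parent, node_time, alleles):
    """One locus end to end: genealogy plus mutations, from one seed."""
    np.random.seed(seed)
    n = _sim_tree(sample_times, sample_counts, breaks, sizes, parent, node_time)
    _drop_mutations(parent, node_time, n, mu, p_gsm, founder, lo, hi, alleles)
    return n


@njit(cache=True)
def _wc_pair(c1, c2, n1, n2):
    """Weir-Cockerham theta components for two samples from state counts.

    Returns (numerator, denominator) summed over alleles; both zero when the
    locus is unusable (monomorphic across both samples, or n < 2 copies).
    Mirrors stats._wc_components exactly.
    """
    nstates = c1.shape[0]
    k = 0
    for st in range(nstates):
        if c1[st] > 0 or c2[st] > 0:
            k += 1
    if k < 2 or n1 < 2 or n2 < 2:
        return 0.0, 0.0
    n_t = float(n1 + n2)
    n_c = n_t - (n1 * n1 + n2 * n2) / n_t
    num = 0.0
    den = 0.0
    for st in range(nstates):
        if c1[st] == 0 and c2[st] == 0:
            continue
        p1 = c1[st] / n1
        p2 = c2[st] / n2
        pbar = (n1 * p1 + n2 * p2) / n_t
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_t - 2.0)
        num += msp - msg
        den += msp + (n_c - 1.0) * msg
    return num, den


@njit(cache=True)
def k_dataset_summaries(locus_seeds, sample_times, sample_counts, breaks, sizes,
                        rates, p_gsm, founder, lo, hi, out):
    """Simulate all loci of one dataset and accumulate the summary vector.

    ``out`` receives, per temporal sample (in the order of ``sample_counts``):
    locus means of unbiased heterozygosity, allele count, unbiased allele-size
    variance and Garza-Williamson M; followed by the multi-locus
    Weir-Cockerham theta between the first and last samples (0.0 when fewer
    than two samples or no usable locus).
    """
    ns = sample_counts.shape[0]
    n = 0
    for i in range(ns):
        n += sample_counts[i]
    nl = rates.shape[0]
    total = 2 * n - 1
    parent = np.empty(total, np.int64)
    node_time = np.empty(total, np.float64)
    alleles = np.empty(n, np.int64)
    nstates = hi - lo + 1
    counts = np.zeros((ns, nstates), np.int64)
    acc = np.zeros((ns, 4), np.float64)
    fst_num = 0.0
    fst_den = 0.0
    for l in range(nl):
        np.random.seed(locus_seeds[l])
        _sim_tree(sample_times, sample_counts, breaks, sizes, parent, node_time)
        _drop_mutations(parent, node_time, n, rates[l], p_gsm, founder, lo, hi, alleles)
        for s in range(ns):
            for st in range(nstates):
                counts[s, st] = 0
        pos = 0
        for s in range(ns):
            for _ in range(sample_counts[s]):
                counts[s, alleles[pos] - lo] += 1
                pos += 1
        for s in range(ns):
            nc = float(sample_counts[s])
            sum_p2 = 0.0
            k_all = 0
            ssum = 0.0
            ssq = 0.0
            mn = hi + 1
            mx = lo - 1
            for st in range(nstates):
                c = counts[s, st]
                if c > 0:
                    k_all += 1
                    p = c / nc
                    sum_p2 += p * p
                    size = lo + st
                    ssum += c * size
                    ssq += c * size * size
                    if size < mn:
                        mn = size
                    if size > mx:
                        mx = size
            acc[s, 0] += nc / (nc - 1.0) * (1.0 - sum_p2)
            acc[s, 1] += k_all
            acc[s, 2] += (ssq - ssum * ssum / nc) / (nc - 1.0)
            acc[s, 3] += k_all / (mx - mn + 1.0)
        if ns >= 2:
            num, den = _wc_pair(counts[0], counts[ns - 1],
                                float(sample_counts[0]),
                                float(sample_counts[ns - 1]))
            fst_num += num
            fst_den += den
    for s in range(ns):
        for q in range(4):
            out[s * 4 + q] = acc[s, q] / nl
    if ns >= 2:
        out[ns * 4] = fst_num / fst_den if fst_den > 0.0 else 0.0
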