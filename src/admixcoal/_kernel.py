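"""Numba kernels for the backward-in-time coalescent over independent loci.

The demography is passed as flat epoch tables (see ``models.Demography``):
piecewise-exponential diploid sizes, per-epoch backward migration rates and
discrete boundary events (admixture pulses, lineage joins).  Within an
epoch, waiting times are drawn exactly by inverting the cumulative hazard
of the time-inhomogeneous coalescence rate k(k-1)/2 / (2 N(t)); migration
is a competing constant-rate exponential clock.  No discretised
generations are involved.
"""

import numpy as np
from numba import njit

_BIG = 1.0e299


@njit(cache=True)
def _coal_wait(k, n_cur, beta, e1):
    """Waiting time to the next coalescence among k lineages.

    Size from the current instant is ``n_cur * exp(beta * s)``; ``e1`` is a
    standard exponential draw.  Returns inf if the hazard saturates first
    (possible when the population grows backward in time, beta > 0).
    """
    if k < 2:
        return np.inf
    c = 0.5 * k * (k - 1.0)
    if beta == 0.0:
        return 2.0 * n_cur * e1 / c
    x = 1.0 - 2.0 * n_cur * beta * e1 / c
    if x <= 0.0:
        return np.inf
    return -np.log(x) / beta


@njit(cache=True)
def sim_genealogy_kernel(breaks, N0, beta, mig,
                         ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
                         sample_pop):
    """Simulate one locus genealogy; caller must seed np.random beforehand.

    Returns (parent, lchild, rchild, node_time) over 2n-1 nodes; leaves are
    nodes 0..n-1, internal nodes appear in coalescence order, the root has
    parent -1.
    """
    n = sample_pop.shape[0]
    n_pops = N0.shape[1]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    lchild = np.full(n_nodes, -1, dtype=np.int64)
    rchild = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)

    act_node = np.empty(n, dtype=np.int64)
    act_pop = np.empty(n, dtype=np.int64)
    for i in range(n):
        act_node[i] = i
        act_pop[i] = sample_pop[i]
    cnt = n
    next_node = n
    t = 0.0
    e = 0
    n_epochs = breaks.shape[0] - 1
    kpop = np.zeros(n_pops, dtype=np.int64)

    while cnt > 1:
        t_end = breaks[e + 1]
        # per-population lineage counts
        for p in range(n_pops):
            kpop[p] = 0
        for i in range(cnt):
            kpop[act_pop[i]] += 1
        # candidate coalescence per population
        best_s = np.inf
        best_pop = -1
        for p in range(n_pops):
            if kpop[p] >= 2:
                d = t - breaks[e]
                n_cur = N0[e, p] * np.exp(beta[e, p] * d)
                s = _coal_wait(kpop[p], n_cur, beta[e, p], np.random.exponential())
                if s < best_s:
                    best_s = s
                    best_pop = p
        # candidate migration (constant rates within the epoch)
        mig_rate = 0.0
        for p in range(n_pops):
            if kpop[p] > 0:
                for q in range(n_pops):
                    mig_rate += kpop[p] * mig[e, p, q]
        is_mig = False
        if mig_rate > 0.0:
            s_m = np.random.exponential() / mig_rate
            if s_m < best_s:
                best_s = s_m
                is_mig = True
        if t + best_s <= t_end and best_s < _BIG:
            t = t + best_s
            if is_mig:
                # choose (lineage, destination) with prob proportional to rate
                u = np.random.random() * mig_rate
                acc = 0.0
                done = False
                for i in range(cnt):
                    if done:
                        break
                    p = act_pop[i]
                    for q in range(n_pops):
                        acc += mig[e, p, q]
                        if acc >= u:
                            act_pop[i] = q
                            done = True
                            break
            else:
                # choose an unordered pair uniformly within best_pop
                k = kpop[best_pop]
                a = np.random.randint(0, k)
                b = np.random.randint(0, k - 1)
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                seen = 0
                for i in range(cnt):
                    if act_pop[i] == best_pop:
                        if seen == a:
                            ia = i
                        if seen == b:
                            ib = i
                        seen += 1
                na = act_node[ia]
                nb = act_node[ib]
                parent[na] = next_node
                parent[nb] = next_node
                lchild[next_node] = na
                rchild[next_node] = nb
                node_time[next_node] = t
                act_node[ia] = next_node
                # remove ib by swapping in the tail
                act_node[ib] = act_node[cnt - 1]
                act_pop[ib] = act_pop[cnt - 1]
                cnt -= 1
                next_node += 1
        else:
            if e >= n_epochs - 1:
                # final epoch is constant-size: coalescence is certain
                break
            t = t_end
            b_idx = e + 1
            for j in range(ev_bidx.shape[0]):
                if ev_bidx[j] == b_idx:
                    if ev_kind[j] == 0:  # pulse
                        for i in range(cnt):
                            if act_pop[i] == ev_src[j]:
                                if np.random.random() < ev_prob[j]:
                                    act_pop[i] = ev_dst[j]
                    else:  # join
                        for i in range(cnt):
                            if act_pop[i] == ev_src[j]:
                                act_pop[i] = ev_dst[j]
            e += 1
    return parent, lchild, rchild, node_time


@njit(cache=True)
def descendant_pop_counts(lchild, rchild, sample_pop, n_leaves):
    """Per-node counts of descendant sampled lineages in pops 0 and 1."""
    n_nodes = lchild.shape[0]
    d0 = np.zeros(n_nodes, dtype=np.int64)
    d1 = np.zeros(n_nodes, dtype=np.int64)
    for v in range(n_leaves):
        if sample_pop[v] == 0:
            d0[v] = 1
        else:
            d1[v] = 1
    for v in range(n_leaves, n_nodes):
        lc = lchild[v]
        rc = rchild[v]
        d0[v] = d0[lc] + d0[rc]
        d1[v] = d1[lc] + d1[rc]
    return d0, d1


@njit(cache=True)
def branch_sfs_many(breaks, N0, beta, mig,
                    ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
                    sample_pop, locus_seeds, n1, n2):
    """Accumulate total branch length subtending each joint allele-count cell.

    Cell (i, j) receives the branch length over which a mutation would be
    carried by i pop-1 and j pop-2 sampled lineages, summed over loci.  This
    is proportional to the expected unfolded joint SFS under infinite sites.
    """
    sfs = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    n_leaves = sample_pop.shape[0]
    for r in range(locus_seeds.shape[0]):
        np.random.seed(locus_seeds[r])
        parent, lchild, rchild, node_time = sim_genealogy_kernel(
            breaks, N0, beta, mig, ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
            sample_pop)
        d0, d1 = descendant_pop_counts(lchild, rchild, sample_pop, n_leaves)
        n_nodes = 2 * n_leaves - 1
        for v in range(n_nodes):
            p = parent[v]
            if p >= 0:
                sfs[d0[v], d1[v]] += node_time[p] - node_time[v]
    return sfs


@njit(cache=True)
def mutate_locus(parent, lchild, rchild, node_time, n_leaves, theta_branch):
    """Drop Poisson(branch_length * theta_branch) infinite-sites mutations.

    Returns an int8 matrix (n_sites, n_leaves) of derived states; caller
    must have seeded np.random (mutation draws continue the locus stream).
    """
    n_nodes = 2 * n_leaves - 1
    hits = np.zeros(n_nodes, dtype=np.int64)
    total = 0
    for v in range(n_nodes):
        p = parent[v]
        if p >= 0:
            bl = node_time[p] - node_time[v]
            m = np.random.poisson(bl * theta_branch)
            hits[v] = m
            total += m
    sites = np.zeros((total, n_leaves), dtype=np.int8)
    stack = np.empty(n_nodes, dtype=np.int64)
    s = 0
    for v in range(n_nodes):
        if hits[v] == 0:
            continue
        # leaves below v via explicit DFS
        mask = np.zeros(n_leaves, dtype=np.int8)
        top = 0
        stack[top] = v
        top += 1
        while top > 0:
            top -= 1
            u = stack[top]
            if u < n_leaves:
                mask[u] = 1
            else:
                stack[top] = lchild[u]
                top += 1
                stack[top] = rchild[u]
                top += 1
        for _ in range(hits[v]):
            for i in range(n_leaves):
                sites[s, i] = mask[i]
            s += 1
    return sites


@njit(cache=True)
def count_sfs_many(breaks, N0, beta, mig,
                   ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
                   sample_pop, locus_seeds, theta_branch, n1, n2):
    """Sampled (Poisson-mutation) joint SFS counts over independent loci."""
    sfs = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    n_leaves = sample_pop.shape[0]
    for r in range(locus_seeds.shape[0]):
        np.random.seed(locus_seeds[r])
        parent, lchild, rchild, node_time = sim_genealogy_kernel(
            breaks, N0, beta, mig, ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
            sample_pop)
        d0, d1 = descendant_pop_counts(lchild, rchild, sample_pop, n_leaves)
        n_nodes = 2 * n_leaves - 1
        for v in range(n_nodes):
            p = parent[v]
            if p >= 0:
                bl = node_time[p] - node_time[v]
                m = np.random.poisson(bl * theta_branch)
                if m > 0:
                    sfs[d0[v], d1[v]] += m
    return sfs


@njit(cache=True)
def tmrca_many(breaks, N0, beta, mig,
               ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
               sample_pop, locus_seeds):
    """TMRCA of the whole sample, one value per locus."""
    out = np.empty(locus_seeds.shape[0], dtype=np.float64)
    n_leaves = sample_pop.shape[0]
    for r in range(locus_seeds.shape[0]):
        np.random.seed(locus_seeds[r])
        _, _, _, node_time = sim_genealogy_kernel(
            breaks, N0, beta, mig, ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
            sample_pop)
        out[r] = node_time[2 * n_leaves - 2]
    return out


@njit(cache=True)
def sim_one(breaks, N0, beta, mig,
            ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
            sample_pop, seed):
    """Seeded single-locus genealogy."""
    np.random.seed(seed)
    return sim_genealogy_kernel(breaks, N0, beta, mig,
                                ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
                                sample_pop)


@njit(cache=True)
def sim_sites_one(breaks, N0, beta, mig,
                  ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
                  sample_pop, seed, theta_branch):
    """Seeded single-locus genealogy + infinite-sites mutations.

    The mutation draws continue the same per-locus stream as the genealogy,
    so site counts match count_sfs_many run with the same seeds.
    """
    np.random.seed(seed)
    parent, lchild, rchild, node_time = sim_genealogy_kernel(
        breaks, N0, beta, mig, ev_bidx, ev_kind, ev_src, ev_dst, ev_prob,
        sample_pop)
    return mutate_locus(parent, lchild, rchild, node_time,
                        sample_pop.shape[0], theta_branch)


@njit(cache=True)
def mutate_locus_seeded(parent, lchild, rchild, node_time, n_leaves,
                        theta_branch, seed):
    """Seeded wrapper around mutate_locus (independent mutation stream)."""
    np.random.seed(seed)
    return mutate_locus(parent, lchild, rchild, node_time, n_leaves,
                        theta_branch)
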