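"""Independent brute-force reference implementations used only by tests.

Each function deliberately takes the slow, obviously-correct route
(all-pairs graphs, exhaustive enumeration, direct combinatorics) so the
fast implementations can be checked against something that shares no code
with them.
"""

from itertools import product
from math import comb

import numpy as np


def merge_bruteforce(intervals, min_overlap=1):
    """Connected-component union via an explicit all-pairs overlap graph."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov >= min_overlap:
                union(i, j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(intervals[i])
    out = []
    for members in comps.values():
        out.append(
            (
                members[0].chrom,
                min(m.start for m in members),
                max(m.end for m in members),
            )
        )
    return sorted(out)


def nearest_tss_bruteforce(interval, annotation):
    """Exhaustive scan: compute every distance, sort by (|d|, gene_id)."""
    cands = []
    for rec in annotation:
        if rec.chrom != interval.chrom:
            continue
        if interval.start <= rec.tss < interval.end:
            d = 0
        else:
            d = min(abs(rec.tss - interval.start), abs(rec.tss - (interval.end - 1)))
        cands.append((d, rec.gene_id))
    if not cands:
        return None, None
    d, g = sorted(cands)[0]
    return g, d


def poisson_binomial_tail_enumeration(r, rates):
    """P(R >= r) by summing over all 2^n outcome vectors."""
    n = len(rates)
    total = 0.0
    for outcome in product((0, 1), repeat=n):
        if sum(outcome) < r:
            continue
        prob = 1.0
        for x, p in zip(outcome, rates):
            prob *= p if x else 1.0 - p
        total += prob
    return total


def bh_stepup(pvalues):
    """Direct step-up: padj_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    # running minimum from the right
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def hypergeom_tail_enumeration(k, M, n_successes, n_draws):
    """P(X >= k) from the hypergeometric pmf written out with binomials."""
    total = 0.0
    for j in range(k, min(n_successes, n_draws) + 1):
        total += comb(n_successes, j) * comb(M - n_successes, n_draws - j)
    return total / comb(M, n_draws)


def overlap_count_bruteforce(a, b):
    """Number of intervals in ``a`` intersecting >= 1 bp with any in ``b``."""
    n = 0
    for x in a:
        for y in b:
            if x.chrom == y.chrom and x.start < y.end and y.start < x.end:
                n += 1
                break
    return n
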