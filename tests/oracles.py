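"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives a quantity by the most literal route available
(double loops, exhaustive pair enumeration, naive agglomeration) and is
kept free of any code path it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_cross_covariance(f1, f2, max_lag):
    """Literal double-loop evaluation of the unbiased windowed covariance."""
    f1 = np.asarray(f1, float)
    f2 = np.asarray(f2, float)
    N = f1.size
    m1 = sum(f1) / N
    m2 = sum(f2) / N
    out = np.zeros(2 * max_lag + 1)
    for m in range(0, max_lag + 1):
        acc = 0.0
        for n in range(0, N - m):
            acc += (f1[n + m] - m1) * (f2[n] - m2)
        out[max_lag + m] = acc / (N - m)
        acc = 0.0
        for n in range(0, N - m):
            acc += (f2[n + m] - m2) * (f1[n] - m1)
        out[max_lag - m] = acc / (N - m)
    return out


def brute_pair_counts(blocks1, blocks2, elements):
    """Classify every element pair by explicit membership lookup."""
    def same(blocks, a, b):
        return any(a in blk and b in blk for blk in blocks)

    n11 = n00 = n10 = n01 = 0
    for a, b in combinations(sorted(elements), 2):
        s1, s2 = same(blocks1, a, b), same(blocks2, a, b)
        if s1 and s2:
            n11 += 1
        elif s1 and not s2:
            n10 += 1
        elif not s1 and s2:
            n01 += 1
        else:
            n00 += 1
    return n11, n00, n10, n01


def brute_entropy(blocks, n):
    h = 0.0
    for blk in blocks:
        p = len(blk) / n
        if p > 0:
            h -= p * np.log2(p)
    return h


def brute_mutual_information(blocks1, blocks2, n):
    mi = 0.0
    for b1 in blocks1:
        for b2 in blocks2:
            pij = len(set(b1) & set(b2)) / n
            if pij > 0:
                pi = len(b1) / n
                pj = len(b2) / n
                mi += pij * np.log2(pij / (pi * pj))
    return mi


def set_partitions(elements):
    """All set partitions of a sequence (restricted growth strings)."""
    elements = list(elements)
    if not elements:
        yield []
        return
    first, rest = elements[0], elements[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield [[first]] + part


def naive_agglomerate(d, method):
    """O(L^3) agglomeration: repeatedly merge the closest pair of clusters.

    Returns merges as (members_a, members_b, height) with cluster distance
    = max (complete) or min (single) over member pairs.
    """
    d = np.asarray(d, float)
    L = d.shape[0]
    clusters = [[i] for i in range(L)]
    merges = []
    agg = max if method == "complete" else min

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = agg(
                    d[a, b] for a in clusters[i] for b in clusters[j]
                )
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        merges.append((list(clusters[i]), list(clusters[j]), dist))
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return merges


def cophenetic_from_merges(merges, L):
    """Cophenetic distance matrix implied by a merge list."""
    C = np.zeros((L, L))
    for a, b, h in merges:
        for x in a:
            for y in b:
                C[x, y] = C[y, x] = h
    return C
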