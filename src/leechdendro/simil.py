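"""Similarity indices between flat clusterings / cut dendrograms.

Two clusterings of the same element set are compared either by pair
counting (Fowlkes-Mallows index, the geometric mean of pairwise precision
and recall) or by information theory (normalized mutual information,
NMI = 2 I / (H + H'), logs base 2).  Both indices lie in [0, 1] with 1
meaning identical partitions.  Dendrograms are compared by cutting both
at k clusters (k = 2 for crawling templates, k = 6 for swimming and
pseudo-swimming) and scoring the cuts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dendro import Clustering, Dendrogram, cut_tree

INDEX_KINDS = ("fowlkes_mallows", "nmi")

#: Cut levels used for template comparison per behavior.
DEFAULT_CUT_K = {"crawling": 2, "swimming": 6, "pseudo_swimming": 6}

#: Index paired with each behavior's cut for sliding-window detection.
#: The chance baseline of an index depends on the cut coarseness: pair
#: counting (Fowlkes-Mallows) is inflated for coarse cuts (two balanced
#: blocks already share half their pairs), while NMI is inflated for fine
#: cuts when k is a sizable fraction of the leaf count.  Each behavior
#: uses the index whose null baseline stays well below the 0.5 detection
#: threshold at its cut level.
DEFAULT_TEMPLATE_INDEX = {
    "crawling": "nmi",
    "swimming": "fowlkes_mallows",
    "pseudo_swimming": "fowlkes_mallows",
}


@dataclass(frozen=True)
class PairCounts:
    """Classification of all n(n-1)/2 element pairs by co-membership.

    n11: same cluster in both; n00: different in both; n10: together only
    in the first; n01: together only in the second.
    """

    n11: int
    n00: int
    n10: int
    n01: int

    @property
    def total(self) -> int:
        return self.n11 + self.n00 + self.n10 + self.n01


def _check_elements(C1: Clustering, C2: Clustering) -> int:
    e1, e2 = C1.elements, C2.elements
    if e1 != e2:
        raise ValueError(
            f"clusterings cover different element sets: "
            f"{sorted(e1 ^ e2)} not shared"
        )
    return len(e1)


def _contingency(C1: Clustering, C2: Clustering) -> np.ndarray:
    table = np.zeros((C1.k, C2.k), dtype=np.int64)
    for i, b1 in enumerate(C1.blocks):
        for j, b2 in enumerate(C2.blocks):
            table[i, j] = len(b1 & b2)
    return table


def pair_counts(C1: Clustering, C2: Clustering) -> PairCounts:
    """Exhaustive pair classification via the contingency table."""
    n = _check_elements(C1, C2)
    table = _contingency(C1, C2)

    def pairs(x):
        x = np.asarray(x, dtype=np.int64)
        return int((x * (x - 1) // 2).sum())

    total = n * (n - 1) // 2
    n11 = pairs(table)
    same1 = pairs(table.sum(axis=1))  # pairs together in C1
    same2 = pairs(table.sum(axis=0))
    n10 = same1 - n11
    n01 = same2 - n11
    n00 = total - n11 - n10 - n01
    return PairCounts(n11=n11, n00=n00, n10=n10, n01=n01)


def fowlkes_mallows(C1: Clustering, C2: Clustering) -> float:
    """B_k = n11 / sqrt((n11 + n10)(n11 + n01)); 0 when n11 = 0."""
    pc = pair_counts(C1, C2)
    denom = (pc.n11 + pc.n10) * (pc.n11 + pc.n01)
    if denom == 0:
        warnings.warn(
            "a clustering has no co-clustered pairs (all singletons); "
            "Fowlkes-Mallows undefined, returning 0", stacklevel=2)
        return 0.0
    return pc.n11 / np.sqrt(denom)


def entropy(C: Clustering) -> float:
    """Shannon entropy of the block-size distribution, in bits."""
    if not C.blocks:
        raise ValueError("empty clustering")
    sizes = np.array([len(b) for b in C.blocks], dtype=float)
    p = sizes / sizes.sum()
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def mutual_information(C1: Clustering, C2: Clustering) -> float:
    """I(C, C') in bits from the joint block-membership distribution."""
    n = _check_elements(C1, C2)
    table = _contingency(C1, C2).astype(float)
    pij = table / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    nz = pij > 0
    ratio = pij[nz] / (pi @ pj)[nz]
    return float((pij[nz] * np.log2(ratio)).sum())


def nmi(C1: Clustering, C2: Clustering) -> float:
    """NMI = 2 I / (H + H'); 1 when both clusterings are the same trivial
    partition, 0 (with a warning) when exactly one entropy vanishes."""
    _check_elements(C1, C2)
    if set(C1.blocks) == set(C2.blocks):
        return 1.0  # identical partitions: exactly 1, no float round-off
    h1, h2 = entropy(C1), entropy(C2)
    if h1 == 0.0 or h2 == 0.0:
        warnings.warn(
            "one clustering is a single block; NMI degenerate, returning 0",
            stacklevel=2)
        return 0.0
    return 2.0 * mutual_information(C1, C2) / (h1 + h2)


def similarity(C1: Clustering, C2: Clustering, index_kind: str = "fowlkes_mallows") -> float:
    if index_kind == "fowlkes_mallows":
        return fowlkes_mallows(C1, C2)
    if index_kind == "nmi":
        return nmi(C1, C2)
    raise ValueError(f"index_kind must be one of {INDEX_KINDS}")


def dendrogram_similarity(
    D1: Dendrogram,
    D2: Dendrogram,
    k: int,
    index_kind: str = "fowlkes_mallows",
) -> float:
    """Cut both trees at k clusters and score the two flat partitions."""
    if set(D1.leaves) != set(D2.leaves):
        raise ValueError(
            f"dendrograms have different leaf sets: "
            f"{sorted(set(D1.leaves) ^ set(D2.leaves))} not shared"
        )
    return similarity(cut_tree(D1, k), cut_tree(D2, k), index_kind)
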