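"""Phage–host gene pairing by nearest relative, and transcript ratios.

An AMG on a phage contig descends from a host gene; in a gene tree holding
the phage copies and the bacterial copies recovered from the same metagenome,
the bacterial leaf closest to a phage leaf (smallest patristic distance) is
taken as the host counterpart.  Trees are built by Saitou–Nei neighbor
joining over Poisson-corrected protein distances.  Expression of each member
of a pair is normalized to RPKM (reads per kilobase of gene per million
mapped reads) and summarized as the phage:host ratio — infinite when only
the phage copy is transcribed, not recorded when neither is.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .align import global_align


@dataclass
class GeneTree:
    """Unrooted weighted tree as an adjacency map over node ids.

    Leaves carry a role label (``phage`` or ``bacterial``); internal nodes
    are named ``_nj<i>``.
    """

    adjacency: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    leaf_roles: dict[str, str] = field(default_factory=dict)

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_roles)

    def add_edge(self, a: str, b: str, length: float) -> None:
        self.adjacency.setdefault(a, []).append((b, length))
        self.adjacency.setdefault(b, []).append((a, length))

    def patristic(self, source: str) -> dict[str, float]:
        """Path lengths from ``source`` to every node (Dijkstra)."""
        dist = {source: 0.0}
        heap = [(0.0, source)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, math.inf):
                continue
            for v, w in self.adjacency[u]:
                nd = d + w
                if nd < dist.get(v, math.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        return dist


@dataclass(frozen=True)
class TranscriptRatioRecord:
    pair_id: str
    phage_rpkm: float
    host_rpkm: float

    @property
    def recorded(self) -> bool:
        return self.phage_rpkm > 0 or self.host_rpkm > 0

    @property
    def ratio(self) -> float | None:
        """phage:host RPKM ratio in [0, inf]; None when neither transcribed."""
        if not self.recorded:
            return None
        if self.host_rpkm == 0:
            return math.inf
        return self.phage_rpkm / self.host_rpkm


def nj_tree(D: np.ndarray, labels: list[str], roles: dict[str, str] | None = None) -> GeneTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero and the deficit
    moved to the sibling branch, preserving the joined pair's distance.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if D.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix/label shape mismatch")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("diagonal must be zero")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")

    tree = GeneTree(leaf_roles={lab: (roles or {}).get(lab, "phage") for lab in labels})
    active = list(labels)
    dist = {
        (a, b): float(D[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }

    def d(a: str, b: str) -> float:
        return 0.0 if a == b else dist[(a, b) if (a, b) in dist else (b, a)]

    counter = 0
    while len(active) > 2:
        m = len(active)
        r = {a: sum(d(a, k) for k in active) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                key = (q, a, b)  # deterministic tie-break by labels
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = d(a, b) - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        u = f"_nj{counter}"
        counter += 1
        tree.add_edge(u, a, la)
        tree.add_edge(u, b, lb)
        for k in active:
            if k in (a, b):
                continue
            duk = max(0.0, 0.5 * (d(a, k) + d(b, k) - d(a, b)))
            dist[(u, k)] = duk
        active = [k for k in active if k not in (a, b)] + [u]
    a, b = active
    tree.add_edge(a, b, max(0.0, d(a, b)))
    return tree


def nearest_relative(tree: GeneTree, focal: str) -> str | None:
    """Bacterial leaf with the smallest patristic distance to a phage leaf.

    Ties break lexicographically; returns None when the tree holds no
    bacterial leaf (no host counterpart recoverable).
    """
    if focal not in tree.leaf_roles:
        raise KeyError(f"unknown leaf {focal!r}")
    dist = tree.patristic(focal)
    candidates = [
        (dist[leaf], leaf)
        for leaf, role in tree.leaf_roles.items()
        if role == "bacterial" and leaf != focal
    ]
    if not candidates:
        return None
    return min(candidates)[1]


def poisson_distance(p: float) -> float:
    """Poisson-corrected protein distance d = -ln(1 - p) for p-distance p."""
    if not 0 <= p < 1:
        raise ValueError(f"p-distance {p} outside [0, 1)")
    return -math.log(1.0 - p)


def protein_distance_matrix(seqs: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise Poisson-corrected distances from semi-global alignments."""
    labels = sorted(seqs)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            stats = global_align(seqs[labels[i]], seqs[labels[j]])
            D[i, j] = D[j, i] = poisson_distance(1.0 - stats.identity)
    return D, labels


def rpkm(reads: float, gene_len: float, total_mapped: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_len <= 0:
        raise ValueError("gene_len must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return reads / ((gene_len / 1e3) * (total_mapped / 1e6))


def ratio_summary(records: list[TranscriptRatioRecord]) -> dict:
    """Fraction of recorded phage:host ratios strictly greater than one.

    Infinite ratios (phage transcribed, host silent) count as greater than
    one; pairs with neither member transcribed are not recorded and leave the
    denominator.
    """
    recorded = [r for r in records if r.recorded]
    if not recorded:
        raise ValueError("no recorded ratios: fraction undefined")
    n_gt_one = sum(1 for r in recorded if r.ratio > 1)
    return {
        "n_recorded": len(recorded),
        "n_gt_one": n_gt_one,
        "fraction_gt_one": n_gt_one / len(recorded),
    }
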