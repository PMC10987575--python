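"""Pairwise semi-global alignment and greedy length-sorted clustering.

The pipeline needs one identity engine for three thresholds: 95%/90%
dereplication of AMG sequences, 95%/85% species-like (vOTU) clustering of
contigs, and 70%/70% pre-clustering of proteins before dN/dS.  Alignment is
global with free end gaps (semi-global), so a fragment aligned inside a
full-length sequence scores no end-gap penalty; identity is the number of
identical aligned positions over the shorter sequence length, the
dereplication convention.  Clustering is greedy on length-sorted input: the
longest sequence founds the first cluster and each subsequent sequence joins
the first representative it matches at the identity/coverage thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

_NT_CHARS = set("ACGTUN")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentStats:
    identity: float
    cov_query: float
    cov_target: float
    n_identical: int
    aln_len: int


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def all_members(self) -> set[str]:
        return {m for c in self.clusters for m in c.member_ids}

    def representative_of(self, member_id: str) -> str:
        for c in self.clusters:
            if member_id in c.member_ids:
                return c.representative_id
        raise KeyError(member_id)


def is_nucleotide(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= _NT_CHARS


def _make_aligner(nucleotide: bool, scoring: dict | None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scoring is None:
        if nucleotide:
            scoring = {"match": 2, "mismatch": -3, "gap_open": 5, "gap_extend": 2}
        else:
            scoring = {"gap_open": 11, "gap_extend": 1}
    if "substitution_matrix" in scoring:
        aligner.substitution_matrix = scoring["substitution_matrix"]
    elif "match" in scoring:
        aligner.match_score = scoring["match"]
        aligner.mismatch_score = scoring["mismatch"]
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(scoring.get("gap_open", 11))
    aligner.extend_gap_score = -abs(scoring.get("gap_extend", 1))
    # free end gaps: fragments pay nothing for overhangs
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def global_align(a: str, b: str, scoring: dict | None = None) -> AlignmentStats:
    """Optimal semi-global alignment statistics for two sequences.

    ``identity`` is identical positions over the shorter length; coverage of
    each sequence is its non-end-gap aligned span over its length.
    """
    if not a or not b:
        raise AlignmentError("empty sequence")
    a, b = a.upper(), b.upper()
    nt_a, nt_b = is_nucleotide(a), is_nucleotide(b)
    if nt_a != nt_b:
        raise AlignmentError("mixed alphabets: one sequence looks nucleotide, the other protein")
    aligner = _make_aligner(nt_a and nt_b, scoring)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        span_a = span_b = 0
        aln_len = 0
    else:
        span_a = int(blocks_a[-1][1] - blocks_a[0][0])
        span_b = int(blocks_b[-1][1] - blocks_b[0][0])
        aln_len = max(span_a, span_b)
    return AlignmentStats(
        identity=counts.identities / min(len(a), len(b)),
        cov_query=span_a / len(a),
        cov_target=span_b / len(b),
        n_identical=int(counts.identities),
        aln_len=aln_len,
    )


def _coverage_ok(
    stats: AlignmentStats, len_q: int, len_t: int, min_cov: float, cov_mode: str
) -> bool:
    if cov_mode == "shorter":
        cov_shorter = stats.cov_query if len_q <= len_t else stats.cov_target
        return cov_shorter >= min_cov
    if cov_mode == "both":
        return stats.cov_query >= min_cov and stats.cov_target >= min_cov
    raise ValueError(f"unknown cov_mode {cov_mode!r}")


def greedy_cluster(
    seqs: dict[str, str],
    min_id: float,
    min_cov: float,
    cov_mode: str = "shorter",
    scoring: dict | None = None,
) -> ClusterSet:
    """Greedy length-sorted clustering at identity/coverage thresholds.

    Sequences are visited longest first (ties by id); each joins the first
    existing representative it matches, otherwise founds a new cluster, so
    every representative is the longest member of its cluster and the result
    does not depend on input order.
    """
    if not (0 < min_id <= 1 and 0 < min_cov <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for sid in order:
        placed = False
        for rep in reps:
            stats = global_align(seqs[sid], seqs[rep], scoring)
            if stats.identity >= min_id and _coverage_ok(
                stats, len(seqs[sid]), len(seqs[rep]), min_cov, cov_mode
            ):
                members[rep].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sid)
            members[sid] = [sid]
    return ClusterSet(
        clusters=[Cluster(rep, tuple(members[rep])) for rep in reps]
    )
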