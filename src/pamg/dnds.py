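"""Nei–Gojobori (1986) dN/dS with Jukes–Cantor correction.

Synonymous site counts weight each codon position by the fraction of possible
single-nucleotide changes that preserve the encoded amino acid; changes that
would create a stop codon are excluded from both the site and the pathway
counts, and the remaining changes renormalized (so a position whose only
non-stop changes are synonymous contributes a full synonymous site).  Codon
pairs differing at more than one position average their synonymous and
nonsynonymous difference counts over all orderings of the single changes,
each pathway weighted equally, skipping pathways that pass through a stop
codon.  Proportions p = differences/sites are corrected for multiple hits by
the Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3); ω = dN/dS indicates
purifying (ω < 1), neutral (ω ≈ 1) or diversifying (ω > 1) selection.

Counting uses the bacterial/archaeal translation table (NCBI table 11).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data import CodonTable

from .align import greedy_cluster

_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
_BASES = "ACGT"


class DnDsError(ValueError):
    pass


@dataclass(frozen=True)
class DnDsResult:
    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None  # None when dS == 0 (undefined ratio)


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise DnDsError(f"invalid or ambiguous codon {codon!r}")
    if codon in STOP_CODONS:
        raise DnDsError(f"stop codon {codon!r} has no site counts")
    return codon


def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon."""
    codon = _check_codon(codon)
    aa = CODON_TO_AA[codon]
    s_total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if valid:
            s_total += syn / valid
    return s_total, 3.0 - s_total


def _codon_path_counts(a: str, b: str) -> tuple[float, float]:
    """Average (Sd, Nd) between two codons over equally weighted pathways."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                through_stop = through_stop or nxt in STOP_CODONS
                nd += 1  # stop-crossing steps only matter in the fallback
            elif CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else paths).append((sd, nd))
    if not paths:  # degenerate: every ordering crosses a stop; fall back to all
        paths = blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance for a proportion of differences."""
    if p < 0:
        raise DnDsError("negative proportion")
    if p >= 0.75:
        raise DnDsError(f"proportion {p:.4f} >= 3/4: correction undefined")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _split_codons(cds: str, label: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise DnDsError(f"{label}: length {len(cds)} not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for j, c in enumerate(codons):
        if any(b not in _BASES for b in c):
            raise DnDsError(f"{label}: ambiguous codon {c!r} at codon {j}")
        if c in STOP_CODONS:
            raise DnDsError(f"{label}: internal stop codon {c!r} at codon {j}")
    return codons


def ng86_pair(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b") -> DnDsResult:
    """NG86 dN/dS for a codon-aligned pair of coding sequences."""
    if len(cds_a) != len(cds_b):
        raise DnDsError(f"length mismatch: {len(cds_a)} vs {len(cds_b)}")
    ca = _split_codons(cds_a, id_a)
    cb = _split_codons(cds_b, id_b)
    s_a = sum(ng86_sites(c)[0] for c in ca)
    s_b = sum(ng86_sites(c)[0] for c in cb)
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(ca) - S
    Sd = Nd = 0.0
    for x, y in zip(ca, cb):
        sd, nd = _codon_path_counts(x, y)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = dN / dS if dS > 0 else None
    return DnDsResult(id_a, id_b, S, N, Sd, Nd, pS, pN, dS, dN, omega)


def dnds_by_kind(
    records: dict[str, list[tuple[str, str, str]]],
    min_id: float = 0.70,
    min_cov: float = 0.70,
) -> tuple[list[DnDsResult], dict[str, str]]:
    """All-pairs dN/dS within protein clusters, per gene kind.

    ``records`` maps kind -> list of (seq_id, protein, cds).  Proteins of each
    kind are clustered greedily at ``min_id`` identity over ``min_cov`` of
    both sequences; every within-cluster pair of equal-length CDS is scored.
    Returns the pair results and a report of skipped kinds/pairs.
    """
    results: list[DnDsResult] = []
    report: dict[str, str] = {}
    for kind in sorted(records):
        entries = records[kind]
        for sid, prot, cds in entries:
            if len(cds) not in (3 * len(prot), 3 * len(prot) + 3):
                raise DnDsError(f"{kind}/{sid}: CDS length inconsistent with protein")
        if len(entries) < 2:
            report[kind] = "skipped: only one sequence"
            continue
        prots = {sid: prot for sid, prot, _ in entries}
        cdss = {sid: cds for sid, _, cds in entries}
        clusters = greedy_cluster(prots, min_id, min_cov, cov_mode="both")
        n_pairs = 0
        for cluster in clusters.clusters:
            ids = sorted(cluster.member_ids)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    a, b = ids[i], ids[j]
                    if len(cdss[a]) != len(cdss[b]):
                        report[f"{kind}:{a}|{b}"] = "skipped: unequal CDS length"
                        continue
                    results.append(ng86_pair(cdss[a], cdss[b], a, b))
                    n_pairs += 1
        report[kind] = f"{n_pairs} pairs in {clusters.n_clusters} clusters"
    return results, report
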