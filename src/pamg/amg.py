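"""AMG calling: auxiliary scores, AMG flags and acceptance rules.

A putative auxiliary metabolic gene (AMG) on a viral contig is scored 1–5 by
its flanking context: the best viral-gene class within a window on each side
(hallmark beats viral-like) maps to

====================  =====
left/right classes    score
====================  =====
hallmark, hallmark      1
hallmark, viral-like    2
viral-like, viral-like  3
one side viral only     4
no viral gene           5
====================  =====

Flags qualify the call: ``M`` metabolic KO in the P-gene catalog, ``V`` the
gene itself hits a viral protein family, ``T`` transposase nearby annotation,
``A``/``P`` attachment/peptidase, ``B`` the gene sits in a run of three or
more adjacent metabolic genes with no viral hit (likely host sequence), ``F``
the gene is near a contig end without a viral hit (flank, possibly host).

Acceptance: scores 1–3 with flag M and/or F (and none of V/A/P/T) are AMGs;
scores 1–3 flagged T are accepted only on contigs independently validated as
phages; complete-or-near-complete pstSCAB transporter clusters at score 4 on
validated contigs are rescued, because intact pst operons are documented in
isolated phage genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .catalog import Catalog
from .screen import ContigAnnotation

PST_KINDS = frozenset({"pstS", "pstC", "pstA", "pstB"})

_CLASS_RANK = {"none": 0, "viral_like": 1, "hallmark": 2}


@dataclass(frozen=True)
class AmgCall:
    contig_id: str
    gene_id: str
    gene_index: int
    kind: str
    category: str
    aux_score: int
    flags: frozenset[str]
    accepted: bool
    rule: str  # score_MF | score_T_validated | pst_rescue | rejected

    def __post_init__(self) -> None:
        if self.accepted and self.rule == "rejected":
            raise ValueError("accepted call cannot carry rule 'rejected'")
        if self.rule == "pst_rescue" and self.aux_score != 4:
            raise ValueError("pst_rescue applies only at auxiliary score 4")


def _best_side_class(contig: ContigAnnotation, gene_index: int, step: int, window: int) -> str:
    best = "none"
    i = gene_index + step
    scanned = 0
    while 0 <= i < len(contig.genes) and scanned < window:
        g = contig.genes[i]
        if _CLASS_RANK[g.vog_class] > _CLASS_RANK[best]:
            best = g.vog_class
        i += step
        scanned += 1
    return best


def aux_score(contig: ContigAnnotation, gene_index: int, window: int = 10) -> int:
    """Auxiliary score (1 best .. 5 worst) of the gene at ``gene_index``."""
    if not 0 <= gene_index < len(contig.genes):
        raise IndexError(f"gene_index {gene_index} out of range")
    if window < 1:
        raise ValueError("window must be >= 1")
    left = _best_side_class(contig, gene_index, -1, window)
    right = _best_side_class(contig, gene_index, +1, window)
    ranks = sorted((_CLASS_RANK[left], _CLASS_RANK[right]), reverse=True)
    table = {
        (2, 2): 1,  # hallmark both sides
        (2, 1): 2,  # hallmark one side, viral-like the other
        (1, 1): 3,  # viral-like both sides
        (2, 0): 4,  # viral evidence on one side only
        (1, 0): 4,
        (0, 0): 5,  # no viral context
    }
    return table[tuple(ranks)]


def _metabolic(contig: ContigAnnotation, idx: int, catalog: Catalog,
               metabolic_kos: frozenset[str] | None) -> bool:
    ko = contig.genes[idx].ko
    if ko is None:
        return False
    if metabolic_kos is not None and ko in metabolic_kos:
        return True
    return catalog.kind_of_ko(ko) is not None


def assign_flags(
    contig: ContigAnnotation,
    gene_index: int,
    catalog: Catalog,
    metabolic_kos: frozenset[str] | None = None,
    end_margin: int = 2,
) -> frozenset[str]:
    """AMG flag set for one gene (subset of {V, M, F, T, B, A, P})."""
    if not 0 <= gene_index < len(contig.genes):
        raise IndexError(f"gene_index {gene_index} out of range")
    gene = contig.genes[gene_index]
    flags: set[str] = set()
    if gene.is_viral:
        flags.add("V")
    if _metabolic(contig, gene_index, catalog, metabolic_kos):
        flags.add("M")
    if "transposase" in gene.extra_flags:
        flags.add("T")
    if "attachment" in gene.extra_flags:
        flags.add("A")
    if "peptidase" in gene.extra_flags:
        flags.add("P")
    # B: member of a maximal run of >=3 adjacent metabolic, virus-free genes
    def in_run(i: int) -> bool:
        return _metabolic(contig, i, catalog, metabolic_kos) and not contig.genes[i].is_viral

    if in_run(gene_index):
        lo = gene_index
        while lo > 0 and in_run(lo - 1):
            lo -= 1
        hi = gene_index
        while hi < len(contig.genes) - 1 and in_run(hi + 1):
            hi += 1
        if hi - lo + 1 >= 3:
            flags.add("B")
    # F: near a contig end without viral evidence of its own
    n = len(contig.genes)
    if not gene.is_viral and (gene_index < end_margin or gene_index >= n - end_margin):
        flags.add("F")
    return frozenset(flags)


def find_pst_cluster(contig: ContigAnnotation, catalog: Catalog) -> list[list[int]]:
    """Maximal runs of adjacent pst-transporter genes with >=3 distinct kinds.

    Order within the run is free (pstSCAB and pstBACS both qualify); three
    distinct kinds tolerate an operon truncated at a contig edge.
    """
    runs: list[list[int]] = []
    current: list[int] = []
    for i, g in enumerate(contig.genes):
        kind = catalog.kind_of_ko(g.ko) if g.ko else None
        if kind in PST_KINDS:
            current.append(i)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    out = []
    for run in runs:
        kinds = {catalog.kind_of_ko(contig.genes[i].ko) for i in run}
        if len(kinds) >= 3:
            out.append(run)
    return out


def call_amgs(
    contig: ContigAnnotation,
    catalog: Catalog,
    validated_phage: bool,
    window: int = 10,
) -> list[AmgCall]:
    """Score, flag and accept/reject every catalog-matching gene on a contig."""
    pst_indices = {i for run in find_pst_cluster(contig, catalog) for i in run}
    calls: list[AmgCall] = []
    for i, gene in enumerate(contig.genes):
        if gene.ko is None:
            continue
        hit = catalog.kind_of_ko(gene.ko)
        if hit is None:
            continue
        score = aux_score(contig, i, window=window)
        flags = assign_flags(contig, i, catalog)
        rule = "rejected"
        if score <= 3 and "T" not in flags and not flags & {"V", "A", "P"} and flags & {"M", "F"}:
            rule = "score_MF"
        elif score <= 3 and "T" in flags and validated_phage:
            rule = "score_T_validated"
        elif score == 4 and i in pst_indices and validated_phage:
            rule = "pst_rescue"
        calls.append(
            AmgCall(
                contig_id=contig.contig_id,
                gene_id=gene.gene_id,
                gene_index=i,
                kind=hit,
                category=catalog.category(hit),
                aux_score=score,
                flags=flags,
                accepted=rule != "rejected",
                rule=rule,
            )
        )
    return calls


def calls_to_frame(calls: Iterable[AmgCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        d = c.__dict__.copy()
        d["flags"] = ",".join(sorted(c.flags))
        rows.append(d)
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id", "gene_id", "gene_index", "kind", "category",
            "aux_score", "flags", "accepted", "rule",
        ],
    )
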