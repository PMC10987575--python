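"""Viral contig screening: annotation profiles and manual-curation criteria.

Contigs longer than the length cutoff are profiled by how many of their genes
carry KEGG Orthology (KO) terms, Pfam domains, or hits to viral protein
families (VOG).  Three curation criteria, each requiring at least five viral
protein family hits, decide whether a contig is called viral:

* c1 — few cellular annotations: KO fraction < 20%, Pfam fraction < 40%, and
  viral-hit fraction > 10%;
* c2 — more viral-family hits than Pfam hits;
* c3 — viral-hit fraction at least 60%.

A contig passing any criterion is a virus call.  Two further lines of
evidence (external tool calls done outside this package) enter as booleans on
the contig; a contig is a *validated phage* when all three agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

VOG_CLASSES = ("hallmark", "viral_like", "none")
EXTRA_FLAGS = ("transposase", "attachment", "peptidase")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig_id: str
    index: int
    start: int
    end: int
    strand: str
    ko: str | None = None
    pfam: tuple[str, ...] = ()
    vog: str | None = None
    vog_class: str = "none"
    extra_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.gene_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.vog_class not in VOG_CLASSES:
            raise ValueError(f"{self.gene_id}: bad vog_class {self.vog_class!r}")
        if self.vog is None and self.vog_class != "none":
            raise ValueError(f"{self.gene_id}: vog_class without a vog hit")
        bad = set(self.extra_flags) - set(EXTRA_FLAGS)
        if bad:
            raise ValueError(f"{self.gene_id}: unknown extra_flags {sorted(bad)}")

    @property
    def is_viral(self) -> bool:
        return self.vog_class != "none"


@dataclass
class ContigAnnotation:
    contig_id: str
    length_bp: int
    genes: list[Gene]
    external_validation: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"{self.contig_id}: non-positive length")
        for i, g in enumerate(self.genes):
            if g.index != i:
                raise ValueError(f"{self.contig_id}: gene indices not consecutive from 0")
            if g.end > self.length_bp:
                raise ValueError(f"{self.contig_id}: gene {g.gene_id} exceeds contig length")


@dataclass(frozen=True)
class Profile:
    n_genes: int
    n_ko: int
    n_pfam: int
    n_vog: int
    frac_ko: float
    frac_pfam: float
    frac_vog: float


@dataclass(frozen=True)
class CurationCall:
    contig_id: str
    n_genes: int
    n_ko: int
    n_pfam: int
    n_vog: int
    c1: bool
    c2: bool
    c3: bool
    is_virus: bool


def length_filter(
    contigs: Iterable[ContigAnnotation], min_bp: int = 10_000
) -> list[ContigAnnotation]:
    """Keep contigs strictly longer than ``min_bp`` (default 10 kb), in order."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return [c for c in contigs if c.length_bp > min_bp]


def profile(contig: ContigAnnotation) -> Profile:
    """Count KO/Pfam/viral-family annotated genes and their fractions."""
    n = len(contig.genes)
    if n == 0:
        raise ValueError(f"{contig.contig_id}: criteria undefined for 0 genes")
    n_ko = sum(1 for g in contig.genes if g.ko)
    n_pfam = sum(1 for g in contig.genes if g.pfam)
    n_vog = sum(1 for g in contig.genes if g.vog)
    return Profile(n, n_ko, n_pfam, n_vog, n_ko / n, n_pfam / n, n_vog / n)


def curate(
    p: Profile,
    contig_id: str = "",
    *,
    min_vog_hits: int = 5,
    max_frac_ko: float = 0.20,
    max_frac_pfam: float = 0.40,
    min_frac_vog_c1: float = 0.10,
    min_frac_vog_c3: float = 0.60,
) -> CurationCall:
    """Apply the three curation criteria to an annotation profile.

    Boundary semantics follow the criteria's wording: the KO and Pfam bounds
    and the c1 viral fraction are strict, the c3 viral fraction ("at least
    60%") and the five-hit floor are inclusive.
    """
    base = p.n_vog >= min_vog_hits
    c1 = (
        base
        and p.frac_ko < max_frac_ko
        and p.frac_pfam < max_frac_pfam
        and p.frac_vog > min_frac_vog_c1
    )
    c2 = base and p.n_vog > p.n_pfam
    c3 = base and p.frac_vog >= min_frac_vog_c3
    return CurationCall(
        contig_id=contig_id,
        n_genes=p.n_genes,
        n_ko=p.n_ko,
        n_pfam=p.n_pfam,
        n_vog=p.n_vog,
        c1=c1,
        c2=c2,
        c3=c3,
        is_virus=c1 or c2 or c3,
    )


def screen_contig(contig: ContigAnnotation) -> CurationCall:
    return curate(profile(contig), contig.contig_id)


def is_validated_phage(contig: ContigAnnotation, call: CurationCall) -> bool:
    """True when manual curation and both external tool calls agree.

    Missing external booleans default to False: a contig never seen by a tool
    cannot count as validated by it.
    """
    ev = contig.external_validation
    return bool(call.is_virus and ev.get("vibrant", False) and ev.get("sop", False))


# ---------------------------------------------------------------------------
# TSV I/O


def _parse_list(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(s for s in str(cell).split(",") if s)


def read_annotations(path: str | Path) -> list[ContigAnnotation]:
    """Read a per-gene annotation TSV into ordered contig annotations.

    Expected columns: contig_id, contig_length, gene_id, index, start, end,
    strand, ko, pfam, vog, vog_class, extra_flags, and optional
    vibrant/sop 0-1 columns carrying external validation calls.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    contigs: list[ContigAnnotation] = []
    for contig_id, sub in df.groupby("contig_id", sort=False):
        sub = sub.sort_values("index", key=lambda s: s.astype(int))
        genes = [
            Gene(
                gene_id=r.gene_id,
                contig_id=contig_id,
                index=int(r.index),
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                ko=r.ko or None,
                pfam=_parse_list(r.pfam),
                vog=r.vog or None,
                vog_class=r.vog_class or "none",
                extra_flags=frozenset(_parse_list(r.extra_flags)),
            )
            for r in sub.itertuples(index=False)
        ]
        ext = {}
        for tool in ("vibrant", "sop"):
            if tool in sub.columns:
                ext[tool] = str(sub.iloc[0][tool]).strip() in ("1", "True", "true")
        contigs.append(
            ContigAnnotation(
                contig_id=contig_id,
                length_bp=int(sub.iloc[0]["contig_length"]),
                genes=genes,
                external_validation=ext,
            )
        )
    return contigs


def calls_to_frame(calls: Iterable[CurationCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
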