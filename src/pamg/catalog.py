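"""Catalog of phosphorus-acquisition gene kinds and their KEGG Orthology ids.

Microbial P acquisition falls into four primary processes: solubilization of
inorganic P polymers (e.g. pyrophosphatase *ppa*), mineralization of organic P
(e.g. alkaline phosphatase *phoD*), transport of orthophosphate and organic P
(e.g. the high-affinity pstSCAB system), and regulation of the phosphate
starvation response (the PhoR–PhoB two-component system and PhoU).  The
catalog maps short gene symbols to KO identifiers and categories, records
which kinds were reported as phage auxiliary metabolic genes (AMGs) before,
and supports the expansion arithmetic (how many newly observed kinds enlarge
the previously known set).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

CATEGORIES = ("solubilization", "mineralization", "transporter", "regulator")

_KO_RE = re.compile(r"^K\d{5}$")


class CatalogError(ValueError):
    """Raised when a catalog file violates its invariants."""


@dataclass(frozen=True)
class GeneKindEntry:
    kind: str
    ko_ids: tuple[str, ...]
    category: str
    previously_reported: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CatalogError(
                f"kind {self.kind!r}: unknown category {self.category!r}"
            )
        if not self.ko_ids:
            raise CatalogError(f"kind {self.kind!r}: empty ko_ids")
        for ko in self.ko_ids:
            if not _KO_RE.match(ko):
                raise CatalogError(f"kind {self.kind!r}: malformed KO id {ko!r}")


@dataclass
class Catalog:
    entries: list[GeneKindEntry]
    prior_kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.kind in seen:
                raise CatalogError(f"duplicate kind {e.kind!r}")
            seen.add(e.kind)
        ko_owner: dict[str, str] = {}
        for e in self.entries:
            for ko in e.ko_ids:
                if ko in ko_owner:
                    raise CatalogError(
                        f"KO {ko} assigned to both {ko_owner[ko]!r} and {e.kind!r}"
                    )
                ko_owner[ko] = e.kind
        if len(set(self.prior_kinds)) != len(self.prior_kinds):
            raise CatalogError("duplicate entries in prior_kinds")
        self._by_ko = {ko: e for e in self.entries for ko in e.ko_ids}
        self._by_kind = {e.kind: e for e in self.entries}

    @property
    def kinds(self) -> list[str]:
        return [e.kind for e in self.entries]

    def entry(self, kind: str) -> GeneKindEntry:
        return self._by_kind[kind]

    def category(self, kind: str) -> str:
        return self._by_kind[kind].category

    def kind_of_ko(self, ko: str) -> str | None:
        e = self._by_ko.get(ko)
        return e.kind if e is not None else None


def _default_path(name: str) -> Path:
    return Path(str(resources.files("pamg").joinpath("data", name)))


def load_catalog(
    path: str | Path | None = None,
    prior_path: str | Path | None = None,
) -> Catalog:
    """Load and validate a gene-kind catalog.

    Parameters
    ----------
    path
        TSV with columns ``kind``, ``ko_ids`` (comma-separated), ``category``,
        ``previously_reported`` (0/1).  ``None`` loads the packaged default
        (17 kinds spanning the four categories).
    prior_path
        One-column TSV (``kind``) listing gene kinds previously reported as
        AMGs, including kinds not present in ``path``.  ``None`` loads the
        packaged default (11 kinds).
    """
    path = _default_path("catalog.tsv") if path is None else Path(path)
    prior_path = (
        _default_path("prior_kinds.tsv") if prior_path is None else Path(prior_path)
    )
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"kind", "ko_ids", "category", "previously_reported"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"catalog {path}: missing columns {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        kos = tuple(k.strip() for k in str(row.ko_ids).split(",") if k.strip())
        if not kos:
            raise CatalogError(f"kind {row.kind!r}: empty ko_ids")
        entries.append(
            GeneKindEntry(
                kind=str(row.kind),
                ko_ids=kos,
                category=str(row.category),
                previously_reported=str(row.previously_reported).strip() in ("1", "True", "true"),
            )
        )
    prior = pd.read_csv(prior_path, sep="\t", dtype=str)["kind"].tolist()
    cat = Catalog(entries=entries, prior_kinds=prior)
    # cross-check: an entry is previously_reported iff its kind is a prior kind
    for e in cat.entries:
        if e.previously_reported != (e.kind in set(prior)):
            raise CatalogError(
                f"kind {e.kind!r}: previously_reported flag inconsistent with prior list"
            )
    return cat


def classify_ko(catalog: Catalog, ko: str) -> tuple[str, str] | None:
    """Map a KO identifier to ``(kind, category)``, or ``None`` if uncataloged."""
    if not _KO_RE.match(ko):
        raise ValueError(f"malformed KO token {ko!r}")
    kind = catalog.kind_of_ko(ko)
    if kind is None:
        return None
    return kind, catalog.category(kind)


def expansion_stats(catalog: Catalog) -> dict[str, float]:
    """Catalog-expansion arithmetic.

    ``n_novel`` counts identified kinds absent from the previously reported
    set; ``pct_increase`` is the percentage growth of the known-kind set,
    100 * n_novel / n_prior.
    """
    identified = set(catalog.kinds)
    prior = set(catalog.prior_kinds)
    if not prior:
        raise ZeroDivisionError("pct_increase undefined: no prior kinds")
    novel = identified - prior
    return {
        "n_identified": len(identified),
        "n_novel": len(novel),
        "n_prior": len(prior),
        "pct_increase": 100.0 * len(novel) / len(prior),
    }
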