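"""Coverage normalization, relative abundance and ecological statistics.

Mean per-base depth of a contig is read-bases over contig length.  Depths are
made comparable across metagenomes of unequal sequencing effort by dividing
each sample's column by its read count and multiplying by the mean read count
over all samples; the normalized table is then rescaled within each sample to
percentages (a proportional table).  Detection counts (how many viral units
show signal in a sample) feed a Kruskal–Wallis test across habitats with
Holm-corrected pairwise Wilcoxon rank-sum follow-ups, and Pearson
correlations against soil phosphorus covariates.

The relative abundance of an AMG is, by construction, the relative abundance
of the viral unit carrying it: read recruitment to the gene itself would be
confounded by reads from homologous host genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

HABITATS = ("farmland", "forest", "grassland", "gobi", "mine")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    n_reads: int
    habitat: str
    site_id: str
    TP: float
    AP: float
    MAT: float

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError(f"{self.sample_id}: n_reads must be positive")
        if self.habitat not in HABITATS:
            raise ValueError(f"{self.sample_id}: unknown habitat {self.habitat!r}")


def mean_depth(mapped_reads: float, read_len: float, contig_len: float) -> float:
    """Mean per-base coverage: mapped read bases divided by contig length."""
    if contig_len <= 0:
        raise ValueError("contig_len must be positive")
    return mapped_reads * read_len / contig_len


def normalize_coverage(cov: pd.DataFrame, meta: list[SampleMeta]) -> pd.DataFrame:
    """Rescale each sample column by mean(read counts) / its read count."""
    if (cov.values < 0).any():
        raise ValueError("coverage values must be non-negative")
    reads = {m.sample_id: m.n_reads for m in meta}
    missing = [s for s in cov.columns if s not in reads]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    r = np.array([reads[s] for s in cov.columns], dtype=float)
    return cov * (r.mean() / r)


def relative_abundance(norm: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Proportional table: each sample column sums to 100.

    All-zero columns are left at zero and reported in the returned flag list.
    """
    if (norm.values < 0).any():
        raise ValueError("normalized coverage must be non-negative")
    totals = norm.sum(axis=0)
    zero_cols = [str(c) for c in norm.columns[totals == 0]]
    safe = totals.replace(0, np.nan)
    rel = norm.div(safe, axis=1) * 100.0
    rel[norm.columns[totals == 0]] = 0.0
    return rel, zero_cols


def detection_counts(norm: pd.DataFrame, threshold: float = 0.0) -> pd.Series:
    """Per-sample count of rows with normalized coverage strictly above threshold."""
    return (norm > threshold).sum(axis=0)


def group_compare(counts: pd.Series, habitat: pd.Series) -> dict:
    """Kruskal–Wallis across habitats plus Holm-corrected pairwise rank-sum tests."""
    groups = {h: counts[habitat == h].to_numpy() for h in habitat.unique()}
    if len(groups) < 2:
        raise ValueError("need at least two habitat groups")
    kw_stat, kw_p = stats.kruskal(*groups.values())
    pairs = list(combinations(sorted(groups), 2))
    raw = [
        stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
        for a, b in pairs
    ]
    adj = multipletests(raw, method="holm")[1] if pairs else []
    return {
        "kruskal_wallis_stat": float(kw_stat),
        "kruskal_wallis_p": float(kw_p),
        "pairwise_holm_p": {f"{a}|{b}": float(p) for (a, b), p in zip(pairs, adj)},
    }


def correlate(counts: pd.Series, env: pd.Series) -> dict:
    """Pearson product-moment correlation between detection counts and a covariate."""
    x = counts.to_numpy(dtype=float)
    y = env.to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3 for correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return {"pearson_r": float(r), "p": float(p), "n": int(len(x))}


def amg_relative_abundance(
    rel_votu: pd.DataFrame, amg_to_votu: dict[str, str]
) -> pd.DataFrame:
    """Per-AMG relative abundance as a pass-through of its carrier unit's row."""
    rows = {amg: rel_votu.loc[votu] for amg, votu in amg_to_votu.items()}
    return pd.DataFrame(rows).T
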