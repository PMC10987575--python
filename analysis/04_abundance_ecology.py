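#!/usr/bin/env python
"""Normalize coverage, build the proportional table and test habitat effects.

Detection counts per sample are compared across the five habitat types
(Kruskal-Wallis with Holm-corrected pairwise rank-sum follow-ups) and
correlated with soil total and available phosphorus.
"""

import json
from pathlib import Path

import pandas as pd

from pamg.abundance import (
    SampleMeta,
    correlate,
    detection_counts,
    group_compare,
    normalize_coverage,
    relative_abundance,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"


def main() -> None:
    cov = pd.read_csv(OUT / "coverage.tsv", sep="\t", index_col=0)
    mdf = pd.read_csv(OUT / "sample_meta.tsv", sep="\t")
    meta = [SampleMeta(**r._asdict()) for r in mdf.itertuples(index=False)]

    norm = normalize_coverage(cov, meta)
    rel, flagged = relative_abundance(norm)
    norm.to_csv(OUT / "normalized_coverage.tsv", sep="\t")
    rel.to_csv(OUT / "relative_abundance.tsv", sep="\t")
    print(f"proportional table written; {len(flagged)} all-zero samples flagged")

    counts = detection_counts(norm)
    mf = mdf.set_index("sample_id").loc[counts.index]
    comp = group_compare(counts, mf.habitat)
    stats = {
        "group_compare": comp,
        "correlation_TP": correlate(counts, mf.TP),
        "correlation_AP": correlate(counts, mf.AP),
    }
    (OUT / "ecology_stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))
    print(f"Kruskal-Wallis across habitats: p = {comp['kruskal_wallis_p']:.3g}")
    print(f"detection ~ TP: r = {stats['correlation_TP']['pearson_r']:.3f} "
          f"(n = {stats['correlation_TP']['n']})")
    print(f"detection ~ AP: r = {stats['correlation_AP']['pearson_r']:.3f}")


if __name__ == "__main__":
    main()
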