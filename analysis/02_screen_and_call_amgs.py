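#!/usr/bin/env python
"""Screen contigs with the viral curation criteria and call AMGs.

Applies the >10 kb length filter and the three annotation-based curation
criteria, then scores every catalog-matching gene (auxiliary score + flags)
and applies the acceptance rules.  Prints how the calls compare with the
planted truth from 01_simulate.
"""

import json
from pathlib import Path

import pandas as pd

from pamg.amg import call_amgs, calls_to_frame
from pamg.catalog import load_catalog
from pamg.screen import (
    calls_to_frame as screen_frame,
    is_validated_phage,
    length_filter,
    read_annotations,
    screen_contig,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"


def main() -> None:
    catalog = load_catalog()
    contigs = read_annotations(OUT / "annotations.tsv")
    kept = length_filter(contigs)
    calls = {c.contig_id: screen_contig(c) for c in kept}
    screen_frame(calls.values()).to_csv(OUT / "screen.tsv", sep="\t", index=False)
    n_virus = sum(c.is_virus for c in calls.values())
    print(f"{len(kept)}/{len(contigs)} contigs pass the length filter; "
          f"{n_virus} called viral by curation")

    amg_calls = []
    for c in kept:
        validated = is_validated_phage(c, calls[c.contig_id])
        amg_calls.extend(call_amgs(c, catalog, validated))
    df = calls_to_frame(amg_calls)
    df.to_csv(OUT / "amgs.tsv", sep="\t", index=False)
    print(f"{int(df.accepted.sum())}/{len(df)} catalog-matching genes accepted as AMGs")
    print(df.rule.value_counts().to_string())

    truth = pd.DataFrame(
        json.loads((OUT / "truth.json").read_text())["amg"]["planted"]
    )
    merged = df.merge(truth, on=["contig_id", "gene_index"])
    agree = (merged.accepted == merged.expected_accept).sum()
    print(f"planted labels recovered: {agree}/{len(truth)}")


if __name__ == "__main__":
    main()
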