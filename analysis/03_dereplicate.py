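#!/usr/bin/env python
"""Dereplicate the simulated AMG protein sets at 95% identity / 90% coverage.

The same greedy engine also supports the coarser 70/70 pre-clustering used
before the selection analysis; both groupings are written for comparison.
"""

from pathlib import Path

import pandas as pd

from pamg.align import greedy_cluster

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"


def read_fasta(path: Path) -> dict[str, str]:
    seqs, sid = {}, None
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            sid = line[1:].split()[0]
            seqs[sid] = ""
        elif sid:
            seqs[sid] += line.strip()
    return seqs


def main() -> None:
    seqs = {}
    for fa in sorted(OUT.glob("prot_*.faa")):
        seqs.update(read_fasta(fa))
    rows = []
    for label, (min_id, min_cov, mode) in {
        "derep_95_90": (0.95, 0.90, "shorter"),
        "cluster_70_70": (0.70, 0.70, "both"),
    }.items():
        cs = greedy_cluster(seqs, min_id, min_cov, mode)
        print(f"{label}: {len(seqs)} sequences -> {cs.n_clusters} clusters")
        for c in cs.clusters:
            for m in c.member_ids:
                rows.append({"stage": label, "representative_id": c.representative_id,
                             "member_id": m})
    pd.DataFrame(rows).to_csv(OUT / "clusters.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
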