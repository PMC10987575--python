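#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Writes annotated contigs with planted AMG contexts (one per acceptance
rule), codon families evolved at known dN/dS, a 333-sample coverage matrix
with phosphorus-linked detection, and the environment table with a dominant
total-P effect — all under results/pipeline/, with the planted truth in
truth.json.
"""

import json
from pathlib import Path

from pamg.pipeline import DEFAULT_PLANTED
from pamg.synth import (
    annotations_to_frame,
    gen_annotated_contigs,
    gen_codon_families,
    gen_coverage_matrix,
    gen_env_table,
    meta_to_frame,
)

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"
FAMILY_OMEGAS = {"phoD": 0.2, "ppa": 0.3, "ugpQ": 0.5}


def write_fasta(path: Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for sid in sorted(seqs):
            fh.write(f">{sid}\n{seqs[sid]}\n")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    contigs, amg_truth = gen_annotated_contigs(list(DEFAULT_PLANTED), seed=SEED)
    annotations_to_frame(contigs).to_csv(OUT / "annotations.tsv", sep="\t", index=False)
    print(f"{len(contigs)} contigs with {len(amg_truth['planted'])} planted AMG contexts")

    fam_truth = {}
    for i, (kind, omega) in enumerate(sorted(FAMILY_OMEGAS.items())):
        cds, prot, truth = gen_codon_families(6, 200, omega, 80, seed=SEED + 100 + i, kind=kind)
        write_fasta(OUT / f"cds_{kind}.fna", cds)
        write_fasta(OUT / f"prot_{kind}.faa", prot)
        fam_truth[kind] = truth
        print(f"family {kind}: 6 sequences at true omega {omega}")

    cov, meta, cov_truth = gen_coverage_matrix(40, seed=SEED + 1)
    cov.to_csv(OUT / "coverage.tsv", sep="\t")
    meta_to_frame(meta).to_csv(OUT / "sample_meta.tsv", sep="\t", index=False)
    print(f"coverage matrix: {cov.shape[0]} vOTUs x {cov.shape[1]} samples")

    env, env_truth = gen_env_table(seed=SEED + 2)
    env.to_csv(OUT / "env.tsv", sep="\t", index=False)
    print(f"environment table: {len(env)} samples, planted coefficients "
          f"{env_truth['coefficients']}")

    (OUT / "truth.json").write_text(
        json.dumps(
            {"amg": amg_truth, "families": fam_truth, "coverage": cov_truth,
             "env": env_truth},
            indent=2, sort_keys=True,
        )
    )


if __name__ == "__main__":
    main()
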