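"""End-to-end orchestration of the synthetic analysis pipeline.

``run_all`` executes simulate → screen → call-amgs → derep → abundance →
dnds → link → ratios → abt against a single seeded configuration and writes
per-stage tables plus a machine-readable summary.  Identical configurations
produce identical summaries; with ``resume`` set, stages whose outputs are
already on disk are loaded instead of recomputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import phylo
from .abt import AbtParams, fit_abt, relative_influence
from .amg import call_amgs, calls_to_frame
from .align import greedy_cluster
from .catalog import expansion_stats, load_catalog
from .dnds import dnds_by_kind
from .screen import is_validated_phage, length_filter, screen_contig
from .synth import (
    PlantedAmg,
    annotations_to_frame,
    gen_annotated_contigs,
    gen_codon_families,
    gen_coverage_matrix,
    gen_env_table,
    gen_transcript_counts,
    meta_to_frame,
)

log = logging.getLogger("pamg")

# one planted context per acceptance rule, plus rejection cases
DEFAULT_PLANTED = (
    PlantedAmg("ppa", target_score=1),
    PlantedAmg("phoD", target_score=2),
    PlantedAmg("phoR", target_score=2),
    PlantedAmg("phoU", target_score=2, with_F=True),
    PlantedAmg("ugpQ", target_score=3, with_T=True),
    PlantedAmg("pit", target_score=3, with_T=True, validated=False),
    PlantedAmg("pstS", target_score=4, rescue_cluster=True),
    PlantedAmg("yjbB", target_score=4),
    PlantedAmg("phnW", target_score=5),
)


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 42
    min_bp: int = 10_000
    window: int = 10
    derep_id: float = 0.95
    derep_cov: float = 0.90
    dnds_id: float = 0.70
    dnds_cov: float = 0.70
    detection_threshold: float = 0.0
    n_votus: int = 40
    zero_rate: float = 0.5
    family_kinds: dict = field(
        default_factory=lambda: {"phoD": 0.2, "ppa": 0.3, "ugpQ": 0.5}
    )
    family_size: int = 6
    family_codons: int = 200
    family_mut_events: int = 80
    # phage:host expression ratio per simulated kind; solubilization pairs
    # run below one, transporter-like pairs above
    rate_ratios: dict = field(
        default_factory=lambda: {"phoD": 2.0, "ppa": 0.4, "ugpQ": 1.5}
    )
    abt_n_trees: int = 500
    abt_max_depth: int = 3
    abt_shrinkage: float = 0.01
    abt_bag_fraction: float = 0.5
    abt_replicates: int = 25
    stages: list = field(
        default_factory=lambda: [
            "simulate", "screen", "call_amgs", "derep", "abundance",
            "dnds", "link", "ratios", "abt",
        ]
    )
    resume: bool = False

    def validate(self) -> None:
        if self.min_bp < 1:
            raise ValueError("min_bp must be >= 1")
        for name in ("derep_id", "derep_cov", "dnds_id", "dnds_cov"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be >= 0")
        AbtParams(
            n_trees=self.abt_n_trees,
            max_depth=self.abt_max_depth,
            shrinkage=self.abt_shrinkage,
            bag_fraction=self.abt_bag_fraction,
            n_replicates=self.abt_replicates,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_all(config: RunConfig) -> dict:
    """Execute every enabled stage; returns (and writes) the run summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.resume and (out / "summary.json").exists():
        log.info("resuming from cached outputs in %s", out)
        return json.loads((out / "summary.json").read_text())
    config.to_json(out / "config.json")
    summary: dict = {"seed": config.seed}
    catalog = load_catalog()
    summary["catalog"] = expansion_stats(catalog)
    seed = config.seed

    # ----- simulate -------------------------------------------------------
    contigs, amg_truth = gen_annotated_contigs(
        list(DEFAULT_PLANTED), genes_per_contig=20, catalog=catalog,
        window=config.window, seed=seed,
    )
    annotations_to_frame(contigs).to_csv(out / "annotations.tsv", sep="\t", index=False)
    families = {}
    for i, (kind, omega) in enumerate(sorted(config.family_kinds.items())):
        cds, prot, truth = gen_codon_families(
            config.family_size, config.family_codons, omega,
            config.family_mut_events, seed=seed + 100 + i, kind=kind,
        )
        families[kind] = {"cds": cds, "proteins": prot, "truth": truth}
    cov, meta, cov_truth = gen_coverage_matrix(
        config.n_votus, zero_rate=config.zero_rate, seed=seed + 1,
    )
    cov.to_csv(out / "coverage.tsv", sep="\t")
    meta_to_frame(meta).to_csv(out / "sample_meta.tsv", sep="\t", index=False)
    env, env_truth = gen_env_table(seed=seed + 2)
    env.to_csv(out / "env.tsv", sep="\t", index=False)
    _write_json(out / "truth.json", {
        "amg": amg_truth, "coverage": cov_truth, "env": env_truth,
        "families": {k: v["truth"] for k, v in families.items()},
    })
    summary["simulate"] = {
        "n_contigs": len(contigs),
        "n_planted": len(amg_truth["planted"]),
        "n_families": len(families),
        "n_samples": len(meta),
    }
    if "simulate" in config.stages and len(config.stages) == 1:
        _write_json(out / "summary.json", summary)
        return summary

    # ----- screen ---------------------------------------------------------
    kept = length_filter(contigs, config.min_bp)
    calls = {c.contig_id: screen_contig(c) for c in kept}
    validated = {
        c.contig_id: is_validated_phage(c, calls[c.contig_id]) for c in kept
    }
    pd.DataFrame(
        [{**calls[c].__dict__, "validated_phage": validated[c]} for c in calls]
    ).to_csv(out / "screen.tsv", sep="\t", index=False)
    summary["screen"] = {
        "n_input": len(contigs),
        "n_passed_length": len(kept),
        "n_virus": sum(c.is_virus for c in calls.values()),
        "n_validated": sum(validated.values()),
    }

    # ----- call AMGs ------------------------------------------------------
    screening_on = "screen" in config.stages
    amg_calls = []
    for c in kept:
        v = validated[c.contig_id] if screening_on else False
        amg_calls.extend(call_amgs(c, catalog, v, window=config.window))
    amg_df = calls_to_frame(amg_calls)
    amg_df.to_csv(out / "amgs.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame(amg_truth["planted"])
    merged = amg_df.merge(
        truth_df, on=["contig_id", "gene_index"], how="inner", suffixes=("", "_true")
    )
    summary["call_amgs"] = {
        "n_calls": len(amg_df),
        "n_accepted": int(amg_df.accepted.sum()),
        "n_planted_recovered": int(
            (merged.accepted == merged.expected_accept).sum()
        ),
        "n_planted": len(truth_df),
        "rules": amg_df.rule.value_counts().to_dict(),
    }

    # ----- dereplication --------------------------------------------------
    all_prot = {sid: s for fam in families.values() for sid, s in fam["proteins"].items()}
    derep = greedy_cluster(all_prot, config.derep_id, config.derep_cov, "shorter")
    pd.DataFrame(
        [
            {"representative_id": cl.representative_id, "member_id": m}
            for cl in derep.clusters
            for m in cl.member_ids
        ]
    ).to_csv(out / "derep.tsv", sep="\t", index=False)
    summary["derep"] = {"n_sequences": len(all_prot), "n_clusters": derep.n_clusters}

    # ----- abundance & ecology -------------------------------------------
    norm = ab.normalize_coverage(cov, meta)
    rel, zero_cols = ab.relative_abundance(norm)
    norm.to_csv(out / "normalized_coverage.tsv", sep="\t")
    rel.to_csv(out / "relative_abundance.tsv", sep="\t")
    counts = ab.detection_counts(norm, config.detection_threshold)
    mf = meta_to_frame(meta).set_index("sample_id").loc[counts.index]
    comp = ab.group_compare(counts, mf.habitat)
    corr = {
        "TP": ab.correlate(counts, mf.TP),
        "AP": ab.correlate(counts, mf.AP),
    }
    summary["abundance"] = {
        "n_zero_columns": len(zero_cols),
        "kruskal_wallis_p": comp["kruskal_wallis_p"],
        "pearson_r_TP": corr["TP"]["pearson_r"],
        "pearson_r_AP": corr["AP"]["pearson_r"],
        "mean_detection_count": float(counts.mean()),
    }
    _write_json(out / "ecology_stats.json", {"group_compare": comp, "correlations": corr})

    # ----- dN/dS ----------------------------------------------------------
    records = {
        kind: [
            (sid, fam["proteins"][sid], fam["cds"][sid])
            for sid in sorted(fam["cds"])
        ]
        for kind, fam in families.items()
    }
    results, report = dnds_by_kind(records, config.dnds_id, config.dnds_cov)
    pairs_df = pd.DataFrame([r.__dict__ for r in results])
    pairs_df.to_csv(out / "dnds_pairs.tsv", sep="\t", index=False)
    medians = {}
    for kind in records:
        ids = set(families[kind]["cds"])
        sub = pairs_df[pairs_df.id_a.isin(ids)] if len(pairs_df) else pairs_df
        vals = sub.omega.dropna() if len(sub) else pd.Series(dtype=float)
        medians[kind] = float(vals.median()) if len(vals) else None
    summary["dnds"] = {
        "n_pairs": len(pairs_df),
        "median_omega_by_kind": medians,
        "frac_pairs_omega_lt_1": float((pairs_df.omega.dropna() < 1).mean())
        if len(pairs_df)
        else None,
    }

    # ----- phage-host linkage and transcript ratios ----------------------
    pair_rows = []
    for kind, fam in sorted(families.items()):
        prots = fam["proteins"]
        ids = sorted(prots)
        roles = {
            sid: ("phage" if i < len(ids) // 2 else "bacterial")
            for i, sid in enumerate(ids)
        }
        D, labels = phylo.protein_distance_matrix(prots)
        tree = phylo.nj_tree(D, labels, roles)
        for sid in ids:
            if roles[sid] != "phage":
                continue
            host = phylo.nearest_relative(tree, sid)
            if host is not None:
                pair_rows.append({"kind": kind, "phage_gene": sid, "host_gene": host})
    pairs = pd.DataFrame(pair_rows)
    pairs.to_csv(out / "phage_host_pairs.tsv", sep="\t", index=False)
    summary["link"] = {"n_pairs": len(pairs)}

    tx_parts = []
    for k, (kind, fam) in enumerate(sorted(families.items())):
        kind_pairs = pairs[pairs.kind == kind] if len(pairs) else pairs
        if not len(kind_pairs):
            continue
        part, _ = gen_transcript_counts(
            [f"{r.kind}:{r.phage_gene}" for r in kind_pairs.itertuples()],
            rate_ratio=config.rate_ratios.get(kind, 1.0),
            seed=seed + 3 + k,
        )
        tx_parts.append(part)
    tx = pd.concat(tx_parts, ignore_index=True)
    tx.to_csv(out / "transcript_counts.tsv", sep="\t", index=False)
    recs = [
        phylo.TranscriptRatioRecord(
            pair_id=f"{r.pair_id}@{r.sample}",
            phage_rpkm=phylo.rpkm(r.phage_reads, r.phage_len, r.library_size),
            host_rpkm=phylo.rpkm(r.host_reads, r.host_len, r.library_size),
        )
        for r in tx.itertuples()
    ]
    ratios = phylo.ratio_summary(recs)
    summary["ratios"] = ratios

    # ----- ABT influence --------------------------------------------------
    X = env[["TP", "MAT", "phage_P_gene", "prok_P_gene", "site"]]
    model = fit_abt(
        X,
        env["AP"],
        AbtParams(
            n_trees=config.abt_n_trees,
            max_depth=config.abt_max_depth,
            shrinkage=config.abt_shrinkage,
            bag_fraction=config.abt_bag_fraction,
            n_replicates=config.abt_replicates,
        ),
        seed=seed + 4,
        categorical=["site"],
    )
    infl = relative_influence(model)
    infl.rename("influence_pct").to_csv(out / "abt_influence.tsv", sep="\t")
    summary["abt"] = {
        "influence_pct": {k: round(float(v), 6) for k, v in infl.items()},
        "top_predictor": infl.index[0],
    }

    _write_json(out / "summary.json", summary)
    log.info("run complete: %s", out / "summary.json")
    return summary
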