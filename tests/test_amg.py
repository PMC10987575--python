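"""Auxiliary scores, AMG flags, pst clusters and acceptance rules."""

import itertools

import pytest

from pamg.amg import assign_flags, aux_score, call_amgs, find_pst_cluster
from pamg.screen import ContigAnnotation, Gene
from pamg.synth import PlantedAmg, gen_annotated_contigs

CLASSES = ("hallmark", "viral_like", "none")

# independent statement of the score decision table, keyed by unordered pair
EXPECTED_SCORE = {
    frozenset(["hallmark"]): 1,
    frozenset(["hallmark", "viral_like"]): 2,
    frozenset(["viral_like"]): 3,
    frozenset(["hallmark", "none"]): 4,
    frozenset(["viral_like", "none"]): 4,
    frozenset(["none"]): 5,
}


def build_contig(classes, kos=None, extra=None, contig_id="c"):
    """Contig whose gene i has viral class classes[i] (None -> non-viral)."""
    genes = []
    kos = kos or [None] * len(classes)
    extra = extra or [frozenset()] * len(classes)
    for i, cls in enumerate(classes):
        genes.append(
            Gene(
                gene_id=f"{contig_id}_g{i}",
                contig_id=contig_id,
                index=i,
                start=i * 1000 + 1,
                end=i * 1000 + 900,
                strand="+",
                ko=kos[i],
                vog=f"VOG{i:05d}" if cls != "none" else None,
                vog_class=cls,
                extra_flags=extra[i],
            )
        )
    return ContigAnnotation(contig_id, len(classes) * 1000, genes)


class TestAuxScore:
    @pytest.mark.parametrize(
        "left,right", list(itertools.product(CLASSES, CLASSES))
    )
    def test_decision_table_all_nine_flank_pairs(self, left, right):
        contig = build_contig([left, "none", right])
        assert aux_score(contig, 1) == EXPECTED_SCORE[frozenset([left, right])]

    def test_contig_with_no_viral_genes_scores_5(self):
        contig = build_contig(["none"] * 7)
        assert aux_score(contig, 3) == 5

    def test_window_limits_the_scan(self):
        # hallmark 3 genes away is invisible at window 2, visible at window 3
        contig = build_contig(["hallmark"] + ["none"] * 5)
        assert aux_score(contig, 3, window=2) == 5
        assert aux_score(contig, 3, window=3) == 4

    def test_best_class_wins_within_a_side(self):
        contig = build_contig(["hallmark", "viral_like", "none", "viral_like", "hallmark"])
        assert aux_score(contig, 2) == 1

    def test_edge_gene_has_one_empty_side(self):
        contig = build_contig(["none", "hallmark", "hallmark"])
        assert aux_score(contig, 0) == 4

    def test_out_of_range_errors(self):
        contig = build_contig(["none", "none"])
        with pytest.raises(IndexError):
            aux_score(contig, 2)


class TestFlags:
    def test_metabolic_run_gets_B(self, catalog):
        kos = [None, "K01507", "K01113", "K01126", None]  # ppa, phoD, ugpQ in a row
        contig = build_contig(["none"] * 5, kos=kos)
        for idx in (1, 2, 3):
            flags = assign_flags(contig, idx, catalog)
            assert {"M", "B"} <= flags
        # a run of two is not enough
        contig2 = build_contig(["none"] * 5, kos=[None, "K01507", "K01113", None, None])
        assert "B" not in assign_flags(contig2, 1, catalog)

    def test_viral_hit_breaks_the_run(self, catalog):
        kos = [None, "K01507", "K01113", "K01126", None]
        contig = build_contig(["none", "none", "viral_like", "none", "none"], kos=kos)
        assert "B" not in assign_flags(contig, 1, catalog)
        assert "V" in assign_flags(contig, 2, catalog)

    def test_contig_end_gets_F_unless_viral(self, catalog):
        kos = [None] * 5 + ["K01113"]
        contig = build_contig(["none"] * 6, kos=kos)
        assert {"M", "F"} <= assign_flags(contig, 5, catalog)
        assert "F" in assign_flags(contig, 0, catalog)
        assert "F" not in assign_flags(contig, 2, catalog)
        viral_end = build_contig(["none"] * 5 + ["viral_like"])
        assert "F" not in assign_flags(viral_end, 5, catalog)

    def test_extra_flags_map_to_TAP(self, catalog):
        contig = build_contig(
            ["none"], kos=["K01113"], extra=[frozenset({"transposase", "peptidase"})]
        )
        flags = assign_flags(contig, 0, catalog)
        assert {"T", "P", "M", "F"} <= flags
        assert "A" not in flags


class TestPstCluster:
    def test_scab_order(self, catalog):
        kos = [None, "K02040", "K02037", "K02038", "K02036", None]  # pstS,C,A,B
        contig = build_contig(["none"] * 6, kos=kos)
        assert find_pst_cluster(contig, catalog) == [[1, 2, 3, 4]]

    def test_bacs_order(self, catalog):
        kos = ["K02036", "K02038", "K02037", "K02040"]  # pstB,A,C,S
        contig = build_contig(["none"] * 4, kos=kos)
        assert find_pst_cluster(contig, catalog) == [[0, 1, 2, 3]]

    def test_isolated_pst_gene_is_no_cluster(self, catalog):
        contig = build_contig(["none"] * 3, kos=[None, "K02040", None])
        assert find_pst_cluster(contig, catalog) == []

    def test_three_distinct_kinds_suffice(self, catalog):
        kos = ["K02040", "K02037", "K02038"]
        contig = build_contig(["none"] * 3, kos=kos)
        assert find_pst_cluster(contig, catalog) == [[0, 1, 2]]

    def test_duplicated_kinds_do_not_count_as_distinct(self, catalog):
        kos = ["K02040", "K02040", "K02040"]
        contig = build_contig(["none"] * 3, kos=kos)
        assert find_pst_cluster(contig, catalog) == []


class TestCallAmgs:
    def test_score_mf_acceptance(self, catalog):
        contig = build_contig(
            ["hallmark", "none", "viral_like"], kos=[None, "K01113", None]
        )
        (call,) = call_amgs(contig, catalog, validated_phage=False)
        assert call.kind == "phoD" and call.aux_score == 2
        assert call.accepted and call.rule == "score_MF"

    def test_transposase_needs_validation(self, catalog):
        contig = build_contig(
            ["viral_like", "none", "viral_like"],
            kos=[None, "K01126", None],
            extra=[frozenset(), frozenset({"transposase"}), frozenset()],
        )
        (rej,) = call_amgs(contig, catalog, validated_phage=False)
        assert not rej.accepted and rej.rule == "rejected"
        (acc,) = call_amgs(contig, catalog, validated_phage=True)
        assert acc.accepted and acc.rule == "score_T_validated"

    def test_pst_rescue_requires_score4_cluster_and_validation(self, catalog):
        classes = ["viral_like"] + ["none"] * 4
        kos = [None, "K02040", "K02037", "K02038", "K02036"]
        contig = build_contig(classes, kos=kos)
        calls = call_amgs(contig, catalog, validated_phage=True)
        assert [c.aux_score for c in calls] == [4, 4, 4, 4]
        assert all(c.rule == "pst_rescue" and c.accepted for c in calls)
        calls_unvalidated = call_amgs(contig, catalog, validated_phage=False)
        assert not any(c.accepted for c in calls_unvalidated)

    def test_own_viral_hit_disqualifies_score_mf(self, catalog):
        contig = build_contig(
            ["hallmark", "viral_like", "hallmark"], kos=[None, "K01113", None]
        )
        (call,) = call_amgs(contig, catalog, validated_phage=False)
        assert "V" in call.flags and not call.accepted

    def test_accepted_scores_bounded(self, catalog):
        contigs, _ = gen_annotated_contigs(
            [
                PlantedAmg("ppa", 1),
                PlantedAmg("pstS", 4, rescue_cluster=True),
                PlantedAmg("phnW", 5),
            ],
            seed=3,
        )
        for contig in contigs:
            for call in call_amgs(contig, catalog, validated_phage=True):
                if call.accepted:
                    assert call.aux_score <= 4
                    if call.aux_score == 4:
                        assert call.rule == "pst_rescue"


def test_planted_contexts_recovered_exactly(catalog):
    """Closed loop: every planted accept/reject label is recovered."""
    specs = [
        PlantedAmg("ppa", 1),
        PlantedAmg("phoD", 2),
        PlantedAmg("phoR", 2),
        PlantedAmg("phoU", 2, with_F=True),
        PlantedAmg("ugpQ", 3, with_T=True),
        PlantedAmg("pit", 3, with_T=True, validated=False),
        PlantedAmg("pstS", 4, rescue_cluster=True),
        PlantedAmg("yjbB", 4),
        PlantedAmg("phnW", 5),
    ]
    contigs, truth = gen_annotated_contigs(specs, seed=17)
    expected = {
        (row["contig_id"], row["gene_index"]): row for row in truth["planted"]
    }
    n_checked = 0
    for contig, spec in zip(contigs, specs):
        calls = call_amgs(contig, catalog, validated_phage=spec.validated)
        for call in calls:
            key = (call.contig_id, call.gene_index)
            assert key in expected, f"unplanted catalog gene called: {key}"
            row = expected[key]
            assert call.aux_score == row["target_score"]
            assert call.rule == row["expected_rule"]
            assert call.accepted == row["expected_accept"]
            n_checked += 1
    assert n_checked == len(expected)
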