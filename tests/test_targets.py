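import math

import numpy as np
import pytest

from mirpipe.expression import DECall
from mirpipe.io_core import PipelineConfig, reverse_complement
from mirpipe.targets import (
    assess_pathway,
    default_tgfb_pathway,
    pathway_summary,
    predict_targets,
)

from .oracles import naive_seed_sites

MATURE = "UAGCUUAUCAGACUGAUGUUGA"  # seed AGCUUAU, complement AUAAGCU


class TestPredictTargets:
    def test_planted_site_found_at_offset(self):
        utr = "GGGGG" + reverse_complement("AGCUUAU") + "GGGGG"
        (site,) = predict_targets([("m1", MATURE)], {"geneA": utr})
        assert (site.gene_id, site.utr_offset) == ("geneA", 5)
        assert site.site_sequence == "AUAAGCU"

    def test_single_base_flip_destroys_site(self):
        site_seq = reverse_complement("AGCUUAU")
        utr_hit = "CCCC" + site_seq + "CCCC"
        flipped = site_seq[:3] + ("G" if site_seq[3] != "G" else "C") + site_seq[4:]
        utr_miss = "CCCC" + flipped + "CCCC"
        assert len(predict_targets([("m1", MATURE)], {"g": utr_hit})) == 1
        assert len(predict_targets([("m1", MATURE)], {"g": utr_miss})) == 0

    def test_all_occurrences_reported(self):
        site_seq = reverse_complement("AGCUUAU")
        utr = site_seq + "CC" + site_seq
        sites = predict_targets([("m1", MATURE)], {"g": utr})
        assert [s.utr_offset for s in sites] == [0, 9]

    def test_matches_naive_scan_oracle(self):
        r = np.random.default_rng(13)
        bases = list("ACGU")
        for _ in range(50):
            mature = "".join(r.choice(bases, 22))
            utrs = {f"g{k}": "".join(r.choice(bases, int(r.integers(30, 120))))
                    for k in range(4)}
            got = {(s.gene_id, s.utr_offset)
                   for s in predict_targets([("m", mature)], utrs)}
            assert got == naive_seed_sites(mature[1:8], utrs)

    def test_equal_seeds_give_equal_gene_sets(self):
        # the formal counterpart of same-seed family members sharing targets
        r = np.random.default_rng(14)
        bases = list("ACGU")
        seed_part = "".join(r.choice(bases, 8))
        m1 = seed_part + "".join(r.choice(bases, 14))
        m2 = seed_part + "".join(r.choice(bases, 14))
        utrs = {f"g{k}": "".join(r.choice(bases, 300)) for k in range(20)}
        s1 = {s.gene_id for s in predict_targets([("m1", m1)], utrs)}
        s2 = {s.gene_id for s in predict_targets([("m2", m2)], utrs)}
        assert s1 == s2

    def test_empty_utr_set(self):
        assert predict_targets([("m1", MATURE)], {}) == []


class TestPathwayAssessment:
    def test_two_distinct_pathway_genes_related(self):
        utr = "AAAA" + reverse_complement("AGCUUAU") + "AAAA"
        sites = predict_targets([("m1", MATURE)],
                                {"SMAD4": utr, "TGFB3": utr})
        (a,) = assess_pathway(sites, {"SMAD4", "TGFB3"})
        assert a.related and a.n_targeted == 2

    def test_multiple_sites_in_one_gene_count_once(self):
        site = reverse_complement("AGCUUAU")
        utr = (site + "AA") * 5
        sites = predict_targets([("m1", MATURE)], {"SMAD4": utr})
        (a,) = assess_pathway(sites, {"SMAD4", "TGFB3"})
        assert len(sites) == 5
        assert a.n_targeted == 1 and not a.related

    def test_empty_pathway_set(self):
        utr = "AAAA" + reverse_complement("AGCUUAU")
        sites = predict_targets([("m1", MATURE)], {"SMAD4": utr})
        (a,) = assess_pathway(sites, set())
        assert a.n_targeted == 0 and not a.related

    def test_adding_sites_never_unrelates(self):
        site = reverse_complement("AGCUUAU")
        utr = "AAAA" + site + "AAAA"
        genes = {"SMAD2", "SMAD3", "SMAD4"}
        small = predict_targets([("m1", MATURE)],
                                {"SMAD2": utr, "SMAD3": utr})
        big = small + predict_targets([("m1", MATURE)], {"SMAD4": utr})
        (a_small,) = assess_pathway(small, genes)
        (a_big,) = assess_pathway(big, genes)
        assert a_small.related and a_big.related
        assert a_big.n_targeted >= a_small.n_targeted

    def test_bundled_pathway_gene_set(self):
        genes = default_tgfb_pathway()
        assert {"SAR1A", "SMAD2", "SMAD3", "SMAD4", "TGFB2", "TGFB3",
                "TGFBR1", "TGFBR2"} == set(genes)


def de_call(mirna_id, direction):
    ratio = {"up": 4.0, "down": 0.25, "none": 1.0}[direction]
    return DECall(mirna_id, 100.0, 100.0 * ratio, ratio, 0.0, 0.001,
                  True, direction != "none", direction)


class TestPathwaySummary:
    def test_partition_matches_study_shape(self):
        from mirpipe.targets import PathwayAssessment

        # 22 DE novel candidates, 15 of them pathway-related (2 up / 13 down)
        de_calls = [de_call(f"seq-{i}_x50", "up" if i < 2 else "down")
                    for i in range(22)]
        assessments = [
            PathwayAssessment(f"seq-{i}_x50", "TGF-beta", {"SMAD4", "TGFB3"},
                              2, True)
            for i in range(15)
        ]
        summary = pathway_summary(assessments, de_calls)
        assert summary.cells[("novel", "up")] == 2
        assert summary.cells[("novel", "down")] == 13
        assert summary.n_de_novel == 22
        assert summary.related_novel_pct == 68.18

    def test_cells_sum_to_related_total(self):
        from mirpipe.targets import PathwayAssessment

        de_calls = [de_call("hsa-miR-1", "up"), de_call("seq-1_x20", "down"),
                    de_call("hsa-miR-2", "none")]
        assessments = [
            PathwayAssessment("hsa-miR-1", "p", {"SMAD2", "SMAD3"}, 2, True),
            PathwayAssessment("seq-1_x20", "p", {"SMAD2", "SMAD4"}, 2, True),
            PathwayAssessment("hsa-miR-2", "p", set(), 0, False),
        ]
        summary = pathway_summary(assessments, de_calls)
        assert sum(summary.cells.values()) == 2

    def test_assessed_mirna_missing_from_de_is_excluded(self):
        from mirpipe.targets import PathwayAssessment

        assessments = [PathwayAssessment("ghost", "p", {"SMAD2", "SMAD3"},
                                         2, True)]
        summary = pathway_summary(assessments, [de_call("other", "up")])
        assert summary.n_related == 0
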