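"""Codon tallies, overlaps, transcription units, terminators, ORF finding."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagearch.annotation_stats import (
    TerminatorParams,
    codon_tally,
    find_overlaps,
    find_terminator,
    partition_units,
    simple_orf_finder,
)
from phagearch.genome_io import BOTTOM, TOP, Feature, GenomeRecord, revcomp


class TestCodonTally:
    def test_top_strand_cds(self):
        g = GenomeRecord(id="x", sequence="AAATGCCCTAAGG")
        summary = codon_tally(g, [Feature("CDS", 3, 11, TOP)])
        assert summary.start_counts["ATG"] == 1 and summary.stop_counts["TAA"] == 1
        assert summary.n_cds == 1 and not summary.violations

    def test_bottom_strand_cds_identical_tally(self):
        cds_seq = "ATGCCCTAA"
        g = GenomeRecord(id="x", sequence="GG" + revcomp(cds_seq) + "GG")
        summary = codon_tally(g, [Feature("CDS", 3, 11, BOTTOM)])
        assert summary.start_counts["ATG"] == 1 and summary.stop_counts["TAA"] == 1

    def test_other_buckets_and_violations(self):
        g = GenomeRecord(id="x", sequence="CCCATGAAATGACC")
        summary = codon_tally(
            g,
            [
                Feature("CDS", 1, 7, TOP, {"ID": "odd"}),  # length 7: violation
                Feature("CDS", 4, 12, TOP),
            ],
        )
        assert summary.start_counts["other"] == 1  # CCC start
        assert summary.stop_counts["TGA"] == 2  # both CDS end in TGA
        assert any("odd" in v for v in summary.violations)

    def test_cds_outside_genome_rejected(self):
        g = GenomeRecord(id="x", sequence="ACGTACGTA")
        with pytest.raises(ValueError):
            codon_tally(g, [Feature("CDS", 5, 40, TOP)])

    def test_totals_equal_cds_count(self, fixture_genome):
        g, _ = fixture_genome
        cds = [f for f in g.features if f.kind == "CDS"]
        summary = codon_tally(g, cds)
        assert sum(summary.start_counts.values()) == len(cds)
        assert sum(summary.stop_counts.values()) == len(cds)


class TestFindOverlaps:
    def test_simple_overlap(self):
        report = find_overlaps(
            [Feature("CDS", 1, 30, TOP, {"ID": "a"}), Feature("CDS", 28, 60, TOP, {"ID": "b"})]
        )
        assert report.pairs == [("a", "b", 3)]
        assert report.max_pair == ("a", "b", 3)

    def test_disjoint_features_give_empty_report(self):
        report = find_overlaps(
            [Feature("CDS", 1, 10, TOP), Feature("CDS", 20, 30, BOTTOM)]
        )
        assert report.pairs == [] and report.max_pair is None

    def test_strand_irrelevant_for_overlap(self):
        report = find_overlaps(
            [Feature("CDS", 1, 30, TOP), Feature("CDS", 10, 40, BOTTOM)]
        )
        assert report.max_pair[2] == 21

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 80), st.integers(0, 30)), min_size=2, max_size=12))
    def test_equivalent_to_brute_force_interval_intersection(self, spans):
        feats = [
            Feature("CDS", s, s + w, TOP, {"ID": f"g{i}"}) for i, (s, w) in enumerate(spans)
        ]
        report = find_overlaps(feats)
        brute = []
        for i in range(len(feats)):
            for j in range(len(feats)):
                if i >= j:
                    continue
                ov = min(feats[i].end, feats[j].end) - max(feats[i].start, feats[j].start) + 1
                if ov > 0:
                    brute.append(ov)
        assert sorted(ov for _, _, ov in report.pairs) == sorted(brute)
        if brute:
            assert report.max_pair[2] == max(brute)


class TestPartitionUnits:
    def test_convergent_blocks_split_at_strand_switch(self):
        feats = [
            Feature("CDS", 1, 10, TOP),
            Feature("CDS", 20, 30, TOP),
            Feature("CDS", 40, 50, TOP),
            Feature("CDS", 70, 80, BOTTOM),
            Feature("CDS", 90, 100, BOTTOM),
        ]
        units = partition_units(feats)
        assert len(units.left_unit) == 3 and len(units.right_unit) == 2
        assert units.boundary_gap == (51, 69)
        assert not units.violations and not units.single_unit

    def test_single_gene_single_unit(self):
        units = partition_units([Feature("CDS", 1, 30, TOP)])
        assert units.single_unit and units.boundary_gap is None

    def test_strand_violators_flagged(self):
        strands = [TOP, TOP, BOTTOM, TOP, TOP, TOP, BOTTOM, BOTTOM, BOTTOM]
        feats = [
            Feature("CDS", 10 * i + 1, 10 * i + 8, s, {"ID": f"g{i}"})
            for i, s in enumerate(strands)
        ]
        units = partition_units(feats)
        assert len(units.left_unit) == 6 and len(units.right_unit) == 3
        assert [f.attributes["ID"] for f in units.violations] == ["g2"]


class TestFindTerminator:
    def test_planted_perfect_hairpin_called(self):
        stem = "GCCGC"
        hairpin = stem + "TTTT" + revcomp(stem)
        seq = "A" * 30 + "C" + hairpin + "C" + "TTTT" + "A" * 30
        g = GenomeRecord(id="x", sequence=seq)
        calls = find_terminator(g)
        exact = [c for c in calls if c.stem_len == 5 and c.mismatches == 0]
        assert exact
        c = exact[0]
        assert c.span == (32, 45) and c.loop_len == 4

    def test_poly_a_has_no_calls(self):
        g = GenomeRecord(id="x", sequence="A" * 120)
        assert find_terminator(g) == []

    def test_bidirectional_flag_requires_t_runs_on_both_sides(self):
        stem = "GCCGCC"
        hairpin = stem + "CAGT" + revcomp(stem)
        uni = "G" * 20 + "C" + hairpin + "C" + "TTT" + "G" * 20
        bi = "G" * 17 + "AAA" + "C" + hairpin + "C" + "TTT" + "G" * 20
        uni_calls = find_terminator(GenomeRecord(id="x", sequence=uni))
        bi_calls = find_terminator(GenomeRecord(id="x", sequence=bi))
        assert uni_calls and not uni_calls[0].bidirectional
        assert bi_calls and bi_calls[0].bidirectional

    def test_stem_arms_are_reverse_complementary_up_to_mismatch(self):
        rng = random.Random(8)
        seq = "".join(rng.choice("ACGT") for _ in range(800))
        g = GenomeRecord(id="x", sequence=seq)
        for c in find_terminator(g):
            s, loop = c.stem_len, c.loop_len
            arm1 = g.subseq(c.span[0], c.span[0] + s - 1)
            arm2 = g.subseq(c.span[1] - s + 1, c.span[1])
            mm = sum(a != b for a, b in zip(arm1, revcomp(arm2)))
            assert mm <= 1 and mm == c.mismatches

    def test_planted_fixture_terminator_recovered(self, fixture_genome):
        g, truth = fixture_genome
        row = truth.terminator().iloc[0]
        span = (int(row["start"]), int(row["end"]))
        calls = find_terminator(g, (span[0] - 300, span[1] + 300))
        exact = [c for c in calls if c.span == span and c.mismatches == 0]
        assert exact and exact[0].stem_len == int(row["stem_len"])
        assert exact[0].bidirectional


class TestSimpleOrfFinder:
    def test_minimal_orf(self):
        g = GenomeRecord(id="x", sequence="ATGAAATAA")
        (orf,) = simple_orf_finder(g, min_len=9)
        assert (orf.start, orf.end, orf.strand) == (1, 9, TOP)

    def test_no_start_codon_gives_empty(self):
        g = GenomeRecord(id="x", sequence="CCCCCCTAACCCCCC")
        assert simple_orf_finder(g, min_len=9) == []

    def test_longest_orf_per_stop(self):
        # two in-frame starts before one stop: the upstream start wins
        g = GenomeRecord(id="x", sequence="ATGCCCATGCCCTAA")
        (orf,) = simple_orf_finder(g, min_len=9)
        assert (orf.start, orf.end) == (1, 15)

    def test_planted_orfs_recovered_in_stop_saturated_background(self):
        rng = random.Random(12)
        background = "C" * 700  # start- and stop-free on both strands
        genes = []
        seq = list(background)
        for pos, strand in ((50, TOP), (300, BOTTOM)):
            body = "".join(rng.choice(["CCA", "CAC", "ACC"]) for _ in range(40))
            gene = "ATG" + body + "TAA"
            placed = gene if strand == TOP else revcomp(gene)
            seq[pos : pos + len(gene)] = placed
            genes.append((pos + 1, pos + len(gene), strand))
        g = GenomeRecord(id="x", sequence="".join(seq))
        found = {(f.start, f.end, f.strand) for f in simple_orf_finder(g, min_len=90)}
        assert found == set(genes)
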