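"""Terminal repeats, end structures, junctions and concatemer processing."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagearch.genome_io import GenomeRecord, revcomp
from phagearch.terminal_architecture import (
    BLUNT,
    EndStructure,
    FIVE_PRIME,
    LEFT,
    RIGHT,
    THREE_PRIME,
    TerminaseModel,
    blunt_ends,
    circularize_and_locate_junction,
    concatemerize,
    cut_concatemer,
    end_structure_report,
    find_dtr,
    find_tail_junction,
    tf_style_ends,
)

dna = st.text(alphabet="ACGT", min_size=4, max_size=30)


def make_tf_like_genome(body_len=400, dtr_len=40, seed=2):
    """Small genome with tf-style DTR: CCCCGG ... GATATCCC ... ATCTC."""
    rng = random.Random(seed)
    dtr = list(rng.choice("ACGT") for _ in range(dtr_len))
    dtr[:6] = "CCCCGG"
    dtr[18:26] = "GATATCCC"
    dtr[-5:] = "ATCTC"
    dtr = "".join(dtr)
    body = "".join(rng.choice("AT") for _ in range(body_len))  # no accidental GC repeat
    return GenomeRecord(id="mini", sequence=dtr + body + dtr)


class TestFindDtr:
    def test_simple_prefix_suffix_repeat(self):
        g = GenomeRecord(id="x", sequence="ATGCAAATGC")
        dtr = find_dtr(g, min_len=2)
        assert dtr.length == 4 and dtr.sequence == "ATGC"
        assert dtr.left_span == (1, 4) and dtr.right_span == (7, 10)

    def test_none_when_below_min_len(self):
        g = GenomeRecord(id="x", sequence="ACGGATTCAC")
        assert find_dtr(g, min_len=3) is None

    def test_repeat_capped_at_half_genome(self):
        g = GenomeRecord(id="x", sequence="ATAT")  # border 2 == N/2 allowed
        assert find_dtr(g).length == 2

    @settings(max_examples=60, deadline=None)
    @given(p=dna, data=st.data())
    def test_planted_repeat_detected(self, p, data):
        x = data.draw(st.text(alphabet="ACGT", min_size=len(p), max_size=80))
        g = GenomeRecord(id="x", sequence=p + x + p)
        dtr = find_dtr(g)
        assert dtr is not None and dtr.length >= len(p)
        assert g.sequence[: dtr.length] == g.sequence[-dtr.length :]


class TestBluntEnds:
    def test_blunt_input_is_identity(self):
        g = GenomeRecord(id="x", sequence="ACGTACGT")
        ends = (EndStructure(LEFT), EndStructure(RIGHT))
        blunted, new_ends = blunt_ends(g, ends)
        assert blunted.sequence == g.sequence
        assert all(e.geometry == BLUNT for e in new_ends)

    def test_left_three_prime_overhang_trim_keeps_top_strand(self):
        g = GenomeRecord(id="x", sequence="ACGTACGTAC")
        blunted, new_ends = blunt_ends(g, tf_style_ends("TTGA"))
        assert blunted.sequence == g.sequence  # bottom-strand tail: metadata only
        assert new_ends[0].geometry == BLUNT and new_ends[0].overhang_length == 0

    def test_right_three_prime_overhang_trims_top_strand(self):
        g = GenomeRecord(id="x", sequence="ACGTACGTAC")
        ends = (EndStructure(LEFT), EndStructure(RIGHT, THREE_PRIME, 3, "TAC"))
        blunted, _ = blunt_ends(g, ends)
        assert blunted.sequence == "ACGTACG"

    def test_right_five_prime_overhang_fill_extends_top_strand(self):
        g = GenomeRecord(id="x", sequence="ACGTACGTAC")
        ends = (EndStructure(LEFT), EndStructure(RIGHT, FIVE_PRIME, 4, "TTGA"))
        blunted, _ = blunt_ends(g, ends)
        assert blunted.sequence == "ACGTACGTAC" + revcomp("TTGA")

    def test_idempotent(self):
        g = GenomeRecord(id="x", sequence="ACGTACGTAC")
        b1, e1 = blunt_ends(g, tf_style_ends("TTGA"))
        b2, e2 = blunt_ends(b1, e1)
        assert b2.sequence == b1.sequence and e1 == e2

    def test_overhang_longer_than_genome_rejected(self):
        g = GenomeRecord(id="x", sequence="ACGT")
        ends = (EndStructure(LEFT, THREE_PRIME, 10, "A" * 10), EndStructure(RIGHT))
        with pytest.raises(ValueError, match="overhang"):
            blunt_ends(g, ends)


class TestJunction:
    def test_simple_junction(self):
        g = GenomeRecord(id="x", sequence="AAAACCGGTTTT")
        junction, boundary = circularize_and_locate_junction(g, k=4)
        assert junction == "TTTTAAAA" and boundary == 4

    def test_reverse_complement_symmetry(self):
        g = GenomeRecord(id="x", sequence="ACGGATTCACAGTCC")
        j1, k = circularize_and_locate_junction(g, k=5)
        g_rc = GenomeRecord(id="x", sequence=revcomp(g.sequence))
        j2, _ = circularize_and_locate_junction(g_rc, k=5)
        assert j2 == revcomp(j1)

    def test_tf_style_junction_orders_right_then_left_terminal(self):
        g = make_tf_like_genome()
        blunted, _ = blunt_ends(g, tf_style_ends("AAAA"))
        junction, boundary = circularize_and_locate_junction(blunted, k=10)
        assert junction[boundary - 5 : boundary] == "ATCTC"
        assert junction[boundary : boundary + 6] == "CCCCGG"


class TestConcatemer:
    def test_length_arithmetic(self):
        g = GenomeRecord(id="x", sequence="ATGC" + "A" * 92 + "ATGC")
        dtr = find_dtr(g)
        assert dtr.length == 4
        cat = concatemerize(g, dtr, 2)
        assert len(cat) == 2 * 100 - 4

    def test_unit_occurs_at_expected_offsets(self):
        g = make_tf_like_genome()
        dtr = find_dtr(g)
        cat = concatemerize(g, dtr, 2)
        N, L = g.length, dtr.length
        assert cat[:N] == g.sequence and cat[N - L : 2 * N - L] == g.sequence

    def test_cut_round_trip_identity(self):
        g = make_tf_like_genome()
        dtr = find_dtr(g)
        model = TerminaseModel()
        for n in (2, 3, 4):
            cat = concatemerize(g, dtr, n)
            products = cut_concatemer(cat, model, g.length, dtr.length)
            assert len(products) == n
            assert all(p.record.sequence == g.sequence for p in products)

    def test_partial_flags_on_terminal_fragments(self):
        g = make_tf_like_genome()
        dtr = find_dtr(g)
        products = cut_concatemer(
            concatemerize(g, dtr, 3), TerminaseModel(), g.length, dtr.length
        )
        assert [p.partial for p in products] == [True, False, True]

    def test_emitted_end_geometry_matches_model(self):
        g = make_tf_like_genome()
        dtr = find_dtr(g)
        products = cut_concatemer(
            concatemerize(g, dtr, 3), TerminaseModel(), g.length, dtr.length
        )
        interior = products[1]
        assert interior.left_end.geometry == THREE_PRIME
        assert interior.left_end.overhang_length == 4
        assert interior.right_end.geometry == BLUNT
        # the left overhang is the 4 concatemer bases preceding the unit
        N, L = g.length, dtr.length
        assert interior.left_end.overhang_sequence == g.sequence[N - L - 4 : N - L]

    def test_missing_core_site_rejected_with_boundary_index(self):
        g = make_tf_like_genome()
        dtr = find_dtr(g)
        cat = concatemerize(g, dtr, 2)
        bad_model = TerminaseModel(core_site="GGGGGGGG")
        with pytest.raises(ValueError, match="boundary 1"):
            cut_concatemer(cat, bad_model, g.length, dtr.length)

    def test_end_structure_report_shape(self):
        left, right = tf_style_ends("TTGA")
        rep = end_structure_report((left, right))
        assert rep["left"]["overhang_length"] == 4
        assert rep["left"]["protruding_strand"] == "bottom"
        assert rep["right"]["geometry"] == BLUNT


class TestTailJunction:
    def test_a_tail_resolved_against_reference(self):
        reference = "GGGCCTACGTTTGCA"
        read = "ACGTTTGCA" + "A" * 8
        assert find_tail_junction(read, reference, "A") == len(reference)

    def test_t_tail_symmetric_case(self):
        reference = "GGGCCTACGTTTGCT"
        read = "ACGTTTGCT" + "T" * 8
        assert find_tail_junction(read, reference, "T") == len(reference)

    def test_terminal_base_equal_to_tail_base_recovered(self):
        # the genomic 3' terminus is itself an A: boundary resolved by reference
        reference = "CCGGTTACGA"
        read = "TTACGA" + "A" * 8
        assert find_tail_junction(read, reference, "A") == 10

    def test_no_homopolymer_run_rejected(self):
        with pytest.raises(ValueError, match="homopolymer"):
            find_tail_junction("ACGTACGTAAA", "ACGTACGT", "A")

    def test_no_reference_match_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            find_tail_junction("CCCCCCCC" + "A" * 8, "GGGGGGGG", "A")

    def test_protruding_left_end_maps_4nt_beyond_blunt_position(self):
        g = make_tf_like_genome()
        ext = "TTGA"  # concatemer bases preceding the unit start
        # bottom strand at the left end, 3' tail included, read 5'->3'
        bottom_end = revcomp(ext + g.sequence[:60])
        blunt_reference = revcomp(g.sequence[:60])
        tailed = bottom_end + "A" * 10
        with_overhang = find_tail_junction(tailed, bottom_end, "A")
        blunt_pos = find_tail_junction(
            blunt_reference + "A" * 10, blunt_reference, "A"
        )
        assert with_overhang - blunt_pos == 4
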