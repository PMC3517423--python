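"""Nick-consensus scanning: IUPAC algebra, oracle equivalence, distribution."""

import random

import pytest
from Bio.SeqUtils import nt_search
from hypothesis import given, settings
from hypothesis import strategies as st

from phagearch.genome_io import BOTTOM, TOP, GenomeRecord, revcomp, reverse_complement_record
from phagearch.nick_analysis import (
    IUPAC_CODES,
    NickConsensus,
    bed_to_sites,
    compare_across_genomes,
    count_matrix,
    enumerate_single_substitutions,
    expand_iupac,
    half_distribution,
    hamming,
    percent_position,
    scan_core_with_substitutions,
    scan_motif,
    site_positions_percent,
    sites_to_bed,
)

CORE = "TACTGTGAC"
PATTERN = "TACTRTGMC"


def brute_force_scan(seq: str, pattern: str) -> list[int]:
    """Naive sliding-window IUPAC matcher: 1-based start positions."""
    out = []
    m = len(pattern)
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in IUPAC_CODES[pattern[j]] for j in range(m)):
            out.append(i + 1)
    return out


class TestExpandIupac:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            (PATTERN, {"TACTATGAC", "TACTATGCC", "TACTGTGAC", "TACTGTGCC"}),
            ("ACGT", {"ACGT"}),
        ],
    )
    def test_expansion_sets(self, pattern, expected):
        assert expand_iupac(pattern) == expected

    def test_nn_expands_to_16_dimers(self):
        assert len(expand_iupac("NN")) == 16

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError):
            expand_iupac("ACX")

    @settings(max_examples=40, deadline=None)
    @given(st.text(alphabet="".join(IUPAC_CODES), min_size=1, max_size=6))
    def test_size_is_product_of_cardinalities(self, pattern):
        expected = 1
        for ch in pattern:
            expected *= len(IUPAC_CODES[ch])
        assert len(expand_iupac(pattern)) == expected


class TestSingleSubstitutions:
    def test_nine_mer_has_27_neighbours(self):
        variants = enumerate_single_substitutions(CORE)
        assert len(variants) == 27
        assert CORE not in variants
        assert all(hamming(v, CORE) == 1 for v in variants)

    def test_single_base(self):
        assert enumerate_single_substitutions("A") == {"C", "G", "T"}


class TestScanMotif:
    def test_single_top_strand_site(self):
        g = GenomeRecord(id="x", sequence="AATACTGTGACAA")
        sites = scan_motif(g, PATTERN)
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.variant, s.strand) == (3, 11, "TACTGTGAC", TOP)
        assert s.mismatches_vs_core == 0
        assert s.nick_bond == 6  # break after the 4th site position (TACT/GTGAC)

    def test_strand_mirror_on_reverse_complement(self):
        g = GenomeRecord(id="x", sequence=revcomp("AATACTGTGACAA"))
        sites = scan_motif(g, PATTERN)
        assert [s.strand for s in sites] == [BOTTOM]
        assert not [s for s in sites if s.strand == TOP]
        s = sites[0]
        assert (s.start, s.end) == (3, 11)
        assert s.variant == "TACTGTGAC"  # read 5'->3' on its own strand

    def test_n_never_matches(self):
        g = GenomeRecord(id="x", sequence="AATACTGTGNCAA")
        assert scan_motif(g, "TACTGTGNC") == []

    def test_overlapping_matches_all_reported(self):
        g = GenomeRecord(id="x", sequence="AAAAA")
        sites = scan_motif(g, "AAA", strands=(TOP,))
        assert [s.start for s in sites] == [1, 2, 3]

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=9, max_size=120), st.integers(0, 10_000))
    def test_oracle_equivalence_with_planted_sites(self, background, seed):
        rng = random.Random(seed)
        seq = list(background)
        for _ in range(rng.randint(0, 3)):
            var = rng.choice(sorted(expand_iupac(PATTERN)))
            if rng.random() < 0.5:
                var = revcomp(var)
            pos = rng.randrange(0, len(seq) - 8)
            seq[pos : pos + 9] = var
        seq = "".join(seq)
        g = GenomeRecord(id="x", sequence=seq)
        got = [s.start for s in scan_motif(g, PATTERN, strands=(TOP,))]
        assert got == brute_force_scan(seq, PATTERN)

    def test_bottom_strand_equals_mirrored_top_scan(self):
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGT") for _ in range(400)) + "GTCACAGTA" + "ACGT"
        g = GenomeRecord(id="x", sequence=seq)
        bottom = [(s.start, s.end) for s in scan_motif(g, PATTERN) if s.strand == BOTTOM]
        L = g.length
        mirrored = [
            (L - s.end + 1, L - s.start + 1)
            for s in scan_motif(reverse_complement_record(g), PATTERN, strands=(TOP,))
        ]
        assert sorted(bottom) == sorted(mirrored)

    def test_agrees_with_biopython_iupac_search(self):
        rng = random.Random(11)
        seq = "".join(rng.choice("ACGT") for _ in range(2000))
        seq = seq[:500] + "TACTATGCC" + seq[509:1200] + "TACTGTGAC" + seq[1209:]
        g = GenomeRecord(id="x", sequence=seq)
        mine = [s.start for s in scan_motif(g, PATTERN, strands=(TOP,))]
        reference = [p + 1 for p in nt_search(seq, PATTERN)[1:]]
        assert mine == reference


class TestScanCoreWithSubstitutions:
    def test_single_mismatch_site(self):
        g = GenomeRecord(id="x", sequence="CACTGTGAC")
        result = scan_core_with_substitutions(g, CORE)
        assert set(result) == {"CACTGTGAC"}
        (site,) = result["CACTGTGAC"]
        assert (site.start, site.end, site.mismatches_vs_core) == (1, 9, 1)

    def test_exact_match_has_zero_mismatches(self):
        g = GenomeRecord(id="x", sequence="AA" + CORE + "AA")
        (site,) = scan_core_with_substitutions(g, CORE)[CORE]
        assert site.mismatches_vs_core == 0 and site.start == 3

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_equivalent_to_position_by_position_hamming_scan(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(2000))
        pos = rng.randrange(0, 1990)
        seq = seq[:pos] + rng.choice([CORE, "TACTGTGAT", "AACTGTGAC"]) + seq[pos + 9 :]
        g = GenomeRecord(id="x", sequence=seq)
        got = {
            (s.start, s.variant, s.mismatches_vs_core)
            for sites in scan_core_with_substitutions(g, CORE).values()
            for s in sites
        }
        expected = set()
        for i in range(len(seq) - 8):
            w = seq[i : i + 9]
            d = hamming(w, CORE)
            if d <= 1:
                expected.add((i + 1, w, d))
        assert got == expected


class TestDistribution:
    def test_two_sites_split(self):
        sites = scan_motif(GenomeRecord(id="x", sequence="AAA"), "AAA")
        mk = lambda bond: type(sites[0])(1, 9, CORE, 0, bond, TOP)
        assert half_distribution([mk(10), mk(90)], 100) == (1, 1)

    def test_bond_at_midpoint_counts_left(self):
        from phagearch.nick_analysis import NickSite

        site = NickSite(1, 9, CORE, 0, nick_bond=50, strand=TOP)
        assert half_distribution([site], 100) == (1, 0)
        assert half_distribution([site], 101) == (1, 0)
        assert half_distribution([site], 99) == (0, 1)

    def test_percent_rounding_half_up(self):
        assert percent_position(4628, 46267) == 10.0
        assert percent_position(46267 - 8, 46267) == 100.0
        assert percent_position(1, 1000) == 0.1
        assert percent_position(15, 10_000) == 0.2  # 0.15 rounds half-up

    def test_site_positions_sorted(self):
        from phagearch.nick_analysis import NickSite

        sites = [NickSite(900, 908, CORE, 0, 903), NickSite(100, 108, CORE, 0, 103)]
        assert site_positions_percent(sites, 1000) == [10.0, 90.0]


class TestCompareAcrossGenomes:
    def _genome_with_site(self, ident, pos, length=2000, seed=3):
        rng = random.Random(seed)
        seq = "".join(rng.choice("CG") for _ in range(length))  # no accidental core
        seq = seq[:pos] + CORE + seq[pos + 9 :]
        return GenomeRecord(id=ident, sequence=seq)

    def test_same_genome_twice_tolerance_zero(self):
        g = self._genome_with_site("a", 200)
        g2 = GenomeRecord(id="b", sequence=g.sequence)
        table = compare_across_genomes([(g, "forward"), (g2, "forward")], [CORE], tolerance=0.0)
        df = table.table
        assert len(df) == 1
        assert df.loc[0, "a"] == df.loc[0, "b"]

    def test_single_planted_site_is_singleton_row(self):
        g = self._genome_with_site("a", 500)
        df = compare_across_genomes([(g, "forward")], [CORE]).table
        assert len(df) == 1 and df.loc[0, "a"] == percent_position(501, 2000)

    def test_nearby_sites_group_within_tolerance(self):
        a = self._genome_with_site("a", 200)  # 10.05% -> 10.1
        b = self._genome_with_site("b", 209)  # 10.5%
        df = compare_across_genomes([(a, "forward"), (b, "forward")], [CORE], tolerance=1.0).table
        assert len(df) == 1
        df0 = compare_across_genomes([(a, "forward"), (b, "forward")], [CORE], tolerance=0.1).table
        assert len(df0) == 2

    def test_reverse_orientation_is_flipped_before_scanning(self):
        g = self._genome_with_site("a", 200)
        flipped = GenomeRecord(id="b", sequence=revcomp(g.sequence))
        df = compare_across_genomes(
            [(g, "forward"), (flipped, "reverse")], [CORE], tolerance=0.0
        ).table
        assert len(df) == 1 and df.loc[0, "a"] == df.loc[0, "b"]


class TestInterchange:
    def test_bed_round_trip(self, tmp_path):
        g = GenomeRecord(id="x", sequence="AA" + CORE + "A" * 40 + revcomp(CORE) + "AA")
        sites = scan_motif(g, PATTERN)
        p = tmp_path / "sites.bed"
        sites_to_bed(sites, g.id, p)
        back = bed_to_sites(p)
        assert [(s.start, s.end, s.variant, s.strand, s.nick_bond) for s in back] == [
            (s.start, s.end, s.variant, s.strand, s.nick_bond) for s in sites
        ]

    def test_count_matrix_columns_sum_to_n(self):
        m = count_matrix(["TACTGTGAC", "TACTATGAC", "TACTGTGCC"])
        assert (m.sum(axis=0) == 3).all()
        assert m.loc["T", 1] == 3 and m.loc["A", 5] == 1


class TestConsensusType:
    def test_core_must_match_pattern(self):
        with pytest.raises(ValueError):
            NickConsensus(core="AAAAAAAAA", iupac_pattern=PATTERN)

    def test_cut_offset_bounds(self):
        with pytest.raises(ValueError):
            NickConsensus(cut_offset=9)
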