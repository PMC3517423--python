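"""Strand-specific nick-consensus scanning and cross-genome comparison.

Some phage genomes carry single-strand interruptions (nicks) at fixed
positions, all on one strand, inside a short degenerate recognition
sequence.  This module enumerates matches of such a consensus (written
in IUPAC code, e.g. ``TACTRTGMC``), places the nick bond within each
site (the phosphodiester bond after a fixed offset, by default after
the fourth position: ``TACT/RTGMC``), summarises their distribution
over the genome halves, and aligns site positions across related
genomes on a percent-of-genome-length scale.

Matching is performed with a vectorised per-position comparison; the
test suite holds it to a naive sliding-window oracle.  ``N`` in the
genome never matches any pattern position.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import BOTTOM, TOP, Feature, GenomeRecord, revcomp, reverse_complement_record

#: IUPAC nucleotide ambiguity codes.  ``N`` expands to ACGT only: an ``N``
#: in the *genome* is unknown sequence and never matches.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _seq_to_ints(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def matches_iupac(seq: str, pattern: str) -> bool:
    """True when a concrete A/C/G/T string matches an IUPAC pattern."""
    if len(seq) != len(pattern):
        return False
    return all(s in IUPAC_CODES.get(p, "") for s, p in zip(seq, pattern))


def expand_iupac(pattern: str) -> set[str]:
    """Cartesian expansion of an IUPAC pattern into concrete DNA strings."""
    pools = []
    for ch in pattern:
        if ch not in IUPAC_CODES:
            raise ValueError(f"illegal IUPAC character {ch!r}")
        pools.append(IUPAC_CODES[ch])
    return {"".join(p) for p in itertools.product(*pools)}


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def enumerate_single_substitutions(core: str) -> set[str]:
    """All Hamming-distance-1 neighbours of ``core`` (core itself excluded)."""
    if set(core) - set("ACGT"):
        raise ValueError("core must be over {A,C,G,T}")
    out = set()
    for i, c in enumerate(core):
        for b in "ACGT":
            if b != c:
                out.add(core[:i] + b + core[i + 1 :])
    return out


@dataclass(frozen=True)
class NickConsensus:
    """The nick recognition 9-mer, its degenerate form, and the cut offset.

    ``cut_offset=4`` means the nick falls between site offsets 4 and 5
    (1-based within the site): TACT/RTGMC.
    """

    core: str = "TACTGTGAC"
    iupac_pattern: str = "TACTRTGMC"
    cut_offset: int = 4

    def __post_init__(self) -> None:
        if not matches_iupac(self.core, self.iupac_pattern):
            raise ValueError("core must match iupac_pattern")
        if not 1 <= self.cut_offset < len(self.core):
            raise ValueError("cut_offset must lie strictly inside the site")


@dataclass
class NickSite:
    """One consensus match on the genome, with the nick bond located.

    ``nick_bond`` is the top-strand coordinate of the last nucleotide 5'
    of the break *on the nicked strand*; the break lies between it and
    the next base in that strand's 5'->3' direction.
    """

    start: int
    end: int
    variant: str
    mismatches_vs_core: int
    nick_bond: int
    strand: str = TOP

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _nick_bond(start: int, end: int, strand: str, cut_offset: int) -> int:
    if strand == TOP:
        return start + cut_offset - 1
    return end - cut_offset + 1


def _match_positions(seq_int: np.ndarray, pattern: str) -> np.ndarray:
    """0-based start positions where ``pattern`` matches (vectorised)."""
    m = len(pattern)
    n = seq_int.size
    if m > n:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n - m + 1, dtype=bool)
    for i, ch in enumerate(pattern):
        allowed = [_BASE_INDEX[b] for b in IUPAC_CODES[ch]]
        window = seq_int[i : i + n - m + 1]
        ok &= np.isin(window, allowed)
    return np.nonzero(ok)[0]


def scan_motif(
    g: GenomeRecord,
    pattern: str,
    strands: Iterable[str] = (TOP, BOTTOM),
    consensus: NickConsensus | None = None,
) -> list[NickSite]:
    """All (possibly overlapping) matches of an IUPAC pattern, both strands.

    Bottom-strand matches are reported in top-strand coordinates with
    ``strand="bottom"``; ``variant`` is always the matched sequence read
    5'->3' on its own strand.  Results are in ascending start order.
    Mismatch counts are taken against ``consensus.core`` when a
    consensus is supplied (default: the tf nick consensus when the
    pattern length matches it), else 0 for every exact pattern match.
    """
    m = len(pattern)
    if m > g.length:
        raise ValueError("pattern longer than genome")
    for ch in pattern:
        if ch not in IUPAC_CODES:
            raise ValueError(f"illegal IUPAC character {ch!r}")
    if consensus is None and m == 9:
        default = NickConsensus()
        if pattern == default.iupac_pattern:
            consensus = default
    cut = consensus.cut_offset if consensus else min(4, m - 1) or 1
    core = consensus.core if consensus else None

    strands = set(strands)
    sites: list[NickSite] = []
    seq_int = _seq_to_ints(g.sequence)
    if TOP in strands:
        for p in _match_positions(seq_int, pattern):
            start, end = int(p) + 1, int(p) + m
            variant = g.sequence[p : p + m]
            mm = hamming(variant, core) if core else 0
            sites.append(NickSite(start, end, variant, mm, _nick_bond(start, end, TOP, cut), TOP))
    if BOTTOM in strands:
        rc_int = _seq_to_ints(revcomp(g.sequence))
        L = g.length
        for p in _match_positions(rc_int, pattern):
            # match at 0-based p..p+m-1 on the reverse complement
            start, end = L - (int(p) + m) + 1, L - int(p)
            variant = revcomp(g.sequence[start - 1 : end])
            mm = hamming(variant, core) if core else 0
            sites.append(NickSite(start, end, variant, mm, _nick_bond(start, end, BOTTOM, cut), BOTTOM))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def scan_core_with_substitutions(
    g: GenomeRecord, core: str = "TACTGTGAC", cut_offset: int = 4
) -> dict[str, list[NickSite]]:
    """Top-strand matches of ``core`` and of every distance-1 variant.

    Returns a mapping variant -> sites, keyed by the concrete matched
    9-mer; each site carries ``mismatches_vs_core`` of 0 or 1.  Windows
    containing N never match (N differs from every concrete base, and a
    single N already spends the one allowed mismatch on an unknown).
    """
    if set(core) - set("ACGT"):
        raise ValueError("core must be over {A,C,G,T}")
    m = len(core)
    seq_int = _seq_to_ints(g.sequence)
    n = seq_int.size
    result: dict[str, list[NickSite]] = {}
    if m > n:
        return result
    nwin = n - m + 1
    mism = np.zeros(nwin, dtype=np.int16)
    has_n = np.zeros(nwin, dtype=bool)
    for i, ch in enumerate(core):
        window = seq_int[i : i + nwin]
        mism += (window != _BASE_INDEX[ch]).astype(np.int16)
        has_n |= window == 4
    for p in np.nonzero((mism <= 1) & ~has_n)[0]:
        start, end = int(p) + 1, int(p) + m
        variant = g.sequence[p : p + m]
        site = NickSite(
            start, end, variant, int(mism[p]), _nick_bond(start, end, TOP, cut_offset), TOP
        )
        result.setdefault(variant, []).append(site)
    for sites in result.values():
        sites.sort(key=lambda s: s.start)
    return result


def half_distribution(sites: Sequence[NickSite], genome_length: int) -> tuple[int, int]:
    """Count nick bonds in the left vs right genome half.

    A bond at exactly ``floor(L/2)`` counts as left.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    mid = genome_length // 2
    left = sum(1 for s in sites if s.nick_bond <= mid)
    return left, len(sites) - left


def percent_position(start: int, genome_length: int) -> float:
    """100 * start / L, rounded half-up to one decimal."""
    q = (Decimal(100 * start) / Decimal(genome_length)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


def site_positions_percent(sites: Sequence[NickSite], genome_length: int) -> list[float]:
    """Site start positions as percent of genome length, ascending."""
    return sorted(percent_position(s.start, genome_length) for s in sites)


@dataclass
class SiteComparisonTable:
    """Matched site groups (rows) across genomes (columns), percent positions."""

    table: pd.DataFrame
    patterns: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, na_rep="")


def compare_across_genomes(
    genomes: Sequence[tuple[GenomeRecord, str]],
    patterns: Sequence[str],
    tolerance: float = 2.0,
) -> SiteComparisonTable:
    """Align nick-site positions across genomes on the percent scale.

    ``genomes`` pairs each record with an orientation flag ("forward" or
    "reverse"); reverse genomes are reverse complemented before
    scanning, mirroring how deposited comparator sequences may be
    flipped relative to the nicked strand.  Sites (top strand, any of
    ``patterns``) whose percent positions fall within ``tolerance`` of
    each other across genomes are grouped by single linkage, per
    pattern; ungrouped sites form singleton rows.
    """
    if not genomes:
        raise ValueError("at least one genome required")
    entries = []  # (pattern, genome_id, percent)
    ids = []
    for g, orientation in genomes:
        if orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        gg = reverse_complement_record(g) if orientation == "reverse" else g
        ids.append(g.id)
        for pat in patterns:
            for s in scan_motif(gg, pat, strands=(TOP,)):
                entries.append((pat, g.id, percent_position(s.start, gg.length)))
    rows = []
    for pat in patterns:
        sub = sorted((e for e in entries if e[0] == pat), key=lambda e: e[2])
        cluster: list[tuple[str, str, float]] = []
        clusters = []
        for e in sub:
            if cluster and e[2] - cluster[-1][2] > tolerance:
                clusters.append(cluster)
                cluster = []
            cluster.append(e)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            row: dict[str, object] = {"pattern": pat}
            for _, gid, pct in cl:
                if gid in row:  # two same-genome sites in one cluster: keep both, joined
                    row[gid] = f"{row[gid]},{pct}"
                else:
                    row[gid] = pct
            rows.append(row)
    table = pd.DataFrame(rows, columns=["pattern", *ids])
    table = table.sort_values(
        by=["pattern", *ids], na_position="last", key=lambda c: c.astype(str)
    ).reset_index(drop=True)
    return SiteComparisonTable(table=table, patterns=list(patterns))


# ---------------------------------------------------------------------------
# Interchange: BED / TSV / GFF3-ready features
# ---------------------------------------------------------------------------


def sites_to_bed(sites: Sequence[NickSite], genome_id: str, path) -> None:
    """Write sites as BED (0-based half-open; conversion at this boundary only)."""
    with open(path, "w") as fh:
        for s in sites:
            strand = "+" if s.strand == TOP else "-"
            fh.write(
                f"{genome_id}\t{s.start - 1}\t{s.end}\t{s.variant}\t{s.mismatches_vs_core}\t{strand}\n"
            )


def bed_to_sites(path, cut_offset: int = 4) -> list[NickSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, bstart, bend, name, score, strand_sym = line.rstrip("\n").split("\t")[:6]
            start, end = int(bstart) + 1, int(bend)
            strand = TOP if strand_sym == "+" else BOTTOM
            sites.append(
                NickSite(start, end, name, int(score), _nick_bond(start, end, strand, cut_offset), strand)
            )
    return sites


def sites_to_tsv(sites: Sequence[NickSite], genome_length: int, path) -> None:
    df = pd.DataFrame(
        {
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "variant": [s.variant for s in sites],
            "mismatches_vs_core": [s.mismatches_vs_core for s in sites],
            "nick_bond": [s.nick_bond for s in sites],
            "strand": [s.strand for s in sites],
            "percent": [percent_position(s.start, genome_length) for s in sites],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def sites_to_features(sites: Sequence[NickSite]) -> list[Feature]:
    return [
        Feature(
            "nick_site",
            s.start,
            s.end,
            s.strand,
            {"variant": s.variant, "mismatches": str(s.mismatches_vs_core), "nick_bond": str(s.nick_bond)},
        )
        for s in sites
    ]


def count_matrix(site_seqs: Sequence[str]) -> pd.DataFrame:
    """Per-position base counts of aligned site sequences (logo-style export)."""
    if not site_seqs:
        raise ValueError("no sequences")
    w = len(site_seqs[0])
    if any(len(s) != w for s in site_seqs):
        raise ValueError("sequences must share one length")
    data = {b: [sum(1 for s in site_seqs if s[i] == b) for i in range(w)] for b in "ACGT"}
    return pd.DataFrame(data, index=range(1, w + 1)).T
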