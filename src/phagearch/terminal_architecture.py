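"""Direct terminal repeats, duplex end structures, and concatemer processing.

A linear phage duplex is represented by its top strand plus per-end
overhang metadata (an :class:`EndStructure` for each side) — enough to
model blunting, circularisation junctions and terminase cutting without
carrying two explicit strands.  At the left end the 5' terminus belongs
to the top strand and the 3' terminus to the bottom strand; at the
right end the roles swap.  Hence a 3'-protruding left end is a bottom-
strand extension (the top strand is untouched by trimming it), while a
3'-protruding right end would be a top-strand extension.

The end geometry modelled by default is the unusual one seen in phage
tf: a blunt right end and a 4-nt 3'-protruding left end, with terminal
sequences CCCCGG (left, top-strand 5') and ATCTC (right).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .genome_io import GenomeRecord, revcomp

LEFT = "left"
RIGHT = "right"

BLUNT = "blunt"
THREE_PRIME = "three_prime_protruding"
FIVE_PRIME = "five_prime_protruding"
GEOMETRIES = (BLUNT, THREE_PRIME, FIVE_PRIME)


@dataclass(frozen=True)
class TerminalRepeat:
    """An exact prefix/suffix repeat of a linear genome."""

    length: int
    left_span: tuple[int, int]
    right_span: tuple[int, int]
    sequence: str


def find_dtr(g: GenomeRecord, min_len: int = 1) -> TerminalRepeat | None:
    """Longest exact direct terminal repeat, or None if shorter than min_len.

    The repeat is the longest border of the sequence (prefix == suffix)
    not exceeding half the genome; found via the KMP failure function,
    so exact-match only.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    s = g.sequence
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    L = fail[-1]
    while L > n // 2:
        L = fail[L - 1]
    if L < min_len:
        return None
    return TerminalRepeat(
        length=L, left_span=(1, L), right_span=(n - L + 1, n), sequence=s[:L]
    )


@dataclass
class EndStructure:
    """Duplex geometry of one genome end.

    ``overhang_sequence`` is the protruding single strand read 5'->3'
    (empty when blunt); ``terminal_sequence`` is the short terminal
    sequence of that end in top-strand orientation (the genome's first
    bases at the left end, its last bases at the right end).
    """

    side: str
    geometry: str = BLUNT
    overhang_length: int = 0
    overhang_sequence: str = ""
    terminal_sequence: str = ""

    def __post_init__(self) -> None:
        if self.side not in (LEFT, RIGHT):
            raise ValueError("side must be 'left' or 'right'")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == BLUNT and self.overhang_length != 0:
            raise ValueError("blunt ends have zero overhang")
        if self.overhang_length != len(self.overhang_sequence) and self.overhang_sequence:
            raise ValueError("overhang_sequence length disagrees with overhang_length")

    @property
    def protruding_strand(self) -> str | None:
        """Which strand protrudes: top 5' / bottom 3' at left, mirrored at right."""
        if self.geometry == BLUNT:
            return None
        if self.side == LEFT:
            return "top" if self.geometry == FIVE_PRIME else "bottom"
        return "bottom" if self.geometry == FIVE_PRIME else "top"


def tf_style_ends(left_overhang_sequence: str = "") -> tuple[EndStructure, EndStructure]:
    """The default end model: 4-nt 3'-protruding left end, blunt right end."""
    seq = left_overhang_sequence
    return (
        EndStructure(LEFT, THREE_PRIME, 4, seq, terminal_sequence="CCCCGG"),
        EndStructure(RIGHT, BLUNT, 0, "", terminal_sequence="ATCTC"),
    )


def blunt_ends(
    g: GenomeRecord, ends: tuple[EndStructure, EndStructure]
) -> tuple[GenomeRecord, tuple[EndStructure, EndStructure]]:
    """T4-polymerase-style blunting: trim 3' overhangs, fill in 5' overhangs.

    Trimming a bottom-strand 3' overhang (e.g. a 4-nt 3'-protruding
    left end) leaves the top strand intact; only a top-strand 3'
    overhang at the right end would shorten the top strand, and only a
    bottom-strand 5' overhang at the right end extends it (fill-in).
    Idempotent: blunt input comes back unchanged.
    """
    left, right = ends
    if {left.side, right.side} != {LEFT, RIGHT}:
        raise ValueError("ends must be one left and one right EndStructure")
    if left.side == RIGHT:
        left, right = right, left
    seq = g.sequence
    for e in (left, right):
        if e.overhang_length > g.length:
            raise ValueError("overhang longer than genome")
    if left.geometry == THREE_PRIME:
        pass  # bottom-strand tail at the left: metadata only
    elif left.geometry == FIVE_PRIME:
        pass  # top strand protrudes; bottom is filled in: metadata only
    if right.geometry == THREE_PRIME:
        seq = seq[: len(seq) - right.overhang_length]  # top-strand 3' tail removed
    elif right.geometry == FIVE_PRIME:
        # bottom-strand 5' tail at the right is filled in: the top strand is
        # extended by the complement of the protruding sequence.
        if not right.overhang_sequence:
            raise ValueError("filling a right 5' overhang requires its sequence")
        seq = seq + revcomp(right.overhang_sequence)
    blunted = GenomeRecord(id=g.id, sequence=seq)
    new_ends = (
        EndStructure(LEFT, BLUNT, 0, "", left.terminal_sequence),
        EndStructure(RIGHT, BLUNT, 0, "", right.terminal_sequence),
    )
    return blunted, new_ends


def circularize_and_locate_junction(blunted: GenomeRecord, k: int = 10) -> tuple[str, int]:
    """Ligation junction of a blunt, circularised genome.

    Returns the 2k-mer spanning the ligation point — the right-end
    k-mer followed by the left-end k-mer — and the index of the
    right/left boundary within it (== k).
    """
    if k < 1 or k > blunted.length:
        raise ValueError("k must be in [1, genome length]")
    s = blunted.sequence
    return s[-k:] + s[:k], k


@dataclass(frozen=True)
class TerminaseModel:
    """Concatemer-processing model: core recognition site and cut asymmetry.

    Cutting at a packaging junction yields one blunt product side and
    one with a 3' overhang, regenerating the two genome-end structures.
    """

    core_site: str = "GATATCCC"
    left_cut_overhang: int = 4
    right_cut_overhang: int = 0


def concatemerize(g: GenomeRecord, dtr: TerminalRepeat, n_copies: int) -> str:
    """Head-to-tail concatemer in which adjacent units share one DTR copy.

    Length is n*N - (n-1)*L; the unit genome occurs as a substring at
    offsets 0, N-L, 2(N-L), ...
    """
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2")
    s = g.sequence
    if s[: dtr.length] != dtr.sequence or s[-dtr.length :] != dtr.sequence:
        raise ValueError("dtr is not valid for this genome")
    return s + s[dtr.length :] * (n_copies - 1)


@dataclass
class CutProduct:
    """One unit genome emitted by terminase cutting of a concatemer."""

    record: GenomeRecord
    left_end: EndStructure
    right_end: EndStructure
    partial: bool  # True for the two terminal fragments (one uncut side)


def cut_concatemer(
    concatemer: str,
    model: TerminaseModel,
    unit_length: int,
    dtr_length: int,
) -> list[CutProduct]:
    """Cut a concatemer at every packaging junction into unit genomes.

    Each internal junction (a shared DTR copy) must contain the model's
    core site; the cut is asymmetric — the upstream product's right end
    is blunt, the downstream product's left end carries a
    ``left_cut_overhang``-nt 3' bottom-strand overhang — and the DTR is
    duplicated into both products (fill-in synthesis is abstracted
    away).  The two outermost fragments have one side that was never
    cut and are flagged ``partial``, not discarded.
    """
    N, L = unit_length, dtr_length
    step = N - L
    if step <= 0:
        raise ValueError("unit_length must exceed dtr_length")
    if (len(concatemer) - L) % step != 0:
        raise ValueError("concatemer length is not n*N - (n-1)*L for any n")
    n = (len(concatemer) - L) // step
    if n < 2:
        raise ValueError("concatemer holds fewer than two units")
    # validate core site inside each shared DTR
    for j in range(1, n):
        boundary = j * step  # 0-based start of the shared DTR copy
        if model.core_site not in concatemer[boundary : boundary + L]:
            raise ValueError(
                f"core site {model.core_site!r} absent at unit boundary {j} "
                f"(concatemer positions {boundary + 1}-{boundary + L})"
            )
    products = []
    for i in range(n):
        off = i * step
        seq = concatemer[off : off + N]
        left_over = concatemer[off - model.left_cut_overhang : off] if i > 0 else ""
        left = EndStructure(
            LEFT,
            THREE_PRIME if model.left_cut_overhang else BLUNT,
            model.left_cut_overhang,
            left_over if i > 0 else "N" * model.left_cut_overhang,
            terminal_sequence=seq[:6],
        )
        right = EndStructure(
            RIGHT,
            BLUNT if model.right_cut_overhang == 0 else THREE_PRIME,
            model.right_cut_overhang,
            "",
            terminal_sequence=seq[-5:],
        )
        products.append(
            CutProduct(
                record=GenomeRecord(id=f"unit_{i + 1}", sequence=seq),
                left_end=left,
                right_end=right,
                partial=(i == 0 or i == n - 1),
            )
        )
    return products


def find_tail_junction(
    read: str,
    reference_end: str,
    tail_base: str,
    min_run: int = 8,
) -> int:
    """Map a homopolymer-tailed 3' end back onto its reference.

    ``read`` is a sequence ending in a homopolymer tail of ``tail_base``
    (terminal-transferase tailing).  The genomic part of the read may
    itself end in ``tail_base``, so the boundary is resolved against the
    reference: the genomic prefix is extended into the run as far as it
    still matches the reference.  Returns the 1-based position in
    ``reference_end`` of the last reference-matching base preceding the
    tail — the template's 3' terminus.
    """
    read = read.upper()
    reference_end = reference_end.upper()
    if tail_base not in ("A", "T"):
        raise ValueError("tail_base must be 'A' or 'T'")
    t = 0
    while t < len(read) and read[len(read) - 1 - t] == tail_base:
        t += 1
    if t < min_run:
        raise ValueError(f"no terminal homopolymer run of {tail_base} (>= {min_run} nt) found")
    best = None
    # give back run bases to the genomic prefix while the reference still matches
    for k in range(t - min_run, -1, -1):
        core = read[: len(read) - t + k]
        if not core:
            continue
        pos = reference_end.rfind(core)
        if pos != -1:
            best = pos + len(core)
            break
    if best is None:
        raise ValueError("tail-stripped read does not match the reference end")
    return best


def end_structure_report(ends: tuple[EndStructure, EndStructure]) -> dict:
    """JSON-ready description of the two genome ends."""
    out = {}
    for e in ends:
        out[e.side] = {
            "geometry": e.geometry,
            "overhang_length": e.overhang_length,
            "overhang_sequence": e.overhang_sequence,
            "terminal_sequence": e.terminal_sequence,
            "protruding_strand": e.protruding_strand,
        }
    return out
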