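"""Annotation-level statistics: codon usage, overlaps, transcription units,
rho-independent terminators, and a naive ORF finder for synthetic genomes.

The ORF finder here is a deliberately simple synthetic-data utility
(longest ORF per stop, six frames); it is not a gene predictor and is
not expected to reproduce an HMM-based annotation of a real genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genome_io import BOTTOM, TOP, Feature, GenomeRecord, revcomp

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TGA", "TAG")


@dataclass
class CodonUsageSummary:
    start_counts: dict[str, int]
    stop_counts: dict[str, int]
    violations: list[str] = field(default_factory=list)

    @property
    def n_cds(self) -> int:
        return sum(self.start_counts.values())


def codon_tally(g: GenomeRecord, cds: Sequence[Feature]) -> CodonUsageSummary:
    """Strand-aware start/stop codon tallies over a CDS set.

    Starts are bucketed as ATG/GTG/TTG/other, stops as TAA/TGA/TAG/other.
    CDS shorter than 6 bp or of length not divisible by 3 are tallied
    anyway but recorded in ``violations`` (not fatal).
    """
    starts = {c: 0 for c in (*START_CODONS, "other")}
    stops = {c: 0 for c in (*STOP_CODONS, "other")}
    violations = []
    for i, f in enumerate(cds):
        if f.end > g.length:
            raise ValueError(f"CDS ({f.start}, {f.end}) outside genome of length {g.length}")
        seq = g.feature_seq(f)
        label = f.attributes.get("ID", f"cds_{i + 1}")
        if len(seq) < 6:
            violations.append(f"{label}: length {len(seq)} < 6")
        elif len(seq) % 3:
            violations.append(f"{label}: length {len(seq)} not a multiple of 3")
        start, stop = seq[:3], seq[-3:]
        starts[start if start in START_CODONS else "other"] += 1
        stops[stop if stop in STOP_CODONS else "other"] += 1
    return CodonUsageSummary(starts, stops, violations)


@dataclass
class OverlapReport:
    pairs: list[tuple[str, str, int]]
    max_pair: tuple[str, str, int] | None

    @property
    def max_overlap(self) -> int:
        return self.max_pair[2] if self.max_pair else 0


def _label(f: Feature, i: int) -> str:
    return f.attributes.get("ID", f"cds_{i + 1}")


def find_overlaps(cds: Sequence[Feature]) -> OverlapReport:
    """All pairwise coordinate overlaps between CDS, irrespective of strand.

    overlap(a,b) = max(0, min(end) - max(start) + 1).  The maximal pair
    is deterministic: ties resolve to the lowest coordinates (then
    input order).
    """
    if len(cds) < 2:
        raise ValueError("need at least two features")
    order = sorted(range(len(cds)), key=lambda i: (cds[i].start, cds[i].end, i))
    pairs: list[tuple[str, str, int]] = []
    best: tuple[int, int, int, int, int] | None = None  # (-ov, start_a, start_b, ia, ib)
    for a_pos, ia in enumerate(order):
        fa = cds[ia]
        for ib in order[a_pos + 1 :]:
            fb = cds[ib]
            if fb.start > fa.end:
                break  # sorted by start: no later feature can overlap fa
            ov = min(fa.end, fb.end) - max(fa.start, fb.start) + 1
            if ov > 0:
                pairs.append((_label(fa, ia), _label(fb, ib), ov))
                key = (-ov, fa.start, fb.start, ia, ib)
                if best is None or key < best:
                    best = key
    max_pair = None
    if best is not None:
        _, _, _, ia, ib = best
        max_pair = (
            _label(cds[ia], ia),
            _label(cds[ib], ib),
            min(cds[ia].end, cds[ib].end) - max(cds[ia].start, cds[ib].start) + 1,
        )
    return OverlapReport(pairs=pairs, max_pair=max_pair)


@dataclass
class TranscriptionUnits:
    left_unit: list[Feature]
    right_unit: list[Feature]
    boundary_gap: tuple[int, int] | None
    violations: list[Feature] = field(default_factory=list)
    single_unit: bool = False


def partition_units(cds: Sequence[Feature]) -> TranscriptionUnits:
    """Split genes into two convergent strand-homogeneous blocks.

    Genes are ordered by start; the boundary is the split maximising
    strand homogeneity (left block one strand, right block the other).
    Genes violating their block's majority strand are flagged.  If all
    genes lie on one strand a single unit is returned with no gap.
    """
    feats = sorted(cds, key=lambda f: (f.start, f.end))
    if not feats:
        raise ValueError("no genes to partition")
    strands = [f.strand for f in feats]
    if len(set(strands)) == 1:
        return TranscriptionUnits(feats, [], None, [], single_unit=True)
    n = len(feats)
    best_score, best = -1, (n, TOP, BOTTOM)
    # prefix counts of 'top'
    pref = [0]
    for s in strands:
        pref.append(pref[-1] + (s == TOP))
    for k in range(1, n):  # left block feats[:k], right block feats[k:]
        top_left = pref[k]
        top_right = pref[n] - pref[k]
        for left_strand in (TOP, BOTTOM):
            right_strand = BOTTOM if left_strand == TOP else TOP
            score = (top_left if left_strand == TOP else k - top_left) + (
                top_right if right_strand == TOP else (n - k) - top_right
            )
            if score > best_score:
                best_score, best = score, (k, left_strand, right_strand)
    k, ls, rs = best
    left, right = feats[:k], feats[k:]
    violations = [f for f in left if f.strand != ls] + [f for f in right if f.strand != rs]
    gap_start = max(f.end for f in left) + 1
    gap_end = min(f.start for f in right) - 1
    gap = (gap_start, gap_end) if gap_start <= gap_end else None
    return TranscriptionUnits(left, right, gap, violations)


@dataclass
class TerminatorParams:
    """Hairpin-caller heuristics (standard rho-independent conventions)."""

    min_stem: int = 5
    max_stem: int = 15
    min_loop: int = 3
    max_loop: int = 10
    max_mismatch: int = 1
    min_u_run: int = 3
    u_window: int = 8  # nt downstream of the hairpin searched for the T-run


@dataclass
class TerminatorCall:
    span: tuple[int, int]
    stem_len: int
    loop_len: int
    u_tract_len: int
    bidirectional: bool
    mismatches: int = 0


def _run_length(seq: str, base: str) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if c == base else 0
        best = max(best, cur)
    return best


def find_terminator(
    g: GenomeRecord,
    search_span: tuple[int, int] | None = None,
    params: TerminatorParams | None = None,
) -> list[TerminatorCall]:
    """Rho-independent terminator calls within a span.

    Enumerates inverted repeats (stem >= min_stem, loop within range,
    <= max_mismatch in the stem) followed within ``u_window`` nt by a
    T-run of >= min_u_run on at least one strand (top: downstream of
    the hairpin; bottom: upstream as an A-run on the top strand);
    ``bidirectional`` when both strands qualify.  Nested shorter stems
    of the same hairpin are suppressed; calls sort by stem length,
    longest first.
    """
    params = params or TerminatorParams()
    if search_span is None:
        search_span = (1, g.length)
    lo, hi = search_span
    if not (1 <= lo <= hi <= g.length):
        raise ValueError("search span outside genome")
    region = g.sequence[lo - 1 : hi]
    calls: list[TerminatorCall] = []
    n = len(region)
    for s in range(params.max_stem, params.min_stem - 1, -1):
        for loop in range(params.min_loop, params.max_loop + 1):
            total = 2 * s + loop
            for i in range(0, n - total + 1):
                arm1 = region[i : i + s]
                arm2 = region[i + s + loop : i + total]
                if "N" in arm1 or "N" in arm2:
                    continue
                mm = sum(a != b for a, b in zip(arm1, revcomp(arm2)))
                if mm > params.max_mismatch:
                    continue
                start, end = lo + i, lo + i + total - 1
                down = g.sequence[end : end + params.u_window]
                up = g.sequence[max(0, start - 1 - params.u_window) : start - 1]
                t_run = _run_length(down, "T")
                a_run = _run_length(up, "A")
                fwd = t_run >= params.min_u_run
                rev = a_run >= params.min_u_run
                if not (fwd or rev):
                    continue
                calls.append(
                    TerminatorCall(
                        span=(start, end),
                        stem_len=s,
                        loop_len=loop,
                        u_tract_len=max(t_run if fwd else 0, a_run if rev else 0),
                        bidirectional=fwd and rev,
                        mismatches=mm,
                    )
                )
    # suppress dominated calls: same centre, no longer stem, no fewer mismatches
    calls.sort(key=lambda c: (-c.stem_len, c.mismatches, c.span))
    kept: list[TerminatorCall] = []
    for c in calls:
        centre = sum(c.span)
        if any(
            sum(k.span) == centre
            and k.stem_len >= c.stem_len
            and k.mismatches <= c.mismatches
            for k in kept
        ):
            continue
        kept.append(c)
    return kept


def simple_orf_finder(
    g: GenomeRecord,
    min_len: int = 60,
    starts: Sequence[str] = START_CODONS,
) -> list[Feature]:
    """Longest-ORF-per-stop in all six frames (synthetic-data utility).

    For each stop codon, the reported ORF runs from the most upstream
    in-frame start codon (of ``starts``) with no intervening stop, to
    the stop inclusive.  Coordinates are top-strand 1-based inclusive;
    bottom-strand ORFs carry strand="bottom".
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    orfs: list[Feature] = []
    for strand, seq in ((TOP, g.sequence), (BOTTOM, revcomp(g.sequence))):
        L = len(seq)
        for frame in range(3):
            first_start: int | None = None
            for p in range(frame, L - 2, 3):
                codon = seq[p : p + 3]
                if codon in STOP_CODONS:
                    if first_start is not None:
                        length = p + 3 - first_start
                        if length >= min_len:
                            if strand == TOP:
                                start, end = first_start + 1, p + 3
                            else:
                                start, end = L - (p + 3) + 1, L - first_start
                            orfs.append(
                                Feature("CDS", start, end, strand, {"frame": str(frame)})
                            )
                    first_start = None
                elif codon in starts and first_start is None:
                    first_start = p
    orfs.sort(key=lambda f: (f.start, f.end, f.strand))
    return orfs


def codon_summary_dict(summary: CodonUsageSummary) -> dict:
    return {
        "n_cds": summary.n_cds,
        "start_counts": dict(summary.start_counts),
        "stop_counts": dict(summary.stop_counts),
        "violations": list(summary.violations),
    }
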