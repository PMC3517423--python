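"""Seeded phage-like genome generator with exact ground truth.

Emits a linear genome emulating the architecture of a nicked
LUZ24-like phage: exact direct terminal repeats carrying the terminal
sequences and the terminase core site, strand-specific nick-consensus
9-mers planted on the top strand only, two convergent transcription
units with controlled start/stop codons and one large gene overlap, a
bidirectional rho-independent terminator in the inter-unit gap, and
two-box promoters in intergenic gaps.

After planting, the background is *masked*: any accidental occurrence
of the nick-consensus family (the core, its full single-substitution
neighbourhood, and the IUPAC expansion) on either strand, and any
two-box promoter placement reaching the scan cutoff, is destroyed by a
minimal substitution, so the planted set is exactly what every scanner
should recover.  The same seed always yields a byte-identical genome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome_io import (
    BOTTOM,
    TOP,
    Feature,
    GenomeRecord,
    revcomp,
    write_fasta,
    write_gff3,
)
from .nick_analysis import (
    NickConsensus,
    enumerate_single_substitutions,
    expand_iupac,
)
from .promoter_scan import TOY_TRAINING, PromoterModel, model_from_pairs, scan_promoters
from .trace_evidence import ExtensionProfile, simulate_primer_extension

# Default planted nick layout: 14 sites, 11 of them in the left half,
# 11 x TACTGTGAC + 1 x TACTATGAC + 2 x TACTGTGCC, positions as percent
# of genome length (the tf-like layout this generator emulates).
DEFAULT_NICK_SITES: tuple[tuple[float, str], ...] = (
    (4.5, "TACTATGAC"),
    (7.6, "TACTGTGAC"),
    (9.1, "TACTGTGAC"),
    (11.4, "TACTGTGAC"),
    (18.7, "TACTGTGAC"),
    (21.5, "TACTGTGAC"),
    (24.5, "TACTGTGCC"),
    (27.1, "TACTGTGCC"),
    (28.8, "TACTGTGAC"),
    (33.9, "TACTGTGAC"),
    (44.9, "TACTGTGAC"),
    (53.4, "TACTGTGAC"),
    (73.2, "TACTGTGAC"),
    (80.2, "TACTGTGAC"),
)

#: Single-substitution variants present in the genome but *not* nicked
#: (recognition-site neighbours the nicking system ignores).
DEFAULT_EXTRA_SITES: tuple[tuple[float, str], ...] = (
    (20.1, "CACTGTGAC"),
    (29.4, "TACCGTGAC"),
    (54.2, "TATTGTGAC"),
)

#: 7 promoters on the top strand of the left half, 3 convergent ones on
#: the bottom strand of the right half: (strand, percent, spacer).
DEFAULT_PROMOTERS: tuple[tuple[str, float, int], ...] = (
    (TOP, 0.8, 17),
    (TOP, 8.0, 16),
    (TOP, 14.0, 17),
    (TOP, 22.0, 18),
    (TOP, 30.0, 17),
    (TOP, 38.0, 19),
    (TOP, 46.0, 17),
    (BOTTOM, 60.0, 17),
    (BOTTOM, 75.0, 18),
    (BOTTOM, 90.0, 16),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic genome."""

    length: int = 46_267
    gc: float = 0.532
    dtr_len: int = 186
    nick_sites: tuple[tuple[float, str], ...] = DEFAULT_NICK_SITES
    extra_sites: tuple[tuple[float, str], ...] = DEFAULT_EXTRA_SITES
    promoters: tuple[tuple[str, float, int], ...] = DEFAULT_PROMOTERS
    orf_left: int = 49
    orf_right: int = 23
    start_codon_counts: tuple[int, int, int] = (61, 7, 4)  # ATG, GTG, TTG
    stop_codon_counts: tuple[int, int, int] = (38, 32, 2)  # TAA, TGA, TAG
    max_overlap_bp: int = 137
    terminator: bool = True
    left_overhang: int = 4
    terminal_left: str = "CCCCGG"
    terminal_right: str = "ATCTC"
    terminase_core: str = "GATATCCC"
    consensus: NickConsensus = field(default_factory=NickConsensus)
    seed: int = 0

    def validate(self) -> None:
        if self.dtr_len < 20 or self.dtr_len > self.length // 2:
            raise ValueError("infeasible spec: dtr_len must be in [20, length/2]")
        if self.length < 20_000:
            raise ValueError("infeasible spec: full layout needs >= 20 kb")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be a fraction in (0, 1)")
        for pct, variant in (*self.nick_sites, *self.extra_sites):
            if not 0.0 <= pct <= 100.0:
                raise ValueError("site positions must be percentages in [0, 100]")
            if len(variant) != len(self.consensus.core):
                raise ValueError("site variants must match the consensus length")
        if sum(self.start_codon_counts) != self.orf_left + self.orf_right:
            raise ValueError("start codon counts must sum to the gene count")
        if sum(self.stop_codon_counts) != self.orf_left + self.orf_right:
            raise ValueError("stop codon counts must sum to the gene count")
        for strand, pct, spacer in self.promoters:
            if strand not in (TOP, BOTTOM) or not 0 <= pct <= 100 or not 14 <= spacer <= 21:
                raise ValueError("bad promoter spec entry")


@dataclass
class TruthTable:
    """Exact coordinates and identities of every planted feature."""

    table: pd.DataFrame

    def _kind(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind].reset_index(drop=True)

    def nick_sites(self, nicked: bool | None = None) -> pd.DataFrame:
        df = self._kind("nick_site")
        if nicked is not None:
            df = df[df["nicked"] == nicked].reset_index(drop=True)
        return df

    def cds(self) -> pd.DataFrame:
        return self._kind("CDS")

    def promoters(self) -> pd.DataFrame:
        return self._kind("promoter")

    def terminator(self) -> pd.DataFrame:
        return self._kind("terminator")

    def dtr(self) -> pd.DataFrame:
        return self._kind("repeat_region")

    def row(self, feature_id: str) -> pd.Series:
        hits = self.table[self.table["feature_id"] == feature_id]
        if hits.empty:
            raise KeyError(f"unknown feature {feature_id!r}")
        return hits.iloc[0]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))


_TRUTH_COLUMNS = [
    "feature_id",
    "kind",
    "start",
    "end",
    "strand",
    "variant",
    "nicked",
    "nick_bond",
    "spacer",
    "box35_start",
    "box10_start",
    "start_codon",
    "stop_codon",
    "stem_len",
    "loop_len",
    "fraction",
]

_STOPS = ("TAA", "TGA", "TAG")
_STARTS = ("ATG", "GTG", "TTG")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


class _Builder:
    """Mutable genome under construction, with protection and DTR mirroring."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
        self.seq = list(self.rng.choice(list("ACGT"), size=spec.length, p=p))
        self.protected = np.zeros(spec.length, dtype=bool)
        self.truth_rows: list[dict] = []
        self.planted_site_starts: set[int] = set()
        codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
        base_p = dict(zip("ACGT", p))
        w = np.array(
            [np.prod([base_p[b] for b in c]) if c not in _STOPS else 0.0 for c in codons]
        )
        self.codons = codons
        self.codon_p = w / w.sum()

    # -- editing ---------------------------------------------------------

    def write(self, pos0: int, s: str, protect: bool = False) -> None:
        for i, ch in enumerate(s):
            self.seq[pos0 + i] = ch
        if protect:
            self.protected[pos0 : pos0 + len(s)] = True

    def mirror_edit(self, pos0: int, base: str) -> None:
        """Point substitution keeping the two DTR copies identical."""
        N, L = self.spec.length, self.spec.dtr_len
        self.seq[pos0] = base
        if pos0 < L:
            self.seq[N - L + pos0] = base
        elif pos0 >= N - L:
            self.seq[pos0 - (N - L)] = base

    def lock(self, pos0: int) -> None:
        """Protect a position (and its DTR mirror) against further edits."""
        N, L = self.spec.length, self.spec.dtr_len
        self.protected[pos0] = True
        if pos0 < L:
            self.protected[N - L + pos0] = True
        elif pos0 >= N - L:
            self.protected[pos0 - (N - L)] = True

    def editable(self, pos0: int) -> bool:
        N, L = self.spec.length, self.spec.dtr_len
        if self.protected[pos0]:
            return False
        if pos0 < L and self.protected[N - L + pos0]:
            return False
        if pos0 >= N - L and self.protected[pos0 - (N - L)]:
            return False
        return True

    def string(self) -> str:
        return "".join(self.seq)

    # -- codon helpers ---------------------------------------------------

    def sample_codons(self, n: int) -> str:
        idx = self.rng.choice(len(self.codons), size=n, p=self.codon_p)
        return "".join(self.codons[i] for i in idx)

    def add_truth(self, **kw) -> None:
        row = {c: "" for c in _TRUTH_COLUMNS}
        row.update(kw)
        self.truth_rows.append(row)


def _plan_layout(spec: SyntheticSpec) -> dict:
    """Deterministic coordinate plan for units, gap, and gene slots."""
    N = spec.length
    gap_lo = int(0.5405 * N)
    gap_hi = gap_lo + 394
    left_lo, left_hi = spec.dtr_len + 150, gap_lo - 1
    right_lo, right_hi = gap_hi + 1, N - spec.dtr_len - 280
    plan = {"gap": (gap_lo, gap_hi)}
    for name, lo, hi, count in (
        ("left", left_lo, left_hi, spec.orf_left),
        ("right", right_lo, right_hi, spec.orf_right),
    ):
        if count == 0:
            plan[name] = []
            continue
        slot = (hi - lo + 1) // count
        gene_len = 3 * ((slot - 70) // 3)
        if gene_len < 90:
            raise ValueError("infeasible spec: gene slots shorter than 90 bp")
        plan[name] = [(lo + i * slot, lo + i * slot + gene_len - 1) for i in range(count)]
    return plan


def _build_overlap_gene(
    b: _Builder, gene_len: int, start_b: str, stop_b: str, stop_a: str, overlap: int
) -> str:
    """Sequence for the downstream gene of the overlapping pair.

    Its first ``overlap`` bases double as the upstream gene's tail: the
    upstream reading frame (offset ``overlap % 3`` within the block)
    must be stop-free until its final codon, which must spell
    ``stop_a`` at the block's last three bases.  Rejection-sample until
    both frames are clean.
    """
    if overlap % 3 != 2:
        raise ValueError("overlap construction assumes overlap % 3 == 2")
    n_body = gene_len // 3 - 2
    for _ in range(2000):
        seqb = start_b + b.sample_codons(n_body) + stop_b
        seqb = seqb[: overlap - 3] + stop_a + seqb[overlap:]
        # downstream (b) frame: codons spanning the substitution
        c44 = seqb[overlap - 5 : overlap - 2]
        c45 = seqb[overlap - 2 : overlap + 1]
        if c44 in _STOPS or c45 in _STOPS:
            continue
        # upstream (a) frame starts at offset 2 inside the block
        a_codons = [seqb[i : i + 3] for i in range(2, overlap - 3, 3)]
        if any(c in _STOPS for c in a_codons):
            continue
        if seqb[overlap - 3 : overlap] != stop_a:
            continue
        return seqb
    raise RuntimeError("could not construct the overlapping gene pair")


def _plant_genes(b: _Builder, plan: dict) -> None:
    spec = b.spec
    rng = b.rng
    starts = sum(([c] * n for c, n in zip(_STARTS, spec.start_codon_counts)), [])
    stops = sum(([c] * n for c, n in zip(_STOPS, spec.stop_codon_counts)), [])
    starts = [starts[i] for i in rng.permutation(len(starts))]
    stops = [stops[i] for i in rng.permutation(len(stops))]
    slots = [(s, e, TOP) for s, e in plan["left"]] + [(s, e, BOTTOM) for s, e in plan["right"]]

    # the overlapping pair: genes 45 and 46 of the left unit (1-based),
    # shifted so they overlap by max_overlap_bp
    ov = spec.max_overlap_bp
    ov_idx = min(45, spec.orf_left - 1) if spec.orf_left >= 2 and ov else None
    if ov_idx is not None:
        s_prev, e_prev, _ = slots[ov_idx - 1]
        s, e = slots[ov_idx][0], slots[ov_idx][1]
        shift = s - (e_prev - ov + 1)
        slots[ov_idx] = (s - shift, e - shift, TOP)

    gene_id = 0
    for i, (s, e, strand) in enumerate(slots):
        gene_id += 1
        gene_len = e - s + 1
        start_c, stop_c = starts[i], stops[i]
        if ov_idx is not None and i == ov_idx:
            gseq = _build_overlap_gene(b, gene_len, start_c, stop_c, stops[ov_idx - 1], ov)
        else:
            gseq = start_c + b.sample_codons(gene_len // 3 - 2) + stop_c
        placed = gseq if strand == TOP else revcomp(gseq)
        b.write(s - 1, placed)
        # protect terminal codons so later planting cannot destroy them
        if strand == TOP:
            b.protected[s - 1 : s + 2] = True
            b.protected[e - 3 : e] = True
        else:
            b.protected[e - 3 : e] = True
            b.protected[s - 1 : s + 2] = True
        b.add_truth(
            feature_id=f"gene_{gene_id:03d}",
            kind="CDS",
            start=s,
            end=e,
            strand=strand,
            start_codon=start_c,
            stop_codon=stop_c,
        )


def _plant_terminator(b: _Builder, plan: dict) -> None:
    spec = b.spec
    gap_lo, _ = plan["gap"]
    stem = "".join(b.rng.choice(list("GC"), size=9)) + "".join(b.rng.choice(list("ACGT"), size=3))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    while True:  # loop ends must not base-pair, or the stem would extend inward
        loop = "".join(b.rng.choice(list("ACGT"), size=5))
        if loop[0] != comp[loop[-1]]:
            break
    # 'C'/'C' separators cannot pair, so the planted stem is exactly maximal
    element = "AAAA" + "C" + stem + loop + revcomp(stem) + "C" + "TTTT"
    pos0 = gap_lo + 199  # 0-based
    b.write(pos0, element, protect=True)
    hp_start = pos0 + 5 + 1  # 1-based hairpin start
    hp_end = hp_start + 2 * len(stem) + len(loop) - 1
    b.add_truth(
        feature_id="terminator_1",
        kind="terminator",
        start=hp_start,
        end=hp_end,
        strand=TOP,
        stem_len=len(stem),
        loop_len=len(loop),
    )


def _gap_intervals(b: _Builder, plan: dict) -> list[tuple[int, int]]:
    """Free intergenic intervals (1-based, inclusive) ordered by position."""
    occupied = sorted(
        [(r["start"], r["end"]) for r in b.truth_rows if r["kind"] in ("CDS", "terminator")]
    )
    gaps = []
    prev_end = b.spec.dtr_len  # keep the DTR itself clear
    for s, e in occupied:
        if s > prev_end + 1:
            gaps.append((prev_end + 1, s - 1))
        prev_end = max(prev_end, e)
    tail_hi = b.spec.length - b.spec.dtr_len
    if prev_end + 1 <= tail_hi:
        gaps.append((prev_end + 1, tail_hi))
    return gaps


def _plant_promoters(b: _Builder, plan: dict) -> None:
    spec = b.spec
    gaps = _gap_intervals(b, plan)
    for j, (strand, pct, spacer) in enumerate(spec.promoters, start=1):
        nominal = _round_half_up(pct / 100 * spec.length)
        window = 12 + spacer
        candidates = [g for g in gaps if g[1] - g[0] + 1 >= window + 4]
        if not candidates:
            raise ValueError("infeasible spec: no intergenic gap can host a promoter")
        g = min(candidates, key=lambda g: abs((g[0] + g[1]) // 2 - nominal))
        centre = (g[0] + g[1]) // 2
        start = min(max(g[0] + 2, centre - window // 2), g[1] - window - 1)
        core = "TTGACA" + "".join(b.rng.choice(list("ACGT"), size=spacer)) + "TATAAT"
        placed = core if strand == TOP else revcomp(core)
        b.write(start - 1, placed)
        # protect the two boxes only (spacer bases are fair game for tuning)
        b.protected[start - 1 : start + 5] = True
        b.protected[start + spacer + 5 : start + spacer + 11] = True
        if strand == TOP:
            b35, b10 = start, start + 6 + spacer
        else:
            b10, b35 = start, start + 6 + spacer
        b.add_truth(
            feature_id=f"promoter_{j:02d}",
            kind="promoter",
            start=start,
            end=start + window - 1,
            strand=strand,
            spacer=spacer,
            box35_start=b35,
            box10_start=b10,
        )
        gaps = [
            gg if gg != g else (g[0], start - 2) for gg in gaps
        ] + ([(start + window + 1, g[1])] if start + window + 1 <= g[1] else [])


def _plant_nick_sites(b: _Builder) -> None:
    spec = b.spec
    cut = spec.consensus.cut_offset
    entries = [(pct, var, True) for pct, var in spec.nick_sites] + [
        (pct, var, False) for pct, var in spec.extra_sites
    ]
    n_id = e_id = 0
    for pct, variant, nicked in sorted(entries, key=lambda t: t[0]):
        nominal = _round_half_up(pct / 100 * spec.length)
        m = len(variant)
        placed_at = None
        for delta in sorted(range(-60, 61), key=abs):
            s0 = nominal - 1 + delta
            if s0 < spec.dtr_len or s0 + m > spec.length - spec.dtr_len:
                continue
            if not b.protected[s0 : s0 + m].any():
                placed_at = s0
                break
        if placed_at is None:
            raise ValueError(f"infeasible spec: no room for a site near {pct}%")
        b.write(placed_at, variant, protect=True)
        start = placed_at + 1
        b.planted_site_starts.add(start)
        if nicked:
            n_id += 1
            fid = f"sci_{n_id:02d}"
        else:
            e_id += 1
            fid = f"extra_site_{e_id}"
        b.add_truth(
            feature_id=fid,
            kind="nick_site",
            start=start,
            end=start + m - 1,
            strand=TOP,
            variant=variant,
            nicked=nicked,
            nick_bond=start + cut - 1,
        )


def _consensus_family(consensus: NickConsensus) -> set[str]:
    fam = {consensus.core}
    fam |= enumerate_single_substitutions(consensus.core)
    fam |= expand_iupac(consensus.iupac_pattern)
    return fam


def _mask_nick_background(b: _Builder, family: set[str], fam_rc: set[str]) -> int:
    """Destroy non-planted consensus-family matches on either strand."""
    s = b.string()
    m = len(b.spec.consensus.core)
    edits = 0
    for i in range(len(s) - m + 1):
        w = s[i : i + m]
        if w not in family and w not in fam_rc:
            continue
        if i + 1 in b.planted_site_starts:
            continue
        for j, base in itertools.product(range(m), "ACGT"):
            if base == w[j] or not b.editable(i + j):
                continue
            w2 = w[:j] + base + w[j + 1 :]
            if w2 in family or w2 in fam_rc:
                continue
            b.mirror_edit(i + j, base)
            b.lock(i + j)  # monotone progress: no later masker may undo this
            edits += 1
            s = b.string()
            break
        else:  # pragma: no cover - layout always leaves an editable base
            raise RuntimeError(f"cannot mask consensus match at {i + 1}")
    return edits


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _degrade_hexamer(b: _Builder, log_odds: np.ndarray, lo0: int, strand: str, target_drop: float) -> tuple[float, int]:
    """Greedily rewrite editable hexamer bases toward the matrix-worst base.

    Stops once the cumulative score drop reaches ``target_drop`` or no
    edit can lower the score further; edited positions are then locked
    so a later pass cannot flip them back.  Returns (achieved drop,
    edits).
    """
    dropped, edits = 0.0, 0
    touched: list[int] = []
    while dropped < target_drop:
        best = None  # (delta, pos, base_to_write)
        for j in range(log_odds.shape[1]):
            pos = lo0 + j if strand == TOP else lo0 + log_odds.shape[1] - 1 - j
            if not b.editable(pos):
                continue
            col = log_odds[:, j]
            cur = b.seq[pos] if strand == TOP else _COMP[b.seq[pos]]
            cur_score = col["ACGT".index(cur)]
            bi = int(np.argmin(col))
            cand = "ACGT"[bi]
            if cand == cur:
                continue
            delta = float(col[bi] - cur_score)
            if best is None or delta < best[0]:
                best = (delta, pos, cand if strand == TOP else _COMP[cand])
        if best is None or best[0] >= 0:
            break
        b.mirror_edit(best[1], best[2])
        touched.append(best[1])
        dropped += -best[0]
        edits += 1
    for pos in touched:
        b.lock(pos)
    return dropped, edits


def _mask_promoter_background(b: _Builder, model: PromoterModel, margin: float = 2.0) -> int:
    """Break non-planted promoter placements reaching the default cutoff.

    Each offending placement is degraded (first its -10 box, then its
    -35 box) until its score sits ``margin`` below the cutoff, so that
    subsequent point edits elsewhere cannot resurrect it.
    """
    from .promoter_scan import build_matrix_from_counts, genome_background

    genome = GenomeRecord(id="tmp", sequence=b.string())
    hits = scan_promoters(genome, model, background="genome")
    q = genome_background(genome)
    lo10 = build_matrix_from_counts(model.box10, q).log_odds
    lo35 = build_matrix_from_counts(model.box35, q).log_odds
    planted = {
        (r["strand"], r["box10_start"]) for r in b.truth_rows if r["kind"] == "promoter"
    }
    edits = 0
    for h in hits:
        if (h.strand, int(h.box10_start)) in planted:
            continue
        need = h.score - (model.default_cutoff - margin)
        got, e = _degrade_hexamer(b, lo10, h.box10_start - 1, h.strand, need)
        edits += e
        if got < need:
            _, e = _degrade_hexamer(b, lo35, h.box35_start - 1, h.strand, need - got)
            edits += e
    return edits


def _tune_gc(b: _Builder, family: set[str], fam_rc: set[str]) -> int:
    """Nudge realised G+C to the requested fraction by point edits."""
    spec = b.spec
    s = b.string()
    gc_now = (s.count("G") + s.count("C")) / len(s)
    delta = spec.gc - gc_now
    n_edits = int(round(abs(delta) * len(s)))
    if n_edits == 0:
        return 0
    src = "AT" if delta > 0 else "GC"
    dst = "GC" if delta > 0 else "AT"
    candidates = [i for i in range(len(s)) if s[i] in src and b.editable(i)]
    order = b.rng.permutation(len(candidates))
    made = 0
    for k in order:
        if made >= n_edits:
            break
        i = candidates[int(k)]
        new = dst[int(b.rng.integers(2))]
        w_lo = max(0, i - 8)
        before = b.seq[i]
        b.mirror_edit(i, new)
        window = "".join(b.seq[w_lo : i + 9])
        bad = any(
            window[p : p + 9] in family or window[p : p + 9] in fam_rc
            for p in range(len(window) - 8)
        )
        if bad:
            b.mirror_edit(i, before)
            continue
        made += 1
    return made


def generate_genome(spec: SyntheticSpec | None = None) -> tuple[GenomeRecord, TruthTable]:
    """Generate a genome and its truth table under a SyntheticSpec."""
    spec = spec or SyntheticSpec()
    spec.validate()
    b = _Builder(spec)
    N, L = spec.length, spec.dtr_len

    # --- DTR prefix: terminal sequences + terminase core, then mirror ---
    b.write(0, spec.terminal_left, protect=True)
    core_off = L // 2
    b.write(core_off, spec.terminase_core, protect=True)
    # right terminal sequence planted in top-strand orientation, so the
    # blunt-circularisation junction reads terminal_right + terminal_left
    b.write(L - len(spec.terminal_right), spec.terminal_right, protect=True)

    plan = _plan_layout(spec)
    _plant_genes(b, plan)
    if spec.terminator:
        _plant_terminator(b, plan)
    _plant_promoters(b, plan)
    _plant_nick_sites(b)

    # --- copy the DTR to the right end and protect both copies' motifs ---
    for i in range(L):
        b.seq[N - L + i] = b.seq[i]
    b.protected[N - L : N] |= b.protected[:L]

    # --- masking / tuning fix point ---
    family = _consensus_family(spec.consensus)
    fam_rc = {revcomp(w) for w in family}
    model = model_from_pairs(TOY_TRAINING)
    for _ in range(25):
        edits = _mask_nick_background(b, family, fam_rc)
        edits += _mask_promoter_background(b, model)
        edits += _tune_gc(b, family, fam_rc)
        if edits == 0:
            break
    else:  # pragma: no cover
        raise RuntimeError("masking did not converge")

    b.add_truth(feature_id="dtr_left", kind="repeat_region", start=1, end=L, strand=TOP)
    b.add_truth(
        feature_id="dtr_right", kind="repeat_region", start=N - L + 1, end=N, strand=TOP
    )

    truth = TruthTable(pd.DataFrame(b.truth_rows, columns=_TRUTH_COLUMNS))
    features = []
    for r in b.truth_rows:
        attributes = {"ID": r["feature_id"]}
        for k in ("variant", "nicked", "nick_bond", "spacer", "start_codon", "stop_codon"):
            if r[k] != "":
                attributes[k] = str(r[k])
        features.append(Feature(r["kind"], r["start"], r["end"], r["strand"], attributes))
    genome = GenomeRecord(id=f"synthetic_phage_seed{spec.seed}", sequence=b.string(), features=features)
    return genome, truth


def left_overhang_sequence(genome: GenomeRecord, spec: SyntheticSpec) -> str:
    """The 4 concatemer bases preceding a unit start (= before the right DTR copy).

    In a concatemer the bottom-strand 3' overhang at a unit's left end
    is the complement of these bases; they define the protruding tail
    of the packaged genome.
    """
    N, L = spec.length, spec.dtr_len
    return genome.sequence[N - L - spec.left_overhang : N - L]


def generate_profile(
    truth: TruthTable,
    site_id: str,
    enzyme: str = "taq",
    fraction: float = 0.95,
    n_molecules: int = 10_000,
    seed: int = 0,
    runthrough_offset: int = 150,
) -> ExtensionProfile:
    """Primer-extension profile for one planted nick site.

    The run-through stop (restriction cut or template end) is placed
    ``runthrough_offset`` bp downstream of the nick bond.
    """
    row = truth.row(site_id)
    if row["kind"] != "nick_site":
        raise KeyError(f"{site_id!r} is not a nick site")
    bond = int(row["nick_bond"])
    return simulate_primer_extension(
        template_len=bond + runthrough_offset + 50,
        nick_positions=[(bond, fraction)],
        terminal_pos=bond + runthrough_offset,
        enzyme=enzyme,
        n_molecules=n_molecules,
        seed=seed,
    )


def write_fixture(
    genome: GenomeRecord,
    truth: TruthTable,
    out_dir,
    spec: SyntheticSpec | None = None,
) -> dict[str, Path]:
    """Write FASTA + GFF3 + truth TSV (+ spec YAML) for a generated genome."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fasta",
        "gff3": out / "features.gff3",
        "truth": out / "truth.tsv",
    }
    write_fasta([genome], paths["fasta"])
    write_gff3(genome, paths["gff3"])
    truth.to_tsv(paths["truth"])
    if spec is not None:
        paths["spec"] = out / "spec.yaml"

        def _plain(x):
            if isinstance(x, tuple):
                return [_plain(v) for v in x]
            if isinstance(x, dict):
                return {k: _plain(v) for k, v in x.items()}
            return x

        payload = _plain(asdict(spec))
        with open(paths["spec"], "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
    return paths
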