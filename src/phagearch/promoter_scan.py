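"""Two-box sigma70 promoter model: log-odds matrices and bidirectional scan.

A sigma70 promoter is scored as a -35 hexamer plus a -10 hexamer
separated by a variable spacer (16-19 bp by default); the score is the
sum of the two box log-odds sums, spacer bases unscored.  Matrices are
trained from aligned hexamer pairs; scoring uses

    log_odds[b][i] = log2((count[b][i] + pc*q_b) / (n + pc)) - log2(q_b)

with pseudocount ``pc`` (default 0.5) distributed over bases by the
background ``q``.  The genome scan is bidirectional, reports all
placements above a cutoff, and keeps only the best spacer per locus
(placements sharing a -10 hexamer).  Windows containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import BOTTOM, TOP, GenomeRecord, revcomp

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class MotifMatrix:
    """A per-position base-count matrix with its log-odds scores."""

    counts: np.ndarray  # (4, width) ints, rows ACGT
    log_odds: np.ndarray  # (4, width) floats
    background: np.ndarray  # (4,) frequencies
    n_sequences: int

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def score(self, hexamer: str) -> float:
        if len(hexamer) != self.width:
            raise ValueError(f"expected width {self.width}, got {len(hexamer)}")
        total = 0.0
        for i, b in enumerate(hexamer):
            if b not in _BASE_INDEX:
                raise ValueError(f"cannot score ambiguous base {b!r}")
            total += self.log_odds[_BASE_INDEX[b], i]
        return total

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def counts_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(_BASES), columns=range(1, self.width + 1))


def build_matrix(
    training: Sequence[str],
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
) -> MotifMatrix:
    """Build a log-odds matrix from equal-length A/C/G/T training strings."""
    if not training:
        raise ValueError("training set is empty")
    w = len(training[0])
    if any(len(s) != w for s in training):
        raise ValueError("ragged training set: all sequences must share one length")
    counts = np.zeros((4, w), dtype=np.int64)
    for s in training:
        s = s.upper()
        for i, b in enumerate(s):
            if b not in _BASE_INDEX:
                raise ValueError(f"training sequences must be ACGT only, got {b!r}")
            counts[_BASE_INDEX[b], i] += 1
    q = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if q.shape != (4,) or not np.isclose(q.sum(), 1.0) or (q <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")
    n = len(training)
    log_odds = np.log2((counts + pseudocount * q[:, None]) / (n + pseudocount)) - np.log2(q)[:, None]
    return MotifMatrix(counts=counts, log_odds=log_odds, background=q, n_sequences=n)


@dataclass
class PromoterModel:
    """Paired -35/-10 matrices with a spacer range and a default cutoff."""

    box35: MotifMatrix
    box10: MotifMatrix
    spacer_min: int = 16
    spacer_max: int = 19
    default_cutoff: float = 5.31

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")

    @property
    def min_window(self) -> int:
        return self.box35.width + self.spacer_min + self.box10.width


@dataclass
class PromoterHit:
    """A scored two-box placement; box starts are leftmost top-strand coords.

    On the top strand box10_start = box35_start + 6 + spacer; on the
    bottom strand the boxes mirror (the -35 box lies to the right).
    """

    strand: str
    box35_start: int
    spacer: int
    box10_start: int
    score: float

    @property
    def span(self) -> tuple[int, int]:
        lo = min(self.box35_start, self.box10_start)
        hi = max(self.box35_start + 5, self.box10_start + 5)
        return lo, hi


#: A small built-in training set of -35/-10 hexamer pairs patterned on
#: canonical E. coli sigma70 promoters (consensus TTGACA / TATAAT with
#: natural-looking variation).  Shipped for tests and synthetic work; it
#: is a toy stand-in, not a curated promoter database.
TOY_TRAINING: tuple[tuple[str, str], ...] = (
    ("TTGACA", "TATAAT"),
    ("TTGACA", "TATAAT"),
    ("TTGACT", "TATAAT"),
    ("TTTACA", "TATGAT"),
    ("TTGATA", "TAAAAT"),
    ("TTGACA", "TACAAT"),
    ("TGGACA", "TATAAT"),
    ("TTGCCA", "TATACT"),
    ("CTGACA", "GATAAT"),
    ("TTGACG", "TATTAT"),
    ("TTCACA", "TATAGT"),
    ("TTGACC", "CATAAT"),
)


def read_training_pairs(path) -> list[tuple[str, str]]:
    """Read 'HEXAMER35<tab>HEXAMER10' lines; '#' comments and blanks skipped."""
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated hexamers")
            pairs.append((parts[0].upper(), parts[1].upper()))
    return pairs


def model_from_pairs(
    pairs: Sequence[tuple[str, str]],
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
    spacer_min: int = 16,
    spacer_max: int = 19,
    cutoff: float = 5.31,
) -> PromoterModel:
    b35 = build_matrix([p[0] for p in pairs], pseudocount, background)
    b10 = build_matrix([p[1] for p in pairs], pseudocount, background)
    return PromoterModel(b35, b10, spacer_min, spacer_max, cutoff)


def genome_background(g: GenomeRecord) -> np.ndarray:
    """Base frequencies of the genome itself (N excluded), strand-symmetrised.

    The scan is bidirectional, so the background is averaged with its
    complement, which also makes scores strand-mirror exactly.
    """
    seq = g.sequence
    counts = np.array([seq.count(b) for b in _BASES], dtype=float)
    if counts.sum() == 0:
        raise ValueError("genome contains no unambiguous bases")
    counts = counts + counts[::-1]  # A<->T, C<->G symmetrisation
    return counts / counts.sum()


def score_two_box(window: str, model: PromoterModel, spacer: int) -> float:
    """Score one two-box window (box35 + spacer + box10); N raises an error."""
    expected = model.box35.width + spacer + model.box10.width
    if len(window) != expected:
        raise ValueError(f"window length {len(window)} != {expected} for spacer {spacer}")
    window = window.upper()
    return model.box35.score(window[: model.box35.width]) + model.box10.score(
        window[-model.box10.width :]
    )


def _box_scores(seq_idx: np.ndarray, matrix: MotifMatrix) -> np.ndarray:
    """Vectorised per-start box scores; NaN where the window contains N."""
    w = matrix.width
    n = seq_idx.size
    if n < w:
        return np.empty(0)
    nwin = n - w + 1
    scores = np.zeros(nwin)
    invalid = np.zeros(nwin, dtype=bool)
    lo = np.vstack([matrix.log_odds, np.zeros(matrix.width)])  # row 4 = N placeholder
    for i in range(w):
        col = seq_idx[i : i + nwin]
        scores += lo[col, i]
        invalid |= col == 4
    scores[invalid] = np.nan
    return scores


def _seq_to_idx(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def scan_promoters(
    g: GenomeRecord,
    model: PromoterModel,
    cutoff: float | None = None,
    background: str = "genome",
) -> list[PromoterHit]:
    """Bidirectional two-box scan of a genome.

    All spacers in the model's range are tried at every position on
    both strands; placements scoring >= cutoff are kept, then reduced
    to the best-scoring spacer per locus (ties -> shortest spacer).
    With ``background="genome"`` the matrices are rebuilt against the
    genome's own (strand-symmetrised) base composition before scoring;
    ``background="matrix"`` keeps the model's stored log-odds.
    """
    if g.length < model.min_window:
        raise ValueError("genome shorter than the minimal promoter window")
    if cutoff is None:
        cutoff = model.default_cutoff
    if background == "genome":
        q = genome_background(g)
        b35 = build_matrix_from_counts(model.box35, q)
        b10 = build_matrix_from_counts(model.box10, q)
        model = PromoterModel(b35, b10, model.spacer_min, model.spacer_max, model.default_cutoff)
    elif background != "matrix":
        raise ValueError("background must be 'genome' or 'matrix'")

    w35, w10 = model.box35.width, model.box10.width
    L = g.length
    hits: list[PromoterHit] = []
    for strand, seq in ((TOP, g.sequence), (BOTTOM, revcomp(g.sequence))):
        idx = _seq_to_idx(seq)
        s35 = _box_scores(idx, model.box35)
        s10 = _box_scores(idx, model.box10)
        for spacer in range(model.spacer_min, model.spacer_max + 1):
            offset = w35 + spacer
            n = min(s35.size, s10.size - offset)
            if n <= 0:
                continue
            total = s35[:n] + s10[offset : offset + n]
            with np.errstate(invalid="ignore"):
                keep = np.nonzero(total >= cutoff)[0]
            for p in keep:
                p = int(p)
                if strand == TOP:
                    b35_start = p + 1
                    b10_start = p + offset + 1
                else:
                    # position p on the reverse complement; map each box's
                    # leftmost top-strand coordinate
                    b35_start = L - (p + w35) + 1
                    b10_start = L - (p + offset + w10) + 1
                hits.append(PromoterHit(strand, b35_start, spacer, b10_start, float(total[p])))
    # Per-locus dedup: placements whose -10 elements overlap on a strand
    # are one physical promoter; only the best-scoring placement (ties:
    # shortest spacer, then leftmost) survives.
    hits.sort(key=lambda h: (-h.score, h.spacer, h.strand, h.box10_start))
    accepted: list[PromoterHit] = []
    for h in hits:
        lo, hi = h.box10_start, h.box10_start + w10 - 1
        if any(
            a.strand == h.strand and lo <= a.box10_start + w10 - 1 and a.box10_start <= hi
            for a in accepted
        ):
            continue
        accepted.append(h)
    return sorted(accepted, key=lambda h: (h.span[0], h.strand, h.box10_start))


def build_matrix_from_counts(matrix: MotifMatrix, background: np.ndarray, pseudocount: float = 0.5) -> MotifMatrix:
    """Re-derive log-odds from an existing count matrix under a new background."""
    q = np.asarray(background, dtype=float)
    n = matrix.n_sequences
    log_odds = (
        np.log2((matrix.counts + pseudocount * q[:, None]) / (n + pseudocount)) - np.log2(q)[:, None]
    )
    return MotifMatrix(counts=matrix.counts.copy(), log_odds=log_odds, background=q, n_sequences=n)


def hits_to_features(hits: Iterable[PromoterHit]):
    from .genome_io import Feature

    out = []
    for h in hits:
        lo, hi = h.span
        out.append(
            Feature(
                "promoter",
                lo,
                hi,
                h.strand,
                {
                    "score": f"{h.score:.2f}",
                    "spacer": str(h.spacer),
                    "box35_start": str(h.box35_start),
                    "box10_start": str(h.box10_start),
                },
            )
        )
    return out
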