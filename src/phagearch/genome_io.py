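"""Genome and annotation I/O with fixed coordinate conventions.

All coordinates in this package are 1-based and inclusive on the *top*
strand, where "top" is the orientation of the sequence as deposited /
read from FASTA.  A feature on the bottom strand keeps its top-strand
span (``start <= end`` always) and records orientation in ``strand``.
FASTA and GenBank parsing is delegated to Biopython, GFF3 parsing to
gffutils; this module only normalises their conventions.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import quote, unquote

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

TOP = "top"
BOTTOM = "bottom"
STRANDS = (TOP, BOTTOM)

#: Feature kinds understood throughout the package.  Anything else read
#: from an annotation file is mapped to "misc" with the original type
#: preserved in ``attributes["original_type"]``.
FEATURE_KINDS = ("CDS", "promoter", "terminator", "nick_site", "repeat_region", "misc")

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file did not conform to the expected format."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """An annotated interval, 1-based inclusive, span on the top strand."""

    kind: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature coordinates must satisfy 1 <= start <= end, got ({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A linear top-strand DNA sequence with its feature annotations."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.topology != "linear":
            raise ValueError("only linear topologies are supported")
        for f in self.features:
            if f.end > self.length:
                raise ValueError(
                    f"feature ({f.start}, {f.end}) exceeds genome length {self.length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Top-strand sequence of the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"interval ({start}, {end}) outside [1, {self.length}]")
        return self.sequence[start - 1 : end]

    def feature_seq(self, f: Feature) -> str:
        """Strand-aware sequence of a feature (reverse complemented for bottom)."""
        s = self.subseq(f.start, f.end)
        return s if f.strand == TOP else revcomp(s)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _validate_fasta_lines(path: Path) -> None:
    seen_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                seen_header = True
                continue
            if not seen_header:
                raise FormatError(f"{path}:{lineno}: sequence data before any FASTA header")
            bad = set(line.upper()) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"{path}:{lineno}: non-nucleotide characters {sorted(bad)}"
                )
    if not seen_header:
        raise FormatError(f"{path}: no FASTA records found")


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords, uppercased, N allowed.

    Raises :class:`FormatError` naming the offending line for malformed
    headers or non-nucleotide characters; empty records are rejected.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Sequence[GenomeRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in records:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations (GenBank / GFF3)
# ---------------------------------------------------------------------------

_GFF_TYPE_MAP = {
    "CDS": "CDS",
    "promoter": "promoter",
    "terminator": "terminator",
    "nick_site": "nick_site",
    "repeat_region": "repeat_region",
}


def _normalise_kind(ftype: str, attributes: dict[str, str]) -> str:
    if ftype in _GFF_TYPE_MAP:
        return _GFF_TYPE_MAP[ftype]
    attributes["original_type"] = ftype
    return "misc"


def read_annotation(
    path: str | os.PathLike,
    dialect: str,
    genome_length: int | None = None,
) -> list[Feature]:
    """Read features from a GenBank flat file or a GFF3 file.

    Coordinates are normalised to 1-based inclusive; GenBank
    ``complement(..)`` and GFF3 ``-`` map to ``strand="bottom"``.  If
    ``genome_length`` is given, features exceeding it raise an error.
    """
    path = Path(path)
    if dialect == "genbank":
        features = _read_genbank(path)
    elif dialect == "gff3":
        features = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if genome_length is not None:
        for f in features:
            if f.end > genome_length:
                raise FormatError(
                    f"{path}: feature ({f.start}, {f.end}) exceeds genome length {genome_length}"
                )
    return features


def _read_genbank(path: Path) -> list[Feature]:
    features: list[Feature] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for bf in rec.features:
            if bf.type == "source":
                continue
            attributes = {
                k: ";".join(str(x) for x in v) for k, v in bf.qualifiers.items()
            }
            kind = _normalise_kind(bf.type, attributes)
            # Biopython locations are 0-based half-open.
            start = int(bf.location.start) + 1
            end = int(bf.location.end)
            strand = BOTTOM if bf.location.strand == -1 else TOP
            features.append(Feature(kind, start, end, strand, attributes))
    return features


def _read_gff3(path: Path) -> list[Feature]:
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            try:
                gf = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # pragma: no cover - gffutils message varies
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            attributes = {k: ",".join(unquote(x) for x in v) for k, v in gf.attributes.items()}
            if gf.score not in (".", "", None):
                attributes.setdefault("score", str(gf.score))
            kind = _normalise_kind(gf.featuretype, attributes)
            strand = BOTTOM if gf.strand == "-" else TOP
            features.append(Feature(kind, gf.start, gf.end, strand, attributes))
    return features


def write_gff3(
    genome: GenomeRecord,
    path: str | os.PathLike,
    source: str = "phagearch",
    features: Sequence[Feature] | None = None,
) -> None:
    """Write features as GFF3 (with version pragma and sequence-region line)."""
    feats = genome.features if features is None else list(features)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for f in feats:
            attributes = dict(f.attributes)
            ftype = attributes.pop("original_type", f.kind if f.kind != "misc" else "region")
            if f.kind != "misc":
                ftype = f.kind
            score = attributes.pop("score", ".")
            attr_str = ";".join(
                f"{quote(str(k), safe='')}={quote(str(v), safe=' ,/|')}"
                for k, v in attributes.items()
            ) or "."
            strand = "+" if f.strand == TOP else "-"
            fh.write(
                "\t".join(
                    [genome.id, source, ftype, str(f.start), str(f.end), str(score), strand, ".", attr_str]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Strand algebra
# ---------------------------------------------------------------------------


def reverse_complement_record(g: GenomeRecord) -> GenomeRecord:
    """Reverse complement a genome; features are remapped and strand-flipped.

    For a genome of length L, a feature (start, end, strand) maps to
    (L - end + 1, L - start + 1, other strand).  The operation is an
    involution on both sequence and features.
    """
    L = g.length
    new_features = [
        replace(
            f,
            start=L - f.end + 1,
            end=L - f.start + 1,
            strand=BOTTOM if f.strand == TOP else TOP,
            attributes=dict(f.attributes),
        )
        for f in g.features
    ]
    return GenomeRecord(id=g.id, sequence=revcomp(g.sequence), features=new_features)
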