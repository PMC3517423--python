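"""Primer-extension simulation and nick-frequency estimation.

A primer-extension reaction on a population of templates produces a
stop-signal profile: each molecule's extension product terminates at
the first nick it carries, or at the template end (run-through).  Band
intensities are modelled as molecule counts.  Taq polymerase adds one
non-templated nucleotide at the 3' end, shifting every recorded stop
by +1; Klenow does not.  Nick fractions are estimated from the ratio
of nick-stop to run-through counts with a Wilson 95% binomial interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

ENZYMES = ("taq", "klenow")
_ENZYME_SHIFT = {"taq": 1, "klenow": 0}


@dataclass
class ExtensionProfile:
    """Per-position counts of molecules terminating there.

    Positions are template coordinates of the *recorded* stop (i.e.
    including any enzyme-specific +1); counts sum to n_molecules.
    """

    positions: np.ndarray
    terminated_counts: np.ndarray
    n_molecules: int
    enzyme: str

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.terminated_counts = np.asarray(self.terminated_counts, dtype=np.int64)
        if self.enzyme not in ENZYMES:
            raise ValueError(f"enzyme must be one of {ENZYMES}")
        if self.positions.shape != self.terminated_counts.shape:
            raise ValueError("positions and counts must align")
        if int(self.terminated_counts.sum()) != self.n_molecules:
            raise ValueError("terminated counts must sum to n_molecules")

    def count_at(self, position: int) -> int:
        idx = np.nonzero(self.positions == position)[0]
        return int(self.terminated_counts[idx[0]]) if idx.size else 0

    @property
    def offset(self) -> int:
        return _ENZYME_SHIFT[self.enzyme]


def simulate_primer_extension(
    template_len: int,
    nick_positions: Sequence[tuple[int, float]],
    terminal_pos: int,
    enzyme: str = "taq",
    n_molecules: int = 10_000,
    seed: int = 0,
) -> ExtensionProfile:
    """Simulate a primer-extension stop profile over a nicked template.

    ``nick_positions`` is an ordered list of (bond position, nicked
    fraction); each molecule carries each nick independently with its
    fraction and the polymerase terminates at the first carried nick,
    else at ``terminal_pos`` (template end or restriction cut).
    Seeded and reproducible.
    """
    if enzyme not in ENZYMES:
        raise ValueError(f"enzyme must be one of {ENZYMES}")
    bonds = [b for b, _ in nick_positions]
    fracs = np.array([f for _, f in nick_positions], dtype=float)
    if list(bonds) != sorted(bonds):
        raise ValueError("nick positions must be ordered")
    if ((fracs < 0) | (fracs > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    if any(not (1 <= b <= template_len) for b in bonds) or not (1 <= terminal_pos <= template_len):
        raise ValueError("positions must lie within the template")
    rng = np.random.default_rng(seed)
    if bonds:
        carried = rng.random((n_molecules, len(bonds))) < fracs
        any_nick = carried.any(axis=1)
        first = np.where(any_nick, carried.argmax(axis=1), -1)
        stops = np.where(any_nick, np.array(bonds + [0])[first], terminal_pos)
    else:
        stops = np.full(n_molecules, terminal_pos, dtype=np.int64)
    stops = stops + _ENZYME_SHIFT[enzyme]
    positions, counts = np.unique(stops, return_counts=True)
    return ExtensionProfile(positions, counts, n_molecules, enzyme)


def call_stops(profile: ExtensionProfile, min_fraction: float) -> list[tuple[int, float]]:
    """Stop positions with terminated fraction >= min_fraction.

    Positions are corrected back to template bond coordinates (the Taq
    +1 is subtracted), so calls from Taq and Klenow profiles of the
    same template coincide.
    """
    out = []
    for pos, cnt in zip(profile.positions, profile.terminated_counts):
        frac = cnt / profile.n_molecules
        if frac >= min_fraction:
            out.append((int(pos) - profile.offset, float(frac)))
    return out


@dataclass
class NickFrequencyEstimate:
    fraction: float
    ci_low: float
    ci_high: float
    stop_position: int
    n_informative: int


def estimate_nick_fraction(
    profile: ExtensionProfile, nick_bond: int, runthrough_pos: int
) -> NickFrequencyEstimate:
    """Nicked fraction from the nick-stop vs run-through band ratio.

    fraction = count(nick) / (count(nick) + count(runthrough)), with a
    Wilson 95% binomial interval.  Both positions are template bond
    coordinates; the enzyme offset is applied internally.
    """
    k = profile.count_at(nick_bond + profile.offset)
    r = profile.count_at(runthrough_pos + profile.offset)
    total = k + r
    if total == 0:
        raise ValueError("no molecules terminate at either position")
    lo, hi = proportion_confint(k, total, alpha=0.05, method="wilson")
    return NickFrequencyEstimate(
        fraction=k / total,
        ci_low=float(lo),
        ci_high=float(hi),
        stop_position=nick_bond,
        n_informative=total,
    )


def minor_band_fraction(profile: ExtensionProfile, major_pos: int) -> float:
    """Fraction of molecules not terminating at the major band.

    ``major_pos`` is a recorded-profile coordinate (offset already in
    the profile's convention); raises if it is not in the support.
    """
    c = profile.count_at(major_pos)
    if c == 0:
        raise ValueError(f"position {major_pos} not in profile support")
    return 1.0 - c / profile.n_molecules


def write_profile_tsv(profile: ExtensionProfile, path) -> None:
    """Two-column TSV (position, count) with a header line carrying metadata."""
    with open(path, "w") as fh:
        fh.write(f"# enzyme={profile.enzyme}\tn_molecules={profile.n_molecules}\n")
        fh.write("position\tcount\n")
        for p, c in zip(profile.positions, profile.terminated_counts):
            fh.write(f"{p}\t{c}\n")


def read_profile_tsv(path) -> ExtensionProfile:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("missing metadata header line")
        meta = dict(kv.split("=", 1) for kv in header[1:].strip().split("\t"))
        colnames = fh.readline()
        positions, counts = [], []
        for line in fh:
            if not line.strip():
                continue
            p, c = line.split("\t")
            positions.append(int(p))
            counts.append(int(c))
    return ExtensionProfile(
        np.array(positions), np.array(counts), int(meta["n_molecules"]), meta["enzyme"]
    )
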