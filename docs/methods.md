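# Methods

This note records the models, conventions, parameter choices and known
limitations behind `phagearch`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate and strand conventions

All coordinates are 1-based and inclusive.  "Top strand" is the
orientation in which a sequence is read from FASTA; features on the
bottom strand keep their top-strand span (`start <= end` always) with
orientation in a separate field.  Reverse complementing a genome maps
a feature `(s, e)` to `(L−e+1, L−s+1)` and flips its strand; the
operation is an involution and is property-tested as such.  BED export
converts to 0-based half-open at the boundary only.

`N` is allowed in sequences and never matches any motif position — an
unknown base is not evidence for a site.

## Nick-consensus model

A nick site is a 9-mer matching a degenerate IUPAC consensus (default
`TACTRTGMC`, core `TACTGTGAC`).  The nick bond sits after position 4
of the site (`TACT/RTGMC`); the reported bond coordinate is the last
nucleotide 5' of the break on the nicked strand, so for a bottom-
strand site the bond maps to `end − 4 + 1` in top-strand coordinates.
Overlapping matches are all reported: the underlying biology does not
forbid them and completeness makes the scanner oracle-testable.

The half-genome boundary is `floor(L/2)`; a bond exactly on the
boundary counts as "left".  Percent positions are `100·start/L`
rounded half-up to one decimal (exact decimal arithmetic, not binary
floats), matching the one-decimal presentation conventional for
cross-genome site tables.

Single-substitution analysis enumerates all 27 Hamming-1 neighbours of
the core and reports matches grouped by variant.  "Additional loci"
are those whose variant does not itself match the degenerate
consensus — the consensus variants are nick sites, not neighbours.

Cross-genome comparison aligns site positions on the percent scale by
single-linkage within a tolerance (default 2.0 %).  Single linkage can
chain two same-genome sites closer than the tolerance into one row;
such cells carry both values comma-joined.  The default tolerance is
deliberately conservative: conserved sites in related phage genomes
drift by a few percent, and a wider tolerance starts merging distinct
sites.

The scanner itself is a vectorised per-position comparison; its oracle
in the tests is a naive sliding window (and, in one test, Biopython's
IUPAC `nt_search`), never the implementation itself.

## Terminal architecture

DTR detection is exact-match (the repeats this pipeline targets are
exact); the longest border of the sequence not exceeding half the
genome is found via the KMP failure chain in O(L).  A mismatch-
tolerant mode is deliberately out of scope.

The duplex is represented as the top strand plus one `EndStructure`
per end (geometry, overhang length, overhang sequence 5'→3', terminal
sequence in top-strand orientation).  At the left end the 5' terminus
belongs to the top strand; at the right end to the bottom strand.
Consequences used throughout: trimming a 3'-protruding *left* end
(bottom-strand tail) leaves the top strand intact, while a
3'-protruding *right* end would shorten it; filling a 5' overhang
extends the complementary strand only.  Blunting is idempotent.

The default end model is the unusual geometry of the genome this
pipeline was built around: blunt right end, 4-nt 3'-protruding left
end, terminal sequences `CCCCGG` (left) and `ATCTC` (right).  The
right-end terminal sequence is carried in top-strand orientation, so
the blunting-plus-circularisation junction reads
`…ATCTC|CCCCGG…`; the printed strand of archival terminal sequences
is ambiguous in secondary sources, and this package pins the
convention that the tests and the junction assay express.

Concatemers join units head-to-tail sharing one DTR copy (length
`n·N − (n−1)·L`).  Terminase cutting is modelled at the level the
data constrain: each shared DTR must contain the core recognition
site (default `GATATCCC`, the lower-confidence half of the published
`GATATCcc` still required — full 8-mer match, configurable); the cut
is asymmetric, emitting a blunt right end upstream and a 4-nt
3'-overhang left end downstream, and the DTR is duplicated into both
products (the fill-in synthesis that must accompany this in vivo is
abstracted away).  The exact within-site cut geometry is not encoded —
published figures of such models are schematic.  The two outermost
fragments of a concatemer have one uncut side and are flagged
`partial`, not discarded.  `cut_concatemer` takes the unit and DTR
lengths explicitly: boundary positions are not inferable from the
core site alone when it also occurs elsewhere.

Tail-junction mapping (terminal-transferase assay) strips the maximal
terminal homopolymer run (minimum 8 nt), then gives bases back to the
genomic prefix while the prefix still matches the reference — this
resolves the ambiguity when the template's own 3' terminus equals the
tail base.

## Promoter model

Two hexamer boxes with a 16–19 bp spacer; the score is the sum of the
two box log-odds sums, spacer unscored.  The matrix rule is

    log_odds[b][i] = log2((count[b][i] + pc·q_b)/(n + pc)) − log2(q_b)

with pc = 0.5 distributed over bases by the background q.  Log base 2
and the pseudocount are package choices: published two-box searches of
this kind rarely state either, so the conventional cutoff 5.31 is
carried as a configurable default rather than a calibrated constant.
The background defaults to the scanned genome's own base composition,
symmetrised A↔T / C↔G so that bidirectional scanning is exactly
strand-mirror; a uniform-background mode (`background="matrix"`) is
available for controlled tests.

A *locus* is an overlapping set of −10 placements on one strand: two
placements whose −10 hexamers overlap describe the same physical
promoter (shifted register or alternative −35 pairing), so only the
best-scoring placement survives, ties resolved to the shorter spacer.
Hit lists are monotone in the cutoff.  Windows containing N are
skipped, not scored.

The shipped training set is a 12-pair toy patterned on canonical
*E. coli* sigma70 promoters (`TTGACA`/`TATAAT` with variation).  It is
a synthetic stand-in for a curated promoter collection, sufficient for
planted-signal recovery; absolute scores from it are not comparable to
scores from a real training database, which is why reproducing the
published promoter coordinates of a real genome is explicitly not a
goal.

## Annotation statistics

Codon tallies read the first and last codon of each CDS strand-aware;
length violations (< 6 bp or not a multiple of 3) are collected, not
fatal.  Overlap is coordinate overlap irrespective of strand — for
convergent gene pairs that is the only well-defined notion — with the
maximal pair made deterministic by lowest-coordinate tie-breaking.
Unit partition picks the split of the start-ordered gene list that
maximises strand homogeneity (left block one strand, right block the
other); violators are flagged, and an all-one-strand input returns a
single unit with a warning flag rather than an error.

Terminator calling enumerates inverted repeats (stem 5–15 nt, ≤ 1
mismatch, loop 3–10 nt) and requires a T-run of ≥ 3 nt within 8 nt
downstream on at least one strand — it is a rho-independent-terminator
caller, not a generic hairpin finder.  "Bidirectional" means both
strands carry the downstream T-run.  These heuristics are standard
field conventions, not measured constants, and all are configurable.
Dominated calls (same centre, shorter stem, no fewer mismatches) are
suppressed; remaining calls sort by stem length.

The ORF finder (longest ORF per stop, six frames, starts ATG/GTG/TTG)
is a synthetic-data utility: it exists so generated genomes have a
self-consistent gene model, and it makes no claim to reproduce an
HMM-based gene caller on real sequence.

## Primer-extension model

Band intensity is modelled as molecule counts.  Each molecule carries
each nick independently with its planted fraction; extension
terminates at the first carried nick (read-through past a nick is not
modelled — the data motivating this show essentially total
termination), else at the template end or restriction cut.  Taq adds
one non-templated nucleotide, recorded as a +1 shift that stop calling
and fraction estimation subtract; Klenow does not, and after
correction the two enzymes' calls coincide (tested).  The nicked
fraction is `k/(k+r)` over the nick-stop and run-through bands with a
Wilson 95 % interval (chosen over Wald for small counts).  Terminal
heterogeneity is one minus the major-band fraction.  Densitometry
calibration and chromatogram parsing are out of scope.

## Synthetic genome generator

The generator's defaults are the study conditions: 46,267 bp, G+C
0.532, 186 bp DTR, the 14-site nick layout with 11 sites in the left
half (where the source table of positions is partly garbled, the two
`TACTGTGCC` positions are placed at 24.5 % and 27.1 %, consistent with
the legible cells and the left-half count), 3 non-nicked
single-substitution loci, 49 + 23 genes with start quota 61/7/4 and
stop quota 38/32/2, a 137 bp overlap between genes 45 and 46, 7
top-strand promoters in the left half and 3 bottom-strand promoters in
the right half, and one bidirectional terminator in the inter-unit
gap.  Percent positions convert to bp by rounding half-up; a planted
site shifts by up to ±60 bp if its nominal position would collide with
a protected element (truth records the realised coordinate).

Construction order: background drawn i.i.d. at the requested G+C; DTR
prefix with terminal sequences and terminase core; genes (bodies
sampled from the non-stop codon distribution at the background base
frequencies; the overlapping pair is built so both reading frames are
stop-free through the shared 137 bp and the upstream gene's stop is
spelled inside the downstream gene's body); terminator (separator
bases around the hairpin are chosen non-complementary so the planted
stem is exactly maximal); promoters snapped to the nearest intergenic
gap; nick sites; then the prefix is copied to the suffix to create the
DTR.

Masking then enforces exact ground truth: any occurrence of the
consensus family (core, all 27 distance-1 neighbours, and the IUPAC
expansion) on either strand outside the planted loci is destroyed by a
minimal substitution, and any two-box placement reaching the scan
cutoff away from a planted promoter is degraded — greedily rewriting
editable box bases toward the matrix-worst base — until it sits a
2-point margin below the cutoff.  Edited positions are locked so later
passes cannot flip them back (this makes the fix-point loop monotone);
edits inside a DTR copy are mirrored into the other copy so the repeat
stays exact.  A G+C tuning pass counteracts the slight GC inflation of
stop-free codon sampling, restricted to edits that do not create
consensus-family matches.  The loop runs to a full zero-edit pass.
Everything is driven by one seeded generator, so a seed determines the
genome byte-for-byte.

"Planted features non-overlapping" holds at the level of signal
elements (nick 9-mers, promoter boxes, terminator, DTR motifs,
terminal start/stop codons); nick 9-mers may fall inside gene
*bodies*, exactly as in the real genome, where most nick sites lie
within coding sequence.

### What the generator does and does not emulate

It emulates the statistical structure the analyses assume: base
composition, exact repeats, planted motifs with controlled
neighbourhoods, codon-quota gene models, and binomially sampled
primer-extension stops.  It does not emulate realistic codon usage,
mutation or phylogenetic processes, sequencing error, or minor nick
populations below the planted fractions.  Passing the synthetic
recovery tests therefore shows the *operations* are correct and
self-consistent under known truth; it does not show that a particular
real genome satisfies the model's assumptions — that is what the four
deposited-genome checks are for, and they require fetching the
accession (see README).

## Problem sizes and numerical choices

The default test run generates one 46 kb genome (about a second) and
reuses it session-wide; oracle-equivalence checks use 200 random
genomes up to 5 kb; fraction-recovery simulations use 10,000 molecules
(binomial sd ≈ 0.002 at 0.95, tested tolerance ±0.02) and 5,000 for
minor-band recovery (sd ≈ 0.003, tolerance ±0.012 ≈ 4 sd).  Percent
rounding uses exact decimals; promoter scores are float64 with ties
broken by spacer then coordinate; all random draws flow from
`numpy.random.default_rng(seed)`.

## Known limitations

- The promoter cutoff's scale is tied to the training matrices; 5.31
  is meaningful only relative to a matrix of comparable information
  content.
- Terminase cut geometry within the core site is not modelled beyond
  the product end structures.
- The GFF3 writer emits a flat feature list (no parent/child
  hierarchy); GenBank reading flattens compound locations to their
  envelope span, and join/partial dialect subtleties are surfaced as
  codon-tally violations rather than corrected.
- `find_dtr` reports only the longest exact repeat; near-exact repeats
  are invisible to it.
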