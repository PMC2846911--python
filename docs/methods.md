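# Methods notes

This note documents the models, defaults, and design choices behind
`u12scan`, and what the synthetic-data tests do and do not demonstrate.

## Matrix conventions

All splice-site matrices follow the SpliceRack layout: 5' splice-site
matrices span 13 positions (3 exonic + 10 intronic), 3' splice-site
matrices span 17 positions (14 intronic + 3 exonic), branch matrices span
12 intronic positions.  The flat file format is self-describing
(`#site_type`, `#intron_class`, `#species`, `#exon_offset` headers, then
one whitespace-separated `A C G T` count row per position) because the
original matrix web services are not a stable dependency.

Counts → probabilities (`to_pwm`) uses a probability floor, default `1e-4`:
positions are normalised, entries below the floor are raised to it, and the
remaining entries are rescaled so each row sums to exactly 1 with no entry
below the floor.  Without the floor, a single zero count would veto any
sequence carrying one off-consensus base in a product-of-probabilities
score.  Counts → log-odds (`to_log_odds`) uses pseudocount 0.001 and a
uniform 0.25 background by default; the background is overridable per run
and recorded on the matrix.  Ambiguous bases in scored sequences contribute
the background probability in product scores and weight 0 in log-odds
sums — unknowns are neither rewarded nor penalised.

## Branch-window scan

Branch windows are scanned in the interval (−40, −5) relative to the
intron's 3' end, both bounds inclusive, and a window must lie entirely
inside it: start offsets run from −40 to −(window length + 4), giving 25
windows for a 12-position matrix and 24 for a 13-position one.  Windows may
never overlap intron positions +1..+10 (the donor region), which truncates
the scan for short introns; an intron too short for any admissible window
is an error, not a silent zero.  Ties take the leftmost (5'-most) window so
output is deterministic.  The probability-ratio and log-odds schemes keep
their own window widths: the scan width always equals the matrix length,
so a 12-position branch matrix scans 12-nt windows and a 13-position matrix
scans 13-nt ones.  The 12-position matrices record the window only; the
position of the branch-point adenosine inside the window is not modelled.

The empirical U2 branch matrix (`build_u2_branch_matrix`) tallies, for each
U2 intron, the single best-scoring window under a U12 branch PWM; each
intron contributes exactly 1 to every column sum, and the routine is tested
against a brute-force scan-everything oracle.

## Intron inference

Coordinates are 0-based half-open throughout.  Reverse-strand ESTs are
reverse-complemented before inference, so introns are always reported on
the coding strand; minus-strand rows of imported tabular alignments are
flipped into the reverse-complemented EST's frame.  The built-in matcher
seeds on exact shared k-mers (k = 14), splits seeds on a common diagonal
into clusters no more than 50 nt apart — a chance k-mer repeat elsewhere on
the same diagonal must not be welded to a genuine exon match — and extends
each cluster gap-free with an x-drop rule (match +1, mismatch −3, drop 12).
It handles substitutions but not indels, which is exactly the synthetic
error model; real data with indel-rich alignments should come in through
the tabular importer.

Defaults: identity ≥ 98%, HSP length ≥ 35 nt (both inclusive), intron
length in [30, 20000] nt.  Junction ambiguity between overlapping HSPs is
enumerated exhaustively (b + 1 candidates for b overlapping bases).
Candidate junctions are scored with the 5' and 3' PWMs of *every* intron
class, a window taking the best class's score; a placement that maximises
both the 5' and 3' scores wins, otherwise the greatest sum, with remaining
ties going to the leftmost genomic start.  Scoring with the U2 matrices
alone systematically mis-places AT–AC and U12-type junctions, which is why
the per-window class maximum is used.  Multiple scoring species are
supported (scores are averaged across species sets — a symmetric,
deterministic combination rule; the alternative of applying species
sequentially was rejected as order-dependent); the packaged offline
default is a single consensus-derived set.

## Classification

Probability-ratio scheme: `s5` and `sb` are log2 ratios of U12 to U2
window probabilities, with the U12 numerator matrix chosen by the intron's
termini (AT–AC introns use the AT–AC matrices, everything else GT–AG;
GC–AG introns are scored with the GT–AG matrices, the 2nd-position
mismatch being absorbed by the probability floor).  z-normalisation
subtracts the scored sample's mean and divides by its (population) standard
deviation; a zero standard deviation is an error.  The U12 call is the
inclusive rectangle rule: both z-scores at least the minima of a reference
U12 set scored with the same matrices and placed in the query sample's
z-space.  The historical reference set of minor introns is not publicly
available, so the default reference is reproducible instead: 20 introns
sampled from the U12 generator PWMs with a fixed seed (101); any curated
reference FASTA can be supplied in its place.  The reference rectangle's
absolute coordinates therefore are this package's own calibration, not a
reproduction of the original one.

Log-odds scheme: 5' windows are scored under each class's log-odds matrix
and the best 12-nt branch window under the U12 branch matrix matching the
termini.  The published discriminant thresholds for this scheme were never
printed, so the default decision rule is a documented stand-in: the U12
5' score must beat the competing U2-class score and both the U12 5' and
branch scores must be ≥ 0 (configurable minima).  Introns with
non-canonical termini are reported OTHER and left unscored.

5'-terminal rule: intron positions +1..+8 must read `R T A T C C T T` with
exactly one of the Cs at +5/+6 allowed to be T ({CC, CT, TC}).

## Synthetic data

The generator emulates the data regime of an EST-to-genome intron survey:
one contig per gene (100 nt random flanks), 4–6 exons of 80–300 nt,
introns sampled per class from consensus-derived PWMs with the class's
termini forced, a branch window planted at a recorded offset in
[−40, −26] (kept clear of the acceptor region so the 3' signal stays
intact), and 1–2 ESTs per gene — spliced transcripts truncated by 0–20 nt
per end with substitution errors at 1% per base by default (capped at 2%
so the identity filter stays meaningful; indels optional-off).  Intron
lengths are log-normal with modal length 62 nt (shape 0.45), resampled —
not clamped — below the 50 nt minimum so no atom forms at the boundary;
the realised mode of a finite sample fluctuates around the planted mode
within the 51–95 nt band typical of compact genomes.  Background sequence
is i.i.d. uniform ACGT, the simplest null against which PWM signals are
detectable.

Consensus masses: 0.85 for U12 sites, 0.55 for U2 sites, mirroring the
stronger conservation of minor-spliceosome signals.  A consensus position
puts the mass on its base — degenerate IUPAC codes split the mass equally
among their bases — and spreads the remainder uniformly over the other
bases; N positions are uniform.  The default class mix (82% U2 GT–AG, 4%
U2 GC–AG, 7% U12 GT–AG, 5% U12 AT–AC, 2% non-canonical) deliberately
enriches the U12 classes relative to real genomes, where minor introns are
closer to 0.1%, so that class-recovery statistics are measurable at
simulation scale (~500 introns per default run).

What passing the synthetic tests shows: the machinery recovers exactly what
was planted under its own generative assumptions — substitution-only
errors, uniform background, independent positions, one gene per contig.
What it does not show: robustness to indels, paralogy, repetitive DNA,
composition bias, alternative splicing, or matrices estimated from real
site collections; on real data the discriminative power is bounded by the
quality of the supplied matrices.  Note also that at consensus mass 0.85
only a minority of sampled U12 sites pass the strict 8-position 5' rule —
real U12 introns are sharper at those positions than the generator's
uniform-mass model.

## Fate classification

Intron positions are (codon index, phase) pairs projected through a
protein alignment; positions falling in alignment gaps are UNKNOWN.  Phase
must match for a same-site call; a shifted U12→U2 conversion (any phase)
is reported with its distance up to `shift_max` = 5 codons — a small
window chosen so a shift is not conflated with an independent loss + gain.
Homolog search is out of scope; the module consumes gene-structure TSVs
plus an aligned FASTA, with a naive global protein aligner included as
convenience plumbing for synthetic tests and a minimal GFF3 CDS reader as
an optional import path.

## Problem sizes

Default test and acceptance runs use ~125 genes / ~500 introns for
pipeline-level statistics and 100+ random instances for oracle-equivalence
checks; boundary-recovery statistics are quoted over canonical-junction
introns (the non-canonical 2% carry no splice signals, so their exact
junction placement is undefined within the ambiguity run by construction).
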