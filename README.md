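# u12scan

Discovery and classification of U2-type (major) and U12-type (minor)
spliceosomal introns from EST-to-genome matches.

## The problem

Most eukaryotic introns are excised by the major (U2-dependent) spliceosome.
A rare second class, the U12-type introns, is removed by the minor
spliceosome and carries distinctive, highly conserved signals: a 5' splice
site matching `/RTATCCTTT`, a branch site near `TCCTTAACT`, a weak 3' splice
site, and sometimes AT–AC instead of GT–AG terminal dinucleotides.  Mapping
where U12 introns survive, where they converted to U2 type, and where they
were lost traces the evolutionary history of the minor spliceosome.
`u12scan` packages the whole analysis for anyone with genomic contigs and
ESTs (or a precomputed tabular alignment): intron inference, U2/U12
classification by two PWM scoring schemes, per-species summary tables, and
an ortholog intron-fate classifier.

## Methods in brief

**Intron inference.** ESTs are matched to contigs (built-in k-mer
anchor-and-extend matcher, or any 12-column tabular local-alignment file).
Hits are kept at identity ≥ 98% and HSP length ≥ 35 nt; per EST the contig
with the most extensive match wins.  A genomic gap between EST-adjacent
HSPs admits `b+1` junction placements when the HSPs overlap by `b` bases on
the EST; every placement is scored with 5' (13-position) and 3'
(17-position) splice-site PWMs and the placement maximising both scores —
or failing that, their sum — is chosen.

**Probability-ratio scheme.** Each intron gets
`s5 = log2 P(X | U12) / P(X | U2)` for its 5' window and
`sb = log2 Pbps(X | U12) / Pbps(X | U2)` for its best branch window in the
range (−40, −5) upstream of the 3' splice site.  Both are z-normalised over
the scored sample; an intron is called U12 (flag **B**) when both z-scores
reach the minima of a reference U12 set placed in the same z-space.
Because no public branch matrix exists for U2 GT–AG introns, one is built
empirically: each U2 intron contributes its best-scoring window under a U12
branch PWM (`build_u2_branch_matrix`).

**Log-odds scheme.** Position weight matrices with pseudocount 0.001 give
per-position log2-odds against a uniform background; an intron is called
U12 (flag **S**) when its U12-class 5' score beats the competing U2-class
score and both the 5' and best 12-nt branch scores are non-negative.

**5'-terminal rule.** Flag **R** marks introns beginning `RTATCCTT`, where
one of the Cs at +5/+6 may be a T — the hallmark of a strong U12 candidate.

**Intron fate.** Given two homologous gene structures and a protein-level
alignment, each U12 intron position (codon index + phase) is projected onto
the second gene and classified: conserved U12, converted to U2 at the same
site, converted at a shifted site (distance in codons), lost, or unknown
when unmappable.

## Worked example

Simulate a small genome with planted introns, infer them back, and
classify (all offline; the packaged consensus matrices are used by
default):

```bash
u12scan simulate --seed 7 --n-genes 40 --est-error-rate 0.0 --out sim
u12scan discover --genome sim/genome.fasta --ests sim/ests.fasta --out introns.tsv
u12scan classify --introns introns.tsv --out-prefix run
```

This prints (after `wrote 40 contigs, 64 ESTs, 161 planted introns` and
`wrote 257 introns`):

```
               B       S
U12_ATAC   7 (3)   7 (3)
U12_GTAG  25 (8)  29 (6)
U2_GCAG       11      11
U2_GTAG      210     206
OTHER          4       4
```

One row per intron category; **B** and **S** count the introns each scheme
places in that category (the 257 inferred introns include duplicates where
two ESTs cover the same gene), and the parenthetical is how many of the
U12 calls additionally conform to the 5'-terminal rule.  `run.scores.tsv`
holds the per-intron probabilities, log ratios, z-scores, log-odds sums and
the B/S/R flags; `u12scan report --scores run.scores.tsv --out-prefix rep`
exports a `(z5, zb)` scatter table.

The same analysis runs on real data by pointing `--genome`/`--ests` at your
FASTA files (or `--alignments` at a BLAST-style tabular file) and
`--matrices` at SpliceRack-derived matrix files in the package's flat
format (`#key value` header lines, then one `A C G T` count row per
position).

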