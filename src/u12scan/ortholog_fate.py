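"""Evolutionary fate of U12 introns in homologous gene pairs.

Given the intron-annotated gene structures of two homologous genes and a
protein-level alignment between them, each U12 intron of the first gene is
projected through the alignment onto the second gene's codon coordinates and
its fate classified: conserved as U12, converted to U2 at the same splice
site, converted to U2 at a nearby (shifted) site, lost outright, or unknown
when the position cannot be mapped (e.g. it falls in an alignment gap or the
alignment does not cover it).

Intron positions are expressed as (codon index, phase): the intron
interrupts the coding sequence after ``3 * codon_index + phase`` nucleotides.
Phase must match for a same-site call; a shifted conversion ignores phase,
since the splice position moved within the coding frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from Bio import Align

from .intron_discovery import TerminalCategory


@dataclass
class IntronPosition:
    codon_index: int
    phase: int  # 0, 1, or 2
    category: TerminalCategory = TerminalCategory.GT_AG
    u12: bool = False


@dataclass
class GeneStructure:
    """A protein plus the positions and types of the introns of its gene."""

    species: str
    protein: str
    introns: list[IntronPosition] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [(i.codon_index, i.phase) for i in self.introns]
        if positions != sorted(positions):
            raise ValueError("intron positions must be strictly increasing")
        for i in self.introns:
            if not 0 <= i.codon_index < max(1, len(self.protein)):
                raise ValueError("intron codon index outside the protein")
            if i.phase not in (0, 1, 2):
                raise ValueError("phase must be 0, 1 or 2")


class FateValue(str, Enum):
    CONSERVED_U12 = "CONSERVED_U12"
    U12_TO_U2_SAME_SITE = "U12_TO_U2_SAME_SITE"
    U12_TO_U2_SHIFTED = "U12_TO_U2_SHIFTED"
    U12_LOST = "U12_LOST"
    UNKNOWN = "UNKNOWN"


@dataclass
class IntronFate:
    value: FateValue
    shift_codons: int = 0


def align_proteins(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                   gap_open: float = -5.0, gap_extend: float = -0.5
                   ) -> tuple[str, str]:
    """Global protein alignment as two gapped strings (convenience plumbing
    for synthetic tests; real analyses should supply a curated alignment)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def map_intron_positions(a: GeneStructure, b: GeneStructure,
                         alignment: tuple[str, str]
                         ) -> list[tuple[int, int] | None]:
    """Project each of ``a``'s intron positions onto ``b``'s codon frame.

    ``alignment`` is the pair of gapped protein strings (a first).  Returns
    one entry per intron of ``a``: a (codon_index, phase) in ``b`` or None
    when the position is unmappable (falls in a gap of ``b`` or beyond the
    alignment).
    """
    row_a, row_b = alignment
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    if row_a.replace("-", "") != a.protein:
        raise ValueError("alignment row 1 does not spell a's protein")
    if row_b.replace("-", "") != b.protein:
        raise ValueError("alignment row 2 does not spell b's protein")

    # column index of each a-residue, and b-residue count before each column
    col_of_a: list[int] = []
    b_before: list[int] = []
    nb = 0
    for col, (ca, cb) in enumerate(zip(row_a, row_b)):
        if ca != "-":
            col_of_a.append(col)
            b_before.append(nb)
        if cb != "-":
            nb += 1

    mapped: list[tuple[int, int] | None] = []
    for intron in a.introns:
        if intron.codon_index >= len(col_of_a):
            mapped.append(None)
            continue
        col = col_of_a[intron.codon_index]
        if row_b[col] == "-":
            mapped.append(None)
        else:
            mapped.append((b_before[intron.codon_index], intron.phase))
    return mapped


def classify_fate(mapped_pos: tuple[int, int] | None, b: GeneStructure,
                  shift_max: int = 5) -> IntronFate:
    """Fate of one U12 intron of gene *a* given its mapped position in *b*.

    Same mapped codon and phase with a U12 intron in b -> conserved; with a
    U2 intron -> same-site conversion; a U2 intron within ``shift_max``
    codons (any phase) -> shifted conversion with the distance; no intron
    within ``shift_max`` codons -> lost; unmappable -> unknown.
    """
    if mapped_pos is None:
        return IntronFate(FateValue.UNKNOWN)
    codon, phase = mapped_pos
    for intron in b.introns:
        if intron.codon_index == codon and intron.phase == phase:
            if intron.u12:
                return IntronFate(FateValue.CONSERVED_U12)
            return IntronFate(FateValue.U12_TO_U2_SAME_SITE)
    nearest = None
    for intron in b.introns:
        d = abs(intron.codon_index - codon)
        if d <= shift_max and (nearest is None or d < nearest[0]):
            nearest = (d, intron)
    if nearest is not None:
        return IntronFate(FateValue.U12_TO_U2_SHIFTED, shift_codons=nearest[0])
    return IntronFate(FateValue.U12_LOST)


def classify_gene_pair(a: GeneStructure, b: GeneStructure,
                       alignment: tuple[str, str] | None = None,
                       shift_max: int = 5) -> list[IntronFate]:
    """Fates of all U12 introns of ``a`` relative to ``b``.

    When no alignment is given the convenience global aligner is used.
    """
    if alignment is None:
        alignment = align_proteins(a.protein, b.protein)
    mapped = map_intron_positions(a, b, alignment)
    return [classify_fate(pos, b, shift_max)
            for intron, pos in zip(a.introns, mapped) if intron.u12]


# ---------------------------------------------------------------------------
# Flat-file I/O: gene structure TSV and aligned FASTA
# ---------------------------------------------------------------------------

def read_gene_structures(path) -> dict[tuple[str, str], GeneStructure]:
    """Read gene structures from a TSV with columns
    species, protein_id, protein, codon_index, phase, donor, acceptor, u12
    (one row per intron; protein repeated; intronless genes use codon_index
    of -1).  Keyed by (species, protein_id)."""
    import csv

    genes: dict[tuple[str, str], GeneStructure] = {}
    rows: dict[tuple[str, str], list[IntronPosition]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            key = (rec["species"], rec["protein_id"])
            if key not in genes:
                genes[key] = GeneStructure(rec["species"], rec["protein"])
                rows[key] = []
            if int(rec["codon_index"]) >= 0:
                donor, acceptor = rec["donor"].upper(), rec["acceptor"].upper()
                if donor == "GT" and acceptor == "AG":
                    cat = TerminalCategory.GT_AG
                elif donor == "GC" and acceptor == "AG":
                    cat = TerminalCategory.GC_AG
                elif donor == "AT" and acceptor == "AC":
                    cat = TerminalCategory.AT_AC
                else:
                    cat = TerminalCategory.OTHER
                rows[key].append(IntronPosition(
                    int(rec["codon_index"]), int(rec["phase"]), cat,
                    rec["u12"].strip().lower() in ("1", "true", "yes", "+")))
    out = {}
    for key, gene in genes.items():
        out[key] = GeneStructure(gene.species, gene.protein,
                                 sorted(rows[key],
                                        key=lambda i: (i.codon_index, i.phase)))
    return out


def read_gene_structure_gff3(path, protein: str, species: str,
                             mrna_id: str | None = None,
                             contigs: dict[str, str] | None = None,
                             u12_positions: set[tuple[int, int]] | None = None
                             ) -> GeneStructure:
    """Optional GFF3 import: derive intron positions from CDS features.

    Collects the CDS features of ``mrna_id`` (or of the only mRNA in the
    file), orders them along the transcript, and converts each inter-CDS gap
    into a (codon index, phase) intron position.  Terminal dinucleotides are
    read from ``contigs`` when given, else left as OTHER; ``u12_positions``
    marks which (codon, phase) positions are U12.
    """
    cds: list[tuple[str, int, int, str]] = []  # (seqid, start0, end, strand)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            parent = attrs.get("Parent", attrs.get("ID", ""))
            if mrna_id is not None and parent != mrna_id:
                continue
            cds.append((f[0], int(f[3]) - 1, int(f[4]), f[6]))
    if not cds:
        raise ValueError(f"{path}: no CDS features"
                         + (f" for {mrna_id}" if mrna_id else ""))
    strand = cds[0][3]
    cds.sort(key=lambda c: c[1], reverse=(strand == "-"))
    introns: list[IntronPosition] = []
    offset = 0
    for (seqid, s0, e0, _), (_, s1, e1, _) in zip(cds, cds[1:]):
        offset += e0 - s0
        codon, phase = divmod(offset, 3)
        category = TerminalCategory.OTHER
        if contigs is not None and strand == "+":
            gap = contigs[seqid][e0:s1]
            donor, acceptor = gap[:2].upper(), gap[-2:].upper()
            category = {("GT", "AG"): TerminalCategory.GT_AG,
                        ("GC", "AG"): TerminalCategory.GC_AG,
                        ("AT", "AC"): TerminalCategory.AT_AC}.get(
                (donor, acceptor), TerminalCategory.OTHER)
        u12 = bool(u12_positions and (codon, phase) in u12_positions)
        introns.append(IntronPosition(codon, phase, category, u12))
    return GeneStructure(species, protein, introns)


def read_aligned_fasta(path) -> tuple[str, str]:
    """Read a two-record aligned FASTA into a pair of gapped strings."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, "
                         f"found {len(records)}")
    return str(records[0].seq), str(records[1].seq)
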