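"""Synthetic genomes, gene structures, and ESTs with planted introns.

The generator emulates the data regime of an EST-to-genome intron survey:
multi-exon genes on random background sequence, introns sampled per class
from consensus-derived splice-site PWMs with the class's terminal
dinucleotides forced, a branch window planted at a recorded offset inside
the (-40, -5) scan range, and ESTs that are spliced transcripts carrying
uniform substitution errors.  Every planted intron is written to a truth
table so each pipeline stage can be checked against ground truth without
any external downloads.

Consensus motifs (IUPAC): U2 5'ss AG/GTRAGT, U12 5'ss /RTATCCTTT, U2 branch
CTRACT, U12 branch TCCTTAACT, U2 3'ss YAG/G with a pyrimidine tract, U12
3'ss weak.  A consensus-mass parameter sets how much probability the
consensus base receives at each position; U12 sites are sharper (default
0.85) than U2 sites (default 0.55), mirroring the stronger conservation of
minor-spliceosome signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .matrices import (BASES, FrequencyMatrix, IntronClass, SiteType)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# 13-position 5'ss (3 exonic + 10 intronic), 17-position 3'ss (14 intronic +
# 3 exonic), 12-position branch.
CONSENSUS: dict[tuple[SiteType, IntronClass], str] = {
    (SiteType.FIVE_PRIME, IntronClass.U2_GTAG): "NAG" + "GTRAGT" + "NNNN",
    (SiteType.FIVE_PRIME, IntronClass.U2_GCAG): "NAG" + "GCRAGT" + "NNNN",
    (SiteType.FIVE_PRIME, IntronClass.U12_GTAG): "NNN" + "GTATCCTTT" + "N",
    (SiteType.FIVE_PRIME, IntronClass.U12_ATAC): "NNN" + "ATATCCTTT" + "N",
    (SiteType.THREE_PRIME, IntronClass.U2_GTAG): "Y" * 11 + "YAG" + "GNN",
    (SiteType.THREE_PRIME, IntronClass.U2_GCAG): "Y" * 11 + "YAG" + "GNN",
    (SiteType.THREE_PRIME, IntronClass.U12_GTAG): "N" * 12 + "AG" + "NNN",
    (SiteType.THREE_PRIME, IntronClass.U12_ATAC): "N" * 12 + "AC" + "NNN",
    (SiteType.BRANCH, IntronClass.U2_GTAG): "NNN" + "CTRACT" + "NNN",
    (SiteType.BRANCH, IntronClass.U2_GCAG): "NNN" + "CTRACT" + "NNN",
    (SiteType.BRANCH, IntronClass.U12_GTAG): "N" + "TCCTTAACT" + "NN",
    (SiteType.BRANCH, IntronClass.U12_ATAC): "N" + "TCCTTAACT" + "NN",
}

TERMINI = {
    IntronClass.U2_GTAG: ("GT", "AG"),
    IntronClass.U2_GCAG: ("GC", "AG"),
    IntronClass.U12_GTAG: ("GT", "AG"),
    IntronClass.U12_ATAC: ("AT", "AC"),
}

#: label used in truth tables for non-canonical planted introns
OTHER_CLASS = "OTHER"

DEFAULT_CLASS_MIX = {
    IntronClass.U2_GTAG.value: 0.82,
    IntronClass.U2_GCAG.value: 0.04,
    IntronClass.U12_GTAG.value: 0.07,
    IntronClass.U12_ATAC.value: 0.05,
    OTHER_CLASS: 0.02,
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-data generator.

    The U12 classes are deliberately enriched relative to real genomes
    (where minor introns are ~0.1% of all introns) so that class-recovery
    statistics are measurable at simulation scale.
    """

    seed: int = 42
    n_genes: int = 125
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_len: tuple[int, int] = (80, 300)
    intron_len_mode: int = 62          # modal intron length, nt
    intron_len_sigma: float = 0.45     # log-normal shape
    intron_len_min: int = 50
    intron_len_cap: int = 2000
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    u12_consensus_mass: float = 0.85
    u2_consensus_mass: float = 0.55
    est_error_rate: float = 0.01
    est_truncation: tuple[int, int] = (0, 20)
    ests_per_gene: tuple[int, int] = (1, 2)
    flank_len: int = 100

    def validate(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not 0.0 <= self.est_error_rate <= 0.02:
            raise ValueError("est_error_rate must be <= 0.02 so the 98% "
                             "identity filter stays meaningful")
        if self.intron_len_min < 50:
            raise ValueError("intron_len_min below 50 nt cannot guarantee "
                             "an admissible branch window")
        if self.exon_len[0] < 40:
            raise ValueError("exons shorter than 40 nt break the HSP "
                             "length filter")


@dataclass
class TruthRecord:
    """Ground truth for one planted intron."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    true_class: str           # IntronClass value or "OTHER"
    branch_offset: int        # relative to intron 3' end; -1 if none planted
    est_ids: list[str] = field(default_factory=list)


@dataclass
class SyntheticBundle:
    contigs: dict[str, str]
    ests: dict[str, str]
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene_id": t.gene_id, "contig_id": t.contig_id,
              "start": t.start, "end": t.end, "true_class": t.true_class,
              "branch_offset": t.branch_offset,
              "est_ids": ",".join(t.est_ids)} for t in self.truth])


# ---------------------------------------------------------------------------
# Fixture PWMs
# ---------------------------------------------------------------------------

def _position_probs(code: str, mass: float) -> np.ndarray:
    bases = IUPAC[code]
    if len(bases) == 4:
        return np.full(4, 0.25)
    probs = np.empty(4)
    k = len(bases)
    for j, b in enumerate(BASES):
        probs[j] = mass / k if b in bases else (1.0 - mass) / (4 - k)
    return probs


def build_fixture_pwms(cfg: GeneratorConfig | None = None,
                       scale: float = 10000.0
                       ) -> dict[tuple[SiteType, IntronClass], FrequencyMatrix]:
    """Consensus-derived frequency matrices for all (site, class) pairs.

    Each position puts the consensus mass on the consensus base (degenerate
    codes split it equally among their bases) and spreads the remainder
    uniformly over the other bases; N positions are uniform.  Counts are the
    probabilities scaled to a nominal site count, so every column sums to
    ``scale``.
    """
    cfg = cfg or GeneratorConfig()
    for mass in (cfg.u12_consensus_mass, cfg.u2_consensus_mass):
        if not 0.25 < mass <= 1.0:
            raise ValueError(
                f"consensus mass {mass} not informative (must be in (0.25, 1])")
    out = {}
    for (site, cls), consensus in CONSENSUS.items():
        mass = (cfg.u12_consensus_mass
                if cls in (IntronClass.U12_GTAG, IntronClass.U12_ATAC)
                else cfg.u2_consensus_mass)
        counts = np.vstack([_position_probs(c, mass) for c in consensus])
        exon_offset = 3 if site != SiteType.BRANCH else 0
        out[(site, cls)] = FrequencyMatrix(
            site, cls, counts * scale, exon_offset=exon_offset,
            species="synthetic")
    return out


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def _sample_from(consensus: str, mass: float, rng: np.random.Generator) -> str:
    return "".join(
        BASES[rng.choice(4, p=_position_probs(c, mass))] for c in consensus)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _intron_length(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    # log-normal with the configured mode; resample (not clamp) below the
    # minimum so no atom forms at the boundary
    mu = math.log(cfg.intron_len_mode) + cfg.intron_len_sigma ** 2
    while True:
        n = int(round(rng.lognormal(mu, cfg.intron_len_sigma)))
        if cfg.intron_len_min <= n <= cfg.intron_len_cap:
            return n


def _other_termini(rng: np.random.Generator) -> tuple[str, str]:
    canonical = set(TERMINI.values())
    while True:
        d = _random_seq(2, rng)
        a = _random_seq(2, rng)
        if (d, a) not in canonical:
            return d, a


def _make_intron(cls_label: str, cfg: GeneratorConfig,
                 rng: np.random.Generator) -> tuple[str, str, str, int]:
    """Returns (intron_seq, exon5_tail, exon3_head, branch_offset)."""
    length = _intron_length(cfg, rng)
    arr = list(_random_seq(length, rng))
    if cls_label == OTHER_CLASS:
        donor, acceptor = _other_termini(rng)
        arr[0:2] = donor
        arr[-2:] = acceptor
        return "".join(arr), _random_seq(3, rng), _random_seq(3, rng), -1
    cls = IntronClass(cls_label)
    mass = (cfg.u12_consensus_mass
            if cls in (IntronClass.U12_GTAG, IntronClass.U12_ATAC)
            else cfg.u2_consensus_mass)
    w5 = _sample_from(CONSENSUS[(SiteType.FIVE_PRIME, cls)], mass, rng)
    w3 = _sample_from(CONSENSUS[(SiteType.THREE_PRIME, cls)], mass, rng)
    wb = _sample_from(CONSENSUS[(SiteType.BRANCH, cls)], mass, rng)
    arr[0:10] = w5[3:]
    arr[length - 14:length] = w3[:14]
    # plant the branch 5' of the acceptor region so the 3'ss stays intact;
    # offsets are relative to the 3' end of the intron
    offset = int(rng.integers(-40, -25))  # window [-40..-26] start
    start = length + offset
    arr[start:start + len(wb)] = wb
    donor, acceptor = TERMINI[cls]
    arr[0:2] = donor
    arr[-2:] = acceptor
    return "".join(arr), w5[:3], w3[14:], offset


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        alternatives = [b for b in BASES if b != arr[i]]
        arr[i] = alternatives[rng.integers(0, 3)]
    return "".join(arr)


def generate(cfg: GeneratorConfig | None = None,
             outdir: str | Path | None = None) -> SyntheticBundle:
    """Generate contigs, ESTs, and the truth table.

    One contig per gene: random flank + exon/intron alternation + random
    flank.  ESTs are the spliced transcript, truncated at each end by a
    uniform draw from ``est_truncation`` and mutated at ``est_error_rate``.
    Identical seeds give byte-identical outputs.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = sorted(cfg.class_mix)
    mix = np.array([cfg.class_mix[label] for label in labels])
    mix = mix / mix.sum()

    contigs: dict[str, str] = {}
    ests: dict[str, str] = {}
    truth: list[TruthRecord] = []

    for g in range(cfg.n_genes):
        gene_id = f"gene{g:04d}"
        contig_id = f"contig{g:04d}"
        n_exons = int(rng.integers(cfg.exons_per_gene[0],
                                   cfg.exons_per_gene[1] + 1))
        exons = [_random_seq(int(rng.integers(cfg.exon_len[0],
                                              cfg.exon_len[1] + 1)), rng)
                 for _ in range(n_exons)]
        introns = []
        for _ in range(n_exons - 1):
            label = labels[int(rng.choice(len(labels), p=mix))]
            introns.append((_make_intron(label, cfg, rng), label))

        # weld boundary triplets into the flanking exons
        for i, ((seq, tail, head, off), label) in enumerate(introns):
            exons[i] = exons[i][:-3] + tail
            exons[i + 1] = head + exons[i + 1][3:]

        pieces = [_random_seq(cfg.flank_len, rng), exons[0]]
        records = []
        pos = cfg.flank_len + len(exons[0])
        for i, ((seq, _, _, off), label) in enumerate(introns):
            records.append(TruthRecord(gene_id, contig_id, pos,
                                       pos + len(seq), label, off))
            pieces.append(seq)
            pos += len(seq)
            pieces.append(exons[i + 1])
            pos += len(exons[i + 1])
        pieces.append(_random_seq(cfg.flank_len, rng))
        contigs[contig_id] = "".join(pieces)

        transcript = "".join(exons)
        exon_ends = np.cumsum([len(e) for e in exons])  # junction positions
        n_ests = int(rng.integers(cfg.ests_per_gene[0],
                                  cfg.ests_per_gene[1] + 1))
        for e in range(n_ests):
            t5 = int(rng.integers(cfg.est_truncation[0],
                                  cfg.est_truncation[1] + 1))
            t3 = int(rng.integers(cfg.est_truncation[0],
                                  cfg.est_truncation[1] + 1))
            est_id = f"{gene_id}.e{e}"
            est = _mutate(transcript[t5:len(transcript) - t3],
                          cfg.est_error_rate, rng)
            ests[est_id] = est
            # an EST covers an intron when it spans the junction with at
            # least 35 nt of exon on each side (the HSP length filter)
            for rec, junction in zip(records, exon_ends[:-1]):
                if junction - t5 >= 35 and \
                        (len(transcript) - t3) - junction >= 35:
                    rec.est_ids.append(est_id)
        truth.extend(records)

    bundle = SyntheticBundle(contigs, ests, truth)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def make_reference_introns(n: int = 20, seed: int = 101,
                           cfg: GeneratorConfig | None = None) -> list:
    """A reproducible reference set of U12 introns for threshold calibration.

    The published reference minor-intron set is not available, so the default
    reference is sampled from the U12 generator PWMs with a fixed seed:
    alternating GT-AG and AT-AC U12 introns, n=20 by default.  Users with a
    curated reference should load it instead and pass it through.
    """
    from .intron_discovery import IntronCandidate

    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = (IntronClass.U12_GTAG.value if i % 2 == 0
                 else IntronClass.U12_ATAC.value)
        seq, tail, head, _ = _make_intron(label, cfg, rng)
        out.append(IntronCandidate(
            contig_id="reference", start=0, end=len(seq), sequence=seq,
            donor_dinuc=seq[:2], acceptor_dinuc=seq[-2:],
            exon5_context=tail, exon3_context=head, est_id=f"ref{i:02d}"))
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.contigs, outdir / "genome.fasta")
    write_fasta(bundle.ests, outdir / "ests.fasta")
    bundle.truth_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
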