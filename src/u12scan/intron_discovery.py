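"""Intron inference from EST-to-genome matches.

An expressed sequence tag (EST) aligned back to genomic DNA reveals introns
as genomic gaps between consecutive gap-free alignment blocks (HSPs).  This
module filters HSPs, selects the best-matching contig per EST, enumerates the
candidate splice junctions a gap is compatible with, resolves the exact
splice sites with multi-species splice-site PWMs, and categorises the
resulting introns by their terminal dinucleotides.

Alignments come either from a standard 12-column tabular alignment file
(BLAST ``-outfmt 6`` dialect) or from the built-in exact-anchor matcher,
which seeds on shared k-mers and extends with an x-drop rule — sufficient for
the substitution-only error model of the synthetic data.

Coordinates are 0-based half-open throughout; reverse-strand ESTs are
reverse-complemented before intron inference, so introns are always reported
on the coding strand.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .matrices import PWM, pwm_window_prob

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FIVE_PRIME_WINDOW = 13   # exon -3..-1 + intron +1..+10
THREE_PRIME_WINDOW = 17  # intron -14..-1 + exon +1..+3
DONOR_SPAN = 10
ACCEPTOR_SPAN = 14


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Hsp:
    """One gap-free local alignment block between an EST and a contig."""

    est_id: str
    contig_id: str
    est_start: int
    est_end: int
    genome_start: int
    genome_end: int
    strand: str = "+"
    identity: float = 100.0

    def __post_init__(self) -> None:
        if self.est_end <= self.est_start or self.genome_end <= self.genome_start:
            raise ValueError("HSP intervals must be non-empty (end > start)")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be a percentage in [0, 100]")

    @property
    def match_len(self) -> int:
        return self.est_end - self.est_start


class TerminalCategory(str, Enum):
    GT_AG = "GT_AG"
    GC_AG = "GC_AG"
    AT_AC = "AT_AC"
    OTHER = "OTHER"


@dataclass
class IntronCandidate:
    """One inferred intron on the coding strand of its contig."""

    contig_id: str
    start: int
    end: int
    sequence: str
    donor_dinuc: str
    acceptor_dinuc: str
    exon5_context: str
    exon3_context: str
    est_id: str = "NA"

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_genome(cls, genome: str, contig_id: str, start: int, end: int,
                    est_id: str = "NA") -> "IntronCandidate":
        seq = genome[start:end].upper()
        exon5 = genome[max(0, start - 3):start].upper().rjust(3, "N")
        exon3 = genome[end:end + 3].upper().ljust(3, "N")
        return cls(contig_id, start, end, seq, seq[:2], seq[-2:],
                   exon5, exon3, est_id)


@dataclass
class SpeciesPwmSet:
    """5' and 3' splice-site PWMs for one scoring species.

    Each slot holds either a single PWM or several (one per intron class);
    with several, a window scores the best of them — a junction is plausible
    if any class's consensus fits it.
    """

    species: str
    five_prime: PWM | Sequence[PWM]
    three_prime: PWM | Sequence[PWM]

    def five_pwms(self) -> Sequence[PWM]:
        return [self.five_prime] if isinstance(self.five_prime, PWM) \
            else list(self.five_prime)

    def three_pwms(self) -> Sequence[PWM]:
        return [self.three_prime] if isinstance(self.three_prime, PWM) \
            else list(self.three_prime)


# ---------------------------------------------------------------------------
# Tabular alignment import
# ---------------------------------------------------------------------------

def read_tabular_alignment(path, est_lengths: Mapping[str, int] | None = None
                           ) -> list[Hsp]:
    """Read 12-column tabular alignments (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore; 1-based
    inclusive) into plus-strand :class:`Hsp` records.

    Minus-strand hits (``sstart > send``) are flipped into the coordinate
    frame of the reverse-complemented EST, which requires ``est_lengths``.
    Gapped hits (``gapopen > 0``) are skipped: intron placement assumes
    gap-free blocks.
    """
    hsps: list[Hsp] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns")
            qid, sid = f[0], f[1]
            pident = float(f[2])
            gapopen = int(f[5])
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            if gapopen > 0:
                continue
            if sstart <= send:
                hsps.append(Hsp(qid, sid, qstart - 1, qend, sstart - 1, send,
                                "+", pident))
            else:
                if est_lengths is None or qid not in est_lengths:
                    raise ValueError(
                        f"{path}:{lineno}: minus-strand hit for {qid} needs "
                        "est_lengths to flip coordinates")
                qlen = est_lengths[qid]
                hsps.append(Hsp(qid, sid, qlen - qend, qlen - (qstart - 1),
                                send - 1, sstart, "-", pident))
    return hsps


# ---------------------------------------------------------------------------
# Built-in exact-anchor matcher
# ---------------------------------------------------------------------------

def _xdrop_extend(est: str, genome: str, epos: int, gpos: int, direction: int,
                  match: int = 1, mismatch: int = -3, xdrop: int = 12
                  ) -> int:
    """Extend a gapless alignment; return offset of the best-scoring end."""
    score = best = 0
    best_i = 0
    i = 0
    while True:
        e, g = epos + direction * (i + 1), gpos + direction * (i + 1)
        if direction > 0 and (e >= len(est) or g >= len(genome)):
            break
        if direction < 0 and (e < 0 or g < 0):
            break
        score += match if est[e] == genome[g] else mismatch
        i += 1
        if score > best:
            best, best_i = score, i
        if best - score > xdrop:
            break
    return best_i


def _match_oriented(est: str, est_id: str, contigs: Mapping[str, str],
                    index: Mapping[str, list[tuple[str, int]]], k: int,
                    strand: str, max_seed_gap: int = 50) -> list[Hsp]:
    # group seed hits by (contig, diagonal), then split each diagonal into
    # clusters of nearby seeds: a chance k-mer repeat elsewhere on the same
    # diagonal must not get welded to a genuine exon match
    diagonals: dict[tuple[str, int], list[int]] = defaultdict(list)
    for i in range(0, len(est) - k + 1):
        kmer = est[i:i + k]
        for contig_id, j in index.get(kmer, ()):
            diagonals[(contig_id, j - i)].append(i)
    hsps: list[Hsp] = []
    seen: set[tuple[str, int, int]] = set()
    for (contig_id, diag), epositions in diagonals.items():
        genome = contigs[contig_id]
        epositions.sort()
        clusters: list[list[int]] = [[epositions[0]]]
        for i in epositions[1:]:
            if i - clusters[-1][-1] <= max_seed_gap:
                clusters[-1].append(i)
            else:
                clusters.append([i])
        for cluster in clusters:
            e0, e1 = cluster[0], cluster[-1] + k - 1
            left = _xdrop_extend(est, genome, e0, e0 + diag, -1)
            right = _xdrop_extend(est, genome, e1, e1 + diag, +1)
            es, ee = e0 - left, e1 + right + 1
            gs, ge = es + diag, ee + diag
            key = (contig_id, es, ee)
            if key in seen:
                continue
            seen.add(key)
            matches = sum(1 for a, b in zip(est[es:ee], genome[gs:ge])
                          if a == b)
            identity = 100.0 * matches / (ee - es)
            hsps.append(Hsp(est_id, contig_id, es, ee, gs, ge, strand,
                            identity))
    return hsps


class AnchorMatcher:
    """Exact k-mer anchor-and-extend matcher for EST-to-genome alignment.

    Seeds on exact shared k-mers, merges seeds on a common diagonal, and
    extends gap-free with an x-drop rule.  Handles substitutions but not
    indels.  Both EST orientations are tried; the one covering more EST bases
    wins, and its HSPs are reported in the frame of the (possibly
    reverse-complemented) EST with the strand recorded.
    """

    def __init__(self, contigs: Mapping[str, str], k: int = 14):
        self.contigs = {cid: seq.upper() for cid, seq in contigs.items()}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for cid, seq in self.contigs.items():
            for j in range(0, len(seq) - k + 1):
                self.index[seq[j:j + k]].append((cid, j))

    def match(self, est: str, est_id: str = "est") -> list[Hsp]:
        est = est.upper()
        fwd = _match_oriented(est, est_id, self.contigs, self.index,
                              self.k, "+")
        rev = _match_oriented(revcomp(est), est_id, self.contigs, self.index,
                              self.k, "-")
        cover_f = sum(h.match_len for h in fwd)
        cover_r = sum(h.match_len for h in rev)
        return fwd if cover_f >= cover_r else rev


# ---------------------------------------------------------------------------
# Filtering and contig selection
# ---------------------------------------------------------------------------

def filter_hsps(hsps: Iterable[Hsp], min_identity: float = 98.0,
                min_len: int = 35) -> list[Hsp]:
    """Keep HSPs with identity >= min_identity and length >= min_len
    (both boundaries inclusive)."""
    return [h for h in hsps
            if h.identity >= min_identity and h.match_len >= min_len]


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        s = max(s, end)
        if e > s:
            total += e - s
            end = e
    return total


def select_best_contig(hsps_by_contig: Mapping[str, Sequence[Hsp]]) -> str:
    """Contig with the most extensive match to the EST: the one whose HSPs
    cover the most non-overlapping EST bases.  Ties break to the
    lexicographically smallest contig id."""
    if not hsps_by_contig:
        raise ValueError("no contigs to select from")
    best_id, best_cov = None, -1
    for contig_id in sorted(hsps_by_contig):
        cov = _union_length([(h.est_start, h.est_end)
                             for h in hsps_by_contig[contig_id]])
        if cov > best_cov:
            best_id, best_cov = contig_id, cov
    return best_id


# ---------------------------------------------------------------------------
# Junction enumeration and splice-site resolution
# ---------------------------------------------------------------------------

def enumerate_intron_placements(left: Hsp, right: Hsp, genome: str,
                                min_intron: int = 30,
                                max_intron: int = 20000
                                ) -> list[IntronCandidate]:
    """All intron placements compatible with two EST-adjacent HSPs.

    When the HSPs overlap by *b* bases on the EST axis the junction is
    ambiguous: any of the b+1 splits conserves the EST sequence.  One
    candidate per split is returned; placements whose genomic gap falls
    outside [min_intron, max_intron] are excluded.  HSPs that leave
    unaligned EST bases between them admit no clean junction and yield [].
    """
    if left.contig_id != right.contig_id or left.strand != right.strand:
        raise ValueError("HSPs must lie on the same contig and strand")
    if left.est_start > right.est_start:
        left, right = right, left
    if right.est_start > left.est_end:   # gap on the EST: no clean junction
        return []
    out: list[IntronCandidate] = []
    for j in range(right.est_start, left.est_end + 1):
        g5 = left.genome_start + (j - left.est_start)
        g3 = right.genome_start + (j - right.est_start)
        gap = g3 - g5
        if min_intron <= gap <= max_intron:
            out.append(IntronCandidate.from_genome(
                genome, left.contig_id, g5, g3, left.est_id))
    return out


def splice_windows(c: IntronCandidate) -> tuple[str, str]:
    """The scored 13-nt 5' window and 17-nt 3' window of a candidate."""
    w5 = c.exon5_context + c.sequence[:DONOR_SPAN]
    w3 = c.sequence[-ACCEPTOR_SPAN:] + c.exon3_context
    return w5, w3


def resolve_splice_sites(cands: Sequence[IntronCandidate],
                         pwm_sets: Sequence[SpeciesPwmSet]
                         ) -> IntronCandidate:
    """Pick the most probable splice junction among ambiguous placements.

    Each candidate's 5' and 3' windows are scored (log probability) under
    every species set and the log scores averaged across species.  If one
    candidate simultaneously maximises both averaged scores it wins;
    otherwise the candidate with the greatest averaged 5'+3' sum wins.
    Remaining ties go to the leftmost genomic start.
    """
    if not cands:
        raise ValueError("no candidates to resolve")
    if len(cands) == 1:
        return cands[0]

    def logp(p: float) -> float:
        return math.log(p) if p > 0 else -math.inf

    s5s, s3s = [], []
    for c in cands:
        w5, w3 = splice_windows(c)
        s5 = np.mean([max(logp(pwm_window_prob(p, w5))
                          for p in ps.five_pwms()) for ps in pwm_sets])
        s3 = np.mean([max(logp(pwm_window_prob(p, w3))
                          for p in ps.three_pwms()) for ps in pwm_sets])
        s5s.append(s5)
        s3s.append(s3)
    best5, best3 = max(s5s), max(s3s)
    order = sorted(range(len(cands)), key=lambda i: cands[i].start)
    for i in order:
        if s5s[i] == best5 and s3s[i] == best3:
            return cands[i]
    best_sum = max(s5s[i] + s3s[i] for i in range(len(cands)))
    for i in order:
        if s5s[i] + s3s[i] == best_sum:
            return cands[i]
    return cands[order[0]]  # unreachable


def classify_termini(c: IntronCandidate | str) -> TerminalCategory:
    """Categorise an intron by its terminal dinucleotides."""
    seq = c.sequence if isinstance(c, IntronCandidate) else str(c)
    seq = seq.upper()
    if len(seq) < 4:
        raise ValueError("intron shorter than 4 nt has no termini")
    donor, acceptor = seq[:2], seq[-2:]
    if donor == "GT" and acceptor == "AG":
        return TerminalCategory.GT_AG
    if donor == "GC" and acceptor == "AG":
        return TerminalCategory.GC_AG
    if donor == "AT" and acceptor == "AC":
        return TerminalCategory.AT_AC
    return TerminalCategory.OTHER


def intron_length_stats(introns: Sequence[IntronCandidate | int]) -> dict:
    """Mode, mean, and histogram of intron lengths (mode ties -> smallest)."""
    if not introns:
        raise ValueError("no introns")
    lengths = [i.length if isinstance(i, IntronCandidate) else int(i)
               for i in introns]
    hist = Counter(lengths)
    top = max(hist.values())
    mode = min(length for length, n in hist.items() if n == top)
    return {"mode": mode, "mean": float(np.mean(lengths)),
            "histogram": dict(sorted(hist.items()))}


INTRON_TSV_COLUMNS = ["contig_id", "start", "end", "length", "donor",
                      "acceptor", "exon5_context", "exon3_context", "est_id",
                      "sequence"]


def write_introns_tsv(introns: Sequence[IntronCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(INTRON_TSV_COLUMNS) + "\n")
        for c in introns:
            fh.write("\t".join(map(str, [
                c.contig_id, c.start, c.end, c.length, c.donor_dinuc,
                c.acceptor_dinuc, c.exon5_context, c.exon3_context,
                c.est_id, c.sequence])) + "\n")


def read_introns_tsv(path) -> list[IntronCandidate]:
    import csv

    out: list[IntronCandidate] = []
    with open(path) as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            out.append(IntronCandidate(
                rec["contig_id"], int(rec["start"]), int(rec["end"]),
                rec["sequence"], rec["donor"], rec["acceptor"],
                rec["exon5_context"], rec["exon3_context"], rec["est_id"]))
    return out


# ---------------------------------------------------------------------------
# End-to-end discovery
# ---------------------------------------------------------------------------

def discover_introns(contigs: Mapping[str, str], ests: Mapping[str, str],
                     pwm_sets: Sequence[SpeciesPwmSet],
                     hsps: Sequence[Hsp] | None = None,
                     min_identity: float = 98.0, min_len: int = 35,
                     min_intron: int = 30, max_intron: int = 20000,
                     k: int = 14) -> list[IntronCandidate]:
    """Run the full inference: align (if needed), filter, pick the best
    contig per EST, enumerate junctions gap by gap, and resolve splice sites.

    Multi-intron ESTs are processed one EST gap at a time, independently.
    """
    if hsps is None:
        matcher = AnchorMatcher(contigs, k=k)
        hsps = [h for eid, seq in ests.items()
                for h in matcher.match(seq, eid)]
    kept = filter_hsps(hsps, min_identity, min_len)

    by_est: dict[str, list[Hsp]] = defaultdict(list)
    for h in kept:
        by_est[h.est_id].append(h)

    introns: list[IntronCandidate] = []
    for est_id in sorted(by_est):
        est_hsps = by_est[est_id]
        by_contig: dict[str, list[Hsp]] = defaultdict(list)
        for h in est_hsps:
            by_contig[h.contig_id].append(h)
        contig_id = select_best_contig(by_contig)
        chosen = [h for h in by_contig[contig_id]
                  if h.strand == by_contig[contig_id][0].strand]
        chosen.sort(key=lambda h: h.est_start)
        genome = contigs[contig_id].upper()
        for left, right in zip(chosen, chosen[1:]):
            cands = enumerate_intron_placements(left, right, genome,
                                                min_intron, max_intron)
            if cands:
                introns.append(resolve_splice_sites(cands, pwm_sets))
    return introns
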