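"""Splice-site matrices: frequency counts, probabilities, and log-odds.

All probability and log-odds arithmetic for splice-site scoring lives here:
reading/writing the flat matrix format, converting counts to position weight
matrices (PWMs) with an optional probability floor, converting counts to
log-odds weights against a background, window scoring, the branch-site window
scan, and construction of a U2 branch frequency matrix from the best-scoring
branch windows of a set of U2 introns.

Matrix conventions follow the SpliceRack layout: 5' splice-site matrices span
13 positions of which the first 3 are exonic; 3' splice-site matrices span 17
positions of which the last 3 are exonic; branch matrices span 12 intronic
positions and are scanned over the window (-40, -5) upstream of the 3' splice
site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: scan interval for branch-site windows, relative to the intron 3' end
BRANCH_SEARCH_RANGE = (-40, -5)

#: number of intron bases at the 5' end that a branch window may never overlap
DONOR_EXCLUSION = 10


class SiteType(str, Enum):
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"
    BRANCH = "branch"


class IntronClass(str, Enum):
    U2_GTAG = "U2_GTAG"
    U2_GCAG = "U2_GCAG"
    U12_GTAG = "U12_GTAG"
    U12_ATAC = "U12_ATAC"


class MatrixParseError(ValueError):
    """Raised when a matrix flat file cannot be parsed; names the bad line."""


@dataclass
class FrequencyMatrix:
    """Per-position base counts for one (site type, intron class) pair.

    ``exon_offset`` counts exonic positions at the exon-proximal edge of the
    window: 3 for 5' and 3' splice sites, 0 for branch sites.  For a matrix
    built from *n* sites every position's column sum equals *n*.
    """

    site_type: SiteType
    intron_class: IntronClass
    counts: np.ndarray  # shape (length, 4), order A C G T
    exon_offset: int = 0
    species: str = "NA"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an (length, 4) array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return self.counts.shape[0]


@dataclass
class PWM:
    """Per-position base probabilities; rows sum to 1."""

    site_type: SiteType
    intron_class: IntronClass
    probs: np.ndarray
    exon_offset: int = 0
    species: str = "NA"
    prob_floor: float = 0.0

    @property
    def length(self) -> int:
        return self.probs.shape[0]


@dataclass
class LogOddsMatrix:
    """Per-position log2-odds weights against a stated background."""

    site_type: SiteType
    intron_class: IntronClass
    weights: np.ndarray
    exon_offset: int = 0
    species: str = "NA"
    pseudocount: float = 0.001
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    @property
    def length(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# Flat-file I/O
#
# Format: '#key value' header lines (site_type, intron_class, species,
# exon_offset), then one whitespace-separated "A C G T" count row per
# position.  Self-describing and durable; round-trips losslessly.
# ---------------------------------------------------------------------------

def load_matrix(path) -> FrequencyMatrix:
    """Read a frequency matrix from the flat text format."""
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split(None, 1)
                if len(parts) != 2:
                    raise MatrixParseError(
                        f"{path}:{lineno}: malformed header line {line!r}")
                header[parts[0]] = parts[1].strip()
                continue
            fields = line.split()
            if len(fields) != 4:
                raise MatrixParseError(
                    f"{path}:{lineno}: expected 4 columns (A C G T), "
                    f"got {len(fields)}")
            try:
                row = [float(x) for x in fields]
            except ValueError:
                raise MatrixParseError(
                    f"{path}:{lineno}: non-numeric count in {line!r}") from None
            if any(x < 0 for x in row):
                raise MatrixParseError(
                    f"{path}:{lineno}: negative count in {line!r}")
            rows.append(row)
    for key in ("site_type", "intron_class", "exon_offset"):
        if key not in header:
            raise MatrixParseError(f"{path}: missing required header '#{key}'")
    if not rows:
        raise MatrixParseError(f"{path}: no count rows")
    try:
        site_type = SiteType(header["site_type"])
        intron_class = IntronClass(header["intron_class"])
    except ValueError as exc:
        raise MatrixParseError(f"{path}: {exc}") from None
    return FrequencyMatrix(
        site_type=site_type,
        intron_class=intron_class,
        counts=np.array(rows, dtype=float),
        exon_offset=int(header["exon_offset"]),
        species=header.get("species", "NA"),
    )


def write_matrix(m: FrequencyMatrix, path) -> None:
    """Write a frequency matrix in the flat text format (load round-trips)."""
    with open(path, "w") as fh:
        fh.write(f"#site_type {m.site_type.value}\n")
        fh.write(f"#intron_class {m.intron_class.value}\n")
        fh.write(f"#species {m.species}\n")
        fh.write(f"#exon_offset {m.exon_offset}\n")
        for row in m.counts:
            fh.write(" ".join(f"{x:g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def to_pwm(m: FrequencyMatrix, prob_floor: float = 1e-4) -> PWM:
    """Normalise counts to per-position probabilities with a floor.

    Each position is normalised to sum 1; probabilities below ``prob_floor``
    are raised to the floor and the remaining entries rescaled so each row
    still sums to 1 and no entry sits below the floor.  The floor prevents a
    single zero count from vetoing every sequence carrying that base.
    """
    totals = m.counts.sum(axis=1)
    if (totals <= 0).any():
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(f"position {bad} has zero total count")
    probs = m.counts / totals[:, None]
    if prob_floor > 0:
        if prob_floor >= 0.25:
            raise ValueError("prob_floor must be < 0.25")
        for i in range(probs.shape[0]):
            row = probs[i]
            low = row < prob_floor
            # rescale the unfloored entries so the row sums to exactly 1
            while low.any():
                free = row[~low].sum()
                row[low] = prob_floor
                row[~low] *= (1.0 - prob_floor * low.sum()) / free
                newlow = row < prob_floor
                if (newlow == low).all():
                    break
                low = newlow
            probs[i] = row
    return PWM(m.site_type, m.intron_class, probs, m.exon_offset,
               m.species, prob_floor)


def to_log_odds(
    m: FrequencyMatrix,
    pseudocount: float = 0.001,
    background: Sequence[float] | None = None,
) -> LogOddsMatrix:
    """Convert counts to log2-odds weights.

    weight[i, j] = log2(((count + pseudocount) / (total + 4*pseudocount))
                        / background[j])
    """
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any():
            raise ValueError("background must be 4 positive probabilities")
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
    totals = m.counts.sum(axis=1)
    probs = (m.counts + pseudocount) / (totals + 4 * pseudocount)[:, None]
    weights = np.log2(probs / bg)
    return LogOddsMatrix(m.site_type, m.intron_class, weights, m.exon_offset,
                         m.species, pseudocount, bg)


# ---------------------------------------------------------------------------
# Window scoring
# ---------------------------------------------------------------------------

def pwm_window_prob(pwm: PWM, window: str) -> float:
    """Product of per-position probabilities of ``window`` under ``pwm``.

    Ambiguity codes (anything outside ACGT) contribute the uniform background
    probability 0.25 — neither rewarded nor penalised.
    """
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != matrix length {pwm.length}")
    p = 1.0
    for i, base in enumerate(window.upper()):
        j = BASE_INDEX.get(base)
        p *= pwm.probs[i, j] if j is not None else 0.25
    return p


def log_odds_window_score(lom: LogOddsMatrix, window: str) -> float:
    """Sum of per-position log-odds weights; ambiguity codes score 0."""
    if len(window) != lom.length:
        raise ValueError(
            f"window length {len(window)} != matrix length {lom.length}")
    s = 0.0
    for i, base in enumerate(window.upper()):
        j = BASE_INDEX.get(base)
        if j is not None:
            s += lom.weights[i, j]
    return s


class IntronTooShortError(ValueError):
    """Intron too short to hold one full branch window inside the scan range."""


def branch_window_offsets(
    intron_len: int,
    window_len: int,
    search_range: tuple[int, int] = BRANCH_SEARCH_RANGE,
) -> list[int]:
    """Admissible branch-window start offsets, 5'-most first.

    Offsets are relative to the intron 3' end (position -1 is the last base).
    A window starting at offset *o* occupies positions ``o .. o+window_len-1``
    and must lie entirely inside ``search_range`` (both bounds inclusive) and
    must not overlap intron positions +1..+10 (the donor region).
    """
    lo, hi = search_range
    first = max(lo, DONOR_EXCLUSION - intron_len)
    last = hi - window_len + 1
    return list(range(first, last + 1)) if first <= last else []


def scan_branch_windows(
    intron: str,
    scorer,
    window_len: int,
    search_range: tuple[int, int] = BRANCH_SEARCH_RANGE,
) -> tuple[float, int]:
    """Maximum ``scorer(window)`` over admissible windows; ties go leftmost.

    Returns ``(best_score, offset)`` with the offset relative to the intron
    3' end.  Raises :class:`IntronTooShortError` when no window fits.
    """
    n = len(intron)
    offsets = branch_window_offsets(n, window_len, search_range)
    if not offsets:
        raise IntronTooShortError(
            f"intron of {n} nt too short for a {window_len} nt branch scan "
            f"in range {search_range}")
    best_score, best_off = -math.inf, offsets[0]
    for off in offsets:
        start = n + off
        window = intron[start:start + window_len]
        score = scorer(window)
        if score > best_score:
            best_score, best_off = score, off
    return best_score, best_off


# ---------------------------------------------------------------------------
# U2 branch matrix construction
# ---------------------------------------------------------------------------

def build_u2_branch_matrix(
    u2_introns: Iterable[str],
    u12_branch_pwm: PWM,
    window_len: int | None = None,
    search_range: tuple[int, int] = BRANCH_SEARCH_RANGE,
    species: str = "NA",
) -> FrequencyMatrix:
    """Build a U2 branch frequency matrix from best-scoring branch windows.

    SpliceRack carries no branch matrix for U2 GT-AG introns, so one is built
    empirically: for every U2 intron the branch window achieving the best
    score under a U12 branch PWM is taken, and the windows are tallied into a
    frequency matrix.  Each contributing intron adds exactly 1 to every
    position's column sum; ambiguous bases in a chosen window are split
    equally across the four bases so conservation holds.
    """
    if window_len is None:
        window_len = u12_branch_pwm.length
    counts = np.zeros((window_len, 4))
    n = 0
    for seq in u2_introns:
        seq = str(seq)
        _, off = scan_branch_windows(
            seq, lambda w: pwm_window_prob(u12_branch_pwm, w),
            window_len, search_range)
        start = len(seq) + off
        window = seq[start:start + window_len].upper()
        for i, base in enumerate(window):
            j = BASE_INDEX.get(base)
            if j is None:
                counts[i] += 0.25
            else:
                counts[i, j] += 1.0
        n += 1
    if n == 0:
        raise ValueError("cannot build a branch matrix from zero introns")
    return FrequencyMatrix(SiteType.BRANCH, IntronClass.U2_GTAG, counts,
                           exon_offset=0, species=species)
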