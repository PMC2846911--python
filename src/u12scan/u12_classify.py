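"""Scoring and classification of introns as U2-type or U12-type.

Two scoring schemes are implemented, following the two classical PWM
approaches to minor-intron detection:

* the *probability-ratio* ("Burge") scheme — per-intron products of PWM
  probabilities for the 5' splice site and the best branch window, expressed
  as log2 ratios U12/U2 and z-normalised over the scored sample; an intron
  qualifies as U12 when both z-scores reach the minima of a reference U12
  set (the inclusive-rectangle rule);

* the *log-odds* ("Sheth") scheme — sums of per-position log2-odds weights
  (pseudocount 0.001 against a stated background) for the 5' splice site
  under each intron class and for the best 12-nt branch window under the
  matching U12 branch matrix.

A third, matrix-free signal is the 5'-terminal consensus rule: a strong U12
intron begins RTATCCTT, where one of the Cs at positions +5/+6 may be a T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intron_discovery import (IntronCandidate, TerminalCategory,
                               classify_termini, splice_windows)
from .matrices import (BRANCH_SEARCH_RANGE, FrequencyMatrix, IntronClass,
                       LogOddsMatrix, PWM, SiteType, log_odds_window_score,
                       pwm_window_prob, scan_branch_windows, to_log_odds,
                       to_pwm)


class IntronCategory(str, Enum):
    U12_ATAC = "U12_ATAC"
    U12_GTAG = "U12_GTAG"
    U2_GCAG = "U2_GCAG"
    U2_GTAG = "U2_GTAG"
    OTHER = "OTHER"


@dataclass
class SpliceScores:
    """All probability-ratio scheme scores for one intron.

    ``s5 = log2(p5_u12 / p5_u2)`` and ``sb = log2(pb_u12 / pb_u2)``; ``z5``
    and ``zb`` are those values normalised by the scored sample's mean and
    standard deviation.  The Sheth-scheme log-odds sums ride along.
    """

    est_id: str
    termini: TerminalCategory
    p5_u12: float
    p5_u2: float
    pb_u12: float
    pb_u2: float
    s5: float = 0.0
    sb: float = 0.0
    z5: float = float("nan")
    zb: float = float("nan")
    sheth_5: float = float("nan")
    sheth_5_u2: float = float("nan")
    sheth_branch: float = float("nan")
    sheth_3: float = float("nan")


@dataclass
class ReferenceThresholds:
    """Minimum z-scores of the reference U12 set in the query sample's
    z-space; the lower-left corner of the qualifying rectangle."""

    min_z5: float
    min_zb: float


@dataclass
class Classification:
    """Final per-intron call: category plus the three method flags.

    ``burge``/``sheth`` are None when the scheme could not score the intron
    (non-canonical termini); the 5'-rule flag is defined for every intron of
    at least 8 nt.
    """

    est_id: str
    termini: TerminalCategory
    category: IntronCategory
    burge: bool | None = None
    sheth: bool | None = None
    rule: bool = False


@dataclass
class BurgeMatrices:
    """Probability matrices for the ratio scheme, keyed by intron class.

    ``five`` needs U12_GTAG, U12_ATAC and U2_GTAG entries; ``branch``
    likewise.  The U12 numerator matrix is chosen by the intron's termini
    (AT-AC introns use the AT-AC matrices, everything else GT-AG); the
    denominator is always the U2 GT-AG matrix.
    """

    five: Mapping[IntronClass, PWM]
    branch: Mapping[IntronClass, PWM]


@dataclass
class ShethMatrices:
    """Log-odds matrices for the Sheth scheme: 5' and 3' per intron class,
    plus the U12 branch matrices (GT-AG and AT-AC)."""

    five: Mapping[IntronClass, LogOddsMatrix]
    three: Mapping[IntronClass, LogOddsMatrix]
    branch: Mapping[IntronClass, LogOddsMatrix]


def matrices_from_frequencies(
    freqs: Mapping[tuple[SiteType, IntronClass], FrequencyMatrix],
    prob_floor: float = 1e-4,
    pseudocount: float = 0.001,
    background: Sequence[float] | None = None,
    u2_branch: FrequencyMatrix | None = None,
) -> tuple[BurgeMatrices, ShethMatrices]:
    """Wire a set of frequency matrices into both scoring schemes.

    The probability-ratio scheme takes floored PWMs; the log-odds scheme
    takes pseudocounted log-odds matrices.  ``u2_branch`` overrides the
    U2 branch matrix, e.g. with one built empirically from the sample's own
    U2 introns (see :func:`u12scan.matrices.build_u2_branch_matrix`).
    """
    five_p, branch_p = {}, {}
    five_lo, three_lo, branch_lo = {}, {}, {}
    for (site, cls), m in freqs.items():
        if site == SiteType.FIVE_PRIME:
            five_p[cls] = to_pwm(m, prob_floor)
            five_lo[cls] = to_log_odds(m, pseudocount, background)
        elif site == SiteType.THREE_PRIME:
            three_lo[cls] = to_log_odds(m, pseudocount, background)
        elif site == SiteType.BRANCH:
            branch_p[cls] = to_pwm(m, prob_floor)
            if cls in (IntronClass.U12_GTAG, IntronClass.U12_ATAC):
                branch_lo[cls] = to_log_odds(m, pseudocount, background)
    if u2_branch is not None:
        branch_p[IntronClass.U2_GTAG] = to_pwm(u2_branch, prob_floor)
    return (BurgeMatrices(five_p, branch_p),
            ShethMatrices(five_lo, three_lo, branch_lo))


def classify_all(introns: Sequence[IntronCandidate],
                 burge_matrices: BurgeMatrices,
                 sheth_matrices: ShethMatrices,
                 reference: Sequence[IntronCandidate] | None = None,
                 min_5: float = 0.0, min_branch: float = 0.0
                 ) -> tuple[list[Classification], list[SpliceScores]]:
    """Run both schemes plus the 5' rule over a set of introns.

    When no reference set is given the packaged reproducible one (20 introns
    sampled from the U12 generator PWMs with a fixed seed) calibrates the
    probability-ratio thresholds.  Returns the classifications and the full
    per-intron score records.
    """
    scores = burge_scores(introns, burge_matrices)
    if reference is None:
        from .synthetic_data import make_reference_introns
        reference = make_reference_introns()
    ref = reference_thresholds(reference, burge_matrices, scores)
    b_flags = burge_classify(scores, ref)
    classes = sheth_classify(introns, sheth_matrices, min_5, min_branch,
                             scores=scores)
    for cls, b in zip(classes, b_flags):
        cls.burge = None if cls.termini == TerminalCategory.OTHER else b
    return classes, scores


# ---------------------------------------------------------------------------
# Elementary scores
# ---------------------------------------------------------------------------

def score_5ss(window: str, pwm: PWM) -> float:
    """Product of per-position PWM probabilities over a 5'ss window."""
    return pwm_window_prob(pwm, window)


def score_branch_max(intron: str, pwm: PWM, window_len: int | None = None,
                     search_range: tuple[int, int] = BRANCH_SEARCH_RANGE
                     ) -> dict:
    """Best branch-window probability in the scan range upstream of the
    3' splice site; ties go to the leftmost window.

    Returns ``{"prob": p, "offset": o}`` with the offset relative to the
    intron's 3' end.  The window length defaults to the PWM's length.
    """
    if window_len is None:
        window_len = pwm.length
    prob, offset = scan_branch_windows(
        intron, lambda w: pwm_window_prob(pwm, w), window_len, search_range)
    return {"prob": prob, "offset": offset}


def _u12_class_for(termini: TerminalCategory) -> IntronClass:
    return (IntronClass.U12_ATAC if termini == TerminalCategory.AT_AC
            else IntronClass.U12_GTAG)


# ---------------------------------------------------------------------------
# Probability-ratio (Burge) scheme
# ---------------------------------------------------------------------------

def burge_scores(introns: Sequence[IntronCandidate],
                 matrices: BurgeMatrices) -> list[SpliceScores]:
    """Score every intron and z-normalise over the sample.

    ``z5`` and ``zb`` subtract the sample mean and divide by the sample
    standard deviation of ``s5``/``sb`` across the scored set, so they are
    comparable regardless of the matrices' absolute scale.
    """
    scores: list[SpliceScores] = []
    for c in introns:
        termini = classify_termini(c)
        u12 = _u12_class_for(termini)
        w5, _ = splice_windows(c)
        p5_u12 = score_5ss(w5, matrices.five[u12])
        p5_u2 = score_5ss(w5, matrices.five[IntronClass.U2_GTAG])
        pb_u12 = score_branch_max(c.sequence, matrices.branch[u12])["prob"]
        pb_u2 = score_branch_max(
            c.sequence, matrices.branch[IntronClass.U2_GTAG])["prob"]
        s = SpliceScores(c.est_id, termini, p5_u12, p5_u2, pb_u12, pb_u2)
        s.s5 = float(np.log2(p5_u12 / p5_u2))
        s.sb = float(np.log2(pb_u12 / pb_u2))
        scores.append(s)
    _z_normalize(scores)
    return scores


def sample_stats(scores: Sequence[SpliceScores]) -> tuple[float, float, float, float]:
    """(mean_s5, sd_s5, mean_sb, sd_sb) of a scored sample."""
    s5 = np.array([s.s5 for s in scores])
    sb = np.array([s.sb for s in scores])
    m5, d5 = float(s5.mean()), float(s5.std())
    mb, db = float(sb.mean()), float(sb.std())
    if d5 == 0.0 or db == 0.0:
        raise ValueError("sample standard deviation is zero; "
                         "z-scores are undefined")
    return m5, d5, mb, db


def _z_normalize(scores: Sequence[SpliceScores]) -> None:
    m5, d5, mb, db = sample_stats(scores)
    for s in scores:
        s.z5 = (s.s5 - m5) / d5
        s.zb = (s.sb - mb) / db


def reference_thresholds(reference: Sequence[IntronCandidate],
                         matrices: BurgeMatrices,
                         sample: Sequence[SpliceScores]
                         ) -> ReferenceThresholds:
    """Score a reference U12 set with the same matrices and place it in the
    query sample's z-space; the reference minima are the U12 thresholds."""
    if len(reference) < 2:
        raise ValueError("reference set needs at least 2 introns")
    m5, d5, mb, db = sample_stats(sample)
    ref_raw: list[tuple[float, float]] = []
    for c in reference:
        termini = classify_termini(c)
        u12 = _u12_class_for(termini)
        w5, _ = splice_windows(c)
        s5 = np.log2(score_5ss(w5, matrices.five[u12])
                     / score_5ss(w5, matrices.five[IntronClass.U2_GTAG]))
        sb = np.log2(
            score_branch_max(c.sequence, matrices.branch[u12])["prob"]
            / score_branch_max(c.sequence,
                               matrices.branch[IntronClass.U2_GTAG])["prob"])
        ref_raw.append((float(s5), float(sb)))
    return ReferenceThresholds(
        min_z5=min((s5 - m5) / d5 for s5, _ in ref_raw),
        min_zb=min((sb - mb) / db for _, sb in ref_raw),
    )


def burge_classify(scores: Sequence[SpliceScores],
                   ref: ReferenceThresholds) -> list[bool]:
    """B flag per intron: inside the qualifying rectangle, inclusively.

    An intron qualifies as U12 when both its 5'ss and branch z-scores are at
    least the corresponding minima of the reference U12 set.
    """
    if ref is None:
        raise ValueError("reference thresholds are required")
    return [(s.z5 >= ref.min_z5) and (s.zb >= ref.min_zb) for s in scores]


# ---------------------------------------------------------------------------
# Log-odds (Sheth) scheme
# ---------------------------------------------------------------------------

SHETH_BRANCH_LEN = 12


def sheth_classify(introns: Sequence[IntronCandidate],
                   matrices: ShethMatrices,
                   min_5: float = 0.0, min_branch: float = 0.0,
                   scores: Sequence[SpliceScores] | None = None
                   ) -> list[Classification]:
    """Assign categories with the log-odds scheme.

    Per intron: the 13-nt 5' window is scored under each class's log-odds
    matrix and the best 12-nt branch window under the U12 branch matrix
    matching the termini.  S is true iff the U12 5'ss score exceeds the
    competing U2-class score and both the U12 5'ss and branch scores reach
    their configured minima.  Introns with non-canonical termini are
    reported OTHER and left unscored (S = None).

    When a parallel ``scores`` list is given, the Sheth score fields of each
    entry are filled in.
    """
    out: list[Classification] = []
    for idx, c in enumerate(introns):
        termini = classify_termini(c)
        rule = five_prime_rule(c.sequence) if c.length >= 8 else False
        if termini == TerminalCategory.OTHER:
            out.append(Classification(c.est_id, termini,
                                      IntronCategory.OTHER, sheth=None,
                                      rule=rule))
            continue
        u12 = _u12_class_for(termini)
        # GC-AG introns are scored with the GT-AG matrices; the 2nd-position
        # mismatch is absorbed by the pseudocount.
        u2 = (IntronClass.U2_GCAG if termini == TerminalCategory.GC_AG
              else IntronClass.U2_GTAG)
        if u12 not in matrices.five or u2 not in matrices.five:
            out.append(Classification(c.est_id, termini,
                                      IntronCategory.OTHER, sheth=None,
                                      rule=rule))
            continue
        w5, w3 = splice_windows(c)
        s5_u12 = log_odds_window_score(matrices.five[u12], w5)
        s5_u2 = log_odds_window_score(matrices.five[u2], w5)
        s3 = log_odds_window_score(matrices.three[u12], w3) \
            if u12 in matrices.three else float("nan")
        lom = matrices.branch[u12]
        sb, _ = scan_branch_windows(
            c.sequence, lambda w: log_odds_window_score(lom, w),
            SHETH_BRANCH_LEN)
        s_flag = bool((s5_u12 > s5_u2) and (s5_u12 >= min_5)
                      and (sb >= min_branch))
        if s_flag:
            category = (IntronCategory.U12_ATAC
                        if termini == TerminalCategory.AT_AC
                        else IntronCategory.U12_GTAG)
        elif termini == TerminalCategory.GT_AG:
            category = IntronCategory.U2_GTAG
        elif termini == TerminalCategory.GC_AG:
            category = IntronCategory.U2_GCAG
        else:  # AT-AC termini not qualifying as U12
            category = IntronCategory.OTHER
        out.append(Classification(c.est_id, termini, category, sheth=s_flag,
                                  rule=rule))
        if scores is not None:
            scores[idx].sheth_5 = s5_u12
            scores[idx].sheth_5_u2 = s5_u2
            scores[idx].sheth_branch = sb
            scores[idx].sheth_3 = s3
    return out


# ---------------------------------------------------------------------------
# 5'-terminal consensus rule
# ---------------------------------------------------------------------------

def five_prime_rule(intron: str) -> bool:
    """R flag: does the intron begin with the relaxed RTATCCTT consensus?

    Positions +1..+8 must read R T A T C C T T, where one (but not both) of
    the Cs at +5 and +6 may be replaced by a T.
    """
    seq = str(intron).upper()
    if len(seq) < 8:
        raise ValueError("intron shorter than 8 nt; 5' rule undefined")
    return (seq[0] in "AG" and seq[1] == "T" and seq[2] == "A"
            and seq[3] == "T" and seq[4:6] in ("CC", "CT", "TC")
            and seq[6] == "T" and seq[7] == "T")


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

_SUMMARY_ROWS = ["U12_ATAC", "U12_GTAG", "U2_GCAG", "U2_GTAG", "OTHER"]


def _category_for_method(termini: TerminalCategory,
                         flag: bool | None) -> str | None:
    if flag is None:
        return "OTHER" if termini == TerminalCategory.OTHER else None
    if flag:
        return ("U12_ATAC" if termini == TerminalCategory.AT_AC
                else "U12_GTAG")
    return {TerminalCategory.GT_AG: "U2_GTAG",
            TerminalCategory.GC_AG: "U2_GCAG",
            TerminalCategory.AT_AC: "OTHER",
            TerminalCategory.OTHER: "OTHER"}[termini]


def summarize_counts(classified: Sequence[Classification]) -> pd.DataFrame:
    """Per-category counts for each method, with the 5'-rule parenthetical.

    Rows are the five categories; columns ``B``/``S`` count introns the
    respective method places in that category, and ``B_rule``/``S_rule``
    count how many of those additionally conform to the 5'-terminal
    consensus rule (reported in parentheses for U12 categories).
    """
    table = pd.DataFrame(0, index=_SUMMARY_ROWS,
                         columns=["B", "B_rule", "S", "S_rule"])
    for c in classified:
        for method, flag in (("B", c.burge), ("S", c.sheth)):
            cat = _category_for_method(c.termini, flag)
            if cat is None:
                continue
            table.loc[cat, method] += 1
            if c.rule:
                table.loc[cat, f"{method}_rule"] += 1
    return table


def format_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Render the summary the way the per-species tallies are printed:
    U12 rows as ``count (rule-conforming)``, other rows as plain counts."""
    out = pd.DataFrame(index=table.index, columns=["B", "S"], dtype=object)
    for row in table.index:
        for method in ("B", "S"):
            n = int(table.loc[row, method])
            if row.startswith("U12"):
                out.loc[row, method] = f"{n} ({int(table.loc[row, f'{method}_rule'])})"
            else:
                out.loc[row, method] = str(n)
    return out
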