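"""Both scoring schemes, the 5'-terminal rule, and the summary table."""

import numpy as np
import pytest

from u12scan.intron_discovery import IntronCandidate, TerminalCategory
from u12scan.matrices import IntronClass, PWM, SiteType
from u12scan.synthetic_data import (GeneratorConfig, _make_intron,
                                    make_reference_introns)
from u12scan.u12_classify import (Classification, IntronCategory,
                                  ReferenceThresholds, SpliceScores,
                                  burge_classify, burge_scores, classify_all,
                                  five_prime_rule, reference_thresholds,
                                  score_5ss, score_branch_max, sheth_classify,
                                  summarize_counts)


def _candidate(seq, est_id="e", exon5="AAA", exon3="TTT"):
    return IntronCandidate("c", 0, len(seq), seq, seq[:2], seq[-2:],
                           exon5, exon3, est_id)


def _make_candidates(label, n, seed, cfg=None):
    rng = np.random.default_rng(seed)
    cfg = cfg or GeneratorConfig()
    out = []
    for i in range(n):
        seq, tail, head, _ = _make_intron(label, cfg, rng)
        out.append(IntronCandidate("c", 0, len(seq), seq, seq[:2], seq[-2:],
                                   tail, head, f"{label}{i}"))
    return out


class TestScore5ss:
    def test_one_hot_consensus_scores_one(self):
        motif = "AAGGTATCCTTTC"
        probs = np.zeros((13, 4))
        for i, b in enumerate(motif):
            probs[i, "ACGT".index(b)] = 1.0
        assert score_5ss(motif, PWM(SiteType.FIVE_PRIME,
                                    IntronClass.U12_GTAG, probs)) == 1.0

    def test_uniform_pwm(self):
        pwm = PWM(SiteType.FIVE_PRIME, IntronClass.U2_GTAG,
                  np.full((13, 4), 0.25))
        assert score_5ss("GTATCCTTTCAGT", pwm) == pytest.approx(0.25 ** 13)

    def test_direct_product(self):
        probs = np.tile([0.5, 0.3, 0.2, 0.0], (3, 1))
        pwm = PWM(SiteType.FIVE_PRIME, IntronClass.U2_GTAG, probs)
        assert score_5ss("ACG", pwm) == pytest.approx(0.5 * 0.3 * 0.2)

    def test_length_mismatch_rejected(self):
        pwm = PWM(SiteType.FIVE_PRIME, IntronClass.U2_GTAG,
                  np.full((13, 4), 0.25))
        with pytest.raises(ValueError, match="length"):
            score_5ss("ACGT", pwm)


class TestScoreBranchMax:
    def test_planted_one_hot_motif_found(self, rng):
        motif = "TCCTTAACTGTC"
        probs = np.zeros((12, 4))
        for i, b in enumerate(motif):
            probs[i, "ACGT".index(b)] = 1.0
        pwm = PWM(SiteType.BRANCH, IntronClass.U12_GTAG, probs)
        seq = list("ACGT" * 25)
        seq[100 - 20:100 - 20 + 12] = motif
        res = score_branch_max("".join(seq), pwm)
        assert res == {"prob": 1.0, "offset": -20}

    def test_matches_brute_force_scan(self, rng):
        for _ in range(30):
            pwm = PWM(SiteType.BRANCH, IntronClass.U12_GTAG,
                      rng.dirichlet(np.ones(4), size=12))
            n = int(rng.integers(40, 200))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            res = score_branch_max(seq, pwm)
            best = None
            for off in range(max(-40, 10 - n), -15):
                w = seq[n + off:n + off + 12]
                p = 1.0
                for i, b in enumerate(w):
                    p *= pwm.probs[i, "ACGT".index(b)]
                if best is None or p > best[0]:
                    best = (p, off)
            assert res["offset"] == best[1]
            assert res["prob"] == pytest.approx(best[0])

    def test_short_intron_raises(self):
        pwm = PWM(SiteType.BRANCH, IntronClass.U12_GTAG,
                  np.full((12, 4), 0.25))
        with pytest.raises(ValueError, match="too short"):
            score_branch_max("GTAAGTTTTTTTTTTTTTTTAG", pwm)


class TestBurgeScheme:
    def test_z_scores_are_standardised(self, scheme_matrices):
        burge_m, _ = scheme_matrices
        cands = _make_candidates("U2_GTAG", 40, seed=3)
        scores = burge_scores(cands, burge_m)
        z5 = np.array([s.z5 for s in scores])
        zb = np.array([s.zb for s in scores])
        assert abs(z5.mean()) < 1e-9 and abs(z5.std() - 1) < 1e-9
        assert abs(zb.mean()) < 1e-9 and abs(zb.std() - 1) < 1e-9

    def test_equal_probabilities_give_zero_log_ratio(self):
        # U12 and U2 matrices agree on base C at +1 and are uniform
        # elsewhere: a window starting with C has p5_u12 == p5_u2 -> s5 = 0
        from u12scan.u12_classify import BurgeMatrices

        p_u12 = np.full((13, 4), 0.25)
        p_u2 = np.full((13, 4), 0.25)
        p_u12[3] = [0.5, 0.1, 0.3, 0.1]
        p_u2[3] = [0.3, 0.1, 0.5, 0.1]
        five = {cls: PWM(SiteType.FIVE_PRIME, cls, p)
                for cls, p in [(IntronClass.U12_GTAG, p_u12),
                               (IntronClass.U12_ATAC, p_u12),
                               (IntronClass.U2_GTAG, p_u2)]}
        ub = PWM(SiteType.BRANCH, IntronClass.U12_GTAG,
                 np.tile(np.array([[0.4, 0.2, 0.2, 0.2]]), (12, 1)))
        u2b = PWM(SiteType.BRANCH, IntronClass.U2_GTAG,
                  np.tile(np.array([[0.2, 0.4, 0.2, 0.2]]), (12, 1)))
        mats = BurgeMatrices(five, {IntronClass.U12_GTAG: ub,
                                    IntronClass.U12_ATAC: ub,
                                    IntronClass.U2_GTAG: u2b})
        cands = [_candidate("CT" + "A" * 70 + "AG"),
                 _candidate("AT" + "C" * 70 + "AG"),
                 _candidate("GT" + "G" * 70 + "AG")]
        scores = burge_scores(cands, mats)
        assert scores[0].s5 == pytest.approx(0.0)   # C at +1: equal matrices
        assert scores[1].s5 != pytest.approx(0.0)

    def test_zero_sample_variance_rejected(self):
        # identical matrices for numerator and denominator make every raw
        # score zero, so z-normalisation is undefined
        from u12scan.u12_classify import BurgeMatrices

        uniform = PWM(SiteType.FIVE_PRIME, IntronClass.U12_GTAG,
                      np.full((13, 4), 0.25))
        ub = PWM(SiteType.BRANCH, IntronClass.U12_GTAG,
                 np.full((12, 4), 0.25))
        mats = BurgeMatrices(
            {IntronClass.U12_GTAG: uniform, IntronClass.U12_ATAC: uniform,
             IntronClass.U2_GTAG: uniform},
            {IntronClass.U12_GTAG: ub, IntronClass.U12_ATAC: ub,
             IntronClass.U2_GTAG: ub})
        cands = _make_candidates("U2_GTAG", 3, seed=4)
        with pytest.raises(ValueError, match="standard deviation"):
            burge_scores(cands, mats)

    def test_planted_u12_introns_dominate_scores(self, scheme_matrices):
        burge_m, _ = scheme_matrices
        cands = _make_candidates("U2_GTAG", 200, seed=6)
        cands.extend(_make_candidates("U12_GTAG", 5, seed=7))
        scores = burge_scores(cands, burge_m)
        ranked = sorted(scores, key=lambda s: s.z5 + s.zb, reverse=True)
        top_ids = {s.est_id for s in ranked[:5]}
        assert top_ids == {f"U12_GTAG{i}" for i in range(5)}

    def test_rectangle_rule_is_inclusive(self):
        ref = ReferenceThresholds(min_z5=1.0, min_zb=2.0)

        def fake(z5, zb):
            s = SpliceScores("e", TerminalCategory.GT_AG, 1, 1, 1, 1)
            s.z5, s.zb = z5, zb
            return s

        flags = burge_classify([fake(1.0, 2.0), fake(1.5, 1.99),
                                fake(0.99, 5.0)], ref)
        assert flags == [True, False, False]

    def test_reference_thresholds_in_sample_z_space(self, scheme_matrices):
        burge_m, _ = scheme_matrices
        sample = burge_scores(_make_candidates("U2_GTAG", 50, seed=8)
                              + _make_candidates("U12_GTAG", 10, seed=9),
                              burge_m)
        ref = reference_thresholds(make_reference_introns(), burge_m, sample)
        # thresholds sit far above the bulk U2 scores
        u2_z5 = [s.z5 for s in sample if s.est_id.startswith("U2")]
        assert ref.min_z5 > np.median(u2_z5)


class TestShethScheme:
    def test_consensus_intron_flagged_u12(self, scheme_matrices):
        _, sheth_m = scheme_matrices
        seq = "GTATCCTTTC" + "A" * 40 + "TTCCTTAACTGA" + "T" * 10 + "TTAG"
        cl = sheth_classify([_candidate(seq)], sheth_m)
        assert cl[0].sheth is True
        assert cl[0].category == IntronCategory.U12_GTAG

    def test_u2_introns_rarely_misflagged(self, scheme_matrices):
        _, sheth_m = scheme_matrices
        cands = _make_candidates("U2_GTAG", 300, seed=10)
        cl = sheth_classify(cands, sheth_m)
        false_pos = sum(bool(c.sheth) for c in cl)
        assert false_pos / 300 <= 0.01

    def test_non_canonical_termini_reported_other(self, scheme_matrices):
        _, sheth_m = scheme_matrices
        cl = sheth_classify([_candidate("CT" + "A" * 60 + "AG" + "T" * 10)],
                            sheth_m)
        assert cl[0].category == IntronCategory.OTHER
        assert cl[0].sheth is None

    def test_monotone_in_u12_probability(self, scheme_matrices):
        # raising the U12 matrix probability of an observed base never
        # lowers the intron's log ratio s5
        burge_m, _ = scheme_matrices
        cands = _make_candidates("U12_GTAG", 5, seed=12)
        base = burge_scores(cands, burge_m)
        boosted = {k: v for k, v in burge_m.five.items()}
        import copy

        pwm = copy.deepcopy(boosted[IntronClass.U12_GTAG])
        for c in cands:
            w5 = c.exon5_context + c.sequence[:10]
            for i, b in enumerate(w5):
                pwm.probs[i, "ACGT".index(b)] += 0.05
        boosted[IntronClass.U12_GTAG] = pwm
        from u12scan.u12_classify import BurgeMatrices

        up = burge_scores(cands, BurgeMatrices(boosted, burge_m.branch))
        for s0, s1 in zip(base, up):
            assert s1.s5 >= s0.s5


class TestFivePrimeRule:
    @pytest.mark.parametrize("seq,expected", [
        ("ATATCCTTTC", True),    # canonical AT-AC U12 opening
        ("GTATTGTTTT", False),   # +5/+6 TG not allowed
        ("GTATCTTTTC", True),    # one C->T substitution allowed
        ("GTATTTTTTT", False),   # both Cs replaced
        ("CTATCCTTTC", False),   # +1 must be purine
    ])
    def test_rule(self, seq, expected):
        assert five_prime_rule(seq) is expected

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            five_prime_rule("GTATCCT")

    def test_reproduces_table1_r_column(self, table1, table1_candidates):
        got = [five_prime_rule(c.sequence) for c in table1_candidates]
        expected = [flag == "+" for flag in table1.rule]
        assert got == expected


class TestSummarizeCounts:
    def test_table1_sheth_counts(self, table1, table1_candidates):
        # all 16 candidates are Sheth-positive U12 calls; the printed
        # per-species tally reads AT-AC 3 (3) and GT-AG 13 (8)
        from u12scan.intron_discovery import classify_termini

        classes = []
        for c, rule_flag in zip(table1_candidates, table1.rule):
            termini = classify_termini(c)
            cat = (IntronCategory.U12_ATAC
                   if termini == TerminalCategory.AT_AC
                   else IntronCategory.U12_GTAG)
            classes.append(Classification(c.est_id, termini, cat, sheth=True,
                                          rule=rule_flag == "+"))
        table = summarize_counts(classes)
        assert table.loc["U12_ATAC", "S"] == 3
        assert table.loc["U12_ATAC", "S_rule"] == 3
        assert table.loc["U12_GTAG", "S"] == 13
        assert table.loc["U12_GTAG", "S_rule"] == 8

    def test_empty_gives_zero_table(self):
        assert (summarize_counts([]).to_numpy() == 0).all()

    def test_synthetic_counts_match_truth(self, scheme_matrices):
        burge_m, sheth_m = scheme_matrices
        cands = (_make_candidates("U2_GTAG", 120, seed=21)
                 + _make_candidates("U12_GTAG", 60, seed=22)
                 + _make_candidates("U12_ATAC", 60, seed=23))
        classes, _ = classify_all(cands, burge_m, sheth_m)
        table = summarize_counts(classes)
        # Sheth assignments track the planted classes at the >=95% level
        assert table.loc["U12_GTAG", "S"] >= 57
        assert table.loc["U12_ATAC", "S"] >= 57
        assert table.loc["U2_GTAG", "S"] >= 114
        # and the marginals account for every intron
        assert table["S"].sum() == 240
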