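import math

import numpy as np
import pytest
from scipy.stats import binom

from peakshift.io_genomics import PWM, pwm_from_consensus
from peakshift.motif_analysis import (
    QUADRANTS,
    best_site,
    central_enrichment,
    motif_prevalence,
    scan_pwm,
    spacing_analysis,
)

from conftest import random_background

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def oracle_scan(seq: str, pwm: PWM):
    """Independent per-position recomputation of log-odds scores."""
    L = len(pwm)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    scores = {}
    for off in range(len(seq) - L + 1):
        for strand in "+-":
            window = seq[off : off + L]
            if strand == "-":
                window = revcomp(window)
            s = 0.0
            for i, base in enumerate(window):
                if base in idx:
                    s += math.log(pwm.matrix[i, idx[base]] / pwm.background[idx[base]])
            scores[(off, strand)] = s
    return scores


class TestScanPWM:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = PWM("u", np.full((4, 4), 0.25))
        hits = scan_pwm("ACGTACGTACG", pwm)
        assert hits and all(h.score == pytest.approx(0.0) for h in hits)

    def test_consensus_score_closed_form(self):
        # deterministic PWM without pseudocount: consensus scores sum ln(1/bg)
        pwm = pwm_from_consensus("x", "ACGT", match_prob=1.0, pseudocount=0.0)
        hit = best_site("ACGT", pwm)
        assert hit.score == pytest.approx(4 * math.log(4))
        assert hit.score == pytest.approx(pwm.max_score)

    def test_reverse_complement_symmetry(self, motifs):
        rng = np.random.default_rng(0)
        seq = random_background(rng, 80)
        pwm = motifs["CTCF"]
        best_f = best_site(seq, pwm)
        best_r = best_site(revcomp(seq), pwm)
        assert best_f.score == pytest.approx(best_r.score)
        assert best_f.strand != best_r.strand or best_f.score == pytest.approx(
            best_site(seq, pwm).score
        )

    def test_too_short_sequence_gives_empty_scan(self, motifs):
        assert scan_pwm("ACG", motifs["CTCF"]) == []

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_independent_recomputation(self, motifs, seed):
        rng = np.random.default_rng(seed)
        seq = random_background(rng, 30)
        pwm = motifs["GAS"]
        expected = oracle_scan(seq, pwm)
        for hit in scan_pwm(seq, pwm):
            assert hit.score == pytest.approx(expected[(hit.offset, hit.strand)])

    def test_n_bases_contribute_zero(self, motifs):
        pwm = motifs["GAS"]
        all_n = "N" * len(pwm)
        (fh, rh) = scan_pwm(all_n, pwm)
        assert fh.score == 0.0 and rh.score == 0.0


class TestBestSite:
    def test_planted_consensus_recovered(self, motifs):
        rng = np.random.default_rng(4)
        pwm = motifs["CTCF"]
        for _ in range(10):
            seq = list(random_background(rng, 200))
            off = int(rng.integers(0, 200 - len(pwm)))
            seq[off : off + len(pwm)] = pwm.consensus
            hit = best_site("".join(seq), pwm)
            assert (hit.offset, hit.strand) == (off, "+")

    def test_tie_broken_by_smaller_offset(self, motifs):
        pwm = pwm_from_consensus("x", "ACGTAC")
        seq = "TTT" + "ACGTAC" + "TTT" + "ACGTAC" + "TTT"
        hit = best_site(seq, pwm)
        assert hit.offset == 3

    def test_palindrome_reports_plus_strand(self):
        pwm = pwm_from_consensus("pal", "ACGCGT")  # reverse complement of itself
        seq = "TTTACGCGTTTT"
        hit = best_site(seq, pwm)
        assert hit.strand == "+"

    def test_all_n_sequence_reports_origin(self, motifs):
        hit = best_site("N" * 50, motifs["GAS"])
        assert (hit.offset, hit.strand, hit.score) == (0, "+", 0.0)


class TestPrevalence:
    def test_all_consensus_sequences(self, motifs):
        pwm = motifs["GAS"]
        seqs = ["TT" + pwm.consensus + "GG"] * 10
        assert motif_prevalence(seqs, pwm) == 1.0

    def test_strict_fraction_without_consensus(self, motifs):
        rng = np.random.default_rng(8)
        seqs = [random_background(rng, 60) for _ in range(20)]
        assert motif_prevalence(seqs, motifs["CTCF"], score_fraction=1.0) == 0.0

    def test_planted_fraction_recovered(self, motifs):
        # 200 sequences, 60 carry the consensus; the CTCF PWM is long enough
        # that background never reaches 80% of the maximum score
        rng = np.random.default_rng(15)
        pwm = motifs["CTCF"]
        seqs = []
        for i in range(200):
            s = list(random_background(rng, 100))
            if i < 60:
                off = int(rng.integers(0, 100 - len(pwm)))
                s[off : off + len(pwm)] = pwm.consensus
            seqs.append("".join(s))
        assert motif_prevalence(seqs, pwm) == pytest.approx(0.30)

    def test_invalid_score_fraction(self, motifs):
        with pytest.raises(ValueError):
            motif_prevalence(["ACGT"], motifs["GAS"], score_fraction=0.0)


class TestCentralEnrichment:
    def test_all_central_matches_exact_binomial(self, motifs):
        # the long CTCF motif guarantees no competing background consensus
        pwm = motifs["CTCF"]
        L = len(pwm)
        rng = np.random.default_rng(23)
        n, seq_len = 100, 400
        off = (seq_len - L) // 2
        seqs = []
        for _ in range(n):
            s = list(random_background(rng, seq_len))
            s[off : off + L] = pwm.consensus
            seqs.append("".join(s))
        res = central_enrichment(seqs, pwm)
        # exact oracle: all n centers fall in every window; smallest window wins
        grid = res.halfwidths_tested
        mid = seq_len / 2
        centers = np.arange(seq_len - L + 1) + L / 2
        best = min(
            binom.sf(n - 1, n, np.mean(np.abs(centers - mid) <= h))
            for h in grid
        )
        assert res.hits_in_window == n
        assert res.p_value == pytest.approx(min(1.0, best * len(grid)), rel=1e-9)
        assert res.p_value < 1e-10

    def test_single_sequence_probability_equals_window_mass(self, motifs):
        pwm = motifs["GAS"]
        L = len(pwm)
        seq = "T" * 45 + pwm.consensus + "T" * (100 - 45 - L)
        res = central_enrichment([seq], pwm, halfwidths=[10])
        centers = np.arange(100 - L + 1) + L / 2
        pi = np.mean(np.abs(centers - 50) <= 10)
        if res.hits_in_window == 1:
            assert res.p_value == pytest.approx(pi)
        else:
            assert res.p_value == pytest.approx(1.0)

    def test_unequal_lengths_rejected(self, motifs):
        with pytest.raises(ValueError, match="equal length"):
            central_enrichment(["A" * 50, "A" * 60], motifs["GAS"])

    def test_shuffle_invariance(self, motifs):
        rng = np.random.default_rng(31)
        pwm = motifs["GAS"]
        seqs = [random_background(rng, 200) for _ in range(40)]
        res1 = central_enrichment(seqs, pwm)
        rng.shuffle(seqs)
        res2 = central_enrichment(seqs, pwm)
        assert res1.p_value == res2.p_value
        assert res1.best_halfwidth == res2.best_halfwidth

    def test_uniform_null_is_conservative(self, motifs):
        # plant the consensus at a uniform random offset: the best-site
        # center is then uniform over all possible centers, which is
        # exactly the binomial null; Bonferroni keeps rejections rare
        rng = np.random.default_rng(37)
        pwm = motifs["GAS"]
        L = len(pwm)
        n_reps, n_seq, seq_len = 100, 50, 200
        rejections = 0
        for _ in range(n_reps):
            seqs = []
            for _ in range(n_seq):
                s = list(random_background(rng, seq_len))
                off = int(rng.integers(0, seq_len - L + 1))
                s[off : off + L] = pwm.consensus
                seqs.append("".join(s))
            if central_enrichment(seqs, pwm).p_value < 0.05:
                rejections += 1
        # true rate <= 0.05; allow binomial sampling slack at 100 replicates
        assert rejections <= 10


class TestSpacing:
    def _planted(self, motifs, n, gap, seq_len=400, seed=51):
        rng = np.random.default_rng(seed)
        p, s = motifs["CTCF"], motifs["ETS"]
        seqs = []
        anchor_off = (seq_len - (len(p) + gap + len(s))) // 2
        for _ in range(n):
            seq = list(random_background(rng, seq_len))
            seq[anchor_off : anchor_off + len(p)] = p.consensus
            soff = anchor_off + len(p) + gap
            seq[soff : soff + len(s)] = s.consensus
            seqs.append("".join(seq))
        return seqs

    def test_planted_gap_matches_exact_binomial(self, motifs):
        n, gap = 50, 7
        seqs = self._planted(motifs, n, gap)
        res = spacing_analysis(seqs, motifs["CTCF"], motifs["ETS"])
        assert res.best_gap == gap
        assert res.best_quadrant == "same-strand/right"
        n_cells = 4 * (res.max_gap + 1)
        expected = min(
            1.0,
            binom.sf(res.best_count - 1, res.n_anchored, 1 / n_cells) * n_cells,
        )
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert res.p_value < 1e-10

    def test_abutting_sites_give_gap_zero(self, motifs):
        seqs = self._planted(motifs, 30, 0, seed=52)
        res = spacing_analysis(seqs, motifs["CTCF"], motifs["ETS"])
        assert res.best_gap == 0
        assert res.best_quadrant == "same-strand/right"

    def test_histogram_counts_anchored_sequences(self, motifs):
        seqs = self._planted(motifs, 25, 7)
        res = spacing_analysis(seqs, motifs["CTCF"], motifs["ETS"])
        total = sum(int(h.sum()) for h in res.gap_histogram.values())
        assert total == res.n_anchored
        assert res.n_anchored + res.n_dropped == 25

    def test_null_background_is_not_significant(self, motifs):
        rng = np.random.default_rng(61)
        seqs = []
        p = motifs["CTCF"]
        for _ in range(30):
            s = list(random_background(rng, 400))
            off = int(rng.integers(170, 210))
            s[off : off + len(p)] = p.consensus
            seqs.append("".join(s))
        res = spacing_analysis(seqs, p, motifs["ETS"])
        assert res.p_value > 0.2

    def test_shuffle_invariance(self, motifs):
        seqs = self._planted(motifs, 20, 12, seed=53)
        res1 = spacing_analysis(seqs, motifs["CTCF"], motifs["ETS"])
        res2 = spacing_analysis(seqs[::-1], motifs["CTCF"], motifs["ETS"])
        assert res1.p_value == res2.p_value
        assert res1.best_gap == res2.best_gap

    def test_edge_anchors_are_dropped(self, motifs):
        p, s = motifs["CTCF"], motifs["ETS"]
        seq = p.consensus + "A" * (400 - len(p))  # anchor flush left
        with pytest.raises(ValueError, match="anchor"):
            spacing_analysis([seq], p, s)

    def test_quadrants_cover_both_sides_and_strands(self, motifs):
        # plant the secondary on the left, opposite strand
        rng = np.random.default_rng(55)
        p, s = motifs["CTCF"], motifs["ETS"]
        seqs = []
        for _ in range(20):
            seq = list(random_background(rng, 400))
            a = 200
            seq[a : a + len(p)] = p.consensus
            rc = s.consensus.translate(COMP)[::-1]
            soff = a - 5 - len(s)
            seq[soff : soff + len(s)] = rc
            seqs.append("".join(seq))
        res = spacing_analysis(seqs, p, s)
        assert res.best_gap == 5
        assert res.best_quadrant == "opposite/left"
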