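"""Motif scanning: normalized scores, strand symmetry, calibration against
exhaustive oracles, shuffle e-values and low-complexity masking."""

import itertools
import math

import numpy as np
import pytest

from gctmir.io_core import MotifMatrix, SequenceRecord, reverse_complement
from gctmir.motif_scan import (Background, calibrate_threshold,
                               empirical_evalue, estimate_background,
                               expected_bin_probabilities, mask_low_complexity,
                               normalized_bit_score, scan_sequence)
from gctmir.synthetic_data import simulate_promoter


def uniform_motif(length=4):
    return MotifMatrix("U", np.full((length, 4), 0.25))


class TestNormalizedBitScore:
    def test_consensus_scores_zero(self, rng):
        m = MotifMatrix.from_counts("m", rng.integers(1, 100, size=(7, 4)))
        assert normalized_bit_score(m, m.consensus) == pytest.approx(0.0)

    def test_non_consensus_scores_negative(self, rng):
        m = MotifMatrix.from_counts("m", np.diag([9, 9, 9, 9])[:3])
        assert normalized_bit_score(m, "TTT") < 0

    def test_uniform_motif_scores_every_word_zero(self):
        m = uniform_motif(3)
        for word in itertools.product("ACGT", repeat=3):
            assert normalized_bit_score(m, "".join(word)) == pytest.approx(0.0)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(20):
            m = MotifMatrix.from_counts("m", rng.integers(1, 50, size=(6, 4)))
            word = "".join(rng.choice(list("ACGT"), 6))
            direct = sum(math.log2(m.frequencies[i, "ACGT".index(b)])
                         for i, b in enumerate(word)) - m.max_raw_score
            assert normalized_bit_score(m, word) == pytest.approx(direct, abs=1e-12)

    def test_word_with_n_is_unscorable(self):
        with pytest.raises(ValueError):
            normalized_bit_score(uniform_motif(3), "ANT")


class TestScanSequence:
    def test_every_window_scored_on_both_strands(self, rng):
        m = MotifMatrix.from_counts("m", rng.integers(1, 50, size=(4, 4)))
        seq = SequenceRecord("s", "ACGTACGTAC")
        hits = scan_sequence(m, seq)
        assert len(hits) == 2 * (10 - 4 + 1)

    def test_revcomp_scan_is_mirror_of_forward_scan(self, rng):
        m = MotifMatrix.from_counts("m", rng.integers(1, 50, size=(5, 4)))
        raw = "".join(rng.choice(list("ACGT"), 60))
        seq = SequenceRecord("s", raw)
        rc = SequenceRecord("s_rc", reverse_complement(raw))
        fwd = {(h.position, h.strand): h.score_bits for h in scan_sequence(m, seq)}
        flipped = {}
        for h in scan_sequence(m, rc):
            pos = len(raw) - m.length - h.position
            strand = "-" if h.strand == "+" else "+"
            flipped[(pos, strand)] = h.score_bits
        assert fwd.keys() == flipped.keys()
        for k in fwd:
            assert fwd[k] == pytest.approx(flipped[k], abs=1e-9)

    def test_all_n_sequence_yields_no_hits(self):
        assert scan_sequence(uniform_motif(3), SequenceRecord("n", "N" * 30)) == []

    def test_windows_containing_n_are_skipped(self):
        m = uniform_motif(3)
        hits = scan_sequence(m, SequenceRecord("s", "ACGNACG"), both_strands=False)
        # windows 1-3 overlap the N and are skipped
        assert sorted(h.position for h in hits) == [0, 4]

    def test_sequence_shorter_than_motif_is_empty(self):
        assert scan_sequence(uniform_motif(5), SequenceRecord("s", "ACG")) == []

    def test_planted_deterministic_copies_found_with_zero_score(self):
        motif = MotifMatrix.from_consensus("NINE", "GATTACAGA", weight=1e7)
        rec, truth = simulate_promoter(5_000, planted=[(motif, 19)], seed=6)
        hits = scan_sequence(motif, rec)
        perfect = {h.position for h in hits
                   if h.strand == "+" and h.score_bits > -1e-6}
        assert perfect >= {p for (_, p, _) in truth.planted_motif_sites}


class TestBackground:
    def test_balanced_sequence_gives_uniform_frequencies(self):
        bg = estimate_background(SequenceRecord("s", "ACGT" * 25))
        assert np.allclose(bg.probs, 0.25)

    def test_single_base_sequence_smoothed(self):
        bg = estimate_background(SequenceRecord("s", "A" * 100))
        assert bg.probs[0] > 0.99
        assert np.all(bg.probs > 0)

    def test_matches_direct_counting_oracle(self, rng):
        raw = "".join(rng.choice(list("ACGT"), 500))
        bg = estimate_background(SequenceRecord("s", raw), pseudocount=0.0)
        counts = np.array([raw.count(b) for b in "ACGT"])
        assert np.allclose(bg.probs, counts / 500)

    def test_masked_bases_excluded(self):
        bg = estimate_background(SequenceRecord("s", "AANN"))
        assert bg.probs[0] > 0.9

    def test_fully_masked_sequence_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(SequenceRecord("s", "NNNN"))


class TestCalibration:
    def test_bin_probabilities_equal_brute_force_enumeration(self, rng):
        # length-3 motif: enumerate all 64 words by hand and compare
        motif = MotifMatrix.from_counts("m3", rng.integers(1, 30, size=(3, 4)))
        bg = Background(0, np.array([0.1, 0.2, 0.3, 0.4]))
        n_bins = 30
        q = expected_bin_probabilities(motif, bg, n_bins, both_strands=True)
        brute = np.zeros(n_bins)
        for word in itertools.product("ACGT", repeat=3):
            w = "".join(word)
            p = math.prod(bg.probs["ACGT".index(b)] for b in w)
            for s, wt in ((normalized_bit_score(motif, w), 0.5),
                          (normalized_bit_score(motif, reverse_complement(w)), 0.5)):
                k = min(int(math.floor(-s - 1e-9)) if s < 0 else 0, n_bins - 1)
                k = max(k, 0)
                brute[k] += wt * p
        assert np.allclose(q, brute, atol=1e-12)

    def test_uniform_motif_shows_no_enrichment(self, rng):
        raw = "".join(rng.choice(list("ACGT"), 400))
        cal = calibrate_threshold(uniform_motif(4), SequenceRecord("s", raw))
        assert cal.threshold_bits is None
        assert cal.significant_hits == []

    def test_planted_high_information_motif_recovered(self):
        motif = MotifMatrix.from_consensus("PLANTED", "GCCGGACGG")
        rec, truth = simulate_promoter(10_000, planted=[(motif, 20)], seed=42)
        cal = calibrate_threshold(motif, rec, estimate_background(rec))
        planted = {p for (_, p, _) in truth.planted_motif_sites}
        found = {h.position for h in cal.significant_hits if h.strand == "+"}
        assert len(planted & found) / len(planted) >= 0.9
        false = [h for h in cal.significant_hits if h.position not in planted]
        assert len(false) <= 1

    def test_observed_counts_cover_all_windows(self, rng):
        raw = "".join(rng.choice(list("ACGT"), 200))
        m = MotifMatrix.from_counts("m", rng.integers(1, 50, size=(5, 4)))
        cal = calibrate_threshold(m, SequenceRecord("s", raw))
        assert cal.observed_counts.sum() == cal.n_windows == 2 * (200 - 5 + 1)


class TestEmpiricalEvalue:
    def test_uniform_motif_always_ties_the_observed_maximum(self, rng):
        raw = "".join(rng.choice(list("ACGT"), 50))
        ev = empirical_evalue(uniform_motif(4), SequenceRecord("s", raw),
                              n_shuffles=200, seed=1)
        assert ev.e_value == 1.0

    def test_matches_exact_permutation_distribution(self):
        # length-6 sequence, length-6 motif: one window per strand; the
        # exact null is enumerable over all 720 orderings
        raw = "AACGTT"
        motif = MotifMatrix.from_counts(
            "m6", np.array([[8, 1, 1, 1], [1, 8, 1, 1], [1, 1, 8, 1],
                            [8, 1, 1, 1], [1, 1, 1, 8], [1, 8, 1, 1]]))
        obs = max(normalized_bit_score(motif, raw),
                  normalized_bit_score(motif, reverse_complement(raw)))
        n_ge = total = 0
        for perm in itertools.permutations(raw):
            w = "".join(perm)
            s = max(normalized_bit_score(motif, w),
                    normalized_bit_score(motif, reverse_complement(w)))
            total += 1
            n_ge += s >= obs - 1e-9
        exact = n_ge / total
        n = 10_000
        ev = empirical_evalue(motif, SequenceRecord("s", raw), n_shuffles=n, seed=3)
        mc_sd = math.sqrt(exact * (1 - exact) / n)
        assert abs(ev.e_value - exact) < 3 * mc_sd

    def test_deterministic_under_fixed_seed(self, rng):
        raw = "".join(rng.choice(list("ACGT"), 100))
        m = MotifMatrix.from_counts("m", rng.integers(1, 50, size=(6, 4)))
        e1 = empirical_evalue(m, SequenceRecord("s", raw), n_shuffles=500, seed=9)
        e2 = empirical_evalue(m, SequenceRecord("s", raw), n_shuffles=500, seed=9)
        assert e1.n_better_or_equal == e2.n_better_or_equal

    def test_evalue_definition_invariants(self, rng):
        raw = "".join(rng.choice(list("ACGT"), 80))
        m = MotifMatrix.from_counts("m", rng.integers(1, 50, size=(5, 4)))
        ev = empirical_evalue(m, SequenceRecord("s", raw), n_shuffles=300, seed=2)
        assert ev.e_value == ev.n_better_or_equal / ev.n_shuffles
        assert 0.0 <= ev.e_value <= 1.0

    def test_masked_positions_stay_fixed(self):
        # with every unmasked base identical, shuffling changes nothing
        seq = SequenceRecord("s", "NNAAAANN")
        ev = empirical_evalue(uniform_motif(4), seq, n_shuffles=150, seed=4)
        assert ev.e_value == 1.0


class TestMaskLowComplexity:
    def test_dinucleotide_repeat_fully_masked(self):
        rec = mask_low_complexity(SequenceRecord("s", "AC" * 100))
        assert set(rec.sequence) == {"N"}

    def test_random_sequence_barely_masked(self, rng):
        raw = "".join(rng.choice(list("ACGT"), 10_000))
        rec = mask_low_complexity(SequenceRecord("s", raw))
        assert rec.sequence.count("N") / 10_000 < 0.02

    def test_idempotent(self, rng):
        raw = "".join(rng.choice(list("ACGT"), 500)) + "AG" * 60
        once = mask_low_complexity(SequenceRecord("s", raw))
        twice = mask_low_complexity(once)
        assert once.sequence == twice.sequence
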