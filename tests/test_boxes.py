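import numpy as np
import pytest

from cdsno import boxes
from cdsno.boxes import (
    Box,
    BoxAnnotation,
    compute_importance,
    define_boundaries,
    detect_peaks,
    find_cd_pair,
    find_prime_boxes,
    stem_complementarity,
)
from cdsno.core_io import GenomicInterval
from cdsno.features import C_CONSENSUS, D_CONSENSUS, box_hamming
from cdsno.scanner import reverse_complement


def _random_window(rng, L=194):
    return "".join(rng.choice(list("ACGT"), L))


def brute_force_cd(seq):
    """Independent exhaustive minimal-Hamming search with the documented
    tie hierarchy (no peaks: score sum, C score, leftmost C, strongest
    implied stem, rightmost D)."""
    L = len(seq)
    half = L // 2
    best = None
    for cs in range(5, half - 7 + 1):
        hc = box_hamming(seq[cs:cs + 7], C_CONSENSUS)
        for ds in range(half, L - 9 + 1):
            hd = box_hamming(seq[ds:ds + 4], D_CONSENSUS)
            key = (hc + hd, hc, 0, cs, -stem_complementarity(seq, cs, ds), -ds)
            if best is None or key < best[0]:
                best = (key, cs, ds)
    return best[1], best[2]


class TestImportance:
    def test_constant_classifier_gives_zero_profile(self, constant_classifier):
        profile = compute_importance(constant_classifier(0.7), "ACGT" * 50)
        assert profile.shape == (200,)
        assert np.allclose(profile, 0.0)

    def test_profile_length_matches_window(self, constant_classifier):
        profile = compute_importance(constant_classifier(1.0), "A" * 194)
        assert len(profile) == 194

    def test_indicator_classifier_localizes_motif(self, motif_classifier):
        rng = np.random.default_rng(11)
        seq = _random_window(rng)
        while "ATGATGA" in seq:
            seq = _random_window(rng)
        seq = seq[:80] + "ATGATGA" + seq[87:]
        profile = compute_importance(motif_classifier, seq)
        # motif at [80, 87): destroying spans start at 75..86 and each
        # span covers 6 nt, so affected positions are 75..91
        destroyable = set(range(75, 92))
        positive = set(np.nonzero(profile > 0)[0])
        assert positive == destroyable
        assert np.all(profile >= 0)


class TestPeaks:
    def test_single_bump_single_peak(self):
        profile = np.zeros(194)
        profile[90:101] = np.concatenate([np.arange(6), np.arange(4, -1, -1)])
        peaks = detect_peaks(profile)
        assert len(peaks) == 1
        assert abs(peaks[0] - 95) <= 2

    def test_two_bumps_in_order(self):
        profile = np.zeros(194)
        for apex in (50, 140):
            profile[apex - 5: apex + 6] += np.concatenate(
                [np.arange(6), np.arange(4, -1, -1)])
        peaks = detect_peaks(profile)
        assert len(peaks) == 2
        assert abs(peaks[0] - 50) <= 2 and abs(peaks[1] - 140) <= 2

    def test_constant_profile_has_no_peaks(self):
        assert detect_peaks(np.ones(194)) == []

    def test_rejects_non_finite(self):
        bad = np.zeros(194)
        bad[5] = np.nan
        with pytest.raises(ValueError):
            detect_peaks(bad)


class TestFindCdPair:
    def _window_with(self, rng, c_at, d_at, c_seq="ATGATGA", d_seq="CTGA"):
        seq = _random_window(rng)
        while ("ATGATGA" in seq or "GTGATGA" in seq or "CTGA" in seq):
            seq = _random_window(rng)
        seq = seq[:c_at] + c_seq + seq[c_at + 7:]
        seq = seq[:d_at] + d_seq + seq[d_at + 4:]
        return seq

    def test_perfect_pair_near_peaks(self):
        rng = np.random.default_rng(21)
        seq = self._window_with(rng, 30, 150)
        c, d = find_cd_pair(seq, peaks=[33, 151])
        assert (c.start, c.score) == (30, 0)
        assert (d.start, d.score) == (150, 0)

    def test_fewer_mutations_win(self):
        rng = np.random.default_rng(22)
        seq = self._window_with(rng, 30, 150)
        seq = seq[:60] + "ATGTTGA" + seq[67:]  # 1-mutation C decoy near a peak
        c, _ = find_cd_pair(seq, peaks=[33, 61, 151])
        assert (c.start, c.score) == (30, 0)

    def test_uniform_profile_matches_bruteforce(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            seq = _random_window(rng)
            c, d = find_cd_pair(seq, peaks=[])
            assert (c.start, d.start) == brute_force_cd(seq)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            find_cd_pair("ACGT" * 7, peaks=[])


class TestPrimeBoxes:
    def test_planted_primes_recovered_exactly(self):
        rng = np.random.default_rng(31)
        seq = _random_window(rng)
        while "CTGA" in seq[37:150] or "TGATGA" in seq[37:150]:
            seq = _random_window(rng)
        seq = seq[:60] + "CTGA" + seq[64:]
        seq = seq[:90] + "GTGATGA" + seq[97:]
        c = Box(30, seq[30:37], box_hamming(seq[30:37], C_CONSENSUS))
        d = Box(150, seq[150:154], box_hamming(seq[150:154], D_CONSENSUS))
        d_prime, c_prime = find_prime_boxes(seq, c, d)
        assert (d_prime.start, d_prime.score) == (60, 0)
        assert (c_prime.start, c_prime.score) == (90, 0)

    def test_small_region_reports_absent(self):
        seq = "A" * 194
        d_prime, c_prime = find_prime_boxes(seq, Box(30, seq[30:37], 3),
                                            Box(47, seq[47:51], 3))
        assert d_prime is None and c_prime is None

    def test_matches_bruteforce_on_random_regions(self):
        rng = np.random.default_rng(32)
        for _ in range(30):
            seq = _random_window(rng)
            c = Box(20, seq[20:27], 0)
            d = Box(100, seq[100:104], 0)
            d_prime, c_prime = find_prime_boxes(seq, c, d)
            best = None
            for dp in range(27, 100 - 4 - 7 + 1):
                hd = box_hamming(seq[dp:dp + 4], D_CONSENSUS)
                for cp in range(dp + 4, 100 - 7 + 1):
                    hc = box_hamming(seq[cp:cp + 7], C_CONSENSUS)
                    key = (hd + hc, hd, dp, cp)
                    if best is None or key < best[0]:
                        best = (key, dp, cp)
            assert (d_prime.start, c_prime.start) == (best[1], best[2])

    def test_box_order_invariant(self):
        rng = np.random.default_rng(33)
        for _ in range(30):
            seq = _random_window(rng)
            c, d = find_cd_pair(seq, peaks=[])
            d_prime, c_prime = find_prime_boxes(seq, c, d)
            if d_prime is not None and c_prime is not None:
                BoxAnnotation(c=c, d=d, d_prime=d_prime, c_prime=c_prime)


class TestBoundaries:
    def test_paper_offsets(self):
        window = GenomicInterval("chr1", 1000, 1194, "+")
        locus = define_boundaries(Box(30, "ATGATGA", 0), Box(150, "CTGA", 0),
                                  window)
        assert (locus.start, locus.end) == (1025, 1159)
        assert locus.length == 134

    def test_c_at_margin_starts_at_window(self):
        window = GenomicInterval("chr1", 1000, 1194, "+")
        locus = define_boundaries(Box(5, "ATGATGA", 0), Box(150, "CTGA", 0),
                                  window)
        assert locus.start == window.start

    def test_out_of_window_clipped_with_warning(self, caplog):
        window = GenomicInterval("chr1", 1000, 1194, "+")
        locus = define_boundaries(Box(2, "ATGATGA", 0), Box(150, "CTGA", 0),
                                  window)
        assert locus.start == window.start
        assert "clipped" in caplog.text

    def test_minus_strand_mirrors_plus_annotation(self):
        rng = np.random.default_rng(41)
        genome = "".join(rng.choice(list("ACGT"), 400))
        window = GenomicInterval("chr1", 100, 294, "-")
        window_seq = reverse_complement(genome[100:294])
        c, d = find_cd_pair(window_seq, peaks=[])
        locus = define_boundaries(c, d, window)
        # mirror oracle: compute relative locus on the rc sequence, then map
        rel_start, rel_end = c.start - 5, d.end + 5
        assert locus.start == 100 + (194 - rel_end)
        assert locus.end == 100 + (194 - rel_start)
        assert locus.strand == "-"

    def test_locus_length_identity(self):
        rng = np.random.default_rng(42)
        window = GenomicInterval("chr1", 0, 194, "+")
        for _ in range(20):
            seq = _random_window(rng)
            c, d = find_cd_pair(seq, peaks=[])
            locus = define_boundaries(c, d, window)
            assert locus.length == (d.end - c.start) + 10
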