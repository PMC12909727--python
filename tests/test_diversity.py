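"""Diversity statistics: S, Watterson's theta, pi, Tajima's D, window scans."""

import math
from itertools import combinations

import numpy as np
import pytest

from hapdiv.diversity import (DiversityStats, diversity_stats, flank_scan,
                              harmonic_a1, mean_pairwise_differences,
                              nucleotide_diversity, segregating_sites,
                              tajima_constants, tajimas_d, watterson_theta,
                              window_pi)
from hapdiv.haplotypes import HaplotypeAlignment
from hapdiv.variant_io import GenomicInterval

from conftest import make_record


def aln_of(*seqs):
    return HaplotypeAlignment([f"s{i}" for i in range(len(seqs))], list(seqs))


def random_alignment(rng, n=None, L=None, alphabet="ACGT"):
    n = n or int(rng.integers(2, 8))
    L = L or int(rng.integers(1, 25))
    return aln_of(*("".join(rng.choice(list(alphabet), L)) for _ in range(n)))


class TestSegregatingSites:
    def test_identical_pair_zero(self):
        assert segregating_sites(aln_of("ACGT", "ACGT")) == (0, 4)

    def test_single_variable_column(self):
        seqs = ["A" * 10, "A" * 10, "A" * 4 + "T" + "A" * 5, "A" * 4 + "T" + "A" * 5]
        S, L = segregating_sites(aln_of(*seqs))
        assert (S, L) == (1, 10)

    def test_complete_deletion_drops_column(self):
        S, L = segregating_sites(aln_of("AC", "AN", "AT"))
        assert (S, L) == (0, 1)

    def test_matches_column_scan(self, rng):
        for _ in range(50):
            aln = random_alignment(rng, alphabet="ACGTN-")
            cols = [j for j in range(aln.length)
                    if all(s[j] not in "N-" for s in aln.sequences)]
            expected = sum(
                1 for j in cols if len({s[j] for s in aln.sequences}) > 1)
            assert segregating_sites(aln) == (expected, len(cols))


class TestWattersonTheta:
    def test_zero_when_invariant(self):
        assert watterson_theta(0, 10, 100) == 0.0

    def test_pair_closed_form(self):
        # n=2 -> a1 = 1, so theta = S/L
        assert watterson_theta(1, 2, 100) == pytest.approx(0.01)

    def test_consistent_with_wild_rice_row(self):
        """Back-solving L from the wild Asian rice summary (n=30, S=57,
        theta=0.00692) and re-applying the formula recovers theta."""
        n, S, theta = 30, 57, 0.00692
        L = S / (harmonic_a1(n) * theta)
        assert L == pytest.approx(2081, abs=10)
        assert watterson_theta(S, n, round(L)) == pytest.approx(theta, rel=1e-3)


class TestNucleotideDiversity:
    def test_identical_sequences_zero(self):
        assert nucleotide_diversity(aln_of("ACGT", "ACGT")) == 0.0

    def test_single_site_half_split(self):
        """4 sequences, one A/A/T/T column, L=10: 4 differing pairs of 6."""
        seqs = ["A" * 10, "A" * 10, "T" + "A" * 9, "T" + "A" * 9]
        assert nucleotide_diversity(aln_of(*seqs)) == pytest.approx(4 / 6 / 10)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            aln = random_alignment(rng, alphabet="ACGN")
            cols = [j for j in range(aln.length)
                    if all(s[j] not in "N-" for s in aln.sequences)]
            if not cols:
                continue
            total = sum(
                sum(1 for j in cols if a[j] != b[j])
                for a, b in combinations(aln.sequences, 2)
            )
            npairs = len(aln.sequences) * (len(aln.sequences) - 1) / 2
            assert nucleotide_diversity(aln) == pytest.approx(
                total / npairs / len(cols))

    def test_bounded_zero_one(self, rng):
        for _ in range(20):
            aln = random_alignment(rng)
            assert 0.0 <= nucleotide_diversity(aln) <= 1.0


class TestTajimasD:
    def test_zero_when_no_segregation(self):
        assert tajimas_d(aln_of("ACGT", "ACGT")) == 0.0

    def test_pair_with_variation_undefined(self):
        """n=2 with S>0 is 0/0: a1=1 makes pi_total = S and e1 = 0."""
        k = tajima_constants(2)
        assert k["e1"] == pytest.approx(0.0, abs=1e-15)
        assert math.isnan(tajimas_d(aln_of("AAAA", "AAAT")))

    def test_dual_implementation_agreement(self, rng):
        """Independently coded constants reproduce D to 1e-12."""

        def oracle_d(aln):
            n = aln.n_samples
            cols = [j for j in range(aln.length)
                    if all(s[j] not in "N-" for s in aln.sequences)]
            S = sum(1 for j in cols if len({s[j] for s in aln.sequences}) > 1)
            if S == 0:
                return 0.0
            a1 = sum(1.0 / i for i in range(1, n))
            a2 = sum(1.0 / i / i for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
            e1, e2 = c1 / a1, c2 / (a1 * a1 + a2)
            var = e1 * S + e2 * S * (S - 1)
            if var <= 0:
                return float("nan")
            diffs = [sum(1 for j in cols if x[j] != y[j])
                     for x, y in combinations(aln.sequences, 2)]
            pi_total = sum(diffs) / len(diffs)
            return (pi_total - S / a1) / math.sqrt(var)

        seqs = ["A" * 10, "A" * 10, "T" + "A" * 9, "T" + "A" * 9]
        assert tajimas_d(aln_of(*seqs)) == pytest.approx(
            oracle_d(aln_of(*seqs)), abs=1e-12)
        for _ in range(30):
            aln = random_alignment(rng, n=int(rng.integers(3, 8)))
            expected = oracle_d(aln)
            got = tajimas_d(aln)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_sign_matches_pi_minus_theta(self, rng):
        for _ in range(30):
            aln = random_alignment(rng, n=int(rng.integers(4, 8)))
            d = tajimas_d(aln)
            if math.isnan(d) or d == 0.0:
                continue
            S, _ = segregating_sites(aln)
            a1 = harmonic_a1(aln.n_samples)
            diff = mean_pairwise_differences(aln) - S / a1
            assert math.copysign(1, d) == math.copysign(1, diff)

    def test_degenerate_group_row_all_zero(self):
        """Two identical sequences — the invariant negative wild-rice group —
        give an all-zero statistics row."""
        stats = diversity_stats(aln_of("ACGTACGT", "ACGTACGT"), group="neg")
        assert (stats.S, stats.theta_w_site, stats.pi_site, stats.tajima_d) == \
               (0, 0.0, 0.0, 0.0)


class TestWindowPi:
    def interval(self, n_windows=3, size=10_000):
        return GenomicInterval("chr04", 1, n_windows * size)

    def test_snp_free_window_zero(self):
        track = window_pi([], self.interval())
        assert [w[2] for w in track.windows] == [0.0, 0.0, 0.0]

    def test_half_frequency_snp(self):
        track = window_pi([(5000, 0.5, 0.5)], self.interval(1))
        assert track.windows[0][2] == pytest.approx(5e-5)

    def test_hand_summed_window(self):
        freqs = [(100, 0.9, 0.1), (200, 0.8, 0.2), (300, 0.5, 0.5)]
        track = window_pi(freqs, self.interval(1))
        assert track.windows[0][2] == pytest.approx((0.18 + 0.32 + 0.5) / 10_000)

    def test_windows_tile_interval(self):
        track = window_pi([], self.interval(5))
        starts = [w[0] for w in track.windows]
        ends = [w[1] for w in track.windows]
        assert starts[0] == 1 and ends[-1] == 50_000
        assert all(s2 == e1 + 1 for e1, s2 in zip(ends, starts[1:]))

    def test_sample_size_correction_flag(self):
        plain = window_pi([(100, 0.5, 0.5)], self.interval(1))
        corrected = window_pi([(100, 0.5, 0.5)], self.interval(1), sample_size=10)
        assert corrected.windows[0][2] == pytest.approx(
            plain.windows[0][2] * 10 / 9)

    def test_upper_bound(self, rng):
        freqs = [(int(p), q, 1 - q) for p, q in
                 zip(rng.integers(1, 10_000, 20), rng.random(20))]
        track = window_pi(freqs, self.interval(1))
        assert track.windows[0][2] <= 0.5 * 20 / 10_000

    def test_invalid_window_size(self):
        with pytest.raises(ValueError):
            window_pi([], self.interval(), window_size=0)


class TestFlankScan:
    def gene(self):
        return GenomicInterval("chr04", 100_001, 102_305)

    def test_empty_records_all_zero(self):
        track = flank_scan([], self.gene(), flank=50_000)
        assert all(pi == 0.0 for _, _, pi in track.windows)
        assert track.windows[0][0] == 50_001

    def test_snps_confined_to_one_window(self):
        gts = [(0, 0)] * 5 + [(1, 1)] * 5
        recs = [make_record(pos=p, genotypes=gts) for p in (60_100, 60_200)]
        track = flank_scan(recs, self.gene(), flank=50_000)
        nonzero = [(s, e, pi) for s, e, pi in track.windows if pi > 0]
        assert len(nonzero) == 1
        s, e, pi = nonzero[0]
        assert s <= 60_100 <= e and pi == pytest.approx(2 * 2 * 0.25 / 10_000)

    def test_composes_with_window_pi(self, rng):
        from hapdiv.variant_io import allele_frequency

        gts_pool = [[(int(a), int(a)) for a in (rng.random(10) < f)]
                    for f in (0.2, 0.4, 0.6)]
        recs = [make_record(pos=int(p), genotypes=gts_pool[i % 3])
                for i, p in enumerate(sorted(rng.integers(30_000, 170_000, 30)))]
        track = flank_scan(recs, self.gene(), flank=50_000)
        scan_iv = GenomicInterval("chr04", 50_001, 152_305)
        freqs = []
        for r in recs:
            if 50_001 <= r.pos <= 152_305:
                af = allele_frequency(r)
                freqs.append((r.pos, af.p, af.q))
        oracle = window_pi(freqs, scan_iv)
        assert track.windows == oracle.windows

    def test_per_group_subset(self):
        gts = [(0, 0)] * 4 + [(1, 1)] * 4
        recs = [make_record(pos=60_100, genotypes=gts)]
        track = flank_scan(recs, self.gene(), flank=50_000,
                           sample_indices=range(4))
        assert all(pi == 0.0 for _, _, pi in track.windows)


def test_haploid_pi_identity(rng):
    """For haploid samples mean-pairwise pi_total equals n/(n-1) * sum 2pq —
    the windowed estimator is the uncorrected variant of alignment pi."""
    for _ in range(20):
        n = int(rng.integers(2, 10))
        L = int(rng.integers(2, 15))
        aln = aln_of(*("".join(rng.choice(list("AG"), L)) for _ in range(n)))
        pi_total = mean_pairwise_differences(aln)
        s2pq = 0.0
        for j in range(L):
            col = [s[j] for s in aln.sequences]
            p = col.count("A") / n
            s2pq += 2 * p * (1 - p)
        assert pi_total == pytest.approx(n / (n - 1) * s2pq, rel=1e-9)
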