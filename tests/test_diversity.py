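import math

import numpy as np
import pytest

from palmscan import diversity
from palmscan.diversity import (
    SFS,
    folded_sfs,
    harmonic,
    harmonic2,
    nucleotide_diversity,
    single_genome_theta,
    site_components,
    tajima_d_from_counts,
    tajimas_d,
    watterson_theta,
    window_scan,
    window_stat,
)
from palmscan.io import GenomicInterval, InputError
from palmscan.simulate import diploid_matrix_from_loci, simulate_coalescent_locus

from conftest import make_matrix

IV = GenomicInterval("S000001", 0, 1000)


class TestSiteComponents:
    def test_missing_data_bookkeeping(self):
        m = make_matrix([[0], [1], [-1]])
        assert site_components(m, None, 0) == (4, 1)

    def test_all_missing_site_uncallable(self):
        m = make_matrix([[-1], [-1]])
        assert site_components(m, None, 0) == (0, 0)

    def test_all_hom_alt(self):
        m = make_matrix([[2]] * 5)
        assert site_components(m, None, 0) == (10, 10)


class TestWatterson:
    def test_monomorphic_window_gives_zero(self):
        m = make_matrix([[0, 0], [0, 0]], scaffold_length=1000)
        assert watterson_theta(m, None, IV) == 0.0

    def test_hand_evaluated_harmonic_scaling(self):
        # 4 chromosomes, S=3, L=1000: 3 / ((1 + 1/2 + 1/3) * 1000)
        m = make_matrix([[0, 1, 0], [1, 0, 1]], scaffold_length=1000)
        expected = 3 / ((11 / 6) * 1000)
        assert watterson_theta(m, None, IV) == pytest.approx(expected, abs=1e-7)
        assert expected == pytest.approx(0.0016364, abs=1e-7)

    def test_zero_length_window_undefined(self):
        m = make_matrix([[0, 1], [1, 0]])
        stat = window_stat(m, None, IV, L=0)
        assert math.isnan(stat.theta_w)


class TestPi:
    def test_two_chromosome_closed_form(self):
        # two chromosomes (one diploid, het) differing at 3 of 1000 sites
        m = make_matrix([[1, 1, 1]], scaffold_length=1000)
        assert nucleotide_diversity(m, None, IV) == pytest.approx(0.003)

    def test_monomorphic_gives_zero(self):
        m = make_matrix([[1, 1], [1, 1]], scaffold_length=1000)
        # every site fixed het means k = n/2 at every site: still segregating
        assert nucleotide_diversity(m, None, IV) > 0
        fixed = make_matrix([[2, 2], [2, 2]], scaffold_length=1000)
        assert nucleotide_diversity(fixed, None, IV) == 0.0


class TestTajimasD:
    def test_matches_brute_force_formula_on_constructed_sfs(self):
        # n=4: sites with derived counts 1,2,3 in neutral proportions 6:3:2
        # (scaled 1/i); brute-force the 1989 formulas independently
        counts = [1] * 6 + [2] * 3 + [3] * 2
        calls = np.zeros((2, len(counts)), dtype=np.int8)
        for j, k in enumerate(counts):
            # distribute k alt alleles over 2 diploids (4 chromosomes)
            calls[0, j] = min(k, 2)
            calls[1, j] = k - min(k, 2)
        m = make_matrix(calls, scaffold_length=1000)
        d = tajimas_d(m, None, IV)

        n, S = 4, len(counts)
        pi_total = sum(2 * k * (n - k) / (n * (n - 1)) for k in counts)
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        expected = (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert d == pytest.approx(expected, abs=1e-12)

    def test_undefined_without_segregating_sites(self):
        m = make_matrix([[0, 0], [0, 0]], scaffold_length=1000)
        assert math.isnan(tajimas_d(m, None, IV))
        assert math.isnan(tajima_d_from_counts(0, 0.0, 10))

    def test_neutral_coalescent_mean_near_zero(self):
        rng = np.random.default_rng(21)
        ds = []
        for _ in range(500):
            haps, pos = simulate_coalescent_locus(20, 0.01, 1000, rng)
            if haps.shape[1] == 0:
                continue
            m = diploid_matrix_from_loci([(haps, pos)], 1000)
            ds.append(tajimas_d(m, None, IV))
        assert abs(np.mean(ds)) < 0.15


class TestWindowScan:
    def test_non_overlapping_tiling_with_trailing_partial(self):
        m = make_matrix([[0, 1], [1, 0]], positions=[100, 24_000],
                        scaffold_length=25_000)
        windows = window_scan(m, None, 10_000)
        spans = [(w.interval.start, w.interval.end) for w in windows]
        assert spans == [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]
        assert windows[-1].n_callable_sites == 5000

    def test_sliding_windows_count(self):
        m = make_matrix([[0, 1], [1, 0]], positions=[100, 9000],
                        scaffold_length=10_000)
        windows = window_scan(m, None, 5000, step=500)
        assert len(windows) == 11
        assert windows[0].interval.start == 0
        assert windows[-1].interval == GenomicInterval("S000001", 5000, 10_000)

    def test_segregating_sites_conserved_over_tiling(self, neutral_two_pop):
        matrix, _, _ = neutral_two_pop
        windows = window_scan(matrix, None, 10_000)
        whole = GenomicInterval("S000001", 0, matrix.scaffold_span("S000001"))
        assert sum(w.S for w in windows) == window_stat(matrix, None, whole).S


class TestInvariance:
    def test_sample_order_and_label_swap_invariance(self, neutral_two_pop):
        matrix, _, _ = neutral_two_pop
        iv = GenomicInterval("S000001", 0, matrix.scaffold_span("S000001"))
        base = window_stat(matrix, None, iv)
        shuffled = matrix.take_samples(matrix.sample_ids[::-1])
        stat2 = window_stat(shuffled, None, iv)
        assert stat2.theta_w == base.theta_w and stat2.pi == base.pi
        # ref/alt swap: dosage d -> 2-d (missing stays missing)
        flipped_calls = np.where(matrix.calls >= 0, 2 - matrix.calls, -1)
        flipped = make_matrix(flipped_calls, positions=matrix.positions,
                              scaffold_length=matrix.scaffold_span("S000001"))
        stat3 = window_stat(flipped, None, iv)
        assert stat3.theta_w == base.theta_w
        assert stat3.pi == pytest.approx(base.pi, rel=1e-12)

    def test_theta_and_pi_agree_in_expectation_under_neutrality(self):
        rng = np.random.default_rng(31)
        diffs = []
        for _ in range(500):
            haps, pos = simulate_coalescent_locus(20, 0.01, 1000, rng)
            m = diploid_matrix_from_loci([(haps, pos)], 1000)
            stat = window_stat(m, None, IV)
            diffs.append(stat.theta_w - stat.pi)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se


class TestFoldedSFS:
    def test_direct_fold_without_projection(self):
        # 2 samples (n=4), alt counts {1, 3, 2} -> folded {1: 2, 2: 1}
        m = make_matrix([[1, 2, 1], [0, 1, 1]])
        sfs = folded_sfs(m, None)
        assert sfs.n == 4
        np.testing.assert_array_equal(sfs.counts, [2, 1])

    def test_projection_equals_hypergeometric_enumeration(self):
        # one site with n=6, k=3 projected to n=4: enumerate all C(6,4) draws
        from itertools import combinations

        m = make_matrix([[1, ], [1, ], [1, ]])  # 3 samples, n=6, k=3
        sfs = folded_sfs(m, None, project_n=4)
        alleles = [1, 1, 1, 0, 0, 0]
        folded = np.zeros(2)
        draws = list(combinations(range(6), 4))
        for d in draws:
            k = sum(alleles[i] for i in d)
            if 0 < k < 4:
                folded[min(k, 4 - k) - 1] += 1 / len(draws)
        np.testing.assert_allclose(sfs.counts, folded, atol=1e-12)

    def test_projection_beyond_site_n_errors(self):
        m = make_matrix([[1], [0]])
        with pytest.raises(InputError):
            folded_sfs(m, None, project_n=6)

    def test_neutral_sfs_matches_expectation_within_mc_error(self):
        # folded neutral expectation per locus: E[eta_i] = theta*L*(1/i + 1/(n-i)),
        # halved at i = n/2.  Per-class MC error estimated from per-locus counts
        # (high classes are driven by rare long internal branches, so the
        # variance is far beyond multinomial).
        rng = np.random.default_rng(41)
        n, theta, L, reps = 12, 0.02, 2000, 400
        per_locus = np.zeros((reps, n // 2))
        for r in range(reps):
            haps, pos = simulate_coalescent_locus(n, theta, L, rng)
            m = diploid_matrix_from_loci([(haps, pos)], L)
            sfs = folded_sfs(m, None)
            if len(sfs.counts):
                per_locus[r] = sfs.counts
        expected = theta * L * np.array(
            [1 / i + 1 / (n - i) for i in range(1, n // 2)] + [1 / (n // 2)]
        )
        mean = per_locus.mean(axis=0)
        se = per_locus.std(axis=0, ddof=1) / np.sqrt(reps)
        assert (np.abs(mean - expected) < 4 * se).all()

    def test_effect_class_filter(self):
        m = make_matrix([[1, 1], [0, 1]],
                        effect_class=["nonsense", "synonymous"])
        sfs = folded_sfs(m, None, site_class_filter="nonsense")
        assert sfs.counts.sum() == 1


class TestSingleGenomeTheta:
    def test_all_homozygous_gives_zero(self):
        m = make_matrix([[0, 2, 0]], scaffold_length=1000)
        assert single_genome_theta(m, "s1") == 0.0

    def test_het_count_over_span(self):
        calls = np.zeros((1, 5), dtype=np.int8)
        calls[0, :5] = 1
        m = make_matrix(calls, scaffold_length=1000)
        assert single_genome_theta(m, "s1") == pytest.approx(0.005)

    def test_recovers_theta_for_random_diploid(self):
        # E[heterozygosity] = theta per site under infinite sites
        rng = np.random.default_rng(51)
        hets = []
        for _ in range(300):
            haps, pos = simulate_coalescent_locus(2, 0.01, 10_000, rng)
            m = diploid_matrix_from_loci([(haps, pos)], 10_000)
            hets.append(single_genome_theta(m, "S001"))
        se = np.std(hets, ddof=1) / np.sqrt(len(hets))
        assert abs(np.mean(hets) - 0.01) < 3 * se


def test_harmonic_sums():
    assert harmonic(3) == pytest.approx(11 / 6)
    assert harmonic(0) == 0.0
    assert harmonic2(2) == pytest.approx(1.25)
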