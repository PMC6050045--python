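"""Mutation-clock and recombination-clock dating against closed forms and oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from wingpop.dating import (
    EHHCurve,
    age_ci,
    age_point,
    coalescent_time,
    cytb_divergence_time,
    divergence_vs_expectation_test,
    ehh_curve,
    expected_snps,
    generations_to_years,
    genetic_distance_cm,
    pairwise_snp_counts,
    similarity_percent,
    span_homozygosity,
    variant_list_pairwise_diffs,
)
from wingpop.popgen_io import MISSING, GenomicRegion

from conftest import small_matrix

MU = 1.42e-9
L_HAP = 102_909  # minimal haplotype length as used by the original dating
L_DENOVO = 92_199


class TestMutationClock:
    def test_expected_snps_over_species_divergence(self):
        assert expected_snps(4e6, MU, L_HAP) == pytest.approx(1169.05, abs=0.005)
        assert expected_snps(5e6, MU, L_HAP) == pytest.approx(1461.31, abs=0.005)
        assert expected_snps(0, MU, L_HAP) == 0.0

    def test_coalescent_time_worked_examples(self):
        assert coalescent_time(26, MU, L_HAP) / 1000 == pytest.approx(89.0, abs=0.5)
        assert coalescent_time(8, MU, L_HAP) / 1000 == pytest.approx(27.4, abs=0.5)
        assert coalescent_time(11, MU, L_DENOVO) / 1000 == pytest.approx(42.0, abs=0.5)
        assert coalescent_time(0, MU, L_HAP) == 0.0

    def test_round_trip_identity(self):
        for T in (0.0, 857.0, 4e6, 7.3e6):
            assert coalescent_time(expected_snps(T, MU, L_HAP), MU, L_HAP) == pytest.approx(
                T, rel=1e-9, abs=1e-9
            )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            coalescent_time(5, 0.0, L_HAP)
        with pytest.raises(ValueError):
            expected_snps(-1.0, MU, L_HAP)

    def test_similarity_percent(self):
        assert similarity_percent(26, 4261) == pytest.approx(99.39, abs=0.005)
        assert similarity_percent(0, 4261) == 100.0
        assert similarity_percent(4261, 4261) == 0.0
        with pytest.raises(ValueError):
            similarity_percent(5000, 4261)

    def test_cytb_divergence_in_stated_range(self):
        t = cytb_divergence_time(8.0, 1.96)
        assert t == pytest.approx(4.0816, abs=0.001)
        assert 4.0 <= t <= 5.0
        assert cytb_divergence_time(0.0, 1.96) == 0.0
        with pytest.raises(ValueError):
            cytb_divergence_time(8.0, 0.0)


class TestDivergenceTest:
    def test_equal_to_expectation(self):
        t, p = divergence_vs_expectation_test([5.0, 5.0, 5.0], 5.0)
        assert (t, p) == (0.0, 1.0)

    def test_closed_form_t(self):
        # mean 384, sd 4: t = (384 - 1169.05) / (4 / sqrt(3))
        t, p = divergence_vs_expectation_test([380, 384, 388], 1169.05)
        expected_t = (384 - 1169.05) / (4 / math.sqrt(3))
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert p < 0.001

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            divergence_vs_expectation_test([380], 1000.0)


class TestPairwiseCounts:
    def test_identical_haplotypes(self):
        _, h = small_matrix([[0, 0, 1, 0]] * 5)
        s = pairwise_snp_counts(h, GenomicRegion("S68", 1, 100), [("s0|0", "s0|1")])
        assert s.counts[("s0|0", "s0|1")] == 0

    def test_two_of_five_sites_differ(self):
        alleles = [[0, 1], [1, 1], [0, 0], [1, 0], [1, 1]]
        _, h = small_matrix(alleles, samples=["x"])
        s = pairwise_snp_counts(h, GenomicRegion("S68", 1, 100), [("x|0", "x|1")])
        assert s.counts[("x|0", "x|1")] == 2

    def test_group_summary_by_hand(self):
        # three pairs with counts {2, 4, 6}: mean 4, sample SD 2
        alleles = np.zeros((6, 8), dtype=np.int8)
        alleles[0:2, 1] = 1  # s0|1 differs from s0|0 at 2 sites
        alleles[0:4, 3] = 1  # s1|1 differs from s1|0 at 4 sites
        alleles[0:6, 5] = 1  # s2|1 differs from s2|0 at 6 sites
        _, h = small_matrix(alleles)
        s = pairwise_snp_counts(
            h,
            GenomicRegion("S68", 1, 100),
            [("s0|0", "s0|1"), ("s1|0", "s1|1"), ("s2|0", "s2|1")],
        )
        assert s.mean == pytest.approx(4.0)
        assert s.sd == pytest.approx(2.0)

    def test_matches_brute_force_oracle_with_missing(self):
        rng = np.random.default_rng(10)
        alleles = rng.integers(0, 2, size=(200, 6)).astype(np.int8)
        alleles[rng.random(alleles.shape) < 0.05] = MISSING
        _, h = small_matrix(alleles, samples=["a", "b", "c"])
        region = GenomicRegion("S68", 500, 1500)  # positions 10..2000 in steps of 10
        pairs = [("a|0", "b|0"), ("b|1", "c|0"), ("a|1", "c|1")]
        s = pairwise_snp_counts(h, region, pairs)
        labels = {lab: i for i, lab in enumerate(h.labels)}
        for (x, y), count in s.counts.items():
            naive = 0
            for i in range(h.n_sites):
                if not (500 <= h.positions[i] <= 1500):
                    continue
                va, vb = alleles[i, labels[x]], alleles[i, labels[y]]
                if va != MISSING and vb != MISSING and va != vb:
                    naive += 1
            assert count == naive

    def test_empty_pairs_rejected(self):
        _, h = small_matrix([[0, 1]])
        with pytest.raises(ValueError):
            pairwise_snp_counts(h, GenomicRegion("S68", 1, 100), [])


class TestVariantListDiffs:
    def test_identical_lists(self):
        assert variant_list_pairwise_diffs({1: "A", 5: "T"}, {1: "A", 5: "T"}) == 0

    def test_private_variants_count(self):
        assert variant_list_pairwise_diffs({1: "A"}, {2: "G"}) == 2

    def test_shared_position_same_alt_is_no_difference(self):
        assert variant_list_pairwise_diffs({7: "C", 9: "A"}, {7: "C"}) == 1

    def test_shared_position_different_alt_counts_once(self):
        assert variant_list_pairwise_diffs({7: "C"}, {7: "G"}) == 1

    def test_malformed_entry_rejected(self):
        with pytest.raises(ValueError):
            variant_list_pairwise_diffs({7: ""}, {7: "G"})


class TestEHH:
    def test_identical_carriers_stay_at_one(self):
        _, h = small_matrix([[0, 0, 1, 1]] * 5, positions=[10, 20, 30, 40, 50])
        curve = ehh_curve(h, 30, ["s0|0", "s0|1"], "right")
        assert np.all(curve.ehh == 1.0)

    def test_split_into_two_pairs_gives_one_third(self):
        # 4 carriers (cols 0-3); beyond the focal site they split into 2 identical
        # pairs: EHH = 2 / C(4,2) = 1/3
        alleles = [
            [0, 0, 0, 0, 9, 9],
            [0, 0, 1, 1, 9, 9],
        ]
        alleles = np.array(alleles, dtype=np.int8)
        alleles[alleles == 9] = MISSING
        _, h = small_matrix(alleles, positions=[10, 20])
        carriers = ["s0|0", "s0|1", "s1|0", "s1|1"]
        curve = ehh_curve(h, 10, carriers, "right")
        assert curve.ehh.tolist() == [1.0, pytest.approx(1 / 3)]

    def test_all_distinct_drops_to_zero(self):
        alleles = np.array([[0, 0], [0, 1]], dtype=np.int8)
        _, h = small_matrix(alleles, positions=[10, 20], samples=["x"])
        curve = ehh_curve(h, 10, ["x|0", "x|1"], "right")
        assert curve.ehh.tolist() == [1.0, 0.0]

    def test_matches_brute_force_pair_identity_oracle(self):
        rng = np.random.default_rng(11)
        n_sites, n_haps = 60, 8
        alleles = rng.integers(0, 2, size=(n_sites, n_haps)).astype(np.int8)
        focal_idx = 30
        alleles[focal_idx] = 1  # shared core allele
        _, h = small_matrix(alleles, samples=[f"h{i}" for i in range(n_haps // 2)])
        carriers = [f"h{i}|{p}" for i in range(n_haps // 2) for p in (0, 1)]
        curve = ehh_curve(h, int(h.positions[focal_idx]), carriers, "right")
        # oracle: fraction of carrier pairs identical over the full span
        for k, pos in enumerate(curve.positions):
            j = focal_idx + k
            span = alleles[focal_idx : j + 1]
            pairs_same = sum(
                np.array_equal(span[:, a], span[:, b])
                for a in range(n_haps)
                for b in range(a + 1, n_haps)
            )
            assert curve.ehh[k] == pytest.approx(pairs_same / (n_haps * (n_haps - 1) / 2))

    def test_discordant_core_rejected(self):
        _, h = small_matrix([[0, 1, 0, 0]], positions=[10])
        with pytest.raises(ValueError):
            ehh_curve(h, 10, ["s0|0", "s0|1"], "left")


class TestSpanAndAge:
    def _curve(self, side, ehh_vals, positions):
        return EHHCurve(side=side, positions=np.array(positions), ehh=np.array(ehh_vals),
                        focal=positions[0], n=22)

    def test_boundary_p_is_mean_of_sides(self):
        left = self._curve("left", [1.0, 0.5, 0.18], [100, 90, 80])
        right = self._curve("right", [1.0, 0.6, 0.228], [100, 110, 130])
        span = span_homozygosity(left, right, threshold=0.25, rate_cm_per_bp=1e-6)
        assert span.p == pytest.approx(0.204)
        assert span.r_left_cm == pytest.approx(20 * 1e-6)
        assert span.r_right_cm == pytest.approx(30 * 1e-6)

    def test_side_never_crossing_rejected(self):
        left = self._curve("left", [1.0, 0.9], [100, 90])
        right = self._curve("right", [1.0, 0.1], [100, 110])
        with pytest.raises(ValueError, match="never"):
            span_homozygosity(left, right, threshold=0.25, rate_cm_per_bp=1e-6)

    def test_degenerate_threshold_stops_at_first_site(self):
        left = self._curve("left", [1.0, 0.8], [100, 90])
        right = self._curve("right", [1.0, 0.7], [100, 110])
        span = span_homozygosity(left, right, threshold=1.0, rate_cm_per_bp=1e-6)
        assert span.p == pytest.approx((0.8 + 0.7) / 2)

    def test_age_point_examples(self):
        assert age_point(0.5, 1.0) == 0.0
        # inversion of the published point estimate
        assert age_point(0.0809, 0.25) == pytest.approx(857, abs=1.0)

    def test_age_point_round_trip(self):
        for g0 in (10.0, 857.0, 5000.0):
            r = 0.0809
            pr = math.exp(-2 * (r / 100) * g0)
            assert age_point(r, pr) == pytest.approx(g0, rel=1e-12)

    def test_age_point_monotonicity(self):
        ages_pr = [age_point(0.1, pr) for pr in (0.1, 0.2, 0.4, 0.8)]
        assert all(b < a for a, b in zip(ages_pr, ages_pr[1:]))
        ages_r = [age_point(r, 0.25) for r in (0.05, 0.1, 0.2)]
        assert all(b < a for a, b in zip(ages_r, ages_r[1:]))

    def test_age_ci_against_binomial_cdf_oracle(self):
        n, p, r = 22, 0.204, 0.0809
        # brute-force quantiles: smallest N with CDF >= target
        def quantile(q):
            cdf = 0.0
            for k in range(n + 1):
                cdf += math.comb(n, k) * p**k * (1 - p) ** (n - k)
                if cdf >= q - 1e-12:
                    return k
            return n
        n_lo, n_hi = quantile(0.025), quantile(0.975)
        g_lo, g_hi = age_ci(n, p, r)
        assert g_lo == pytest.approx(age_point(r, n_hi / n))
        assert g_hi == pytest.approx(age_point(r, n_lo / n))
        assert g_lo <= age_point(r, p) <= g_hi

    def test_age_ci_widens_as_n_decreases(self):
        wide = age_ci(8, 0.204, 0.0809)
        narrow = age_ci(44, 0.204, 0.0809)
        assert (wide[1] - wide[0]) > (narrow[1] - narrow[0])

    def test_zero_quantile_flags_unbounded_upper_age(self):
        g_lo, g_hi = age_ci(5, 0.05, 0.1)
        assert math.isinf(g_hi)

    def test_generations_to_years(self):
        assert generations_to_years(857, 1) == 857
        assert generations_to_years(857, 2) == pytest.approx(428.5)
        assert generations_to_years(1000, 2) == 500
        with pytest.raises(ValueError):
            generations_to_years(857, 3)

    def test_genetic_distance_from_map_table(self):
        import pandas as pd

        gmap = pd.DataFrame({"pos": [0, 1_000_000], "cM": [0.0, 2.0]})
        assert genetic_distance_cm(250_000, 750_000, rec_map=gmap) == pytest.approx(1.0)
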