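import numpy as np
import pytest
from hypothesis import given, strategies as st

from infrapopgen.exceptions import InsufficientDataError
from infrapopgen.io import Alignment
from infrapopgen.stats import (
    compute_diversity_stats,
    nucleotide_diversity,
    pairwise_differences,
    r2_pvalue,
    r2_statistic,
    replicate_to_alignment,
    segregating_sites,
    simulate_coalescent_fixed_S,
    singleton_counts,
    tajima_constants,
    tajimas_d,
)

from oracles import (
    brute_k_hat,
    brute_pi,
    brute_r2,
    brute_segregating,
    brute_singletons,
    brute_tajimas_d,
    random_alignment,
)


def _al(*seqs):
    return Alignment([f"s{i}" for i in range(len(seqs))], list(seqs))


class TestPairwiseDifferences:
    def test_identical_sequences_give_zero(self):
        k, _ = pairwise_differences(_al("ACGTACGT", "ACGTACGT"))
        assert k == 0.0

    def test_single_difference_pair(self):
        k, d = pairwise_differences(_al("ACGTACGTAA", "ACGTACGTAG"))
        assert k == 1.0 and d[0, 1] == 1

    def test_needs_two_sequences(self):
        with pytest.raises(InsufficientDataError):
            pairwise_differences(_al("ACGT"))

    def test_missing_sites_excluded_pairwise(self):
        # the N masks the difference for that pair only
        k, d = pairwise_differences(_al("ACGT", "NCGT", "TCGT"))
        assert d[0, 1] == 0 and d[0, 2] == 1 and d[1, 2] == 0


class TestNucleotideDiversity:
    def test_two_sequences_one_diff_over_ten_sites(self):
        assert nucleotide_diversity(_al("ACGTACGTAA", "ACGTACGTAG")) == 0.1

    def test_monomorphic_alignment_is_zero(self):
        assert nucleotide_diversity(_al("ACGT", "ACGT", "ACGT")) == 0.0

    def test_pair_without_compared_sites_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            pi = nucleotide_diversity(_al("ACNN", "NNGT", "ACGT"))
        assert not np.isnan(pi)

    def test_equals_khat_over_L_without_missing(self, rng):
        seqs = random_alignment(rng, 6, 30, p_missing=0.0)
        al = _al(*seqs)
        k, _ = pairwise_differences(al)
        assert nucleotide_diversity(al) == pytest.approx(k / 30, abs=1e-12)


class TestSegregatingSites:
    def test_monomorphic_is_zero(self):
        S, pos = segregating_sites(_al("ACGT", "ACGT"))
        assert (S, pos) == (0, [])

    def test_positions_are_one_based(self):
        S, pos = segregating_sites(_al("ACGT", "GCGA"))
        assert (S, pos) == (2, [1, 4])

    def test_ambiguity_does_not_segregate(self):
        # N vs A is not evidence of polymorphism
        S, _ = segregating_sites(_al("ACGT", "NCGT"))
        assert S == 0


class TestSingletons:
    def test_two_sequences_all_sites_singleton_in_both(self):
        U = singleton_counts(_al("ACGTAC", "AGGTAT"))
        assert list(U) == [2, 2]

    def test_star_alignment_one_private_mutation_each(self):
        base = "A" * 8
        seqs = [base[:i] + "G" + base[i + 1:] for i in range(4)]
        assert list(singleton_counts(_al(*seqs))) == [1, 1, 1, 1]


class TestTajimasD:
    def test_two_sequence_alignment_has_zero_numerator(self):
        # with n=2, a1=1 and k-hat == S so D == 0 exactly
        D, p = tajimas_d(_al("ACGTACGTAA", "ACCTACGAAA"))
        assert D == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_monomorphic_alignment_undefined_not_zero(self):
        D, p = tajimas_d(_al("ACGT", "ACGT", "ACGT"))
        assert np.isnan(D) and np.isnan(p)

    def test_n4_s3_toy_matches_independent_evaluation(self):
        seqs = ["ACGTACGTAA", "GCGTACGTAA", "ATGTACGTAA", "ACATACGTAA"]
        D, _ = tajimas_d(_al(*seqs))
        assert D == pytest.approx(brute_tajimas_d(seqs), abs=1e-12)

    def test_constants_sum_identities(self):
        c = tajima_constants(10)
        assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))
        assert c["e1"] == pytest.approx(c["c1"] / c["a1"])


class TestR2:
    @pytest.mark.parametrize("seqs", [("ACGTAC", "AGGTAT"), ("AAAA", "AAAG")])
    def test_two_sequences_closed_form_half(self, seqs):
        assert r2_statistic(_al(*seqs)) == pytest.approx(0.5, abs=1e-15)

    def test_undefined_when_monomorphic(self):
        assert np.isnan(r2_statistic(_al("ACGT", "ACGT")))


@pytest.mark.parametrize("case", range(40))
def test_statistics_match_brute_force_oracles(case):
    """Vectorised statistics equal nested-loop reimplementations exactly."""
    rng = np.random.default_rng(1000 + case)
    n = int(rng.integers(2, 11))
    L = int(rng.integers(5, 51))
    seqs = random_alignment(rng, n, L)
    al = _al(*seqs)
    k, _ = pairwise_differences(al)
    assert k == pytest.approx(brute_k_hat(seqs), abs=1e-12)
    S, pos = segregating_sites(al)
    assert (S, pos) == brute_segregating(seqs)
    assert list(singleton_counts(al)) == brute_singletons(seqs)
    bpi = brute_pi(seqs)
    pi = nucleotide_diversity(al)
    assert pi == pytest.approx(bpi, abs=1e-12) or (np.isnan(pi) and np.isnan(bpi))
    D, _ = tajimas_d(al)
    bD = brute_tajimas_d(seqs)
    assert D == pytest.approx(bD, abs=1e-12) or (np.isnan(D) and np.isnan(bD))
    r2 = r2_statistic(al)
    br2 = brute_r2(seqs)
    assert r2 == pytest.approx(br2, abs=1e-12) or (np.isnan(r2) and np.isnan(br2))


class TestCoalescentSimulator:
    def test_two_lineages_every_site_is_a_singleton(self, rng):
        rep = simulate_coalescent_fixed_S(2, 5, rng)
        assert rep.incidence.sum(axis=0).tolist() == [1] * 5

    def test_every_site_polymorphic(self, rng):
        for _ in range(50):
            rep = simulate_coalescent_fixed_S(8, 12, rng)
            d = rep.incidence.sum(axis=0)
            assert d.min() >= 1 and d.max() <= 7

    def test_incidence_summary_consistency(self, rng):
        # k-hat/U computed from bitmasks agree with the rendered alignment
        rep = simulate_coalescent_fixed_S(7, 9, rng)
        al = replicate_to_alignment(rep)
        k, _ = pairwise_differences(al)
        k2, U2 = rep.summary()
        assert k == pytest.approx(k2, abs=1e-12)
        assert list(singleton_counts(al)) == list(U2)
        assert rep.r2() == pytest.approx(r2_statistic(al), abs=1e-12)

    def test_mean_total_tree_length_matches_closed_form(self):
        rng = np.random.default_rng(5)
        n, reps = 6, 3000
        tl = [simulate_coalescent_fixed_S(n, 1, rng).total_tree_length
              for _ in range(reps)]
        expected = 2 * sum(1 / i for i in range(1, n))
        se = np.std(tl) / np.sqrt(reps)
        assert abs(np.mean(tl) - expected) < 3 * se


class TestR2Pvalue:
    def test_deterministic_given_seed(self):
        al = _al("ACGTACGTAA", "ACCTACGAAA", "ACGAACGTAT", "GCGTACGTAA")
        r1 = r2_pvalue(al, reps=200, rng=np.random.default_rng(3))
        r2 = r2_pvalue(al, reps=200, rng=np.random.default_rng(3))
        assert r1 == r2

    def test_pvalue_in_unit_interval_and_never_zero(self, rng):
        al = _al("ACGTACGTAA", "ACCTACGAAA", "ACGAACGTAT", "GCGTACGTAA")
        _, p = r2_pvalue(al, reps=99, rng=rng)
        assert 1 / 100 <= p <= 1.0

    def test_undefined_without_polymorphism(self, rng):
        r2, p = r2_pvalue(_al("ACGT", "ACGT"), reps=10, rng=rng)
        assert np.isnan(r2) and np.isnan(p)


@given(st.integers(0, 2**31 - 1))
def test_masking_never_increases_differences(seed):
    """Replacing a base with N can only remove pairwise differences."""
    rng = np.random.default_rng(seed)
    seqs = random_alignment(rng, 4, 12, p_missing=0.0)
    al = _al(*seqs)
    _, before = pairwise_differences(al)
    i = int(rng.integers(4))
    site = int(rng.integers(12))
    masked = [s if k != i else s[:site] + "N" + s[site + 1:]
              for k, s in enumerate(seqs)]
    _, after = pairwise_differences(_al(*masked))
    assert (after <= before).all()

    # masking at a non-segregating site never changes S
    S0, pos = segregating_sites(al)
    non_seg = [p - 1 for p in range(1, 13) if p not in pos]
    if non_seg:
        site = non_seg[int(rng.integers(len(non_seg)))]
        masked = [s if k != i else s[:site] + "N" + s[site + 1:]
                  for k, s in enumerate(seqs)]
        assert segregating_sites(_al(*masked))[0] == S0


def test_compute_diversity_stats_bundles_everything(rng):
    seqs = random_alignment(rng, 6, 40)
    st_ = compute_diversity_stats(_al(*seqs), r2_reps=100, rng=rng)
    assert st_.n == 6 and st_.L == 40
    assert st_.S == brute_segregating(seqs)[0]
    assert st_.pi == pytest.approx(brute_pi(seqs), abs=1e-12)
    if st_.S > 0:
        assert 0 < st_.p_R2 <= 1
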