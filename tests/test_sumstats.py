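"""Diversity statistics against brute-force oracles, hand computations and
an Ewens-sampling-formula Monte Carlo."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_alignment, random_alignment
from mitodem.coalsim import default_sample_config, drop_mutations, simulate_genealogy, simulate_variants
from mitodem.demography import build_scenario
from mitodem.sumstats import (
    LayerSummaryStats,
    abc_feature_vector,
    effective_columns,
    features_from_variants,
    fold_change_report,
    fus_fs,
    _fus_fs_float,
    haplotype_stats,
    layer_stats,
    mean_pairwise_differences,
    nucleotide_diversity,
    segregating_sites,
    tajimas_d,
    unsigned_stirling_first,
)


def brute_pairwise_k(aln):
    """Double-loop mean pairwise differences over complete-deletion columns."""
    keep = effective_columns(aln)
    mat = aln.matrix[:, keep]
    n = mat.shape[0]
    total = sum(
        (mat[i] != mat[j]).sum() for i, j in combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


class TestEffectiveColumns:
    def test_clean_alignment_keeps_all(self):
        aln = make_alignment(["ACGT", "ACGA"])
        assert effective_columns(aln).tolist() == [0, 1, 2, 3]

    def test_single_n_drops_one_column(self):
        aln = make_alignment(["ACGTACGT", "ACGTACGN"])
        assert effective_columns(aln).size == 7

    def test_all_missing_column_errors(self):
        aln = make_alignment(["N", "N"])
        with pytest.raises(ValueError, match="survive"):
            effective_columns(aln)

    def test_surviving_fraction_matches_independence_product(self, rng):
        """With 2% independent N per cell and n sequences, a column survives
        with probability 0.98^n."""
        n, L, f = 8, 4000, 0.02
        fracs = [
            effective_columns(random_alignment(rng, n, L, n_fraction=f)).size / L
            for _ in range(30)
        ]
        expect = (1 - f) ** n
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expect) < 3 * se


class TestCountingStats:
    def test_identical_sequences(self):
        aln = make_alignment(["ACGT"] * 4)
        assert segregating_sites(aln) == 0
        assert mean_pairwise_differences(aln) == 0.0

    def test_two_sequences_three_diffs(self):
        aln = make_alignment(["AAAAACGT", "AAAAAGCA"])
        assert segregating_sites(aln) == 3
        assert mean_pairwise_differences(aln) == 3.0
        pi, k = nucleotide_diversity(aln)
        assert k == 3.0 and pi == pytest.approx(3 / 8)

    def test_matches_brute_force_on_random_alignments(self, rng):
        for _ in range(20):
            aln = random_alignment(rng, n=rng.integers(3, 9), length=30, n_fraction=0.05)
            assert mean_pairwise_differences(aln) == pytest.approx(brute_pairwise_k(aln))
            pi, k = nucleotide_diversity(aln)
            assert pi * effective_columns(aln).size == pytest.approx(k)

    def test_needs_two_sequences(self):
        aln = make_alignment(["ACGT"])
        with pytest.raises(ValueError):
            segregating_sites(aln)

    def test_infinite_sites_S_equals_mutation_count(self, rng):
        """On simulated infinite-sites data, every mutation is one
        segregating site (simulator bookkeeping oracle)."""
        sc = build_scenario("constant", {"ne": 500, "mu": 1e-6})
        cfg = default_sample_config(n_modern=6, n_historical=4, locus_length=3000)
        g = simulate_genealogy(sc, cfg, rng)
        sim = drop_mutations(g, 1e-6, 3000, rng)
        from mitodem.sumstats import TemporalAlignment

        aln = TemporalAlignment.from_simulation(sim)
        assert segregating_sites(aln) == (~(sim.matrix == sim.matrix[0]).all(axis=0)).sum()


class TestHaplotypes:
    def test_all_identical(self):
        h, hd, se = haplotype_stats(make_alignment(["ACGT"] * 5))
        assert (h, hd, se) == (1, 0.0, 0.0)

    def test_two_haplotypes_two_plus_two(self):
        h, hd, _ = haplotype_stats(make_alignment(["AAAA", "AAAA", "AAAT", "AAAT"]))
        assert h == 2
        assert hd == pytest.approx((4 / 3) * (1 - 0.5))

    def test_museum_layer_configuration(self):
        """39 samples as 33 singleton + 3 doubleton haplotypes give the
        published historical haplotype diversity of 0.996."""
        counts = [1] * 33 + [2] * 3
        n = sum(counts)
        assert n == 39
        seqs = []
        for idx, c in enumerate(counts):
            base = format(idx, "06b").replace("0", "A").replace("1", "C")
            seqs.extend([base] * c)
        h, hd, se = haplotype_stats(make_alignment(seqs))
        assert h == 36
        assert hd == pytest.approx((39 / 38) * (1 - 45 / 1521))
        assert hd == pytest.approx(0.996, abs=5e-4)
        assert 0 < se < 0.05


class TestTajimasD:
    def test_historical_worked_example(self):
        assert tajimas_d(39, 100, 0.00059 * 16_588) == pytest.approx(-2.1537, abs=1e-4)

    def test_modern_worked_example(self):
        assert tajimas_d(79, 7, 0.00005 * 16_588) == pytest.approx(-1.0098, abs=1e-4)

    def test_monomorphic_undefined(self):
        assert tajimas_d(39, 0, 0.0) is None

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(3, 5, 1.0)


class TestStirling:
    def test_small_values_by_recurrence(self):
        assert unsigned_stirling_first(3) == (0, 2, 3, 1)
        assert unsigned_stirling_first(4)[2] == 11

    def test_factorial_identity(self):
        for n in (2, 5, 10):
            assert unsigned_stirling_first(n)[1] == math.factorial(n - 1)

    def test_rising_factorial_identity(self):
        """sum_j |s(n,j)| theta^j = theta (theta+1) ... (theta+n-1)."""
        n, theta = 6, 2
        row = unsigned_stirling_first(n)
        lhs = sum(row[j] * theta**j for j in range(n + 1))
        rhs = math.prod(theta + i for i in range(n))
        assert lhs == rhs


class TestFusFs:
    def test_hand_example(self):
        """n=3, h=2, theta=1: S' = (3 + 1)/6 = 2/3, Fs = ln 2."""
        assert fus_fs(3, 2, 1.0) == pytest.approx(math.log(2))

    def test_single_haplotype_is_infinite(self):
        assert fus_fs(10, 1, 2.0) == math.inf

    def test_zero_theta_undefined(self):
        assert fus_fs(10, 3, 0.0) is None

    def test_exact_matches_log_space_float(self):
        for n, h, k in [(39, 36, 9.787), (79, 4, 0.8294), (79, 70, 25.0), (50, 2, 0.5)]:
            assert fus_fs(n, h, k) == pytest.approx(_fus_fs_float(n, h, k), abs=1e-6)

    def test_tail_probability_matches_crp_monte_carlo(self, rng):
        """P(K >= h) under the Ewens sampling formula, checked against a
        Chinese-restaurant-process simulation."""
        n, h, theta, reps = 8, 4, 2.5, 40_000
        new_table = rng.random((reps, n - 1)) < theta / (theta + np.arange(1, n))
        K = 1 + new_table.sum(axis=1)
        mc = np.mean(K >= h)
        sp = math.exp(fus_fs(n, h, theta)) / (1 + math.exp(fus_fs(n, h, theta)))
        se = math.sqrt(mc * (1 - mc) / reps)
        assert abs(sp - mc) < 3 * se


class TestLayerStats:
    def test_two_layer_feature_vector_shape_and_order(self, rng):
        aln = random_alignment(
            rng, 8, 40, layers=["modern"] * 4 + ["historical"] * 4
        )
        v = abc_feature_vector(aln)
        assert v.shape == (8,)
        stats = layer_stats(aln)
        assert v[0] == stats["modern"].h and v[4] == stats["historical"].h
        assert v[1] == stats["modern"].S and v[5] == stats["historical"].S

    def test_monomorphic_layer_encodes_zero_d(self):
        aln = make_alignment(["ACGT"] * 4)
        assert abc_feature_vector(aln).tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_feature_vector_is_compositional(self, rng):
        aln = random_alignment(rng, 10, 60, layers=["modern"] * 6 + ["historical"] * 4)
        v = abc_feature_vector(aln)
        for offset, layer in ((0, "modern"), (4, "historical")):
            sub = aln.subset(aln.layer_rows(layer))
            keep_all = effective_columns(aln)
            sub.matrix = aln.matrix[np.ix_(aln.layer_rows(layer), keep_all)]
            h, _, _ = haplotype_stats(sub)
            k = mean_pairwise_differences(sub)
            assert v[offset] == h
            assert v[offset + 2] == pytest.approx(k)

    def test_small_layer_raises_in_strict_mode(self):
        aln = make_alignment(["ACGT", "ACGA", "ACGG"], layers=["modern", "modern", "historical"])
        with pytest.raises(ValueError, match="historical"):
            layer_stats(aln, strict=True)

    def test_fast_path_equals_alignment_path(self, rng):
        """features_from_variants on the incidence matrix must equal the
        full string-alignment route on the same simulated data."""
        sc = build_scenario("constant", {"ne": 800, "mu": 5e-7})
        cfg = default_sample_config(n_modern=8, n_historical=6, locus_length=5000)
        for _ in range(10):
            seed = int(rng.integers(2**31))
            d, layers = simulate_variants(sc, cfg, 5e-7, np.random.default_rng(seed))
            fast = features_from_variants(d, layers, cfg.ages_by_layer())
            rng2 = np.random.default_rng(seed)  # replay the same draw sequence
            g = simulate_genealogy(sc, cfg, rng2)
            sim = drop_mutations(g, 5e-7, 5000, rng2)
            from mitodem.sumstats import TemporalAlignment

            slow = abc_feature_vector(TemporalAlignment.from_simulation(sim))
            # same genealogy (same seed) -> identical counting stats
            np.testing.assert_allclose(fast, slow, atol=1e-9)


class TestFoldChange:
    def _stats(self, hd, pi):
        return LayerSummaryStats(
            n=10, h=3, S=5, Hd=hd, Hd_se=0.0, pi=pi, pi_se=0.0, k=pi * 100, D=None, Fs=None, L_eff=100
        )

    def test_published_ratios(self):
        hd_ratio, pi_ratio = fold_change_report(
            self._stats(0.996, 0.00059), self._stats(0.0331, 0.00005)
        )
        assert hd_ratio == pytest.approx(30.09, abs=0.01)
        assert pi_ratio == pytest.approx(11.8, abs=0.01)

    def test_equal_layers(self):
        s = self._stats(0.5, 0.001)
        assert fold_change_report(s, s) == (1.0, 1.0)

    def test_zero_modern_diversity_warns_infinite(self):
        with pytest.warns(UserWarning):
            hd_ratio, _ = fold_change_report(self._stats(0.9, 0.1), self._stats(0.0, 0.0))
        assert hd_ratio == math.inf


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    n=st.integers(4, 8),
    length=st.integers(6, 25),
    seed=st.integers(0, 2**20),
)
def test_invariants_on_random_alignments(n, length, seed):
    """Hd in [0,1]; 1 <= h <= n; pi * L_eff = k; D agrees with a direct
    transcription of its defining formula."""
    rng = np.random.default_rng(seed)
    aln = random_alignment(rng, n, length, n_fraction=0.03)
    try:
        keep = effective_columns(aln)
    except ValueError:
        return  # everything deleted: statistic undefined by construction
    h, hd, _ = haplotype_stats(aln)
    assert 1 <= h <= n
    assert 0.0 <= hd <= 1.0 + 1e-12
    pi, k = nucleotide_diversity(aln)
    assert pi * keep.size == pytest.approx(k)
    S = segregating_sites(aln)
    if h == 1:
        assert S == 0
    if S > 0:
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        expect = (k - S / a1) / math.sqrt(c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1))
        assert tajimas_d(n, S, k) == pytest.approx(expect, abs=1e-9)
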