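"""Shared-variation statistics: closed forms vs enumeration/Monte-Carlo
oracles, PCA and structure regression properties."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cnsvar.stats import (
    binary_pca,
    count_correlation,
    expected_distinct,
    hypergeom_overlap_test,
    hypergeom_pmf,
    kmer_expected,
    rarefaction,
    shared_event_fraction,
    structure_r2,
    variation_matrix,
)


def mc_distinct(k, N, n_reps, rng):
    """Monte-Carlo oracle: distinct count of independent uniform draws
    without replacement, vectorised over replicates."""
    hit = np.zeros((n_reps, N), dtype=bool)
    for ki in k:
        if ki == 0:
            continue
        u = rng.random((n_reps, N))
        thresh = np.partition(u, ki - 1, axis=1)[:, ki - 1 : ki]
        hit |= u <= thresh
    return hit.sum(axis=1)


class TestExpectedDistinct:
    def test_single_accession_is_its_own_count(self):
        assert expected_distinct([5], 100) == pytest.approx(5.0)

    def test_saturating_accession_gives_universe(self):
        assert expected_distinct([100, 3, 7], 100) == 100.0

    def test_counts_beyond_universe_rejected(self):
        with pytest.raises(ValueError):
            expected_distinct([101], 100)

    def test_matches_monte_carlo_oracle_over_random_configs(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            N = int(rng.integers(50, 2000))
            n_acc = int(rng.integers(2, 8))
            k = rng.integers(0, N + 1, n_acc)
            draws = mc_distinct(k, N, 10_000, rng)
            se = draws.std(ddof=1) / np.sqrt(len(draws))
            closed = expected_distinct(k, N)
            assert abs(closed - draws.mean()) <= 3 * max(se, 1e-9)


class TestSharedEventFraction:
    def test_private_events_give_zero(self):
        assert shared_event_fraction(np.eye(4, dtype=int)) == 0.0

    def test_universal_events_give_one(self):
        assert shared_event_fraction(np.ones((3, 5), dtype=int)) == 1.0

    def test_mixed_column_sums(self):
        m = np.zeros((3, 4), dtype=int)
        m[0, 0] = 1                      # sum 1
        m[1, 1] = 1                      # sum 1
        m[:2, 2] = 1                     # sum 2
        m[:, 3] = 1                      # sum 3
        assert shared_event_fraction(m) == 0.5

    def test_no_variable_cns_is_an_error(self):
        with pytest.raises(ValueError):
            shared_event_fraction(np.zeros((2, 3), dtype=int))


class TestHypergeom:
    def test_pmf_sums_to_one_over_support(self):
        for N, nA, nB in [(100, 30, 40), (62_916, 1_524, 4_801), (10, 4, 5)]:
            lo = max(0, nA + nB - N)
            ks = np.arange(lo, min(nA, nB) + 1)
            total = hypergeom_pmf(ks, N, nA, nB).sum()
            assert abs(total - 1) < 1e-12

    def test_small_case_matches_exact_fraction_enumeration(self):
        # universe 10, |A|=4, |B|=5: enumerate all C(10,5) draws of B
        N, nA, x = 10, 4, 2
        hits = 0
        total = 0
        for draw in combinations(range(N), 5):
            total += 1
            if len(set(draw) & set(range(nA))) >= x:
                hits += 1
        exact = Fraction(hits, total)
        res = hypergeom_overlap_test(10, 4, 5, 2, tail="ge")
        assert res.p == pytest.approx(float(exact), abs=1e-12)

    def test_matches_scipy_survival_function(self):
        res = hypergeom_overlap_test(62_916, 1_524, 4_801, 118, tail="gt")
        assert res.p == pytest.approx(sps.hypergeom(62_916, 1_524, 4_801).sf(118), rel=1e-9)

    def test_forced_overlap_has_probability_one(self):
        assert hypergeom_overlap_test(10, 10, 5, 5, tail="ge").p == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap_test(10, 11, 5, 2)
        with pytest.raises(ValueError):
            hypergeom_overlap_test(10, 4, 5, 5)


class TestKmerExpected:
    def test_degenerate_genome_equal_to_k(self):
        assert kmer_expected(6, 6) == pytest.approx(4.0 ** -6)

    def test_both_strands_doubles(self):
        assert kmer_expected(1000, 6, both_strands=True) == pytest.approx(
            2 * kmer_expected(1000, 6)
        )

    def test_k_larger_than_genome_rejected(self):
        with pytest.raises(ValueError):
            kmer_expected(10, 11)


class TestRarefaction:
    MATRIX = pd.DataFrame(
        (np.random.default_rng(5).random((6, 40)) < 0.2).astype(int)
    )

    def test_full_subsample_recovers_total_distinct_exactly(self):
        t = rarefaction(self.MATRIX, n_draws=50, seed=1)
        total = int((self.MATRIX.sum(axis=0) >= 1).sum())
        last = t.iloc[-1]
        assert last["mean_distinct"] == total
        assert last["sd_distinct"] == 0.0

    def test_single_accession_mean_approximates_mean_row_sum(self):
        t = rarefaction(self.MATRIX, n_draws=4000, seed=2)
        k_mean = self.MATRIX.sum(axis=1).mean()
        assert t.iloc[0]["mean_distinct"] == pytest.approx(k_mean, rel=0.05)

    def test_curve_is_monotone(self):
        t = rarefaction(self.MATRIX, n_draws=500, seed=3)
        assert (np.diff(t["mean_distinct"]) >= 0).all()

    def test_deterministic_for_fixed_seed(self):
        a = rarefaction(self.MATRIX, n_draws=20, seed=9)
        b = rarefaction(self.MATRIX, n_draws=20, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCountCorrelation:
    def test_proportional_counts_correlate_perfectly(self):
        r, p = count_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_reversed_counts_anticorrelate(self):
        r, _ = count_correlation([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_null_simulation_is_calibrated(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(1000):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            ps.append(count_correlation(x, y)[1])
        assert np.mean(np.array(ps) <= 0.05) <= 0.075

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            count_correlation([1, 1, 1], [1, 2, 3])


class TestBinaryPca:
    def test_planted_groups_separate_on_pc1(self):
        m = np.zeros((10, 60), dtype=int)
        m[:5, :30] = 1          # group 1 varies in the first CNS block
        m[5:, 30:] = 1          # group 2 in the second
        rng = np.random.default_rng(0)
        m ^= rng.random(m.shape) < 0.05
        res = binary_pca(pd.DataFrame(m))
        pc1 = res.scores["PC1"].to_numpy()
        assert (np.sign(pc1[:5]) != np.sign(pc1[5:])).all()

    def test_percent_variance_non_increasing_and_bounded(self):
        rng = np.random.default_rng(1)
        res = binary_pca(pd.DataFrame((rng.random((8, 30)) < 0.3).astype(int)))
        assert (np.diff(res.percent_variance) <= 1e-9).all()
        assert res.percent_variance.sum() <= 100 + 1e-9

    def test_duplicate_accessions_get_identical_scores(self):
        rng = np.random.default_rng(2)
        m = (rng.random((5, 20)) < 0.4).astype(int)
        m = np.vstack([m, m[0]])
        res = binary_pca(pd.DataFrame(m))
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[-1])

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            binary_pca(pd.DataFrame(np.ones((4, 5), dtype=int)))


class TestStructureR2:
    def test_exact_linear_combination_gives_r2_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, -2.0, 0.5] + 3
        assert structure_r2(X, y).r2_base == pytest.approx(1.0)

    def test_null_mean_r2_matches_p_over_n_minus_1(self):
        rng = np.random.default_rng(4)
        r2s = [
            structure_r2(rng.normal(size=(30, 3)), rng.normal(size=30)).r2_base
            for _ in range(1000)
        ]
        assert np.mean(r2s) == pytest.approx(3 / 29, abs=0.02)

    def test_adding_a_covariate_never_decreases_r2(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        cov = rng.normal(size=30)
        res = structure_r2(X, y, covariate=cov)
        assert res.r2_with_covariate >= res.r2_base - 1e-12
        assert res.increment == pytest.approx(res.r2_with_covariate - res.r2_base)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            structure_r2(X, np.arange(10, dtype=float))


def test_variation_matrix_from_calls_roundtrip():
    calls = pd.DataFrame(
        {
            "accession": ["a1", "a1", "a2", "a2"],
            "cns_id": ["c1", "c2", "c1", "c2"],
            "status": ["pav", "collinear", "pav", "posv"],
        }
    )
    m = variation_matrix(calls, "pav")
    assert m.loc["a1", "c1"] == 1 and m.loc["a2", "c2"] == 0
    assert m.to_numpy().sum() == 2
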