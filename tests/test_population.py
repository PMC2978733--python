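"""Population summaries: classification, frequencies, trios, permutations."""

import itertools

import numpy as np
import pandas as pd
import pytest

import copydepth as cd
from copydepth.mappability import Locus
from copydepth.population import (
    BIALLELIC_DELETION,
    BIALLELIC_DUPLICATION,
    MULTI_ALLELIC,
    NON_VARIABLE,
)


class TestClassifyLocus:
    @pytest.mark.parametrize(
        "genotypes,label",
        [
            ([2, 2, 2], NON_VARIABLE),
            ([0, 1, 2, 2], BIALLELIC_DELETION),
            ([1, 1, 1], BIALLELIC_DELETION),
            ([2, 3, 4], BIALLELIC_DUPLICATION),
            ([1, 2, 3], MULTI_ALLELIC),
            ([2, 2, 5], MULTI_ALLELIC),
        ],
    )
    def test_rules(self, genotypes, label):
        assert cd.classify_locus(genotypes).label == label

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cd.classify_locus([])

    def test_na_dropped_and_permutation_invariant(self):
        assert cd.classify_locus(pd.array([1, 2, None])).label == BIALLELIC_DELETION
        rng = np.random.default_rng(0)
        g = [0, 1, 2, 2, 1]
        for _ in range(5):
            assert cd.classify_locus(rng.permutation(g)).label == BIALLELIC_DELETION

    def test_adding_reference_sample_never_changes_class(self):
        for g in ([2, 2], [0, 1, 2], [3, 4], [1, 3]):
            assert cd.classify_locus(list(g) + [2]).label == cd.classify_locus(g).label


class TestAlleleFrequencies:
    def test_all_reference(self):
        vf, rf, (lo, hi) = cd.allele_freq_biallelic([2] * 10)
        assert vf == 0.0 and rf == 1.0

    def test_deletion_allele_counting(self):
        g = [0] * 2 + [1] * 4 + [2] * 4
        vf, rf, _ = cd.allele_freq_biallelic(g)
        assert vf == pytest.approx(0.4)  # (2*2 + 4) / 20
        assert rf == pytest.approx(0.6)

    def test_duplication_allele_counting(self):
        g = [4] * 1 + [3] * 2 + [2] * 7
        vf, _, _ = cd.allele_freq_biallelic(g)
        assert vf == pytest.approx(0.2)

    def test_wilson_bound_at_monomorphic_locus(self):
        _, rf, (lo, hi) = cd.allele_freq_biallelic([2] * 150)
        assert rf == 1.0
        assert lo == pytest.approx(0.9874, abs=2e-4)

    def test_multiallelic_input_rejected(self):
        with pytest.raises(ValueError):
            cd.allele_freq_biallelic([1, 2, 3])

    def test_hardy_weinberg_recovery(self):
        q = 0.3
        g = cd.genotypes_from_allele_freq(1, 500, q, "deletion", seed=1)[0]
        vf, _, _ = cd.allele_freq_biallelic(g)
        assert vf == pytest.approx(q, abs=0.03)

    @pytest.mark.parametrize("p2,expected", [(1.0, 1.0), (0.25, 0.5), (0.0, 0.0)])
    def test_multiallelic_sqrt_estimator(self, p2, expected):
        n = 100
        n2 = int(round(p2 * n))
        g = [2] * n2 + [5] * (n - n2)
        assert cd.ref_freq_multiallelic(g) == pytest.approx(expected)
        assert cd.ref_freq_multiallelic(g, estimator="p2") == pytest.approx(p2)

    def test_multiallelic_sqrt_consistency_on_simulated_triallelic(self):
        # two variant alleles (del + dup) at HW; p2 = ref_freq^2 exactly
        rng = np.random.default_rng(2)
        ref = 0.7
        alleles = rng.choice([-1, 0, 1], p=[0.15, ref, 0.15], size=(500, 2))
        g = 2 + alleles.sum(axis=1)
        est = cd.ref_freq_multiallelic(g)
        # p2 includes del+dup compound heterozygotes (-1,+1): subtract their share
        p2_true = ref**2 + 2 * 0.15 * 0.15
        assert est == pytest.approx(np.sqrt(p2_true), abs=0.03)


class TestPairwiseDiff:
    def test_sum_of_absolute_differences(self):
        m = pd.DataFrame({"s1": [2, 2, 1], "s2": [2, 0, 3]})
        d = cd.pairwise_diff(m)
        assert d.loc["s1", "s2"] == 4

    def test_metric_properties(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(0, 5, size=(20, 6)), columns=list("abcdef"))
        d = cd.pairwise_diff(m)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for x, y, z in itertools.permutations("abcdef", 3):
            assert d.loc[x, z] <= d.loc[x, y] + d.loc[y, z] + 1e-9

    def test_single_variable_locus_carries_all_difference(self):
        m = pd.DataFrame({"s1": [2, 2, 1], "s2": [2, 2, 3]})
        curve = cd.ranked_cumulative_diff(m)
        assert curve["pct_max_diff"].iloc[0] == 100.0
        assert len(curve) == 1  # one frequency class only

    def test_common_cnvs_dominate_curve(self):
        rng = np.random.default_rng(4)
        common = cd.genotypes_from_allele_freq(10, 50, 0.4, "deletion", seed=5)
        rare = cd.genotypes_from_allele_freq(90, 50, 0.01, "deletion", seed=6)
        m = pd.DataFrame(np.vstack([common, rare]))
        curve = cd.ranked_cumulative_diff(m)
        # dropping the rare loci first barely reduces the mean difference
        mid = curve.iloc[len(curve) // 2]
        assert mid["pct_max_diff"] > mid["pct_loci_kept"]


class TestMendelianCheck:
    @pytest.mark.parametrize(
        "f,m,c,kind,expected",
        [
            (1, 1, 0, "deletion", True),
            (2, 2, 1, "deletion", False),
            (3, 2, 3, "duplication", True),
            (0, 2, 1, "deletion", True),
            (0, 2, 2, "deletion", False),
            (4, 4, 3, "duplication", False),
        ],
    )
    def test_examples(self, f, m, c, kind, expected):
        assert cd.mendelian_check(f, m, c, kind) is expected

    def test_multiallelic_rejected(self):
        with pytest.raises(ValueError, match="deletion|duplication|decompos"):
            cd.mendelian_check(1, 1, 0, "multi")
        with pytest.raises(ValueError):
            cd.mendelian_check(5, 2, 2, "duplication")

    def test_simulated_trios_always_consistent(self):
        rng = np.random.default_rng(7)
        freqs = rng.uniform(0.05, 0.95, 100)
        kinds = rng.choice(["deletion", "duplication"], 100)
        trio = cd.simulate_trio(freqs, kinds, seed=8)
        assert all(
            cd.mendelian_check(r.father, r.mother, r.child, r.kind) for r in trio.itertuples()
        )


class TestPermutationTest:
    def exhaustive_p(self, a, b):
        pooled = np.array(list(a) + list(b))
        t_obs = np.mean(a) - np.mean(b)
        n_a = len(a)
        hits = total = 0
        for idx in itertools.combinations(range(len(pooled)), n_a):
            mask = np.zeros(len(pooled), bool)
            mask[list(idx)] = True
            t = pooled[mask].mean() - pooled[~mask].mean()
            total += 1
            if abs(t) >= abs(t_obs) - 1e-12:
                hits += 1
        return hits / total

    def test_identical_groups_give_p_one(self):
        _, p = cd.permutation_test([1, 2, 3], [3, 1, 2], n_perm=500, seed=0)
        assert p == 1.0

    def test_exact_enumeration_small_case(self):
        # A=(1,1), B=(0,0): 6 assignments, 2 as extreme as observed
        assert self.exhaustive_p([1, 1], [0, 0]) == pytest.approx(2 / 6)
        _, p = cd.permutation_test([1, 1], [0, 0], n_perm=10_000, seed=1)
        se = np.sqrt((1 / 3) * (2 / 3) / 10_000)
        assert abs(p - 1 / 3) < 3 * se

    def test_monte_carlo_converges_to_enumeration(self):
        a, b = [0.0, 1.0, 2.0], [2.0, 3.0, 4.0]
        p_exact = self.exhaustive_p(a, b)
        _, p_mc = cd.permutation_test(a, b, n_perm=10_000, seed=2)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(p_mc - p_exact) < 3 * se

    def test_seeded_determinism(self):
        r1 = cd.permutation_test([1, 2], [3, 4], n_perm=100, seed=5)
        r2 = cd.permutation_test([1, 2], [3, 4], n_perm=100, seed=5)
        assert r1 == r2

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            cd.permutation_test([], [1.0], seed=0)


class TestMergeAdjacentCalls:
    def test_direction_runs(self):
        events = cd.merge_adjacent_calls(list("ABCD"), [3, 3, 2, 1])
        assert len(events) == 2
        dup, dele = events
        assert dup.direction == "duplication" and dup.n_loci == 2 and dup.multi_locus
        assert dele.direction == "deletion" and not dele.multi_locus

    def test_all_reference_no_events(self):
        assert cd.merge_adjacent_calls(["A", "B"], [2, 2]) == []

    def test_direction_change_breaks_run(self):
        events = cd.merge_adjacent_calls(["A", "B"], [1, 3])
        assert [e.direction for e in events] == ["deletion", "duplication"]

    def test_na_breaks_run(self):
        events = cd.merge_adjacent_calls(list("ABC"), pd.array([1, None, 1]))
        assert len(events) == 2


class TestSubstituteBoundaries:
    def test_identical_interval_substituted(self):
        loci = [Locus("L", "c", 100, 200)]
        out = cd.substitute_boundaries(loci, [("c", 100, 200)])
        assert (out[0].start, out[0].end) == (100, 200)

    def test_half_overlap_not_substituted(self):
        loci = [Locus("L", "c", 100, 200)]
        out = cd.substitute_boundaries(loci, [("c", 150, 250)])
        assert (out[0].start, out[0].end) == (100, 200)

    def test_disjoint_not_substituted(self):
        loci = [Locus("L", "c", 100, 200)]
        out = cd.substitute_boundaries(loci, [("c", 300, 400)])
        assert (out[0].start, out[0].end) == (100, 200)

    def test_best_reciprocal_overlap_wins(self):
        loci = [Locus("L", "c", 100, 200)]
        out = cd.substitute_boundaries(loci, [("c", 95, 205), ("c", 98, 201)])
        assert (out[0].start, out[0].end) == (98, 201)

    def test_equal_candidates_keep_original_with_warning(self):
        loci = [Locus("L", "c", 100, 200)]
        with pytest.warns(UserWarning, match="equally good"):
            out = cd.substitute_boundaries(loci, [("c", 95, 200), ("c", 100, 205)])
        assert (out[0].start, out[0].end) == (100, 200)


class TestConcordance:
    def test_identical_matrices(self):
        m = pd.DataFrame({"s1": [2, 1], "s2": [3, 2]}).astype("Int64")
        assert cd.concordance(m, m) == 1.0

    def test_one_mismatch_in_ten(self):
        a = pd.DataFrame(np.full((5, 2), 2)).astype("Int64")
        b = a.copy()
        b.iloc[0, 0] = 3
        assert cd.concordance(a, b) == pytest.approx(0.9)

    def test_na_cells_excluded(self):
        a = pd.DataFrame({"s": pd.array([2, None, 1])})
        b = pd.DataFrame({"s": pd.array([2, 2, 2])})
        assert cd.concordance(a, b) == pytest.approx(0.5)

    def test_all_na_errors(self):
        a = pd.DataFrame({"s": pd.array([None, None], dtype="Int64")})
        b = pd.DataFrame({"s": pd.array([2, 2], dtype="Int64")})
        with pytest.raises(ValueError):
            cd.concordance(a, b)
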