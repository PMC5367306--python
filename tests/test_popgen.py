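import numpy as np
import pandas as pd
import pytest

from _oracles import benjamini_hochberg, hwe_enum_biallelic, hwe_enum_general
from conftest import table_from_counts
from scallopop import (
    filter_microsat_loci,
    filter_snp_calls,
    hwe_exact_mc,
    ld_perm_test,
    make_snp_callset,
    sample_genotypes,
    storey_q,
    summary_stats,
)
from scallopop.genotypes import MISSING, CallSet, GenotypeTable, Locus


class TestSummaryStats:
    def test_all_heterozygous(self):
        gt = table_from_counts([{(0, 1): 8}])
        row = summary_stats(gt).iloc[0]
        assert row.Ho == 1.0

    def test_monomorphic_locus(self):
        gt = table_from_counts([{(0, 0): 5}])
        row = summary_stats(gt).iloc[0]
        assert row.He == 0.0 and row.n_alleles == 1

    def test_unbiased_he_hand_value(self):
        # AA=4, AB=4, BB=2: p=0.6, Ho=0.4, He=(20/19)(1-0.36-0.16)
        gt = table_from_counts([{(0, 0): 4, (0, 1): 4, (1, 1): 2}])
        row = summary_stats(gt).iloc[0]
        assert row.Ho == pytest.approx(0.4)
        assert row.He == pytest.approx(20 / 19 * 0.48, abs=1e-12)


class TestHWEExactMC:
    def test_monomorphic_locus_gives_p_one(self):
        r = hwe_exact_mc({(0, 0): 12})
        assert r.p == 1.0 and r.mc_se == 0.0

    def test_mc_matches_enumeration_on_example_table(self):
        r = hwe_exact_mc({(0, 0): 3, (0, 1): 5, (1, 1): 2}, 1000, 100, 200, seed=3)
        exact = hwe_enum_biallelic(3, 5, 2)
        assert abs(r.p - exact) <= 3 * r.mc_se + 1e-9

    def test_mc_matches_enumeration_multiallelic(self):
        counts = {(0, 0): 2, (0, 1): 2, (1, 1): 1, (1, 2): 1, (0, 2): 1}
        r = hwe_exact_mc(counts, 2000, 100, 400, seed=5)
        exact = hwe_enum_general(counts)
        assert abs(r.p - exact) <= 3 * r.mc_se + 10 / (100 * 400)

    def test_default_settings_recorded(self):
        r = hwe_exact_mc({(0, 0): 4}, seed=0)
        assert r.meta["dememorization"] == 10_000
        assert r.meta["batches"] == 1_000
        assert r.meta["iterations_per_batch"] == 10_000


class TestLDPermTest:
    def _table_with_copy(self, rng, n=40):
        gt = sample_genotypes([np.array([[0.4, 0.6]]), np.array([[0.5, 0.5]])], n,
                              seed=int(rng.integers(2**31)))
        calls = gt.calls.copy()
        calls[:, 1, :] = calls[:, 0, :]  # locus 1 duplicates locus 0
        return GenotypeTable(gt.individual_ids, gt.pop_labels, gt.loci, calls)

    def test_duplicated_locus_is_detected(self, rng):
        gt = self._table_with_copy(rng)
        res = ld_perm_test(gt, 0, 1, n_perm=999, seed=1)
        assert res["pop1"].p <= 0.01

    def test_type_one_error_calibration(self, rng):
        hits = 0
        reps = 400
        for k in range(reps):
            gt = sample_genotypes(
                [np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]])], 30,
                seed=int(rng.integers(2**31)),
            )
            res = ld_perm_test(gt, 0, 1, n_perm=99, seed=k)
            if res["pop1"].testable and res["pop1"].p <= 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) < 0.02 + 0.01  # binomial slack on 400 reps

    def test_zero_permutations_rejected(self, rng):
        gt = self._table_with_copy(rng)
        with pytest.raises(ValueError):
            ld_perm_test(gt, 0, 1, n_perm=0)

    def test_untestable_population_excluded_from_combination(self):
        gt = table_from_counts([{(0, 0): 10}])  # monomorphic: no genotype classes
        calls = np.concatenate([gt.calls, gt.calls], axis=1)
        gt2 = GenotypeTable(gt.individual_ids, gt.pop_labels,
                            [Locus("a"), Locus("b")], calls)
        res = ld_perm_test(gt2, 0, 1, n_perm=9)
        assert not res["pop1"].testable and not res["combined"].testable


class TestStoreyQ:
    def test_all_ones_stay_one(self):
        assert np.all(storey_q(np.ones(7)) == 1.0)

    def test_pi0_one_reduces_to_bh_hand_example(self):
        q = storey_q(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_pi0_one_equals_bh_exactly(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            assert np.allclose(storey_q(p, pi0=1.0), benjamini_hochberg(p), atol=0, rtol=0)

    def test_lower_bound_and_monotonicity(self, rng):
        p = rng.random(50)
        q = storey_q(p)
        pi0 = min(1.0, np.mean(p > 0.5) / 0.5)
        assert q.min() >= pi0 * p.min() - 1e-12
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty_input(self):
        assert storey_q(np.array([])).size == 0


class TestFilterMicrosat:
    def test_deviation_count_rule(self):
        sig = pd.DataFrame(
            False, index=["L1", "L2", "L3"], columns=[f"p{i}" for i in range(9)]
        )
        sig.loc["L1", sig.columns[:7]] = True  # deviates in 7 of 9
        sig.loc["L2", sig.columns[:5]] = True  # deviates in 5 of 9
        sig.loc["L3", sig.columns[:1]] = True  # deviates in 1 of 9
        kept, report = filter_microsat_loci(sig, max_deviating_pops=4)
        assert kept == ["L3"]
        assert report.loc["L1", "n_deviating_pops"] == 7
        assert report.loc["L2", "excluded"] and not report.loc["L3", "excluded"]


def _callset(call_counts, depths_value=10, snps_per_tag=1, n_ind=45):
    """Build a CallSet where SNP j is called in call_counts[j] individuals."""
    m = len(call_counts)
    calls = np.zeros((n_ind, m, 2), dtype=np.int64)
    calls[:, :, 1] = np.arange(n_ind)[:, None] % 2  # biallelic everywhere
    depths = np.full((n_ind, m), depths_value, dtype=np.int64)
    for j, c in enumerate(call_counts):
        calls[c:, j, :] = MISSING
        depths[c:, j] = 0
    gt = GenotypeTable(
        [f"i{i}" for i in range(n_ind)],
        ["p1"] * n_ind,
        [Locus(f"s{j}") for j in range(m)],
        calls,
    )
    tags = [f"t{j // snps_per_tag}" for j in range(m)]
    return CallSet(gt, depths, tags)


class TestFilterSNPCalls:
    def test_call_count_threshold(self):
        cs = _callset([39, 40, 45])
        res = filter_snp_calls(cs, min_individuals=40)
        assert [l.id for l in res.table.loci] == ["s1", "s2"]

    def test_best_snp_per_tag(self):
        cs = _callset([44, 41], snps_per_tag=2)
        res = filter_snp_calls(cs, min_individuals=40)
        assert [l.id for l in res.table.loci] == ["s0"]

    def test_depth_threshold_masks_genotypes(self):
        cs = _callset([45])
        cs.depths[0, 0] = 4
        cs.depths[1, 0] = 5
        res = filter_snp_calls(cs, min_individuals=40, min_depth=5)
        assert res.table.missing_mask()[0, 0]
        assert not res.table.missing_mask()[1, 0]

    def test_refiltering_is_noop(self):
        cs = _callset([45, 44, 41, 39], snps_per_tag=2)
        cs.depths[:3, 0] = 3
        once = filter_snp_calls(cs)
        twice = filter_snp_calls(once.callset)
        assert once.table.equals(twice.table)
        assert np.array_equal(once.callset.depths, twice.callset.depths)

    def test_non_biallelic_dropped(self):
        cs = _callset([45, 45])
        cs.table.calls[0, 0, 0] = 2  # third allele at SNP 0
        res = filter_snp_calls(cs, min_individuals=40)
        assert [l.id for l in res.table.loci] == ["s1"]

    def test_empty_callset_reports_zero(self):
        gt = GenotypeTable([], [], [], np.empty((0, 0, 2)))
        cs = CallSet(gt, np.empty((0, 0), dtype=int), [])
        with pytest.warns(UserWarning):
            res = filter_snp_calls(cs)
        assert res.report["n_after_one_per_tag"] == 0
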