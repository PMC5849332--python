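import numpy as np
import pytest

from ndanet.grouping import build_groups
from ndanet.nullmodels import (
    circular_shift_regions,
    circular_shift_snps,
    empirical_significance,
    ks_compare,
    post_mapping_null,
)
from ndanet.regions import SnpRecord

from oracles import brute_bh, brute_ks_statistic

GENOME = [("chr1", 50), ("chr2", 50)]


class TestCircularShiftSnps:
    def test_wrap_to_next_chromosome(self):
        snps = [SnpRecord("a", "chr1", 10, 0.5), SnpRecord("b", "chr1", 20, 0.5)]
        out = circular_shift_snps(snps, GENOME, 45)
        assert [(s.chrom, s.pos) for s in out] == [("chr2", 5), ("chr2", 15)]

    def test_wrap_past_genome_end(self):
        out = circular_shift_snps([SnpRecord("a", "chr2", 45, 0.5)], GENOME, 10)
        assert (out[0].chrom, out[0].pos) == ("chr1", 5)

    def test_identity_offset_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            circular_shift_snps([SnpRecord("a", "chr1", 1, 0.5)], GENOME, 100)

    def test_preserves_count_and_pvalues(self, rng):
        snps = [SnpRecord(f"s{k}", "chr1", int(rng.integers(1, 51)), float(rng.random())) for k in range(20)]
        out = circular_shift_snps(snps, GENOME, 37)
        assert len(out) == len(snps)
        assert [s.pvalue for s in out] == [s.pvalue for s in snps]

    def test_inverse_shift_round_trips(self):
        snps = [SnpRecord("a", "chr1", 10, 0.5), SnpRecord("b", "chr2", 33, 0.1)]
        out = circular_shift_snps(circular_shift_snps(snps, GENOME, 37), GENOME, 100 - 37)
        assert [(s.chrom, s.pos) for s in out] == [(s.chrom, s.pos) for s in snps]


class TestCircularShiftRegions:
    def test_wraparound_example(self):
        out = circular_shift_regions([1, 2, 9], 10, 3)
        assert sorted(out.tolist()) == [2, 4, 5]

    def test_identity_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            circular_shift_regions([0, 1], 10, 20)


class TestEmpiricalSignificance:
    def test_counting_and_bh_oracle(self):
        # pool 1..999; observed values chosen to land on raw p 0.001/0.01/0.04/0.5
        pool = np.arange(1.0, 1000.0)
        obs = [1000.0, 990.5, 960.5, 500.5]
        sig = empirical_significance(["a", "b", "c", "d"], obs, pool)
        np.testing.assert_allclose(sig["raw_p"], [0.001, 0.01, 0.04, 0.5])
        np.testing.assert_allclose(sig["fdr"], brute_bh([0.001, 0.01, 0.04, 0.5]), atol=1e-12)
        np.testing.assert_allclose(sig["fdr"], [0.004, 0.02, 0.04 * 4 / 3, 0.5], atol=1e-12)

    def test_observed_at_median(self):
        pool = np.arange(1.0, 1000.0)
        sig = empirical_significance(["a"], [500.0], pool)
        assert sig["raw_p"].iloc[0] == pytest.approx(0.5, abs=0.01)

    def test_p_floor_never_zero(self):
        sig = empirical_significance(["a"], [1e9], np.arange(100.0))
        assert sig["raw_p"].iloc[0] == pytest.approx(1 / 101)

    def test_ties_count_as_extreme(self):
        pool = np.array([1.0, 2.0, 2.0, 3.0])
        sig = empirical_significance(["a"], [2.0], pool)
        assert sig["raw_p"].iloc[0] == pytest.approx((1 + 3) / 5)


class TestKsCompare:
    def test_identical_samples(self):
        d, _ = ks_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, p = ks_compare([1, 2, 3], [10, 11, 12])
        assert d == 1.0 and p < 0.2

    def test_matches_ecdf_oracle(self, rng):
        a = rng.normal(size=40).tolist()
        b = rng.normal(0.5, 1.3, size=25).tolist()
        d, _ = ks_compare(a, b)
        assert d == pytest.approx(brute_ks_statistic(a, b), abs=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestPostMappingNull:
    def make_obs(self, chain_bundle, chain_network):
        _, cat, _, _, _ = chain_bundle
        by_id = cat.by_id()
        regs = [by_id[i] for i in "ABCDEFGH"]
        groups = build_groups(regs, chain_network)
        ordered = [r.id for r in cat.ordered() if r.id in set(chain_network.region_ids)]
        return cat, by_id, groups, ordered

    def test_group_size_multiset_preserved(self, chain_bundle, chain_network):
        cat, by_id, groups, ordered = self.make_obs(chain_bundle, chain_network)
        target = sorted((len(g.members) for g in groups), reverse=True)
        null = post_mapping_null(
            chain_network, ordered, groups, 150, np.random.default_rng(1),
            regions_by_id={r.id: r for r in cat.entries},
        )
        assert len(null.group_sizes) == 150
        for sizes in null.group_sizes:
            assert sizes == target
        assert all(n == len(groups) for n in null.subset_sizes)

    def test_distinct_offsets(self, chain_bundle, chain_network):
        cat, by_id, groups, ordered = self.make_obs(chain_bundle, chain_network)
        null = post_mapping_null(
            chain_network, ordered, groups, 100, np.random.default_rng(2),
            regions_by_id={r.id: r for r in cat.entries},
        )
        assert len(set(null.offsets)) == 100 and 0 not in null.offsets

    def test_seed_determinism(self, chain_bundle, chain_network):
        cat, by_id, groups, ordered = self.make_obs(chain_bundle, chain_network)
        kw = dict(regions_by_id={r.id: r for r in cat.entries})
        a = post_mapping_null(chain_network, ordered, groups, 50, np.random.default_rng(7), **kw)
        b = post_mapping_null(chain_network, ordered, groups, 50, np.random.default_rng(7), **kw)
        assert a.offsets == b.offsets
        np.testing.assert_allclose(a.pooled(), b.pooled())

    def test_too_many_perms_rejected(self, chain_bundle, chain_network):
        cat, by_id, groups, ordered = self.make_obs(chain_bundle, chain_network)
        with pytest.raises(ValueError, match="distinct offsets"):
            post_mapping_null(
                chain_network, ordered, groups, len(ordered) + 5, np.random.default_rng(0)
            )


class TestPreMappingNull:
    def test_rotated_snp_sets_remapped_and_deterministic(self, chain_bundle, chain_network):
        from ndanet.nullmodels import pre_mapping_null
        from ndanet.regions import filter_putative_snps

        _, cat, _, gwas, _ = chain_bundle
        K = filter_putative_snps(gwas.records, 5e-6)
        null = pre_mapping_null(
            chain_network, K, cat.entries, cat.genome, 100, np.random.default_rng(3)
        )
        assert null.mode == "pre_mapping" and len(null.scores) == 100
        # unlike the post-mapping scheme, the rotated SNP sets may land in any
        # number of regions (regulatory sequence covers <1% of this genome)
        assert min(null.subset_sizes) >= 0
        assert all(len(s) == n for s, n in zip(null.scores, null.subset_sizes))
        again = pre_mapping_null(
            chain_network, K, cat.entries, cat.genome, 100, np.random.default_rng(3)
        )
        assert again.subset_sizes == null.subset_sizes
        np.testing.assert_allclose(again.pooled(), null.pooled())
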