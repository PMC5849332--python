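import filecmp

import numpy as np
import pytest

from ndanet.io_formats import read_expression_matrix, read_genome_table, read_gwas, read_region_catalog
from ndanet.regions import filter_putative_snps
from ndanet.synthdata import (
    ModuleSpec,
    SimScenario,
    SnpBin,
    copula_loading,
    make_fixture,
    simulate_atlas,
    simulate_catalog,
    simulate_gwas,
)


def realized_module_spearman(atlas, truth, name):
    from scipy.stats import spearmanr

    idx = np.flatnonzero((truth["module"] == name).to_numpy())
    rho = spearmanr(atlas.matrix[idx].T).statistic
    off = rho[~np.eye(len(idx), dtype=bool)]
    return off.mean()


class TestSimulateAtlas:
    def test_target_rho_calibration(self):
        sc = SimScenario(
            n_regions=500, n_samples=100,
            modules=[ModuleSpec(size=10, rho=0.8, name="m")], seed=11,
        )
        rng = sc.rng()
        cat = simulate_catalog(sc, rng)
        atlas, truth = simulate_atlas(sc, cat, rng)
        assert 0.75 <= realized_module_spearman(atlas, truth, "m") <= 0.85

    def test_null_rho_near_zero(self):
        sc = SimScenario(
            n_regions=300, n_samples=100,
            modules=[ModuleSpec(size=10, rho=0.0, name="m")], seed=12,
        )
        rng = sc.rng()
        cat = simulate_catalog(sc, rng)
        atlas, truth = simulate_atlas(sc, cat, rng)
        assert abs(realized_module_spearman(atlas, truth, "m")) < 0.05

    def test_restricted_module_top_ranks_in_active_samples(self):
        active = ["ct000", "ct001"]
        sc = SimScenario(
            n_regions=200, n_samples=50, n_celltypes=10,
            modules=[ModuleSpec(size=5, rho=0.8, name="m", active_celltypes=active)],
            seed=13,
        )
        rng = sc.rng()
        cat = simulate_catalog(sc, rng)
        atlas, truth = simulate_atlas(sc, cat, rng)
        idx = np.flatnonzero((truth["module"] == "m").to_numpy())
        ct = np.asarray(atlas.cell_types)
        inactive_cols = ~np.isin(ct, active)
        assert (atlas.matrix[np.ix_(idx, np.flatnonzero(inactive_cols))] == 0).all()
        assert (atlas.matrix[idx][:, ~inactive_cols] > 0).all()

    def test_infeasible_rho_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimScenario(modules=[ModuleSpec(size=5, rho=1.5)])

    def test_copula_loading_identity_points(self):
        assert copula_loading(0.0) == 0.0
        assert copula_loading(1.0) == pytest.approx(1.0)


class TestSimulateGwas:
    def scenario(self):
        return SimScenario(
            n_regions=400, n_samples=20,
            modules=[ModuleSpec(size=8, rho=0.7, name="m")],
            n_background_snps=30_000, seed=14,
        )

    def test_signal_snps_inside_planted_regions(self):
        sc = self.scenario()
        rng = sc.rng()
        cat = simulate_catalog(sc, rng)
        atlas, truth = simulate_atlas(sc, cat, rng)
        gwas = simulate_gwas(sc, cat, truth, rng)
        K = filter_putative_snps(gwas.records, 5e-6)
        planted = set(truth.loc[truth.module == "m", "region_id"])
        by_id = cat.by_id()
        in_planted = sum(
            any(by_id[rid].contains(s.chrom, s.pos) for rid in planted) for s in K
        )
        assert in_planted >= len(planted)  # one planted signal SNP per module region

    def test_background_k_binomial_expectation(self):
        # background-only: E|K| = threshold * n at p<threshold; use a permissive
        # threshold so the expectation is testable at desk scale
        sc = SimScenario(n_regions=100, n_samples=10, n_background_snps=50_000, seed=15)
        rng = sc.rng()
        cat = simulate_catalog(sc, rng)
        atlas, truth = simulate_atlas(sc, cat, rng)
        gwas = simulate_gwas(sc, cat, truth, rng)
        thr = 0.01
        expected = thr * sc.n_background_snps
        sd = np.sqrt(sc.n_background_snps * thr * (1 - thr))
        assert abs(len(filter_putative_snps(gwas.records, thr)) - expected) < 4 * sd

    def test_zero_signal_snps(self):
        sc = SimScenario(n_regions=100, n_samples=10, n_background_snps=1000, seed=16)
        rng = sc.rng()
        cat = simulate_catalog(sc, rng)
        atlas, truth = simulate_atlas(sc, cat, rng)
        gwas = simulate_gwas(sc, cat, truth, rng)
        assert len(filter_putative_snps(gwas.records, 5e-6)) <= 2  # chance only

    def test_custom_bin_placement_in_background_regions(self):
        sc = self.scenario()
        rng = sc.rng()
        cat = simulate_catalog(sc, rng)
        atlas, truth = simulate_atlas(sc, cat, rng)
        bins = [SnpBin(n=10, p_low=1e-4, p_high=1e-2, placement="nonmodule_regions", log_uniform=False)]
        gwas = simulate_gwas(sc, cat, truth, rng, bins=bins)
        assert len(gwas) == 10
        assert all(1e-4 <= s.pvalue <= 1e-2 for s in gwas.records)
        planted = set(truth.loc[truth.module == "m", "region_id"])
        by_id = cat.by_id()
        assert not any(
            by_id[rid].contains(s.chrom, s.pos) for rid in planted for s in gwas.records
        )


class TestFixtures:
    def test_byte_identical_regeneration(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        make_fixture("null_small", out_dir=a, seed=3)
        make_fixture("null_small", out_dir=b, seed=3)
        for name in ("expression.tsv", "gwas.tsv", "promoters.bed", "enhancers.bed",
                     "samples.tsv", "truth.tsv", "genome.tsv"):
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_round_trip_through_io(self, tmp_path):
        _, cat, atlas, gwas, _ = make_fixture("null_small", out_dir=tmp_path, seed=4)
        genome = read_genome_table(tmp_path / "genome.tsv")
        assert genome == cat.genome
        cat2 = read_region_catalog(tmp_path / "promoters.bed", "promoter", genome).merged_with(
            read_region_catalog(tmp_path / "enhancers.bed", "enhancer", genome)
        )
        assert sorted(cat2.ids) == sorted(cat.ids)
        by_id, by_id2 = cat.by_id(), cat2.by_id()
        for rid in cat.ids:
            r, r2 = by_id[rid], by_id2[rid]
            assert (r.chrom, r.start, r.end, r.kind) == (r2.chrom, r2.start, r2.end, r2.kind)
        atlas2 = read_expression_matrix(tmp_path / "expression.tsv", tmp_path / "samples.tsv", catalog=cat2)
        assert atlas2.matrix.shape == atlas.matrix.shape
        np.testing.assert_allclose(
            np.sort(atlas2.matrix.sum(axis=1)), np.sort(atlas.matrix.sum(axis=1)), rtol=1e-4
        )
        gwas2 = read_gwas(tmp_path / "gwas.tsv")
        assert len(gwas2) == len(gwas)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture("nonesuch")

    def test_planted_module_truth_labels(self):
        _, cat, atlas, gwas, truth = make_fixture("planted_module", seed=1)
        assert (truth["module"] == "planted").sum() == 15
        assert len(cat) == 2000 and atlas.matrix.shape == (2000, 100)
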