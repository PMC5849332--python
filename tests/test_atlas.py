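import numpy as np
import pytest

from ndanet.atlas import CoexpressionNetwork, ExpressionAtlas, spearman, spearman_matrix

from oracles import brute_link_weights, brute_rho_matrix


def toy_network(n=100, m=30, seed=0, **kw):
    rng = np.random.default_rng(seed)
    atlas = ExpressionAtlas(
        matrix=rng.lognormal(size=(n, m)),
        region_ids=[f"r{k:03d}" for k in range(n)],
        sample_ids=[f"s{k}" for k in range(m)],
        cell_types=[f"c{k}" for k in range(m)],
    )
    kw.setdefault("min_background", 10)
    return CoexpressionNetwork(atlas, **kw)


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_midrank_tie_formula(self):
        # brute-force rank formula with midranks: u ranks (1.5,1.5,3), v ranks (1,2,3)
        ru, rv = np.array([1.5, 1.5, 3.0]), np.array([1.0, 2.0, 3.0])
        expected = np.sum((ru - ru.mean()) * (rv - rv.mean())) / np.sqrt(
            np.sum((ru - ru.mean()) ** 2) * np.sum((rv - rv.mean()) ** 2)
        )
        assert spearman([1, 1, 2], [3, 5, 9]) == pytest.approx(float(expected))

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))

    def test_matches_scipy_on_random_vectors(self, rng):
        from scipy.stats import spearmanr

        for _ in range(10):
            u, v = rng.integers(0, 5, size=20), rng.lognormal(size=20)
            assert spearman(u, v) == pytest.approx(spearmanr(u, v).statistic, abs=1e-12)


class TestSpearmanMatrix:
    def test_chunk_size_invariance(self, rng):
        mat = rng.lognormal(size=(37, 15))
        a = spearman_matrix(mat, chunk=5)
        b = spearman_matrix(mat, chunk=512)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_agrees_with_scipy(self, rng):
        mat = rng.lognormal(size=(25, 12))
        np.testing.assert_allclose(spearman_matrix(mat), brute_rho_matrix(mat), atol=1e-10)


class TestNodeDistributions:
    def test_size_is_n_minus_one(self):
        net = toy_network(n=60)
        assert len(net.node_empirical_distribution(0)) == 59

    def test_duplicated_node_contains_unit_correlation(self, rng):
        mat = rng.lognormal(size=(30, 20))
        mat[1] = mat[0]
        atlas = ExpressionAtlas(
            matrix=mat,
            region_ids=[f"r{k}" for k in range(30)],
            sample_ids=[f"s{k}" for k in range(20)],
            cell_types=[f"c{k}" for k in range(20)],
        )
        net = CoexpressionNetwork(atlas, min_background=10)
        assert net.node_empirical_distribution(0)[-1] == pytest.approx(1.0)

    def test_too_few_nodes_error(self):
        with pytest.raises(ValueError, match="comparison nodes"):
            toy_network(n=20, min_background=50)

    def test_constant_row_excluded_with_warning(self, rng):
        mat = rng.lognormal(size=(40, 10))
        mat[3] = 2.5  # constant but nonzero
        atlas = ExpressionAtlas(
            matrix=mat,
            region_ids=[f"r{k}" for k in range(40)],
            sample_ids=[f"s{k}" for k in range(10)],
            cell_types=[f"c{k}" for k in range(10)],
        )
        with pytest.warns(UserWarning, match="constant-expression"):
            net = CoexpressionNetwork(atlas, min_background=10)
        assert "r3" not in net.region_ids and net.n_nodes == 39


class TestLinkP:
    def test_unique_maximum_pseudocount(self):
        # x the unique max among N=99 comparisons -> p = (0+1)/(99+1)
        net = toy_network(n=100)
        i = 0
        row = net.rho[i].copy()
        row[i] = -np.inf
        j = int(np.argmax(row))
        assert net.link_p(i, j).p == pytest.approx(1 / 100)

    def test_minimum_is_near_one(self):
        # x the unique min among N=99: 98 background correlations exceed it,
        # so the strict count plus pseudo-count gives (98+1)/(99+1)
        net = toy_network(n=100)
        i = 0
        row = net.rho[i].copy()
        row[i] = np.inf
        j = int(np.argmin(row))
        assert net.link_p(i, j).p == pytest.approx(99 / 100)

    def test_self_link_forbidden(self):
        net = toy_network(n=60)
        with pytest.raises(ValueError, match="self-link"):
            net.link_p(3, 3)

    def test_directionality(self):
        net = toy_network(n=100)
        a = net.link_p("r001", "r002")
        b = net.link_p("r002", "r001")
        assert a.rho == pytest.approx(b.rho)
        assert a.p != b.p  # node-specific backgrounds differ in general

    def test_monotone_in_rho(self):
        net = toy_network(n=120)
        i = 0
        others = np.arange(1, 120)
        ps = np.array([net.link_p(i, int(j)).p for j in others])
        rhos = net.rho[i, others]
        order = np.argsort(rhos)
        assert (np.diff(ps[order]) <= 1e-12).all()

    def test_approximately_uniform_under_null(self):
        from scipy.stats import kstest

        net = toy_network(n=300, m=40, seed=4)
        P = net.pvalue_matrix(np.arange(300))
        off = P[~np.eye(300, dtype=bool)]
        assert kstest(off, "uniform").statistic < 0.02


class TestWeightMatrix:
    def test_matches_brute_force(self, rng):
        net = toy_network(n=80, m=25, seed=2)
        rho = brute_rho_matrix(net.atlas.matrix)
        for _ in range(5):
            subset = sorted(rng.choice(80, size=12, replace=False).tolist())
            W = net.weight_matrix(subset)
            expected = brute_link_weights(rho, subset)
            for a, i in enumerate(subset):
                for b, j in enumerate(subset):
                    if i == j:
                        continue
                    assert W[a, b] == pytest.approx(expected[(i, j)], rel=1e-9, abs=1e-12)

    def test_anticorrelated_links_weigh_zero(self):
        net = toy_network(n=80, seed=3)
        subset = np.arange(20)
        W = net.weight_matrix(subset)
        rho_sub = net.rho[np.ix_(subset, subset)]
        assert (W[rho_sub <= 0] == 0).all()
        assert (W >= 0).all()
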