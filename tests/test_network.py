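"""Network construction tests: correlation, adjacency, TOM, clustering,
eigengenes and module membership against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oracles import average_linkage_brute_force, pearson_hand, tom_brute_force

from netscore.network import (
    DEFAULT_POWER,
    AdjacencyMatrix,
    adjacency,
    gene_module_membership,
    hierarchical_cluster,
    module_eigengenes,
    pearson_correlation_matrix,
    pick_soft_threshold,
    top_variable_genes,
    topological_overlap,
    _scale_free_fit,
)


def _random_corr(rng, n):
    X = rng.standard_normal((n, 30))
    r = np.corrcoef(X)
    return r


class TestCorrelation:
    def test_self_correlation_unit_diagonal(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((5, 10)))
        corr = pearson_correlation_matrix(expr)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_negated_gene_anticorrelated(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(12)
        expr = pd.DataFrame([x, -x], index=["a", "b"])
        corr = pearson_correlation_matrix(expr)
        assert corr.values[0, 1] == pytest.approx(-1.0)

    def test_toy_matrix_hand_formula(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((3, 4))
        corr = pearson_correlation_matrix(pd.DataFrame(X))
        for i in range(3):
            for j in range(3):
                assert corr.values[i, j] == pytest.approx(
                    pearson_hand(X[i], X[j]), abs=1e-12
                )

    def test_zero_variance_gene_named(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["ok", "flat"]
        )
        with pytest.raises(ValueError, match="flat"):
            pearson_correlation_matrix(expr)

    def test_missing_values_rejected(self):
        expr = pd.DataFrame([[1.0, np.nan, 3.0], [1.0, 2.0, 0.0]])
        with pytest.raises(ValueError, match="missing"):
            pearson_correlation_matrix(expr)


class TestAdjacency:
    def test_default_power_is_six(self):
        assert DEFAULT_POWER == 6

    def test_unit_correlation_fixed_point(self):
        from netscore.network import CorrelationMatrix

        corr = CorrelationMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        for p in (1, 3, 6):
            assert adjacency(corr, p).values[0, 1] == 1.0

    def test_arithmetic_example(self):
        from netscore.network import CorrelationMatrix

        corr = CorrelationMatrix(["a", "b"], np.array([[1.0, -0.5], [-0.5, 1.0]]))
        assert adjacency(corr, 6).values[0, 1] == pytest.approx(0.015625)

    def test_elementwise_oracle_random_fixture(self):
        rng = np.random.default_rng(3)
        r = _random_corr(rng, 5)
        from netscore.network import CorrelationMatrix

        adj = adjacency(CorrelationMatrix(list("abcde"), r), 6)
        expected = np.abs(r) ** 6
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(adj.values, expected, atol=1e-15)


class TestTOM:
    def test_empty_network(self):
        adj = AdjacencyMatrix(list("abc"), np.zeros((3, 3)), 6)
        tom = topological_overlap(adj)
        assert np.allclose(tom.values, np.eye(3))

    def test_single_edge(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        tom = topological_overlap(AdjacencyMatrix(["a", "b"], a, 6))
        assert tom.values[0, 1] == pytest.approx(1.0)

    def test_four_node_brute_force(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, (4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(AdjacencyMatrix(list("abcd"), a, 6))
        assert np.allclose(tom.values, tom_brute_force(a), atol=1e-10)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_and_brute_force_random(self, seed):
        """TOM in [0,1] and equal to the triple loop on instances <= 50."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 51))
        r = _random_corr(rng, n)
        adj = adjacency(
            pearson_correlation_matrix(
                pd.DataFrame(rng.standard_normal((n, 20)))
            ),
            6,
        )
        tom = topological_overlap(adj)
        assert np.all(tom.values >= 0) and np.all(tom.values <= 1)
        assert np.allclose(tom.values, tom_brute_force(adj.values), atol=1e-10)

    def test_asymmetric_rejected(self):
        a = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(AdjacencyMatrix(["a", "b"], a, 6))


class TestHierarchicalCluster:
    def test_two_genes_single_merge(self):
        d = np.array([[0.0, 0.37], [0.37, 0.0]])
        dend = hierarchical_cluster(d)
        assert dend.heights.tolist() == [pytest.approx(0.37)]

    def test_two_blocks_last_merge_height(self):
        d = np.full((6, 6), 0.9)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0.0)
        dend = hierarchical_cluster(d)
        assert dend.heights[-1] == pytest.approx(0.9)

    def test_ten_gene_reference_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0.05, 1.0, (10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = hierarchical_cluster(d)
        assert np.allclose(
            np.sort(dend.heights), np.sort(average_linkage_brute_force(d)), atol=1e-10
        )

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            hierarchical_cluster(np.zeros((3, 4)))


class TestPowerSelection:
    def test_scale_free_fixture_reaches_threshold(self):
        """Degrees from preferential attachment follow a power law, so the
        signed fit index on the log-log histogram regression is high and
        matches an independent regression on the same bins."""
        igraph = pytest.importorskip("networkx")
        g = igraph.barabasi_albert_graph(600, 2, seed=1)
        k = np.array([d for _, d in g.degree()], dtype=float)
        fit = _scale_free_fit(k, n_bins=10)
        assert fit >= 0.8
        # independent regression oracle on identical bins
        logk = np.log10(k)
        edges = np.linspace(logk.min(), logk.max() + 1e-9, 11)
        counts, _ = np.histogram(logk, bins=edges)
        centers = (edges[:-1] + edges[1:]) / 2
        mask = counts > 0
        res = stats.linregress(centers[mask], np.log10(counts[mask]))
        assert fit == pytest.approx(-np.sign(res.slope) * res.rvalue**2, abs=1e-10)

    def test_smallest_passing_power_rule(self, small_cohort):
        _, cohort, _ = small_cohort
        sel = pick_soft_threshold(
            pearson_correlation_matrix(cohort.expression), candidates=[2, 4, 6, 8]
        )
        assert sel.chosen in sel.table["power"].tolist()
        passing = sel.table[sel.table["r2_signed"] >= sel.threshold]
        if len(passing):
            assert sel.chosen == passing["power"].iloc[0]
        else:
            assert sel.chosen == int(
                sel.table.loc[sel.table["r2_signed"].idxmax(), "power"]
            )

    def test_degenerate_connectivity_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            _scale_free_fit(np.full(20, 3.0), 10)

    def test_empty_candidates_rejected(self, small_cohort):
        _, cohort, _ = small_cohort
        corr = pearson_correlation_matrix(cohort.expression.iloc[:10])
        with pytest.raises(ValueError, match="candidate"):
            pick_soft_threshold(corr, candidates=[])


class TestEigengenes:
    def test_rank_one_module(self):
        rng = np.random.default_rng(6)
        profile = rng.standard_normal(30)
        expr = pd.DataFrame(
            np.tile(profile, (5, 1)) * rng.uniform(0.5, 2.0, (5, 1)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(30)],
        )
        labels = pd.Series("turquoise", index=expr.index)
        mes = module_eigengenes(expr, labels)
        assert mes.variance_explained["turquoise"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(np.abs(np.corrcoef(mes.values["turquoise"], z)[0, 1]), 1.0)

    def test_orientation_convention(self, small_cohort):
        _, cohort, truth = small_cohort
        genes = truth.module_genes(0)
        labels = pd.Series("blue", index=genes)
        mes1 = module_eigengenes(cohort.expression, labels)
        negated = cohort.expression.copy()
        negated.loc[genes] = -negated.loc[genes]
        mes2 = module_eigengenes(negated, labels)
        for mes, expr in ((mes1, cohort.expression), (mes2, negated)):
            mean_profile = expr.loc[genes].mean(axis=0)
            r = np.corrcoef(mes.values["blue"], mean_profile)[0, 1]
            assert r >= 0

    def test_me_unit_variance_zero_mean(self, small_cohort):
        _, cohort, truth = small_cohort
        labels = truth.gene_to_module.map(lambda m: "gray" if m < 0 else f"mod{m}")
        mes = module_eigengenes(cohort.expression, labels)
        vals = mes.values.to_numpy()
        assert np.allclose(vals.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(vals.std(axis=0), 1.0, atol=1e-10)

    def test_matches_independent_eigendecomposition(self, small_cohort):
        """First-PC scores agree (to sign, 1e-8) with PCA done through an
        eigendecomposition of the sample covariance."""
        _, cohort, truth = small_cohort
        genes = truth.module_genes(1)
        labels = pd.Series("brown", index=genes)
        mes = module_eigengenes(cohort.expression, labels)
        Z = cohort.expression.loc[genes].to_numpy()
        Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, ddof=1, keepdims=True)
        C = Z.T @ Z  # samples x samples
        w, V = np.linalg.eigh(C)
        pc = V[:, -1]
        pc = (pc - pc.mean()) / pc.std()
        me = mes.values["brown"].to_numpy()
        assert min(np.max(np.abs(me - pc)), np.max(np.abs(me + pc))) < 1e-8


class TestGMM:
    def test_gene_equal_to_me_has_unit_kme(self, small_cohort):
        _, cohort, truth = small_cohort
        labels = pd.Series("red", index=truth.module_genes(0))
        mes = module_eigengenes(cohort.expression, labels)
        expr = cohort.expression.copy()
        expr.loc["fake"] = mes.values["red"].to_numpy()
        kme = gene_module_membership(expr, mes)
        assert kme.loc["fake", "red"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_pair_pearson(self, small_cohort):
        _, cohort, truth = small_cohort
        labels = pd.Series("red", index=truth.module_genes(0))
        mes = module_eigengenes(cohort.expression, labels)
        kme = gene_module_membership(cohort.expression.iloc[:20], mes)
        for g in kme.index:
            r, _ = stats.pearsonr(cohort.expression.loc[g], mes.values["red"])
            assert kme.loc[g, "red"] == pytest.approx(r, abs=1e-12)

    def test_noise_gene_small_kme_large_n(self):
        """|kME| of an independent gene stays below 0.15 at n = 500."""
        rng = np.random.default_rng(12)
        from netscore.simulate import SimulationConfig, generate_cohort

        cfg = SimulationConfig(
            n_genes=45, n_samples_per_cohort=(500,), n_modules=1, module_sizes=(40,),
            module_loading=(0.8,), survival_effect=(0.0,), seed=12,
        )
        cohort, truth = generate_cohort(cfg, 0)
        labels = pd.Series("m", index=truth.module_genes(0))
        mes = module_eigengenes(cohort.expression, labels)
        kme = gene_module_membership(cohort.expression, mes)
        noise = truth.gene_to_module.index[truth.gene_to_module == -1]
        assert np.all(kme.loc[noise, "m"].abs() < 0.15)

    def test_kme_monotone_in_loading(self):
        """Mean within-module |kME| increases with the planted loading
        (0.4 < 0.6 < 0.8), averaged over 10 seeds."""
        from netscore.simulate import SimulationConfig, generate_cohort

        means = {}
        for loading in (0.4, 0.6, 0.8):
            vals = []
            for seed in range(10):
                cfg = SimulationConfig(
                    n_genes=30, n_samples_per_cohort=(100,), n_modules=1,
                    module_sizes=(30,), module_loading=(loading,),
                    survival_effect=(0.0,), seed=seed,
                )
                cohort, truth = generate_cohort(cfg, 0)
                labels = pd.Series("m", index=truth.module_genes(0))
                mes = module_eigengenes(cohort.expression, labels)
                kme = gene_module_membership(cohort.expression, mes)
                vals.append(kme["m"].abs().mean())
            means[loading] = np.mean(vals)
        assert means[0.4] < means[0.6] < means[0.8]


def test_top_variable_genes_filter():
    rng = np.random.default_rng(20)
    expr = pd.DataFrame(
        rng.standard_normal((10, 50)) * np.arange(1, 11)[:, None],
        index=[f"g{i}" for i in range(10)],
    )
    kept = top_variable_genes(expr, 3)
    expected = expr.var(axis=1).sort_values(ascending=False).index[:3]
    assert list(kept.index) == list(expected)
    assert np.allclose(kept.to_numpy(), expr.loc[expected].to_numpy())
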