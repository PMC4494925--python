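"""Signed co-expression network: adjacency, TO, modules, eigengenes, GS/MM."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gliomosaic import network as net


def _expr(rng, n_genes=30, n_samples=20):
    return pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                        index=[f"g{i:03d}" for i in range(n_genes)])


def _block_expr(rng, block_sizes, n_samples=40, within_sd=0.5):
    rows, labels = [], []
    for b, size in enumerate(block_sizes):
        driver = rng.standard_normal(n_samples)
        rows.append(driver * rng.uniform(0.8, 1.2, (size, 1))
                    + rng.normal(0, within_sd, (size, n_samples)))
        labels += [b] * size
    X = pd.DataFrame(np.vstack(rows),
                     index=[f"g{i:04d}" for i in range(sum(block_sizes))])
    return X, np.array(labels)


class TestAdjacency:
    def test_formula_cases(self):
        x = np.array([1.0, -1.0, 2.0, 0.5, -0.7])
        X = pd.DataFrame({"a": x, "b": x, "c": -x}).T
        X.columns = [f"s{i}" for i in range(5)]
        adj = net.signed_adjacency(X, beta=12)
        assert adj.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)   # r = +1
        assert adj.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)   # r = -1
        assert np.allclose(np.diag(adj), 1.0)

    def test_orthogonal_genes_give_half_to_the_beta(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1], "b": [1, 1, -1, -1]}).T
        adj = net.signed_adjacency(X, beta=12)
        assert adj.loc["a", "b"] == pytest.approx(0.5 ** 12, abs=1e-15)

    def test_raising_beta_never_increases_off_diagonal(self, rng):
        X = _expr(rng)
        a6 = net.signed_adjacency(X, 6).to_numpy()
        a12 = net.signed_adjacency(X, 12).to_numpy()
        a18 = net.signed_adjacency(X, 18).to_numpy()
        off = ~np.eye(len(X), dtype=bool)
        assert (a12[off] <= a6[off] + 1e-12).all()
        assert (a18[off] <= a12[off] + 1e-12).all()

    def test_errors(self, rng):
        X = _expr(rng)
        with pytest.raises(ValueError):
            net.signed_adjacency(X, beta=0)
        with pytest.raises(ValueError):
            net.signed_adjacency(X.iloc[:, :3])
        X.iloc[0] = 1.0
        with pytest.raises(ValueError):
            net.signed_adjacency(X)


def _to_bruteforce(A):
    n = len(A)
    out = np.eye(n)
    k = A.sum(axis=0) - 1
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return out


class TestTopologicalOverlap:
    def test_complete_graph_gives_all_ones(self):
        adj = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        to = net.topological_overlap(adj)
        assert np.allclose(to, 1.0)

    def test_empty_graph_gives_zero_off_diagonal(self):
        adj = pd.DataFrame(np.eye(4))
        to = net.topological_overlap(adj).to_numpy()
        assert np.allclose(to[~np.eye(4, dtype=bool)], 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        X = _expr(rng, 50, 15)
        adj = net.signed_adjacency(X, beta=6)
        to = net.topological_overlap(adj).to_numpy()
        ref = _to_bruteforce(adj.to_numpy())
        assert np.abs(to - ref).max() < 1e-10

    def test_bounded_and_symmetric(self, rng):
        to = net.topological_overlap(net.signed_adjacency(_expr(rng), 12))
        T = to.to_numpy()
        assert T.min() >= 0.0 and T.max() <= 1.0
        assert np.allclose(T, T.T)

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            net.topological_overlap(bad)


class TestDetectModules:
    def test_three_planted_blocks_recovered(self, rng):
        X, truth = _block_expr(rng, [200, 200, 200])
        to = net.topological_overlap(net.signed_adjacency(X, 12))
        labels = net.detect_modules(to, min_module_size=100)
        assert labels.nunique() >= 3
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_block_below_min_size_unassigned(self, rng):
        X, truth = _block_expr(rng, [200, 50])
        to = net.topological_overlap(net.signed_adjacency(X, 12))
        labels = net.detect_modules(to, min_module_size=175)
        small = labels[truth == 1]
        assert (small == net.UNASSIGNED).all()

    def test_permuted_expression_mostly_unassigned(self, default_cohort):
        rng = np.random.default_rng(0)
        X = default_cohort.expression.iloc[:1200]
        Xp = pd.DataFrame(np.array([rng.permutation(r) for r in X.to_numpy()]),
                          index=X.index, columns=X.columns)
        to = net.topological_overlap(net.signed_adjacency(Xp, 12))
        labels = net.detect_modules(to, min_module_size=175)
        assert (labels == net.UNASSIGNED).mean() >= 0.95

    def test_min_size_larger_than_genes_rejected(self, rng):
        to = net.topological_overlap(net.signed_adjacency(_expr(rng), 12))
        with pytest.raises(ValueError):
            net.detect_modules(to, min_module_size=1000)

    def test_static_cut_mode(self, rng):
        X, truth = _block_expr(rng, [150, 150], within_sd=0.3)
        to = net.topological_overlap(net.signed_adjacency(X, 12))
        labels = net.detect_modules(to, min_module_size=100, cut_height=0.9)
        assert adjusted_rand_score(truth, labels) >= 0.95


class TestEigengene:
    def test_identical_genes_module(self, rng):
        base = rng.standard_normal(20)
        X = pd.DataFrame([base, base, base], index=list("abc"))
        labels = pd.Series("M1", index=X.index)
        eig, varexp = net.module_eigengene(X, labels)
        r = np.corrcoef(eig["M1"], base)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert varexp["M1"] == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(eig["M1"]) == pytest.approx(1.0, abs=1e-10)

    def test_orientation_positive_with_mean_profile(self, rng):
        X = _expr(rng, 30, 25)
        labels = pd.Series(["M1"] * 15 + ["M2"] * 15, index=X.index)
        eig, _ = net.module_eigengene(X, labels)
        for m in ("M1", "M2"):
            genes = labels.index[labels == m]
            z = X.loc[genes].sub(X.loc[genes].mean(axis=1), axis=0)
            z = z.div(z.std(axis=1, ddof=1), axis=0)
            assert np.corrcoef(eig[m], z.mean(axis=0))[0, 1] >= 0

    def test_singleton_module_is_standardized_gene(self, rng):
        X = _expr(rng, 5, 12)
        labels = pd.Series(["M1"] + [net.UNASSIGNED] * 4, index=X.index)
        eig, _ = net.module_eigengene(X, labels)
        r = np.corrcoef(eig["M1"], X.iloc[0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_planted_driver_recovered(self, small_cohort):
        c = small_cohort
        tm = c.truth.gene_module
        genes = tm.index[tm == "turquoise"]
        labels = pd.Series("M1", index=genes)
        eig, _ = net.module_eigengene(c.expression.loc[genes], labels)
        r = np.corrcoef(eig["M1"], c.truth.module_drivers.loc["turquoise"])[0, 1]
        assert abs(r) >= 0.9


class TestMembershipAndSignificance:
    def test_hub_equal_to_eigengene_scores_one(self, rng):
        X = _expr(rng, 10, 16)
        eig = pd.DataFrame({"M1": X.iloc[0] - X.iloc[0].mean()})
        eig["M1"] /= np.linalg.norm(eig["M1"])
        mm = net.module_membership(X, eig)
        assert mm.loc[X.index[0], "M1"] == pytest.approx(1.0, abs=1e-10)

    def test_gene_significance_transform(self):
        p = pd.Series([1.0, 0.001, 0.0, np.nan], index=list("abcd"))
        gs = net.gene_significance(p)
        assert gs["a"] == pytest.approx(0.0)
        assert gs["b"] == pytest.approx(3.0)
        assert gs["c"] == pytest.approx(16.0)
        assert np.isnan(gs["d"])

    def test_flat_gs_gives_no_significant_module(self):
        gs = pd.Series(1.0, index=[f"g{i}" for i in range(300)])
        labels = pd.Series(["M1"] * 150 + ["M2"] * 150, index=gs.index)
        stats = net.module_significance(gs, labels, n_perm=200, seed=0)
        assert not stats["significant"].any()

    def test_concentrated_gs_module_maximally_significant(self):
        gs = pd.Series([10.0] * 100 + [0.0] * 400,
                       index=[f"g{i}" for i in range(500)])
        labels = pd.Series(["M1"] * 100 + ["M2"] * 400, index=gs.index)
        stats = net.module_significance(gs, labels, n_perm=200, seed=0)
        assert stats.loc["M1", "significant"]
        assert stats.loc["M1", "p"] <= 1 / 201 + 1e-12
        assert not stats.loc["M2", "significant"]

    def test_small_n_perm_rejected(self):
        gs = pd.Series([1.0, 2.0])
        labels = pd.Series(["M1", "M1"], index=gs.index)
        with pytest.raises(ValueError):
            net.module_significance(gs, labels, n_perm=50)


class TestCoreModule:
    def test_upper_quartile_sizes(self, rng):
        X = _expr(rng, 13, 12)
        labels = pd.Series(["M1"] * 8 + ["M2"] * 5, index=X.index)
        eig, _ = net.module_eigengene(X, labels)
        mm = net.module_membership(X, eig)
        cores = net.core_module(mm, labels)
        assert len(cores["M1"]) == 2  # ceil(8/4)
        assert len(cores["M2"]) == 2  # ceil(5/4)

    def test_core_mm_at_least_module_mean(self, rng):
        X = _expr(rng, 40, 20)
        labels = pd.Series(["M1"] * 40, index=X.index)
        eig, _ = net.module_eigengene(X, labels)
        mm = net.module_membership(X, eig)
        cores = net.core_module(mm, labels)
        assert mm.loc[cores["M1"], "M1"].mean() >= mm["M1"].mean()


def test_build_module_set_and_eigengene_dendrogram(rng):
    X, truth = _block_expr(rng, [60, 60], n_samples=30, within_sd=0.4)
    labels = pd.Series(np.where(truth == 0, "M1", "M2"), index=X.index)
    p_adj = pd.Series(rng.uniform(size=len(X)), index=X.index)
    ms = net.build_module_set(X, labels, p_adj, n_perm=200, seed=0)
    assert set(ms.eigengenes.columns) == {"M1", "M2"}
    assert ms.mm.shape == (120, 2)
    assert set(ms.cores) == {"M1", "M2"}
    Z = net.eigengene_dendrogram(ms.eigengenes)
    assert Z.shape == (1, 4)
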