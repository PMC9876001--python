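"""PCA feature blocks, canonical-correlation edge weights, network assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, optimize

from methccanet import (
    BetaMatrix,
    PriorNetwork,
    build_weighted_network,
    canonical_weight,
    reduce_gene_features,
    restrict_prior_network,
)
from methccanet.ccanet import GeneFeatureBlock
from methccanet.io import read_annotation
from methccanet.synthetic import SyntheticConfig, generate_dataset


def block(X, gene="g", samples=None):
    X = np.asarray(X, dtype=float)
    idx = samples if samples is not None else [f"s{i}" for i in range(X.shape[0])]
    return GeneFeatureBlock(
        gene_symbol=gene,
        scores=pd.DataFrame(X, index=idx),
        explained_variance=np.ones(X.shape[1]) / X.shape[1],
        n_sites_original=X.shape[1],
    )


def cca_first_oracle(X, Y):
    """Largest canonical correlation via the generalized eigenvalue problem
    [0 Sxy; Syx 0] v = rho [Sxx 0; 0 Syy] v — independent of the SVD route."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    n = X.shape[0]
    Sxx, Syy, Sxy = X.T @ X / n, Y.T @ Y / n, X.T @ Y / n
    p, q = Sxx.shape[0], Syy.shape[0]
    A = np.block([[np.zeros((p, p)), Sxy], [Sxy.T, np.zeros((q, q))]])
    B = linalg.block_diag(Sxx, Syy)
    return float(np.max(linalg.eigh(A, B, eigvals_only=True)))


class TestRestrictPriorNetwork:
    def test_both_policy(self):
        prior = PriorNetwork([("A", "B"), ("B", "C"), ("C", "D")])
        out = restrict_prior_network(prior, {"A", "B", "C"})
        assert sorted(out.edges) == [("A", "B"), ("B", "C")]

    def test_either_policy(self):
        prior = PriorNetwork([("A", "B")])
        out = restrict_prior_network(prior, {"A"}, policy="either")
        assert out.edges == [("A", "B")]

    def test_disjoint_dmgs_error(self):
        prior = PriorNetwork([("A", "B")])
        with pytest.raises(ValueError, match="no prior edges"):
            restrict_prior_network(prior, {"X", "Y"})


class TestReduceGeneFeatures:
    @staticmethod
    def _fixture(tmp_path, site_rows, gene="G1"):
        sites = [f"cg{i}" for i in range(len(site_rows))]
        n = len(site_rows[0])
        bm = BetaMatrix(
            pd.DataFrame(site_rows, index=sites, columns=[f"s{i}" for i in range(n)])
        )
        p = tmp_path / "annot.tsv"
        p.write_text(
            "site_id\tgene_symbol\n" + "".join(f"{s}\t{gene}\n" for s in sites)
        )
        return bm, read_annotation(p)

    def test_single_site_scores_are_centered_beta(self, tmp_path):
        row = [0.1, 0.4, 0.2, 0.8, 0.5]
        bm, annot = self._fixture(tmp_path, [row])
        blk = reduce_gene_features(bm, annot, "G1")
        assert blk.n_components == 1
        expected = np.asarray(row) - np.mean(row)
        got = blk.scores.to_numpy().ravel()
        sign = np.sign(np.dot(got, expected))
        np.testing.assert_allclose(sign * got, expected, atol=1e-12)

    def test_duplicate_sites_collapse_to_one_component(self, tmp_path):
        row = [0.1, 0.4, 0.2, 0.8, 0.5]
        bm, annot = self._fixture(tmp_path, [row, row, row])
        blk = reduce_gene_features(bm, annot, "G1", var_retained=0.9)
        assert blk.n_components == 1
        assert blk.explained_variance[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, tmp_path):
        rng = np.random.default_rng(4)
        rows = np.clip(rng.normal(0.5, 0.1, size=(5, 20)), 0, 1)
        bm, annot = self._fixture(tmp_path, rows.tolist())
        blk = reduce_gene_features(bm, annot, "G1", var_retained=0.99)
        X = rows.T - rows.T.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        frac = evals / evals.sum()
        np.testing.assert_allclose(
            blk.explained_variance, frac[: blk.n_components], atol=1e-8
        )
        # score columns are mutually orthogonal
        G = blk.scores.to_numpy().T @ blk.scores.to_numpy()
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_unknown_gene_is_error(self, tmp_path):
        bm, annot = self._fixture(tmp_path, [[0.1, 0.2, 0.3]])
        with pytest.raises(ValueError, match="no sites"):
            reduce_gene_features(bm, annot, "NOPE")


class TestCanonicalWeight:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        a = block(rng.normal(size=(30, 3)))
        assert canonical_weight(a, a) == pytest.approx(1.0, abs=1e-10)

    def test_single_component_reduces_to_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        w = canonical_weight(block(x[:, None]), block(y[:, None]))
        r = np.corrcoef(x, y)[0, 1]
        assert w == pytest.approx(abs(r), abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = block(rng.normal(size=(40, 3)))
        b = block(rng.normal(size=(40, 2)))
        assert canonical_weight(a, b) == pytest.approx(canonical_weight(b, a), abs=1e-10)

    def test_invariance_to_invertible_transforms(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        Y = rng.normal(size=(50, 2))
        w0 = canonical_weight(block(X), block(Y))
        for _ in range(5):
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            B = rng.normal(size=(2, 2)) + 3 * np.eye(2)
            w = canonical_weight(block(X @ A), block(Y @ B))
            assert w == pytest.approx(w0, abs=1e-6)

    def test_matches_brute_force_maximization(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 3))
        Y = rng.normal(size=(50, 2))
        w = canonical_weight(block(X), block(Y))

        def neg_corr(uv):
            u, v = uv[:3], uv[3:]
            return -abs(np.corrcoef(X @ u, Y @ v)[0, 1])

        best = 0.0
        for _ in range(20):
            res = optimize.minimize(neg_corr, rng.normal(size=5), method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            best = max(best, -res.fun)
        assert w == pytest.approx(best, abs=1e-6)

    def test_shared_column_space_gives_weight_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        Y = np.column_stack([X[:, 0], rng.normal(size=40)])  # shares one direction
        assert canonical_weight(block(X), block(Y)) == pytest.approx(1.0, abs=1e-8)
        Z = rng.normal(size=(40, 2))
        assert canonical_weight(block(X), block(Z)) < 1.0

    def test_bounds_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = block(rng.normal(size=(25, rng.integers(1, 4))))
            b = block(rng.normal(size=(25, rng.integers(1, 4))))
            assert 0.0 <= canonical_weight(a, b) <= 1.0

    def test_zero_variance_block_is_error(self):
        a = block(np.zeros((20, 2)))
        b = block(np.random.default_rng(0).normal(size=(20, 2)))
        with pytest.raises(ValueError, match="zero-variance"):
            canonical_weight(a, b)

    def test_mismatched_samples_is_error(self):
        rng = np.random.default_rng(1)
        a = block(rng.normal(size=(10, 1)), samples=[f"a{i}" for i in range(10)])
        b = block(rng.normal(size=(10, 1)), samples=[f"b{i}" for i in range(10)])
        with pytest.raises(ValueError, match="identical ordered samples"):
            canonical_weight(a, b)


class TestBuildWeightedNetwork:
    @staticmethod
    def _blocks(genes, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return {g: block(rng.normal(size=(n, 2)), gene=g) for g in genes}

    def test_largest_component_identified(self):
        prior = PriorNetwork(
            [("A", "B"), ("B", "C"), ("A", "C"), ("A", "X"),  # 4-node component
             ("D", "E"), ("E", "F"), ("D", "F")]  # triangle
        )
        net = build_weighted_network(prior, self._blocks("ABCXDEF"))
        assert sorted(net.largest_component_nodes()) == ["A", "B", "C", "X"]
        assert len(net.analysis_network().nodes) == 4

    def test_missing_block_on_only_edge_is_error(self):
        prior = PriorNetwork([("A", "B")])
        with pytest.warns(UserWarning, match="lack feature blocks"):
            with pytest.raises(ValueError, match="empty"):
                build_weighted_network(prior, self._blocks("A"))

    def test_unconnected_gene_does_not_change_weights(self):
        blocks = self._blocks("ABCZ")
        prior = PriorNetwork([("A", "B"), ("B", "C")])
        w0 = {e[:2]: e[2] for e in build_weighted_network(prior, blocks).edges}
        prior2 = PriorNetwork([("A", "B"), ("B", "C"), ("Z", "A")])
        w1 = {e[:2]: e[2] for e in build_weighted_network(prior2, blocks).edges}
        for e, w in w0.items():
            assert w1[e] == pytest.approx(w, abs=1e-12)

    def test_planted_within_module_weights_exceed_between(self):
        ds = generate_dataset(
            SyntheticConfig(n_case=60, n_control=12, genes_per_module=10), seed=3
        )
        case_ids = ds.clinical.case_ids()
        bm = ds.beta.subset_samples(case_ids)
        blocks = {
            g: reduce_gene_features(bm, ds.annotation, g) for g in sorted(ds.prior.nodes)
        }
        net = build_weighted_network(ds.prior, blocks)
        mod = ds.truth.module_of_gene
        within = [w for a, b, w in net.edges if mod[a] == mod[b]]
        between = [w for a, b, w in net.edges if mod[a] != mod[b]]
        assert np.median(within) - np.median(between) > 0
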