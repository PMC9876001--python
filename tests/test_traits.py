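"""Module eigengenes, trait association, MM/GS screening, meth-expr correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methccanet import (
    BetaMatrix,
    associate_traits,
    compute_me,
    correlate_meth_expr,
    screen_key_sites,
    significant_sites,
)
from methccanet.synthetic import SyntheticConfig, generate_dataset, two_group_beta_dataset

from conftest import make_clinical


def beta_from_rows(rows, prefix="s"):
    rows = np.atleast_2d(rows)
    return BetaMatrix(
        pd.DataFrame(
            rows,
            index=[f"cg{i}" for i in range(rows.shape[0])],
            columns=[f"{prefix}{i}" for i in range(rows.shape[1])],
        )
    )


class TestSignificantSites:
    def test_planted_shift_included_identical_excluded(self):
        rng = np.random.default_rng(0)
        shifted = np.concatenate([rng.normal(0.7, 0.05, 20), rng.normal(0.3, 0.05, 20)])
        flat = np.full(40, 0.5)
        noisy = np.clip(rng.normal(0.5, 0.05, 40), 0, 1)
        bm = beta_from_rows([np.clip(shifted, 0, 1), flat, noisy])
        groups = pd.Series(["case"] * 20 + ["control"] * 20, index=bm.sample_ids)
        with pytest.warns(UserWarning, match="zero variance"):
            sig = significant_sites(bm, groups, alpha=0.05)
        assert "cg0" in sig
        assert "cg1" not in sig

    def test_alpha_one_keeps_all(self):
        bm = beta_from_rows(np.random.default_rng(1).uniform(0.1, 0.9, (5, 10)))
        groups = pd.Series(["case"] * 5 + ["control"] * 5, index=bm.sample_ids)
        assert significant_sites(bm, groups, alpha=1.0) == bm.site_ids


class TestComputeMe:
    def test_single_site_me_proportional_to_beta(self):
        rng = np.random.default_rng(2)
        row = rng.uniform(0.2, 0.8, 15)
        bm = beta_from_rows([row])
        me = compute_me(bm, ["cg0"], module=1)
        r = stats.pearsonr(me.scores.to_numpy(), row)[0]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_collinear_sites_explain_everything(self):
        rng = np.random.default_rng(3)
        row = rng.uniform(0.2, 0.8, 12)
        bm = beta_from_rows([row, np.clip(row * 0.5 + 0.1, 0, 1)])
        me = compute_me(bm, ["cg0", "cg1"])
        assert me.explained_variance == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigenvector_oracle(self):
        rng = np.random.default_rng(4)
        rows = np.clip(rng.normal(0.5, 0.1, size=(10, 25)), 0, 1)
        bm = beta_from_rows(rows)
        me = compute_me(bm, bm.site_ids)
        X = rows.T - rows.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        lead = evecs[:, -1]
        oracle = X @ lead
        got = me.scores.to_numpy()
        sign = np.sign(np.dot(got, oracle))
        np.testing.assert_allclose(got, sign * oracle, atol=1e-8)

    def test_sign_convention_positive_against_mean_beta(self, default_dataset):
        ds = default_dataset
        sites_by_mod = {}
        for s, m in ds.truth.module_of_site.items():
            sites_by_mod.setdefault(m, []).append(s)
        for m, sites in sites_by_mod.items():
            me = compute_me(ds.beta, sites, module=m)
            mean_beta = ds.beta.values.loc[sites].mean(axis=0)
            assert stats.pearsonr(me.scores, mean_beta)[0] >= 0

    def test_no_sites_is_error(self, tiny_beta):
        with pytest.raises(ValueError, match="no sites"):
            compute_me(tiny_beta, ["nope"])


class TestAssociateTraits:
    def test_perfect_monotone_gives_rho_one(self):
        rng = np.random.default_rng(5)
        row = rng.uniform(0.2, 0.8, 20)
        bm = beta_from_rows([row])
        me = compute_me(bm, ["cg0"])
        clin = make_clinical(bm.sample_ids)
        clin.table["stage_N"] = stats.rankdata(me.scores.to_numpy())
        out = associate_traits([me], clin)
        cell = out[(out.trait == "stage_N")].iloc[0]
        assert cell.rho == pytest.approx(1.0, abs=1e-12)

    def test_reversed_trait_negates_rho(self):
        rng = np.random.default_rng(6)
        bm = beta_from_rows([rng.uniform(0.2, 0.8, 20)])
        me = compute_me(bm, ["cg0"])
        clin = make_clinical(bm.sample_ids)
        rho1 = associate_traits([me], clin).set_index("trait").at["age", "rho"]
        clin.table["age"] = -clin.table["age"]
        rho2 = associate_traits([me], clin).set_index("trait").at["age", "rho"]
        assert rho2 == pytest.approx(-rho1, abs=1e-12)

    def test_constant_trait_recorded_missing(self):
        rng = np.random.default_rng(7)
        bm = beta_from_rows([rng.uniform(0.2, 0.8, 12)])
        me = compute_me(bm, ["cg0"])
        clin = make_clinical(bm.sample_ids, stage_M=[0] * 12)
        with pytest.warns(UserWarning, match="constant"):
            out = associate_traits([me], clin)
        assert np.isnan(out.set_index("trait").at["stage_M", "rho"])

    def test_null_rho_quantile_matches_permutation_oracle(self):
        rng = np.random.default_rng(8)
        n = 50
        trait = rng.integers(0, 3, n).astype(float)
        obs = []
        for _ in range(200):
            x = rng.normal(size=n)
            obs.append(abs(stats.spearmanr(x, trait)[0]))
        perm = []
        x = rng.normal(size=n)
        for _ in range(200):
            perm.append(abs(stats.spearmanr(x, rng.permutation(trait))[0]))
        assert np.quantile(obs, 0.95) == pytest.approx(np.quantile(perm, 0.95), abs=0.07)

    def test_spearman_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = stats.spearmanr(x, y)[0]
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            assert stats.spearmanr(f(x), y)[0] == pytest.approx(base, abs=1e-12)


class TestScreenKeySites:
    def test_site_identical_to_me_passes(self):
        rng = np.random.default_rng(10)
        row = rng.uniform(0.2, 0.8, 20)
        bm = beta_from_rows([row])
        me = compute_me(bm, ["cg0"])
        trait = pd.Series(stats.rankdata(row), index=bm.sample_ids)
        out = screen_key_sites(bm, ["cg0"], me, trait, mm_threshold=0.9, gs_threshold=0.9)
        rec = out.iloc[0]
        assert rec.mm == pytest.approx(1.0, abs=1e-10)
        assert rec.gs == pytest.approx(1.0, abs=1e-10)
        assert rec.passes

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(11)
        row = rng.uniform(0.2, 0.8, 20)
        bm = beta_from_rows([row])
        me = compute_me(bm, ["cg0"])
        trait = pd.Series(stats.rankdata(row), index=bm.sample_ids)
        out = screen_key_sites(bm, ["cg0"], me, trait, mm_threshold=1.0, gs_threshold=0.5)
        assert not out.iloc[0].passes  # mm == 1.0 is not > 1.0

    def test_constant_site_fails_with_missing_stats(self):
        rng = np.random.default_rng(12)
        rows = [rng.uniform(0.2, 0.8, 20), np.full(20, 0.5)]
        bm = beta_from_rows(rows)
        me = compute_me(bm, ["cg0"])
        trait = pd.Series(rng.integers(0, 3, 20), index=bm.sample_ids)
        out = screen_key_sites(bm, ["cg0", "cg1"], me, trait).set_index("site_id")
        assert np.isnan(out.at["cg1", "mm"])
        assert not out.at["cg1", "passes"]

    def test_matches_brute_force_enumeration(self, default_dataset):
        ds = default_dataset
        cases = ds.clinical.case_ids()
        bm = ds.beta.subset_samples(cases)
        sites = [s for s, m in ds.truth.module_of_site.items() if m == 1]
        me = compute_me(bm, sites, module=1)
        trait = ds.clinical.table.loc[cases, "stage_N"]
        out = screen_key_sites(bm, sites, me, trait)
        passing = set(out.loc[out.passes, "site_id"])
        expected = set()
        for s in sites:
            b = bm.values.loc[s, cases].to_numpy()
            mm = stats.pearsonr(b, me.scores.to_numpy())[0]
            gs = stats.spearmanr(b, trait.to_numpy())[0]
            if abs(mm) > 0.85 and abs(gs) > 0.17:
                expected.add(s)
        assert passing == expected

    def test_most_collinear_site_has_max_mm(self, default_dataset):
        ds = default_dataset
        cases = ds.clinical.case_ids()
        bm = ds.beta.subset_samples(cases)
        sites = [s for s, m in ds.truth.module_of_site.items() if m == 2]
        me = compute_me(bm, sites, module=2)
        trait = ds.clinical.table.loc[cases, "stage_N"]
        out = screen_key_sites(bm, sites, me, trait)
        best = out.loc[out.mm.abs().idxmax(), "site_id"]
        corr = {
            s: abs(stats.pearsonr(bm.values.loc[s, cases], me.scores)[0]) for s in sites
        }
        assert best == max(corr, key=corr.get)


class TestCorrelateMethExpr:
    def test_monotone_transform_gives_one(self):
        rng = np.random.default_rng(13)
        b = rng.uniform(0.1, 0.9, 30)
        rho, p = correlate_meth_expr(b, np.exp(b))
        assert rho == pytest.approx(1.0)
        rho_neg, _ = correlate_meth_expr(b, -b)
        assert rho_neg == pytest.approx(-1.0)

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError, match="at least 5"):
            correlate_meth_expr([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(500):
            rho, p = correlate_meth_expr(rng.uniform(0, 1, 30), rng.normal(size=30))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_generated_expression_anticorrelated(self, default_dataset):
        ds = default_dataset
        rhos = []
        for gene in list(ds.truth.module_of_gene)[:30]:
            site = ds.annotation.sites_for_gene(gene)[0]
            rho, _ = correlate_meth_expr(
                ds.beta.values.loc[site], ds.expression.loc[gene]
            )
            rhos.append(rho)
        assert np.mean(rhos) == pytest.approx(-0.5, abs=0.15)


def test_trait_linked_module_wins_association(default_dataset):
    """The module whose factor drives nodal stage has the top |rho| with it."""
    ds = default_dataset
    cases = ds.clinical.case_ids()
    bm = ds.beta.subset_samples(cases)
    clin = ds.clinical.subset(cases)
    groups = ds.clinical.table["group"]
    sig = set(significant_sites(ds.beta, groups, alpha=0.05))
    mes = []
    for m in range(1, 5):
        sites = [s for s, mm in ds.truth.module_of_site.items() if mm == m and s in sig]
        mes.append(compute_me(bm, sites, module=m))
    out = associate_traits(mes, clin)
    sub = out[out.trait == "stage_N"]
    top = int(sub.loc[sub.rho.abs().idxmax(), "module"])
    assert top == ds.truth.trait_module
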