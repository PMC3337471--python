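"""Prediction models: BLUP, single-step GBLUP, BayesB, de-regression."""

import numpy as np
import pandas as pd
import pytest

from genoval.errors import ConfigurationError, DataError
from genoval.genotypes import GenotypeMatrix
from genoval.models import (
    BayesB,
    BayesBConfig,
    PedigreeBlup,
    SingleStepGblup,
    VarianceComponents,
    bayesb,
    deregress,
    gblup,
    pedigree_blup,
    predict_gebv,
    ssgblup,
)
from genoval.pedigree import Pedigree
from genoval.relmat import (
    RelationshipMatrix,
    a_inverse,
    a_matrix,
    g_matrix,
    h_inverse,
)

from conftest import random_pedigree_frame


def _founder_ped(n):
    return Pedigree.from_frame(
        pd.DataFrame(
            {
                "animal": [str(i + 1) for i in range(n)],
                "sire": ["0"] * n,
                "dam": ["0"] * n,
            }
        )
    )


class TestPedigreeBlup:
    def test_own_record_regression_identity(self):
        """For unrelated animals with one record each, EBV = h²(y - mu)."""
        n = 50
        ped = _founder_ped(n)
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=n), index=[str(i + 1) for i in range(n)])
        vc = VarianceComponents.from_h2(0.38, 1.0)
        res = pedigree_blup(y, a_inverse(ped), vc)
        expected = vc.h2 * (y - res.mu)
        np.testing.assert_allclose(res.estimates[y.index], expected, atol=1e-10)

    def test_own_record_reliability_near_h2(self):
        n = 300
        ped = _founder_ped(n)
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(size=n), index=[str(i + 1) for i in range(n)])
        vc = VarianceComponents.from_h2(0.38, 1.0)
        res = pedigree_blup(y, a_inverse(ped), vc)
        rel = res.frame["reliability"][y.index]
        assert np.all(np.abs(rel - 0.38) < 0.02)
        assert res.frame["reliability"].between(0, 1).all()

    def test_matches_gls_oracle(self):
        """Dense MME solution equals the direct GLS/BLUP closed form."""
        frame = random_pedigree_frame(np.random.default_rng(4), 100)
        ped = Pedigree.from_frame(frame)
        rng = np.random.default_rng(5)
        rec = [str(i + 1) for i in range(0, 100, 2)]
        y = pd.Series(rng.normal(size=len(rec)), index=rec)
        vc = VarianceComponents(1.3, 2.1)
        res = pedigree_blup(y, a_inverse(ped), vc)
        A = a_matrix(ped)
        pos = A.positions(rec)
        V = A.values[np.ix_(pos, pos)] * vc.var_a + np.eye(len(rec)) * vc.var_e
        Vi = np.linalg.inv(V)
        ones = np.ones(len(rec))
        beta = (ones @ Vi @ y.to_numpy()) / (ones @ Vi @ ones)
        u = vc.var_a * A.values[:, pos] @ Vi @ (y.to_numpy() - beta)
        assert res.mu == pytest.approx(beta, abs=1e-8)
        np.testing.assert_allclose(res.estimates.to_numpy(), u, atol=1e-8)

    def test_no_records_rejected(self, trio_ped):
        vc = VarianceComponents(1.0, 1.0)
        with pytest.raises(DataError):
            pedigree_blup(pd.Series(dtype=float), a_inverse(trio_ped), vc)

    def test_estimator_interface(self, trio_ped):
        y = pd.Series([1.0, -1.0], index=["S", "D"])
        est = PedigreeBlup(var_a=1.0, var_e=1.0).fit(trio_ped, y)
        assert est.get_params()["var_a"] == 1.0
        assert len(est.ebv_) == 3
        assert est.predict(["X"])[0] == pytest.approx(
            (est.ebv_["S"] + est.ebv_["D"]) / 2, abs=1e-8
        )


class TestSingleStep:
    def test_degenerates_to_blup_when_gstar_is_a22(self, small_pop):
        ped = small_pop.pedigree
        gids = [str(t) for t in ped.ids[::3]]
        a_inv = a_inverse(ped)
        a22 = a_matrix(ped, subset=gids)
        fake_g = RelationshipMatrix("G", a22.ids, a22.values)
        hinv = h_inverse(a_inv, fake_g, a22, blend=0.0)
        y = small_pop.traits.phenotypes["T4"].dropna().iloc[:150]
        vc = VarianceComponents.from_h2(0.58, 4.93)
        r_blup = pedigree_blup(y, a_inv, vc, compute_pev=False)
        r_ss = ssgblup(y, hinv, vc)
        dev = np.abs(r_blup.estimates - r_ss.estimates).max()
        assert dev < 1e-6

    def test_all_genotyped_equals_gblup(self, small_pop):
        """With everyone genotyped, single-step collapses to GBLUP on G*."""
        geno = small_pop.genotypes
        from genoval.qc import impute_dosages

        full = impute_dosages(geno, small_pop.pedigree)
        g = g_matrix(full)
        blend = 0.05
        a_inv = a_inverse(small_pop.pedigree)
        a22 = a_matrix(small_pop.pedigree, subset=g.ids)
        hinv = h_inverse(a_inv, g, a22, blend)
        y = small_pop.traits.phenotypes["T4"].dropna()
        vc = VarianceComponents.from_h2(0.58, 4.93)
        r_ss = ssgblup(y, hinv, vc)
        g_star = RelationshipMatrix(
            "G", g.ids, (1 - blend) * g.values + blend * a22.values
        )
        r_g = gblup(y, g_star, vc)
        dev = np.abs(r_ss.estimates[g_star.ids] - r_g.estimates).max()
        assert dev < 1e-6

    def test_id_mismatch_rejected(self, small_pop):
        a_inv = a_inverse(small_pop.pedigree)
        y = pd.Series([1.0], index=["not-an-animal"])
        vc = VarianceComponents(1.0, 1.0)
        with pytest.raises(DataError):
            ssgblup(y, a_inv, vc)


def _marker_data(seed=9, n=300, m=400, n_qtl=30, h2=0.5):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, m)
    D = rng.binomial(2, p, size=(n, m)).astype(float)
    qtl = rng.choice(m, n_qtl, replace=False)
    beta = np.zeros(m)
    beta[qtl] = rng.normal(0, 1.0, n_qtl)
    g = (D - 2 * p) @ beta
    g *= 1.0 / g.std()
    e = rng.normal(0, np.sqrt((1 - h2) / h2), n)
    return D, g + e, g, qtl


class TestBayesB:
    def test_pi_one_gives_null_model(self):
        D, y, _, _ = _marker_data()
        cfg = BayesBConfig(pi=1.0, chain_length=200, burn_in=50, thin=2, rng_seed=3)
        model = BayesB(1.0, 1.0, cfg).fit(D, y)
        assert np.all(model.effects_ == 0.0)
        assert np.all(model.predict(D) == 0.0)

    def test_chain_shorter_than_burnin_rejected(self):
        with pytest.raises(ConfigurationError):
            BayesBConfig(chain_length=100, burn_in=100)

    def test_seed_determinism(self):
        D, y, _, _ = _marker_data()
        cfg = BayesBConfig(pi=0.9, chain_length=300, burn_in=50, thin=2, rng_seed=42)
        a = BayesB(1.0, 1.0, cfg).fit(D, y)
        b = BayesB(1.0, 1.0, cfg).fit(D, y)
        np.testing.assert_array_equal(a.effects_.to_numpy(), b.effects_.to_numpy())

    def test_ridge_oracle_common_variance(self):
        """pi=0 with one shared variance matches closed-form SNP-BLUP."""
        D, y, g, _ = _marker_data(seed=17, n=400, m=500)
        var_a, var_e = float(np.var(g)), float(np.var(y - g))
        cfg = BayesBConfig(
            pi=0.0, chain_length=1200, burn_in=200, thin=4,
            common_variance=True, rng_seed=5,
        )
        model = BayesB(var_a, var_e, cfg).fit(D, y)
        p = D.mean(axis=0) / 2
        Z = D - 2 * p
        lam = var_e / (var_a / float(np.sum(2 * p * (1 - p))))
        a_hat = np.linalg.solve(Z.T @ Z + lam * np.eye(D.shape[1]), Z.T @ (y - y.mean()))
        r = np.corrcoef(Z @ model.effects_.to_numpy(), Z @ a_hat)[0, 1]
        assert r > 0.98

    def test_qtl_inclusion_enrichment(self):
        """True QTL get far higher posterior inclusion than null markers."""
        D, y, g, qtl = _marker_data(seed=23, n=800, m=600, n_qtl=15)
        var_a, var_e = float(np.var(g)), float(np.var(y - g))
        cfg = BayesBConfig(
            pi=0.95, chain_length=1000, burn_in=200, thin=4, rng_seed=7
        )
        model = BayesB(var_a, var_e, cfg).fit(D, y)
        incl = model.inclusion_prob_.to_numpy()
        null = np.setdiff1d(np.arange(600), qtl)
        assert incl[qtl].mean() >= 5 * incl[null].mean()

    def test_training_self_prediction_consistency(self):
        """Ridge-mode fitted values track the sampler's own predictions."""
        D, y, g, _ = _marker_data(seed=31, n=300, m=300)
        var_a, var_e = float(np.var(g)), float(np.var(y - g))
        cfg = BayesBConfig(
            pi=0.0, chain_length=800, burn_in=200, thin=3,
            common_variance=True, rng_seed=11,
        )
        model = BayesB(var_a, var_e, cfg).fit(D, y)
        fitted = model.predict(D) + model.mu_
        assert np.corrcoef(fitted, y)[0, 1] > 0.5  # captures real signal
        r = np.corrcoef(model.predict(D), g)[0, 1]
        assert r > 0.6

    def test_functional_wrapper_scores_all_animals(self, small_pop):
        from genoval.qc import impute_dosages

        geno = impute_dosages(small_pop.genotypes, small_pop.pedigree)
        y = small_pop.traits.phenotypes["T4"].iloc[:150].dropna()
        vc = VarianceComponents.from_h2(0.58, 4.93)
        cfg = BayesBConfig(chain_length=300, burn_in=100, thin=2, rng_seed=1)
        res = bayesb(geno, y, cfg, vc)
        assert len(res.frame) == geno.n_animals
        assert res.snp_effects is not None
        assert res.method == "BayesB_ph"


class TestDeregress:
    def test_zero_pebv_maps_to_zero(self):
        out = deregress(
            pd.Series({"a": 0.0, "b": 1.0}),
            pd.Series({"a": 0.5, "b": 0.25}),
            h2=0.38,
        )
        assert out.loc["a", "debv"] == 0.0
        assert out.loc["b", "debv"] == pytest.approx(4.0)

    def test_weight_formula_value(self):
        out = deregress(
            pd.Series({"a": 1.0}), pd.Series({"a": 0.5}), h2=0.38, c=0.5
        )
        # (1 - 0.38) / ((0.5 + 1.0) * 0.38)
        assert out.loc["a", "weight"] == pytest.approx(0.62 / 0.57)

    def test_unbounded_weight_capped(self):
        out = deregress(
            pd.Series({"a": 1.0}), pd.Series({"a": 1.0}), h2=0.38, c=0.0
        )
        assert out.loc["a", "weight"] == 20.0

    def test_low_reliability_excluded_not_zero_weighted(self):
        out = deregress(
            pd.Series({"a": 1.0, "b": 2.0}),
            pd.Series({"a": 0.01, "b": 0.4}),
            h2=0.38,
            r2_floor=0.05,
        )
        assert list(out.index) == ["b"]

    def test_floor_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            deregress(pd.Series({"a": 1.0}), pd.Series({"a": 0.5}), 0.38, r2_floor=0.0)

    def test_debv_unbiased_against_tbv(self, medium_pop):
        """Regression of dEBV on TBV has slope near one (shrinkage removed)."""
        traits = medium_pop.traits
        t = "T3"
        out = deregress(
            traits.pebv[t], traits.accuracy[t], float(traits.h2[t])
        )
        tbv = medium_pop.truth.tbv[t].reindex(out.index)
        slope = np.polyfit(tbv, out["debv"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)


class TestPredictGebv:
    def test_zero_effects_zero_scores(self, small_pop):
        geno = small_pop.genotypes
        eff = pd.Series(0.0, index=geno.snp_ids[:10])
        from genoval.qc import impute_dosages

        full = impute_dosages(geno, small_pop.pedigree)
        scores = predict_gebv(eff, full.subset_snps(np.arange(10)), np.full(10, 0.3))
        assert np.all(scores == 0.0)

    def test_single_snp_linearity(self):
        p = 0.3
        g = GenotypeMatrix(
            ["a", "b", "c"], ["s0"], np.array([[0.0], [1.0], [2.0]])
        )
        scores = predict_gebv(pd.Series({"s0": 1.0}), g, np.array([p]))
        np.testing.assert_allclose(scores, [-2 * p, 1 - 2 * p, 2 - 2 * p])

    def test_missing_marker_listed(self):
        g = GenotypeMatrix(["a"], ["s0"], np.array([[1.0]]))
        with pytest.raises(DataError, match="ghost"):
            predict_gebv(pd.Series({"ghost": 1.0}), g, np.array([0.5]))
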