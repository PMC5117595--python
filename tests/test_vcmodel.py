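from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, multivariate_normal, norm

from pedvc import (
    additive_relationship,
    fit_multivariate,
    fit_univariate,
    generate_pedigree,
    loglik_direct,
    lrt_heritability,
    simulate_phenotypes,
    wald_fixed_effects,
)
from pedvc.kinship import RelationshipMatrix
from pedvc.pedio import Individual, Pedigree
from pedvc.vcmodel import ModelDataError, UnivariateVarianceComponents

from conftest import univariate_config


def _founder_frame(rng, n, p_cov=0):
    ids = [f"f{k}" for k in range(n)]
    df = pd.DataFrame({"y": rng.normal(size=n)}, index=pd.Index(ids, name="id"))
    for j in range(p_cov):
        df[f"x{j}"] = rng.normal(size=n)
    rm = RelationshipMatrix(ids, np.eye(n))
    return df, rm


class TestLoglikDirect:
    def test_single_individual_standard_normal_density(self):
        df = pd.DataFrame({"y": [1.3]}, index=pd.Index(["a"], name="id"))
        rm = RelationshipMatrix(["a"], np.eye(1))
        ll = loglik_direct(
            df, rm, "y", VA=0.0, VE=1.0, beta=[[1.3]], method="ml"
        )
        assert ll == pytest.approx(norm.logpdf(0.0), abs=1e-12)

    def test_parent_offspring_bivariate_closed_form(self):
        ped = Pedigree(
            [
                Individual("p", "F", sex="male"),
                Individual("o", "F", father_id="p"),
            ]
        )
        rm = additive_relationship(ped)
        y = np.array([0.7, -0.4])
        df = pd.DataFrame({"y": y}, index=pd.Index(["p", "o"], name="id"))
        va, ve, mu = 0.8, 0.6, 0.1
        cov = va * np.array([[1.0, 0.5], [0.5, 1.0]]) + ve * np.eye(2)
        expected = multivariate_normal.logpdf(y, mean=[mu, mu], cov=cov)
        ll = loglik_direct(df, rm, "y", VA=va, VE=ve, beta=[[mu]], method="ml")
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_identity_relationship_variance_reallocation_invariance(self):
        rng = np.random.default_rng(0)
        df, rm = _founder_frame(rng, 30)
        lls = [
            loglik_direct(df, rm, "y", VA=va, VE=1.0 - va, method="reml")
            for va in (0.0, 0.3, 0.7)
        ]
        assert np.ptp(lls) < 1e-9

    def test_non_pd_covariance_raises(self):
        rng = np.random.default_rng(1)
        df, rm = _founder_frame(rng, 5)
        with pytest.raises(ValueError, match="positive-definite"):
            loglik_direct(df, rm, "y", VA=-2.0, VE=1.0)


class TestUnivariateFit:
    def test_converged_fit_reproduces_direct_loglik(self):
        cfg = univariate_config()
        ped = generate_pedigree(cfg, 7)
        rm = additive_relationship(ped)
        ph = simulate_phenotypes(ped, None, cfg, 7, relationship=rm)
        fit = fit_univariate(ph, rm, "y")
        ll = loglik_direct(ph, rm, "y", VA=fit.VA_, VE=fit.VE_)
        assert fit.loglik_ == pytest.approx(ll, abs=1e-8)

    def test_monte_carlo_recovery_h2_half(self):
        """60 nuclear families, true h2=0.5: mean estimate within 0.05."""
        cfg = univariate_config(va=0.5, ve=0.5)
        ped = generate_pedigree(cfg, 17)
        rm = additive_relationship(ped)
        rng = np.random.default_rng(17)
        h2 = [
            fit_univariate(
                simulate_phenotypes(ped, None, cfg, rng, relationship=rm),
                rm,
                "y",
            ).h2_
            for _ in range(100)
        ]
        assert abs(np.mean(h2) - 0.5) < 0.05

    def test_null_simulation_median_at_zero_boundary(self):
        cfg = univariate_config(va=0.0, ve=1.0)
        ped = generate_pedigree(cfg, 23)
        rm = additive_relationship(ped)
        rng = np.random.default_rng(23)
        fits = [
            fit_univariate(
                simulate_phenotypes(ped, None, cfg, rng, relationship=rm),
                rm,
                "y",
            )
            for _ in range(40)
        ]
        assert np.median([f.h2_ for f in fits]) == 0.0
        boundary_zero = [f for f in fits if f.h2_ == 0.0]
        assert all(f.boundary_ for f in boundary_zero)

    def test_founders_only_flagged_and_matches_ols(self):
        rng = np.random.default_rng(5)
        df, rm = _founder_frame(rng, 80, p_cov=2)
        df["y"] = df["y"] + 0.5 * df["x0"] - 0.2 * df["x1"]
        fit = fit_univariate(df, rm, "y", ("x0", "x1"), method="ml")
        assert not fit.identifiable_
        X = np.column_stack([np.ones(80), df["x0"], df["x1"]])
        beta_ols, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        rss = np.sum((df["y"].to_numpy() - X @ beta_ols) ** 2)
        assert fit.VA_ + fit.VE_ == pytest.approx(rss / 80, abs=1e-6)

    def test_constant_trait_errors(self):
        rng = np.random.default_rng(6)
        df, rm = _founder_frame(rng, 10)
        df["y"] = 3.0
        with pytest.raises(ModelDataError, match="zero phenotypic variance"):
            fit_univariate(df, rm, "y")

    def test_collinear_design_names_term(self):
        rng = np.random.default_rng(7)
        df, rm = _founder_frame(rng, 20, p_cov=1)
        df["x_dup"] = 2.0 * df["x0"]
        with pytest.raises(ModelDataError, match="x_dup|x0"):
            fit_univariate(df, rm, "y", ("x0", "x_dup"))

    def test_h2_within_unit_interval_and_estimator_params(self):
        est = UnivariateVarianceComponents(trait="y")
        assert est.get_params()["trait"] == "y"
        est.set_params(method="ml")
        cfg = univariate_config()
        ped = generate_pedigree(cfg, 3)
        rm = additive_relationship(ped)
        ph = simulate_phenotypes(ped, None, cfg, 3, relationship=rm)
        est.fit(ph, rm)
        assert 0.0 <= est.h2_ <= 1.0


class TestLikelihoodInvariances:
    def test_permutation_of_individuals_and_matrix(self):
        cfg = univariate_config(n_families=10)
        ped = generate_pedigree(cfg, 31)
        rm = additive_relationship(ped)
        ph = simulate_phenotypes(ped, None, cfg, 31, relationship=rm)
        ll = loglik_direct(ph, rm, "y", VA=0.4, VE=0.6)
        rng = np.random.default_rng(31)
        perm = rng.permutation(len(ped))
        ids_p = [rm.ids[k] for k in perm]
        rm_p = RelationshipMatrix(ids_p, rm.A[np.ix_(perm, perm)])
        ph_p = ph.data.loc[ids_p]
        ll_p = loglik_direct(ph_p, rm_p, "y", VA=0.4, VE=0.6)
        assert ll == pytest.approx(ll_p, abs=1e-9)

    def test_optimum_beats_random_multistart(self):
        """REML optimum is at least as good as 1000 random (V_A, V_E) points."""
        cfg = univariate_config(n_families=20)  # 100 individuals
        ped = generate_pedigree(cfg, 41)
        rm = additive_relationship(ped)
        ph = simulate_phenotypes(ped, None, cfg, 41, relationship=rm)
        fit = fit_univariate(ph, rm, "y")
        rng = np.random.default_rng(41)
        vp = np.var(ph.data["y"])
        best = -np.inf
        for _ in range(1000):
            va = rng.uniform(0, 3 * vp)
            ve = rng.uniform(1e-6, 3 * vp)
            best = max(best, loglik_direct(ph, rm, "y", VA=va, VE=ve))
        assert fit.loglik_ >= best - 1e-6


class TestMultivariateFit:
    def _bivariate_cfg(self, g12, e12, v=(0.5, 0.5)):
        from pedvc import SimulationConfig, TraitModel

        G = np.array([[v[0], g12], [g12, v[0]]])
        E = np.array([[v[1], e12], [e12, v[1]]])
        tm = TraitModel(
            traits=("u", "v"),
            G=G,
            E=E,
            intercepts={"u": 0.0, "v": 0.0},
            betas={"u": {}, "v": {}},
        )
        return SimulationConfig(
            n_families=30,
            offspring_fixed=3,
            extend_prob=0.0,
            max_generations=2,
            phenotyping_fraction=1.0,
            loci=(),
            trait_model=tm,
        )

    def test_independent_traits_rg_near_zero(self):
        cfg = self._bivariate_cfg(0.0, 0.0)
        ped = generate_pedigree(cfg, 51)
        rm = additive_relationship(ped)
        rng = np.random.default_rng(51)
        rgs = []
        for _ in range(40):
            ph = simulate_phenotypes(ped, None, cfg, rng, relationship=rm)
            fit = fit_multivariate(ph, rm, ["u", "v"])
            rgs.append(fit.rG_.loc["u", "v"])
        assert abs(np.mean(rgs)) < 0.1

    def test_uncorrelated_truth_h2_matches_univariate(self):
        cfg = self._bivariate_cfg(0.0, 0.0)
        ped = generate_pedigree(cfg, 52)
        rm = additive_relationship(ped)
        ph = simulate_phenotypes(ped, None, cfg, 52, relationship=rm)
        multi = fit_multivariate(ph, rm, ["u", "v"])
        uni = fit_univariate(ph, rm, "u")
        assert multi.h2_["u"] == pytest.approx(uni.h2_, abs=0.05)

    def test_duplicated_trait_values_degenerate(self):
        cfg = self._bivariate_cfg(0.2, 0.1)
        ped = generate_pedigree(cfg, 53)
        rm = additive_relationship(ped)
        ph = simulate_phenotypes(ped, None, cfg, 53, relationship=rm)
        df = ph.data.copy()
        df["u_again"] = df["u"]
        fit = fit_multivariate(df, rm, ["u", "u_again"])
        assert fit.degenerate_
        assert fit.rG_.loc["u", "u_again"] > 0.99
        assert fit.rE_.loc["u", "u_again"] > 0.99

    def test_duplicate_trait_name_rejected(self, study, study_relationship):
        with pytest.raises(ModelDataError, match="duplicated"):
            fit_multivariate(study.phenotypes, study_relationship, ["sBP", "sBP"])

    def test_single_trait_directed_to_univariate(self, study, study_relationship):
        with pytest.raises(ModelDataError, match="Univariate"):
            fit_multivariate(study.phenotypes, study_relationship, ["sBP"])

    def test_g_e_psd_and_h2_partition(self):
        cfg = self._bivariate_cfg(0.2, 0.1)
        ped = generate_pedigree(cfg, 54)
        rm = additive_relationship(ped)
        ph = simulate_phenotypes(ped, None, cfg, 54, relationship=rm)
        fit = fit_multivariate(ph, rm, ["u", "v"])
        for M in (fit.G_, fit.E_):
            assert np.linalg.eigvalsh(M.to_numpy()).min() >= -1e-10
        e2 = np.diag(fit.E_) / (np.diag(fit.G_) + np.diag(fit.E_))
        np.testing.assert_allclose(fit.h2_.to_numpy() + e2, 1.0, atol=1e-12)

    def test_missing_blocks_match_dense_oracle(self):
        cfg = self._bivariate_cfg(0.2, 0.1)
        ped = generate_pedigree(cfg, 55)
        rm = additive_relationship(ped)
        ph = simulate_phenotypes(ped, None, cfg, 55, relationship=rm)
        df = ph.data.copy()
        df.iloc[::5, df.columns.get_loc("u")] = np.nan
        fit = fit_multivariate(df, rm, ["u", "v"])
        ll = loglik_direct(
            df, rm, ["u", "v"], G=fit.G_.to_numpy(), E=fit.E_.to_numpy()
        )
        assert fit.loglik_ == pytest.approx(ll, abs=1e-8)


class TestLrtAndWald:
    def _fake_fit(self, ll):
        return SimpleNamespace(terms_=["(intercept)"], method="reml", loglik_=ll)

    def test_equal_likelihoods_give_p_one(self):
        res = lrt_heritability(self._fake_fit(-10.0), self._fake_fit(-10.0))
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_boundary_mixture_quantile(self):
        res = lrt_heritability(self._fake_fit(-10.0), self._fake_fit(-11.353))
        assert res.statistic == pytest.approx(2.706, abs=1e-9)
        assert res.p == pytest.approx(0.5 * chi2.sf(2.706, 1), rel=1e-9)
        assert res.p == pytest.approx(0.05, abs=0.0005)

    def test_mismatched_fixed_effects_error(self):
        a = SimpleNamespace(terms_=["(intercept)", "age"], method="reml", loglik_=0)
        b = SimpleNamespace(terms_=["(intercept)"], method="reml", loglik_=0)
        with pytest.raises(ValueError, match="fixed-effect"):
            lrt_heritability(a, b)

    def test_wald_reference_points(self):
        fit = SimpleNamespace(
            beta_=pd.Series([0.0, 1.959964], index=["a", "b"]),
            beta_se_=pd.Series([0.5, 1.0], index=["a", "b"]),
        )
        out = wald_fixed_effects(fit).set_index("term")
        assert out.loc["a", "p"] == 1.0
        assert out.loc["b", "p"] == pytest.approx(0.05, abs=1e-6)

    def test_wald_agrees_with_lrt_on_large_sample(self):
        """With many founders a covariate's Wald and LRT p-values agree."""
        rng = np.random.default_rng(77)
        n = 800
        ids = [f"f{k}" for k in range(n)]
        x = rng.normal(size=n)
        y = 0.1 * x + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x": x}, index=pd.Index(ids, name="id"))
        rm = RelationshipMatrix(ids, np.eye(n))
        full = fit_univariate(df, rm, "y", ("x",), method="ml")
        null = fit_univariate(df, rm, "y", (), method="ml")
        wald = wald_fixed_effects(full).set_index("term")
        lrt_stat = 2 * (full.loglik_ - null.loglik_)
        p_lrt = chi2.sf(lrt_stat, 1)
        assert wald.loc["x", "p"] == pytest.approx(p_lrt, abs=0.01)
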