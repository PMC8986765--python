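"""Mixed-model fitting, AICc machinery, VIF and model selection."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from wildhb import (
    AICcSearch,
    MixedEffectsModel,
    SimConfig,
    aicc,
    consumption_curve,
    generate_cohort,
    standardize,
    vif,
)
from wildhb.recovery import assemble_analysis_frame


class TestStandardize:
    def test_hand_z_scores(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        out, transform = standardize(df, ["x"])
        sd = np.std([1, 2, 3, 4], ddof=1)
        np.testing.assert_allclose(
            out["x"], (np.array([1, 2, 3, 4]) - 2.5) / sd, atol=1e-12
        )
        assert transform["x"] == (2.5, pytest.approx(sd))

    def test_already_standardized_unchanged(self):
        x = np.array([-1.5, -0.5, 0.5, 1.5]) / np.std([-1.5, -0.5, 0.5, 1.5], ddof=1)
        out, _ = standardize(pd.DataFrame({"x": x}), ["x"])
        np.testing.assert_allclose(out["x"], x, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])


class TestAICc:
    def test_hand_value(self):
        # -2(-47) + 2*3 = 100, correction 2*3*4/(100-4) = 0.25
        assert aicc(-47.0, 3, 100) == pytest.approx(100.25)

    def test_smallest_valid_sample(self):
        k = 3
        base = aicc(0.0, k, k + 2)
        assert base == pytest.approx(2 * k + 2 * k * (k + 1))

    def test_approaches_aic_for_large_n(self):
        aic = -2 * (-47.0) + 2 * 3
        assert aicc(-47.0, 3, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(-47.0, 3, 4)


class TestVIF:
    def test_orthogonal_columns_give_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=64)
        b = rng.normal(size=64)
        # orthogonalize and center exactly
        a = a - a.mean()
        b = b - b.mean()
        b = b - a * (a @ b) / (a @ a)
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert out["a"] == pytest.approx(1.0, abs=1e-9)
        assert out["b"] == pytest.approx(1.0, abs=1e-9)

    def test_correlation_point_eight_hand_value(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        e = rng.normal(size=200)
        a = (a - a.mean()) / np.std(a)
        e = e - e.mean()
        e = e - a * (a @ e) / (a @ a)
        e /= np.std(e)
        b = 0.8 * a + np.sqrt(1 - 0.64) * e  # sample correlation exactly 0.8
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert out["b"] == pytest.approx(1.0 / (1.0 - 0.64), abs=1e-6)

    def test_duplicated_column_flagged_infinite(self):
        x = np.arange(10.0)
        out = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(out["a"]) and np.isinf(out["b"])


def _independent_gaussian_frame(n=12, seed=0):
    """Each child its own household: the zero-variance degenerate design."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 1.0 + 0.5 * x + rng.normal(scale=0.7, size=n)
    return pd.DataFrame(
        {
            "household_id": [f"H{i}" for i in range(n)],
            "x": x,
            "y": y,
        }
    )


class TestGaussianFits:
    def test_zero_variance_limit_matches_ols(self):
        data = _independent_gaussian_frame(n=40, seed=2)
        m = MixedEffectsModel(
            response="y", fixed_effects=("x",), family="gaussian",
            group_col="household_id", standardize_numeric=False,
        ).fit(data)
        ols = sm.OLS(data["y"], sm.add_constant(data["x"])).fit()
        got = m.coefficients_.set_index("term")["estimate"]
        assert got["Intercept"] == pytest.approx(ols.params["const"], abs=1e-4)
        assert got["x"] == pytest.approx(ols.params["x"], abs=1e-4)

    def test_loglik_matches_marginal_mvn_density(self):
        """Tiny-cohort oracle: the mixed-model loglik equals the marginal
        multivariate-normal density evaluated at the fitted parameters."""
        rng = np.random.default_rng(3)
        hh_of = np.repeat([f"H{i}" for i in range(4)], 3)
        u = rng.normal(scale=0.6, size=4)
        x = rng.normal(size=12)
        y = 10.0 + 0.4 * x + u[np.repeat(np.arange(4), 3)] + rng.normal(size=12)
        data = pd.DataFrame({"household_id": hh_of, "x": x, "y": y})
        m = MixedEffectsModel(
            response="y", fixed_effects=("x",), family="gaussian",
            group_col="household_id", standardize_numeric=False,
        ).fit(data)
        coef = m.coefficients_.set_index("term")["estimate"]
        mean = coef["Intercept"] + coef["x"] * x
        Z = (hh_of[:, None] == np.unique(hh_of)[None, :]).astype(float)
        V = (
            m.variance_components_["residual"] * np.eye(12)
            + m.variance_components_["household"] * Z @ Z.T
        )
        direct = stats.multivariate_normal(mean=mean, cov=V).logpdf(y)
        assert m.loglik_ == pytest.approx(direct, abs=1e-3)

    def test_aicc_ranking_invariant_to_standardization(self, analysis_frame):
        rural = analysis_frame[analysis_frame["location"] == "rural"].head(150)
        for std in (True, False):
            m = MixedEffectsModel(
                response="hemoglobin_gdl",
                fixed_effects=("child_meals_30d", "age_years"),
                family="gaussian",
                community_col="community_id",
                standardize_numeric=std,
            ).fit(rural)
            if std:
                ll_std, aicc_std = m.loglik_, m.aicc_
            else:
                ll_raw, aicc_raw = m.loglik_, m.aicc_
        assert ll_std == pytest.approx(ll_raw, abs=5e-3)
        assert aicc_std == pytest.approx(aicc_raw, abs=5e-3)


def _binomial_frame(n_households=120, kids=2, sigma=0.0, beta_age=0.9, seed=4):
    rng = np.random.default_rng(seed)
    hh = np.repeat([f"H{i}" for i in range(n_households)], kids)
    age = rng.uniform(0.5, 5.0, size=len(hh))
    u = rng.normal(scale=sigma, size=n_households)
    eta = -1.5 + beta_age * age + u[np.repeat(np.arange(n_households), kids)]
    y = rng.random(len(hh)) < 1 / (1 + np.exp(-eta))
    return pd.DataFrame({"household_id": hh, "age_years": age, "eats": y})


class TestBinomialFits:
    def test_no_cluster_variance_limit_near_glm(self):
        """With no true cluster variance the Laplace ML fit sits close to an
        ordinary logistic regression (the residual gap is the finite-sample
        variance estimate, shared with lme4's Laplace)."""
        data = _binomial_frame(sigma=0.0)
        m = MixedEffectsModel(
            response="eats", fixed_effects=("age_years",), family="binomial",
            group_col="household_id", standardize_numeric=False,
        ).fit(data)
        glm = sm.GLM(
            data["eats"].astype(float),
            sm.add_constant(data["age_years"]),
            family=sm.families.Binomial(),
        ).fit()
        got = m.coefficients_.set_index("term")["estimate"]
        assert got["age_years"] == pytest.approx(glm.params["age_years"], abs=0.05)
        assert m.variance_components_["household"] < 0.3
        assert m.approximation_ == "laplace"

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_matches_lme4_glmer_laplace(self, tmp_path):
        """Independent oracle: lme4's glmer with nAGQ=1 uses the same Laplace
        approximation; coefficients and loglik should agree closely."""
        data = _binomial_frame(n_households=60, sigma=0.8, seed=5)
        csv = tmp_path / "d.csv"
        data.assign(eats=data["eats"].astype(int)).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{csv}")\n'
            'm <- glmer(eats ~ age_years + (1|household_id), data=d,'
            ' family=binomial, nAGQ=1)\n'
            'cat(jsonlite::toJSON(list(beta=unname(fixef(m)),'
            ' loglik=as.numeric(logLik(m)))))\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout[out.stdout.index("{"):])
        m = MixedEffectsModel(
            response="eats", fixed_effects=("age_years",), family="binomial",
            group_col="household_id", standardize_numeric=False,
        ).fit(data)
        got = m.coefficients_.set_index("term")["estimate"]
        assert got["Intercept"] == pytest.approx(ref["beta"][0], abs=5e-3)
        assert got["age_years"] == pytest.approx(ref["beta"][1], abs=5e-3)
        assert m.loglik_ == pytest.approx(ref["loglik"][0], abs=5e-3)

    def test_age_odds_ratio_recovered_over_replicates(self):
        """Logistic fits on synthetic consuming-household children recover an
        age odds ratio near the generative 2.4 per year."""
        logs = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_urban_households=60,
                            n_rural_households=500,
                            communities_per_rural_municipality=6)
            hh, ch = generate_cohort(cfg)
            frame = assemble_analysis_frame(hh, ch)
            rural = frame[
                (frame["location"] == "rural") & frame["consumed_wildmeat_12mo"]
            ].reset_index(drop=True)
            m = MixedEffectsModel(
                response="normally_eats_wildmeat",
                fixed_effects=("age_years", "sex", "maternal_education_years",
                               "monthly_income_per_capita"),
                family="binomial",
                group_col="household_id",
                community_col="community_id",
            ).fit(rural)
            if not m.converged_:
                continue  # cluster-level separation; flagged honestly
            coef = m.coefficients_.set_index("term")
            logs.append(float(coef.loc["age_years", "estimate_natural"]))
        assert len(logs) >= 15
        mean_or = float(np.exp(np.mean(logs)))
        assert 2.19 <= mean_or <= 2.75


@pytest.fixture(scope="module")
def rural_frame(analysis_frame):
    return (
        analysis_frame[analysis_frame["location"] == "rural"]
        .head(160)
        .reset_index(drop=True)
    )


class TestAllSubsets:
    def _proto(self):
        return MixedEffectsModel(
            response="hemoglobin_gdl", family="gaussian",
            group_col="household_id", community_col="community_id",
        )

    def test_single_candidate_yields_two_models(self, rural_frame):
        search = AICcSearch(self._proto(), candidate_terms=("age_years",)).fit(
            rural_frame
        )
        assert len(search.results_) == 2

    def test_three_candidates_enumerate_and_rank(self, rural_frame):
        cands = ("child_meals_30d", "age_years", "malaria_12mo")
        search = AICcSearch(self._proto(), candidate_terms=cands).fit(rural_frame)
        res = search.results_
        assert len(res) == 8
        assert res["delta_aicc"].iloc[0] == 0.0
        assert (res["delta_aicc"].diff().dropna() >= -1e-12).all()
        # oracle: refit each subset independently and compare AICc values
        import itertools

        for terms in res["terms"]:
            est = self._proto()
            est.set_params(fixed_effects=terms)
            est.fit(rural_frame)
            row = res[res["terms"] == terms].iloc[0]
            assert est.aicc_ == pytest.approx(row["aicc"], abs=1e-2)
        assert set(res["terms"]) == {
            tuple(sorted(c))
            for r in range(4)
            for c in itertools.combinations(cands, r)
        }

    def test_candidate_order_does_not_change_best_model(self, rural_frame):
        cands = ("child_meals_30d", "age_years", "malaria_12mo")
        a = AICcSearch(self._proto(), candidate_terms=cands).fit(rural_frame)
        b = AICcSearch(self._proto(), candidate_terms=cands[::-1]).fit(rural_frame)
        assert a.best_terms_ == b.best_terms_
        assert a.results_["aicc"].iloc[0] == pytest.approx(
            b.results_["aicc"].iloc[0], abs=1e-6
        )

    def test_combinatorial_guard(self, rural_frame):
        with pytest.raises(ValueError, match="guard"):
            AICcSearch(
                self._proto(), candidate_terms=tuple(f"t{i}" for i in range(21))
            ).fit(rural_frame)


@pytest.fixture(scope="module")
def fitted(analysis_frame):
    rural = analysis_frame[
        (analysis_frame["location"] == "rural")
        & analysis_frame["consumed_wildmeat_12mo"]
    ].reset_index(drop=True)
    return MixedEffectsModel(
        response="normally_eats_wildmeat", fixed_effects=("age_years",),
        family="binomial", group_col="household_id",
        community_col="community_id",
    ).fit(rural)


class TestConsumptionCurve:
    def test_monotone_increasing_for_positive_age_effect(self, fitted):
        curve = consumption_curve(fitted, ages=np.linspace(0.5, 5, 10))
        assert (curve["probability"].diff().dropna() > 0).all()
        assert (
            (curve["lower"] <= curve["probability"])
            & (curve["probability"] <= curve["upper"])
        ).all()

    def test_flat_when_age_coefficient_zero(self, fitted):
        import copy

        m = copy.deepcopy(fitted)
        idx = m._design_columns_.index("age_years")
        m._beta_ = m._beta_.copy()
        m._beta_[idx] = 0.0
        curve = consumption_curve(m, ages=[1.0, 2.5, 4.0])
        assert curve["probability"].nunique() == 1

    def test_band_covers_generative_curve(self):
        """At three grid ages the 95% band should usually contain the true
        sharing probability implied by the generator."""
        from scipy.special import expit

        cfg0 = SimConfig()
        hits = total = 0
        for seed in range(12):
            cfg = SimConfig(seed=100 + seed, n_urban_households=60,
                            n_rural_households=250,
                            communities_per_rural_municipality=4,
                            sigma_logit_household=0.0)
            hh, ch = generate_cohort(cfg)
            frame = assemble_analysis_frame(hh, ch)
            rural = frame[
                (frame["location"] == "rural") & frame["consumed_wildmeat_12mo"]
            ].reset_index(drop=True)
            m = MixedEffectsModel(
                response="normally_eats_wildmeat", fixed_effects=("age_years",),
                family="binomial", group_col="household_id",
                community_col="community_id",
            ).fit(rural)
            if not m.converged_:
                continue
            curve = consumption_curve(m, ages=[1.0, 2.5, 4.0])
            truth = expit(
                cfg0.sharing_intercept_rural
                + np.log(cfg0.age_or_per_year) * curve["age_years"].to_numpy()
            )
            hits += int(((curve["lower"] <= truth) & (truth <= curve["upper"])).sum())
            total += 3
        assert hits / total >= 0.8
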