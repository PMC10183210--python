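"""Mixed-model fitting, selection, contrasts, and dispersion checks.

Frozen reference values come from independent fits of the same data in
R: lme4::glmer with adaptive quadrature (nAGQ=15) for Poisson models,
glmmTMB for NB1 and beta models (Laplace approximation, hence the slightly
looser tolerances), and multcomp::glht for Tukey contrasts.  The marginal
log-likelihood itself was additionally validated against brute-force
numerical integration (scipy.integrate.quad per group).
"""

import numpy as np
import pandas as pd
import pytest

import orcaforage as of
from orcaforage.glmm import build_design


class TestBetaTransform:
    def test_boundary_values(self):
        assert of.transform_beta_response(0.0, 51) == pytest.approx(0.5 / 51)
        assert of.transform_beta_response(1.0, 51) == pytest.approx(50.5 / 51)

    def test_interior_unchanged(self):
        y = np.array([0.0, 0.3, 1.0])
        out = of.transform_beta_response(y, 51)
        assert out[1] == 0.3 and 0 < out[0] and out[2] < 1

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            of.transform_beta_response(0.5, 1)


class TestDesign:
    def test_treatment_coding_and_interaction(self):
        df = pd.DataFrame({"a": ["x", "y", "y"], "b": [1.0, 2.0, 3.0]})
        X, names, levels = build_design(df, ["a", "b", "a:b"])
        assert names == ["(Intercept)", "a[y]", "b", "a[y]:b"]
        np.testing.assert_allclose(X[:, 1], [0, 1, 1])
        np.testing.assert_allclose(X[:, 3], [0, 2, 3])

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"a": ["x", "x"]})
        with pytest.raises(ValueError, match="single level"):
            build_design(df, ["a"])


class TestPoissonAGQ:
    """Adult-female capture-count model vs the lme4 nAGQ=15 oracle."""

    SPEC = of.ModelSpec(
        "n_capture_dives", "poisson", fixed=("population", "calf"),
        random_intercepts=("week_year",), offset=("log", "duration_h"),
    )

    def test_matches_lme4_oracle(self, adult_female_frame):
        fit = of.fit_glmm(self.SPEC, adult_female_frame)
        assert fit.converged and fit.n_obs == 15
        assert fit.coefficients["(Intercept)"] == pytest.approx(2.7671454, abs=1e-3)
        assert fit.coefficients["population[SRKW]"] == pytest.approx(-2.5043474, abs=1e-3)
        assert fit.coefficients["calf"] == pytest.approx(-2.2953539, abs=1e-3)
        assert fit.standard_errors["population[SRKW]"] == pytest.approx(0.48560603, abs=2e-3)
        assert fit.standard_errors["calf"] == pytest.approx(0.65430956, abs=2e-3)
        assert fit.variance_components["week_year"] == pytest.approx(0.90827962, abs=5e-3)

    def test_marginal_loglik_matches_quadrature_oracle(self, adult_female_frame):
        # brute-force scipy.integrate.quad marginalization gives -35.31314
        fit = of.fit_glmm(self.SPEC, adult_female_frame)
        assert fit.loglik == pytest.approx(-35.31314, abs=1e-3)

    def test_loglik_stable_in_quadrature_nodes(self, adult_female_frame):
        f9 = of.fit_glmm(self.SPEC, adult_female_frame, n_quad=9)
        f15 = of.fit_glmm(self.SPEC, adult_female_frame, n_quad=15)
        assert abs(f9.loglik - f15.loglik) < 1e-4

    def test_adult_male_interaction_model(self, cohort):
        am = of.records_to_frame([r for r in cohort if r.sex == "M" and r.adult])
        spec = of.ModelSpec(
            "n_capture_dives", "poisson",
            fixed=("population", "mother_alive", "population:mother_alive"),
            random_intercepts=("week_year",), offset=("log", "duration_h"),
        )
        fit = of.fit_glmm(spec, am)
        assert fit.n_obs == 22
        assert fit.coefficients["population[SRKW]:mother_alive"] == pytest.approx(
            1.13418397, abs=2e-3
        )
        assert fit.variance_components["week_year"] == pytest.approx(0.12188823, abs=5e-3)

    def test_aic_identity(self, adult_female_frame):
        fit = of.fit_glmm(self.SPEC, adult_female_frame)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
        assert fit.n_params == 4  # 3 fixed + 1 variance


class TestGLMLimit:
    @staticmethod
    def _underdispersed():
        # identical response pattern in every group: zero between-group
        # variance, so the mixed fit must collapse onto the plain GLM
        g = np.repeat(np.arange(10), 4)
        x = np.tile([0.0, 1.0, 0.0, 1.0], 10)
        y = np.tile([1.0, 3.0, 1.0, 3.0], 10)
        return pd.DataFrame({"y": y, "x": x, "g": g.astype(str)})

    def test_glmm_collapses_to_glm_at_zero_variance(self):
        import statsmodels.api as sm

        df = self._underdispersed()
        mixed = of.fit_glmm(
            of.ModelSpec("y", "poisson", fixed=("x",), random_intercepts=("g",)), df
        )
        glm = sm.GLM(
            df["y"], sm.add_constant(df["x"]), family=sm.families.Poisson()
        ).fit()
        assert mixed.variance_components["g"] < 1e-6
        assert mixed.coefficients["(Intercept)"] == pytest.approx(
            glm.params.iloc[0], abs=1e-6
        )
        assert mixed.coefficients["x"] == pytest.approx(glm.params.iloc[1], abs=1e-6)

    def test_nbinom1_with_tiny_alpha_reproduces_poisson(self):
        rng = np.random.default_rng(8)
        g = np.repeat(np.arange(8), 6)
        x = np.tile([0.0, 1.0], 24)
        b = rng.normal(0, 0.4, 8)
        y = rng.poisson(np.exp(0.8 + 0.7 * x + b[g])).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "g": g.astype(str)})
        pois = of.fit_glmm(
            of.ModelSpec("y", "poisson", fixed=("x",), random_intercepts=("g",)), df
        )
        nb1 = of.fit_glmm(
            of.ModelSpec("y", "nbinom1", fixed=("x",), random_intercepts=("g",)), df
        )
        assert nb1.dispersion["alpha"] < 0.2
        assert nb1.coefficients["x"] == pytest.approx(pois.coefficients["x"], abs=0.02)


class TestNB1:
    def test_matches_glmmtmb_oracle(self, cohort_frame):
        kn = cohort_frame[cohort_frame["sex"] != "U"]
        spec = of.ModelSpec(
            "n_capture_dives", "nbinom1",
            fixed=("population", "sex", "population:sex"),
            random_intercepts=("week_year",), offset=("log", "duration_h"),
        )
        fit = of.fit_glmm(spec, kn)
        assert fit.n_obs == 51
        assert fit.coefficients["population[SRKW]"] == pytest.approx(-1.16579606, abs=3e-3)
        assert fit.coefficients["sex[M]"] == pytest.approx(-0.51002016, abs=3e-3)
        assert fit.coefficients["population[SRKW]:sex[M]"] == pytest.approx(
            1.55492507, abs=3e-3
        )
        assert fit.dispersion["alpha"] == pytest.approx(2.3586922, rel=0.02)
        # Laplace (glmmTMB) vs AGQ15: small likelihood gap expected
        assert fit.loglik == pytest.approx(-141.188792, abs=0.05)


class TestBetaFamily:
    @staticmethod
    def _data():
        rng = np.random.default_rng(20240915)
        g = np.repeat(np.arange(8), 6)
        x = np.tile([0, 1], 24)
        b = rng.normal(0, 0.4, 8)
        mu = 1 / (1 + np.exp(-(-0.5 + 0.9 * x + b[g])))
        y = rng.beta(mu * 15, (1 - mu) * 15)
        return pd.DataFrame({"y": y, "x": x.astype(str), "g": g.astype(str)})

    def test_matches_glmmtmb_oracle(self):
        fit = of.fit_glmm(
            of.ModelSpec("y", "beta", fixed=("x",), random_intercepts=("g",)),
            self._data(),
        )
        assert fit.coefficients["(Intercept)"] == pytest.approx(-0.421071832, abs=2e-3)
        assert fit.coefficients["x[1]"] == pytest.approx(0.710606185, abs=2e-3)
        assert fit.variance_components["g"] == pytest.approx(0.165652195, abs=5e-3)
        assert np.exp(fit.dispersion["log_phi:(Intercept)"]) == pytest.approx(
            15.6801066, rel=0.02
        )

    def test_variable_dispersion_matches_glmmtmb(self):
        fit = of.fit_glmm(
            of.ModelSpec("y", "beta", fixed=("x",), random_intercepts=("g",),
                         dispersion_covariate="x"),
            self._data(),
        )
        assert fit.coefficients["x[1]"] == pytest.approx(0.709242009, abs=2e-3)
        assert fit.dispersion["log_phi:(Intercept)"] == pytest.approx(2.646528572, abs=0.01)
        assert fit.dispersion["log_phi:x[1]"] == pytest.approx(0.202575729, abs=0.01)

    def test_out_of_range_response_rejected(self):
        df = self._data()
        df.loc[0, "y"] = 1.0
        with pytest.raises(ValueError, match="transform_beta_response"):
            of.fit_glmm(
                of.ModelSpec("y", "beta", fixed=("x",), random_intercepts=("g",)), df
            )


class TestGaussian:
    def test_crossed_intercepts_recover_variances(self):
        rng = np.random.default_rng(7)
        n = 400
        f1 = rng.integers(0, 12, n)
        f2 = rng.integers(0, 10, n)
        x = rng.normal(0, 1, n)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.6, 12)[f1] + rng.normal(0, 0.4, 10)[f2] \
            + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "x": x, "f1": f1.astype(str), "f2": f2.astype(str)})
        fit = of.fit_glmm(
            of.ModelSpec("y", "gaussian", fixed=("x",), random_intercepts=("f1", "f2")),
            df,
        )
        assert fit.converged
        assert fit.coefficients["x"] == pytest.approx(0.5, abs=0.1)
        assert fit.variance_components["f1"] == pytest.approx(0.36, abs=0.25)
        assert fit.variance_components["f2"] == pytest.approx(0.16, abs=0.15)
        assert fit.method == "REML"


class TestRandomStructureSelection:
    def test_random_effect_kept_when_it_matters(self, adult_female_frame):
        base = of.ModelSpec(
            "n_capture_dives", "poisson", fixed=("population", "calf"),
            offset=("log", "duration_h"),
        )
        cand = [
            base,
            of.ModelSpec(**{**base.__dict__, "random_intercepts": ("week_year",)}),
        ]
        chosen = of.select_random_structure(cand, adult_female_frame)
        assert chosen.random_intercepts == ("week_year",)

    def test_simpler_model_wins_within_delta(self):
        # no group structure: the GLM has one fewer parameter and lies
        # within delta-2 of the mixed model, so it must be selected
        rng = np.random.default_rng(3)
        g = np.repeat(np.arange(10), 4)
        x = np.tile([0.0, 1.0], 20)
        y = rng.poisson(np.exp(0.5 + 0.5 * x)).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "g": g.astype(str)})
        base = of.ModelSpec("y", "poisson", fixed=("x",))
        cand = [
            of.ModelSpec(**{**base.__dict__, "random_intercepts": ("g",)}),
            base,
        ]
        chosen = of.select_random_structure(cand, df)
        assert chosen.random_intercepts == ()

    def test_single_candidate_returned(self, adult_female_frame):
        spec = of.ModelSpec(
            "n_capture_dives", "poisson", fixed=("population",),
            offset=("log", "duration_h"),
        )
        assert of.select_random_structure([spec], adult_female_frame) is spec


class TestTermDeletion:
    @staticmethod
    def _data(interaction: float):
        rng = np.random.default_rng(17)
        n = 120
        a = rng.integers(0, 2, n).astype(float)
        b = rng.integers(0, 2, n).astype(float)
        g = rng.integers(0, 10, n)
        eta = 0.5 + 0.8 * a - 0.7 * b + interaction * a * b + rng.normal(0, 0.3, 10)[g]
        y = rng.poisson(np.exp(eta)).astype(float)
        return pd.DataFrame({"y": y, "a": a, "b": b, "g": g.astype(str)})

    def test_null_interaction_dropped_mains_kept(self):
        spec = of.ModelSpec(
            "y", "poisson", fixed=("a", "b", "a:b"), random_intercepts=("g",)
        )
        final, trace = of.drop_terms_lrt(spec, self._data(0.0))
        assert "a:b" not in final.fixed
        assert set(final.fixed) == {"a", "b"}

    def test_marginality_protects_mains_under_interaction(self):
        spec = of.ModelSpec(
            "y", "poisson", fixed=("a", "b", "a:b"), random_intercepts=("g",)
        )
        final, trace = of.drop_terms_lrt(spec, self._data(1.5))
        assert "a:b" in final.fixed and {"a", "b"} <= set(final.fixed)
        # main effects were never even tested while the interaction stood
        tested_first_round = {t for t, *_ in trace[:1]}
        assert tested_first_round == {"a:b"}

    def test_all_significant_model_unchanged(self):
        spec = of.ModelSpec("y", "poisson", fixed=("a", "b"), random_intercepts=("g",))
        final, _ = of.drop_terms_lrt(spec, self._data(0.0))
        assert final.fixed == spec.fixed


@pytest.fixture(scope="module")
def group_fit(cohort):
    df = of.records_to_frame([r for r in cohort if r.sex != "U"])
    df["grp"] = df["population"] + "." + df["sex"]
    spec = of.ModelSpec(
        "n_capture_dives", "poisson", fixed=("grp",),
        random_intercepts=("week_year",), offset=("log", "duration_h"),
    )
    return of.fit_glmm(spec, df)


class TestContrasts:

    def test_six_contrasts_for_four_groups(self, group_fit):
        out = of.pairwise_contrasts(group_fit, "grp")
        assert len(out) == 6
        assert all(c.p_value >= c.p_unadjusted - 1e-12 for c in out)

    def test_matches_glht_estimates_and_adjusted_p(self, group_fit):
        # multcomp::glht single-step oracle on the same model (lme4 fit)
        out = {c.pair: c for c in of.pairwise_contrasts(group_fit, "grp")}
        c = out[("NRKW.F", "SRKW.F")]
        assert c.estimate == pytest.approx(1.159941, abs=5e-3)
        assert c.p_value < 0.001
        c = out[("NRKW.M", "SRKW.M")]
        assert c.estimate == pytest.approx(-0.502420, abs=5e-3)
        assert c.p_value == pytest.approx(0.053939, abs=0.01)
        c = out[("NRKW.F", "SRKW.M")]
        assert c.estimate == pytest.approx(0.190755, abs=5e-3)
        assert c.p_value == pytest.approx(0.639722, abs=0.02)

    def test_two_level_factor_single_unadjusted_contrast(self, adult_female_frame):
        fit = of.fit_glmm(
            of.ModelSpec("n_capture_dives", "poisson", fixed=("population", "calf"),
                         random_intercepts=("week_year",), offset=("log", "duration_h")),
            adult_female_frame,
        )
        (c,) = of.pairwise_contrasts(fit, "population")
        assert c.p_value == pytest.approx(c.p_unadjusted)

    def test_single_level_factor_rejected(self, group_fit):
        with pytest.raises(ValueError):
            of.pairwise_contrasts(group_fit, "nonexistent")


class TestOverdispersionCheck:
    @staticmethod
    def _fit(extra_noise: float, seed=5):
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(10), 6)
        x = np.tile([0.0, 1.0], 30)
        eta = 1.0 + 0.5 * x + rng.normal(0, 0.3, 10)[g]
        if extra_noise:
            eta = eta + rng.normal(0, extra_noise, 60)
        y = rng.poisson(np.exp(eta)).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "g": g.astype(str)})
        return of.fit_glmm(
            of.ModelSpec("y", "poisson", fixed=("x",), random_intercepts=("g",)), df
        )

    def test_well_specified_model_passes(self):
        out = of.overdispersion_check(self._fit(0.0), n_sim=199, seed=1)
        assert out["p"] > 0.01
        assert 0.6 < out["ratio"] < 1.5

    def test_inflated_variance_detected(self):
        out = of.overdispersion_check(self._fit(0.8), n_sim=199, seed=1)
        assert out["ratio"] > 1.3
        assert out["p"] < 0.05

    def test_zero_simulations_rejected(self):
        with pytest.raises(ValueError):
            of.overdispersion_check(self._fit(0.0), n_sim=0)

    def test_non_count_family_rejected(self):
        df = TestBetaFamily._data()
        fit = of.fit_glmm(
            of.ModelSpec("y", "beta", fixed=("x",), random_intercepts=("g",)), df
        )
        with pytest.raises(ValueError):
            of.overdispersion_check(fit)
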