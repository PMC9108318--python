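import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import special, stats

from baycomm._design import build_design
from baycomm.glmm import (
    GlmmSpec,
    MixedGLM,
    fit_glmm,
    likelihood_ratio_test,
    parse_formula,
)


def simulate_occurrence(seed, n_groups=25, n_per_group=120, interaction=0.6,
                        interaction_sd=0.55, intercept_sd=1.0):
    """Draws from the occurrence model itself (species-level random
    intercept and slopes)."""
    rng = np.random.default_rng(seed)
    season = rng.choice([0.0, 1.0], n_per_group)
    layer = rng.choice([0.0, 1.0], n_per_group)
    b0 = rng.normal(-0.5, intercept_sd, n_groups)
    b1 = rng.normal(-0.4, 0.6, n_groups)
    b2 = rng.normal(0.25, 0.6, n_groups)
    b3 = rng.normal(interaction, interaction_sd, n_groups)
    eta = b0[:, None] + b1[:, None] * season + b2[:, None] * layer + b3[:, None] * season * layer
    y = (rng.random(eta.shape) < special.expit(eta)).astype(float)
    data = pd.DataFrame(
        {
            "season": np.where(np.tile(season, (n_groups, 1)).ravel() == 1, "normoxia", "hypoxia"),
            "layer": np.where(np.tile(layer, (n_groups, 1)).ravel() == 1, "bottom", "surface"),
            "species": np.repeat([f"s{i:02d}" for i in range(n_groups)], n_per_group),
            "detected": y.ravel(),
        }
    )
    return data


class TestAgainstIrlsGlm:
    @pytest.mark.parametrize("family,simulator", [
        ("bernoulli-logit", lambda rng, eta: (rng.random(eta.shape) < special.expit(eta)).astype(float)),
        ("poisson-log", lambda rng, eta: rng.poisson(np.exp(eta)).astype(float)),
    ])
    def test_zero_group_variance_matches_pooled_glm(self, family, simulator):
        """With no group-level variation the Laplace fit collapses to the
        ordinary GLM; fixed effects agree with IRLS to 1e-4."""
        rng = np.random.default_rng(7)
        n = 1500
        data = pd.DataFrame(
            {
                "season": rng.choice(["hypoxia", "normoxia"], n),
                "layer": rng.choice(["surface", "bottom"], n),
                "group": rng.choice([f"g{i}" for i in range(15)], n),
            }
        )
        X, _, _ = build_design(data, ["season", "layer"])
        eta = X @ np.array([-0.6, 0.5, 0.3])
        y = simulator(rng, eta)
        est = MixedGLM(family=family, fixed_terms=("season", "layer"),
                       random_terms=("intercept",), group="group").fit(data, y)
        fam = sm.families.Binomial() if family == "bernoulli-logit" else sm.families.Poisson()
        ref = sm.GLM(y, X, family=fam).fit()
        np.testing.assert_allclose(est.coef_.to_numpy(), ref.params, atol=1e-4)
        assert est.random_variances_.iloc[0] < 1e-3

    def test_poisson_intercept_only_conserves_total(self):
        """GLM score equation: with only an intercept the fitted mean
        reproduces the observed total count."""
        rng = np.random.default_rng(8)
        n = 600
        data = pd.DataFrame({"group": rng.choice(["a", "b", "c"], n)})
        y = rng.poisson(5.0, n).astype(float)
        est = MixedGLM(family="poisson-log", fixed_terms=(),
                       random_terms=("intercept",), group="group").fit(data, y)
        fitted_total = n * np.exp(est.coef_.iloc[0])
        assert fitted_total == pytest.approx(y.sum(), rel=1e-3)


def test_single_level_grouping_raises():
    data = pd.DataFrame({"season": ["hypoxia", "normoxia"], "layer": ["surface", "bottom"],
                         "group": ["g", "g"]})
    with pytest.raises(ValueError, match="2 levels"):
        MixedGLM(fixed_terms=("season",), group="group").fit(data, np.array([0.0, 1.0]))


def test_matches_glmmtmb_reference(tmp_path):
    """Coefficients, Wald SEs, random-effect SDs and the marginal
    log-likelihood agree with glmmTMB (independent Laplace implementation)."""
    data = simulate_occurrence(3)
    num = data.assign(
        season=(data["season"] == "normoxia").astype(int),
        layer=(data["layer"] == "bottom").astype(int),
        y=data["detected"].astype(int),
    )[["y", "season", "layer", "species"]]
    num.to_csv(tmp_path / "d.csv", index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(glmmTMB))\n"
        f'd <- read.csv("{tmp_path}/d.csv")\n'
        "m <- glmmTMB(y ~ season*layer + (1|species) + (0+season|species)"
        " + (0+layer|species) + (0+season:layer|species), family=binomial, data=d)\n"
        "co <- summary(m)$coefficients$cond\n"
        "sds <- sqrt(unlist(lapply(VarCorr(m)$cond, function(x) diag(x))))\n"
        "out <- c(co[,1], co[,2], sds, as.numeric(logLik(m)))\n"
        f'write.csv(data.frame(v=out), "{tmp_path}/out.csv", row.names=FALSE)\n'
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.csv")["v"].to_numpy()

    est = MixedGLM(
        fixed_terms=("season", "layer", "season:layer"),
        random_terms=("intercept", "season", "layer", "season:layer"),
        group="species",
    ).fit(data, data["detected"])
    np.testing.assert_allclose(est.coef_.to_numpy(), ref[:4], atol=2e-3)
    np.testing.assert_allclose(est.se_.to_numpy(), ref[4:8], atol=2e-3)
    np.testing.assert_allclose(
        np.sqrt(est.random_variances_.to_numpy()), ref[8:12], atol=5e-3
    )
    assert est.loglik_ == pytest.approx(ref[12], abs=1e-2)


class TestLikelihoodRatio:
    def fits(self, seed=4):
        data = simulate_occurrence(seed, n_groups=20, n_per_group=80)
        spec_full = GlmmSpec(
            family="bernoulli-logit",
            fixed_terms=("season", "layer", "season:layer"),
            random_group="species",
            random_terms=("intercept", "season", "layer", "season:layer"),
        )
        spec_reduced = GlmmSpec(
            family="bernoulli-logit",
            fixed_terms=("season", "layer", "season:layer"),
            random_group="species",
            random_terms=("intercept", "season", "layer"),
        )
        full = fit_glmm(data, "detected", spec_full, compute_se=False)
        reduced = fit_glmm(data, "detected", spec_reduced, compute_se=False)
        return full, reduced

    def test_nesting_monotone_and_df_one(self):
        full, reduced = self.fits()
        assert full.log_likelihood >= reduced.log_likelihood - 1e-4
        lrt = likelihood_ratio_test(full, reduced)
        assert lrt.df == 1
        assert 0 <= lrt.p_value <= 1

    def test_identical_models_give_chi2_zero(self):
        full, _ = self.fits()
        copy = type(full)(
            fixed_effects=full.fixed_effects,
            random_variances=full.random_variances,
            log_likelihood=full.log_likelihood,
            converged=full.converged,
            boundary=full.boundary,
            n_obs=full.n_obs,
            n_params=full.n_params - 1,
        )
        lrt = likelihood_ratio_test(full, copy)
        assert lrt.chi2 == pytest.approx(0.0, abs=1e-9)
        assert lrt.p_value == pytest.approx(1.0)

    def test_matches_glm_deviance_difference_in_zero_variance_case(self):
        """Nested fixed-effect comparison: with no group variance the LRT
        chi-square equals the pooled GLM deviance difference."""
        rng = np.random.default_rng(9)
        n = 1200
        data = pd.DataFrame(
            {
                "season": rng.choice(["hypoxia", "normoxia"], n),
                "layer": rng.choice(["surface", "bottom"], n),
                "group": rng.choice([f"g{i}" for i in range(12)], n),
            }
        )
        X_full, _, _ = build_design(data, ["season", "layer"])
        eta = X_full @ np.array([-0.4, 0.7, 0.0])
        y = (rng.random(n) < special.expit(eta)).astype(float)
        full = MixedGLM(fixed_terms=("season", "layer"), random_terms=("intercept",),
                        group="group", compute_se=False).fit(data, y)
        reduced = MixedGLM(fixed_terms=("season",), random_terms=("intercept",),
                           group="group", compute_se=False).fit(data, y)
        chi2 = 2 * (full.loglik_ - reduced.loglik_)
        glm_full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit()
        X_red, _, _ = build_design(data, ["season"])
        glm_red = sm.GLM(y, X_red, family=sm.families.Binomial()).fit()
        # near-boundary variance estimates differ slightly between the two
        # fits, so agreement is approximate rather than exact
        assert chi2 == pytest.approx(glm_red.deviance - glm_full.deviance, abs=0.1)


def test_correlated_random_effects_nest_independent_fit():
    """The full-covariance parameterization recovers an induced negative
    intercept-slope correlation and never fits worse than the diagonal one."""
    rng = np.random.default_rng(2)
    n_groups, m = 15, 80
    season = rng.choice([0.0, 1.0], m)
    b0 = rng.normal(-0.5, 1.0, n_groups)
    b1 = -0.8 * b0 + rng.normal(0, 0.3, n_groups)
    eta = b0[:, None] + b1[:, None] * season
    y = (rng.random(eta.shape) < special.expit(eta)).astype(float).ravel()
    data = pd.DataFrame(
        {"season": np.where(np.tile(season, (n_groups, 1)).ravel() == 1,
                            "normoxia", "hypoxia"),
         "g": np.repeat(np.arange(n_groups), m)}
    )
    diag = MixedGLM(fixed_terms=("season",), random_terms=("intercept", "season"),
                    group="g", compute_se=False).fit(data, y)
    full = MixedGLM(fixed_terms=("season",), random_terms=("intercept", "season"),
                    group="g", independent_random_effects=False,
                    compute_se=False).fit(data, y)
    assert full.loglik_ >= diag.loglik_ - 1e-3
    cov = full.random_covariance_
    corr = cov.iloc[0, 1] / np.sqrt(cov.iloc[0, 0] * cov.iloc[1, 1])
    assert corr < -0.5


def test_parse_formula():
    resp, fixed, random, group = parse_formula(
        "detected ~ season + layer + season:layer + (1 + season + layer | species)"
    )
    assert resp == "detected"
    assert fixed == ["season", "layer", "season:layer"]
    assert random == ["intercept", "season", "layer"]
    assert group == "species"


def test_spec_rejects_unknown_random_term():
    with pytest.raises(ValueError, match="random"):
        GlmmSpec(family="bernoulli-logit", fixed_terms=("season",),
                 random_group="species", random_terms=("layer",))
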