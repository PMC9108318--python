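"""Hierarchical generalized linear mixed models via the Laplace approximation.

Two families are supported: Poisson with log link (species richness as a
function of season, layer and their interaction, with a site-level random
intercept) and Bernoulli with logit link (species occurrence with
species-level random intercept and slopes):

    logit(p_is) = b0_i + b1_i * Season_s + b2_i * Layer_s
                  + b3_i * Season_s * Layer_s,

where each species-level coefficient is a fixed effect plus a normal
deviation. Random effects are independent normals by default (diagonal
covariance); a fully correlated covariance is available via
``independent_random_effects=False``.

Estimation maximizes the Laplace-approximated marginal likelihood: for
each group the joint log-density is maximized over the group's random
effects by Newton iterations, and the integral over random effects is
replaced by the Gaussian integral at that mode. Fixed effects and
variance parameters are then optimized by quasi-Newton search. Standard
errors are Wald, from the observed information (numerical Hessian of the
marginal log-likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from ._design import build_design

__all__ = [
    "GlmmSpec",
    "GlmmFit",
    "MixedGLM",
    "fit_glmm",
    "likelihood_ratio_test",
    "parse_formula",
]

_FAMILIES = ("bernoulli-logit", "poisson-log")
_LOG_SD_BOUNDS = (-6.0, 4.0)


def _loglik_terms(family: str, y: np.ndarray, eta: np.ndarray):
    """Pointwise log-likelihood, mean and IRLS weight for a canonical family."""
    if family == "bernoulli-logit":
        ll = y * eta - np.logaddexp(0.0, eta)
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
    else:  # poisson-log
        eta_c = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta_c)
        ll = y * eta_c - mu - special.gammaln(y + 1.0)
        w = mu
    return ll, mu, w


@dataclass
class GlmmSpec:
    """Declarative model description.

    ``fixed_terms`` use the shared dummy coding (season: hypoxia=0,
    normoxia=1; layer: surface=0, bottom=1). ``random_terms`` is the subset
    of {"intercept"} | fixed_terms receiving group-specific deviations.
    """

    family: str
    fixed_terms: tuple[str, ...]
    random_group: str
    random_terms: tuple[str, ...] = ("intercept",)
    independent_random_effects: bool = True

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        allowed = {"intercept", *self.fixed_terms}
        bad = set(self.random_terms) - allowed
        if bad:
            raise ValueError(f"random terms not among fixed terms: {sorted(bad)}")


@dataclass
class GlmmFit:
    """Fitted model summary: estimates, random-effect variances, likelihood."""

    fixed_effects: pd.DataFrame  # estimate, se, z, p_value per coefficient
    random_variances: pd.Series
    log_likelihood: float
    converged: bool
    boundary: bool
    n_obs: int
    n_params: int
    random_modes: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "fixed_effects": self.fixed_effects.to_dict(orient="index"),
            "random_variances": self.random_variances.to_dict(),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
        }


class MixedGLM(BaseEstimator):
    """Laplace-approximation GLMM with group-specific random coefficients.

    Parameters
    ----------
    family:
        "bernoulli-logit" or "poisson-log".
    fixed_terms:
        Ordered fixed-effect terms (':' for interactions); an intercept is
        always included.
    random_terms:
        Terms (from {"intercept"} | fixed_terms) with group-specific
        normal deviations.
    group:
        Column of the design data identifying the grouping level
        (site for the richness model, species for the occurrence model).
    independent_random_effects:
        If True (default) random effects are independent normals; if False
        a fully correlated covariance is estimated via its Cholesky factor.

    Attributes
    ----------
    coef_ : pd.Series           fixed-effect estimates
    se_ : pd.Series             Wald standard errors
    pvalues_ : pd.Series        two-sided normal p-values
    random_variances_ : pd.Series   variance per random term
    loglik_ : float             Laplace marginal log-likelihood
    n_params_ : int             fixed + covariance parameter count
    converged_ : bool
    boundary_ : bool            some variance collapsed to the boundary
    """

    def __init__(
        self,
        family: str = "bernoulli-logit",
        fixed_terms: Sequence[str] = ("season", "layer", "season:layer"),
        random_terms: Sequence[str] = ("intercept",),
        group: str = "group",
        independent_random_effects: bool = True,
        max_outer_iter: int = 300,
        tol: float = 1e-8,
        compute_se: bool = True,
    ):
        self.family = family
        self.fixed_terms = tuple(fixed_terms)
        self.random_terms = tuple(random_terms)
        self.group = group
        self.independent_random_effects = independent_random_effects
        self.max_outer_iter = max_outer_iter
        self.tol = tol
        self.compute_se = compute_se

    # ------------------------------------------------------------------ #

    def fit(self, X: pd.DataFrame, y):
        """Fit the model. ``X`` holds predictor and group columns; ``y`` is
        the response (0/1 or counts)."""
        GlmmSpec(self.family, self.fixed_terms, self.group, self.random_terms,
                 self.independent_random_effects)  # validates
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        Xmat, names, _ = build_design(X, list(self.fixed_terms))
        zblocks, znames = [], []
        for term in self.random_terms:
            if term == "intercept":
                zblocks.append(np.ones((len(X), 1)))
                znames.append("intercept")
            else:
                from ._design import term_columns

                b, bn = term_columns(X, term)
                zblocks.append(b)
                znames.extend(bn)
        Z = np.hstack(zblocks)
        codes, levels = pd.factorize(X[self.group])
        if len(levels) < 2:
            raise ValueError("grouping variable needs at least 2 levels")

        p, q = Xmat.shape[1], Z.shape[1]
        n_groups = len(levels)
        order = np.argsort(codes, kind="stable")
        sizes = np.bincount(codes, minlength=n_groups)
        balanced = sizes.min() == sizes.max()
        if balanced:
            idx = order.reshape(n_groups, sizes[0])
            yg = y[idx]
            Zg = Z[idx]
        else:
            bounds = np.r_[0, np.cumsum(sizes)]
            idx = [order[bounds[g]:bounds[g + 1]] for g in range(n_groups)]
            yg = [y[i] for i in idx]
            Zg = [Z[i] for i in idx]

        beta0 = self._start_values(Xmat, y)
        if self.independent_random_effects:
            theta0 = np.r_[beta0, np.full(q, np.log(0.5))]
            n_cov = q
        else:
            # Cholesky of the covariance: log-diagonal then row-wise off-diagonals
            theta0 = np.r_[beta0, np.full(q, np.log(0.5)), np.zeros(q * (q - 1) // 2)]
            n_cov = q + q * (q - 1) // 2
        lb = np.r_[np.full(p, -np.inf), np.full(q, _LOG_SD_BOUNDS[0]),
                   np.full(n_cov - q, -10.0)]
        ub = np.r_[np.full(p, np.inf), np.full(q, _LOG_SD_BOUNDS[1]),
                   np.full(n_cov - q, 10.0)]

        state = {"b": np.zeros((n_groups, q))}

        def negll(theta):
            ll, bhat = self._laplace_loglik(theta, Xmat, idx, yg, Zg, balanced,
                                            n_groups, p, q, state["b"])
            state["b"] = bhat
            return -ll

        opt = optimize.minimize(
            negll, theta0, method="L-BFGS-B", bounds=list(zip(lb, ub)),
            options={"maxiter": self.max_outer_iter, "ftol": 1e-11, "gtol": 1e-7},
        )
        theta = opt.x
        self.loglik_ = -float(opt.fun)
        self.converged_ = bool(opt.success)
        self.boundary_ = bool(np.any(theta[p:p + q] <= _LOG_SD_BOUNDS[0] + 1e-6))

        if self.compute_se:
            cov = self._wald_cov(negll, theta)
            se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
        else:
            se = np.full(p, np.nan)
        zval = np.divide(theta[:p], se, out=np.full(p, np.nan), where=se > 0)
        pval = 2.0 * stats.norm.sf(np.abs(zval))

        self.coef_ = pd.Series(theta[:p], index=names, name="estimate")
        self.se_ = pd.Series(se, index=names, name="se")
        self.pvalues_ = pd.Series(pval, index=names, name="p_value")
        sigma = self._covariance(theta[p:], q)
        self.random_variances_ = pd.Series(np.diag(sigma), index=znames, name="variance")
        self.random_covariance_ = pd.DataFrame(sigma, index=znames, columns=znames)
        self.random_modes_ = pd.DataFrame(state["b"], index=levels, columns=znames)
        self.n_obs_ = len(y)
        self.n_params_ = p + n_cov
        self.group_levels_ = list(levels)
        self.feature_names_ = names
        return self

    # ------------------------------------------------------------------ #

    def _start_values(self, Xmat, y):
        """Pooled GLM fit (IRLS) ignoring the grouping, for starting values."""
        import statsmodels.api as sm

        fam = sm.families.Binomial() if self.family == "bernoulli-logit" else sm.families.Poisson()
        try:
            return np.asarray(sm.GLM(y, Xmat, family=fam).fit().params, dtype=float)
        except Exception:
            return np.zeros(Xmat.shape[1])

    def _covariance(self, cov_params, q):
        log_sd = cov_params[:q]
        if self.independent_random_effects:
            return np.diag(np.exp(2.0 * log_sd))
        L = np.zeros((q, q))
        L[np.diag_indices(q)] = np.exp(log_sd)
        if q > 1:
            L[np.tril_indices(q, -1)] = cov_params[q:]
        return L @ L.T

    def _laplace_loglik(self, theta, Xmat, idx, yg, Zg, balanced, n_groups, p, q, b_start):
        beta = theta[:p]
        sigma = self._covariance(theta[p:], q)
        # keep the precision well conditioned at the variance boundary
        prec = np.linalg.inv(sigma + 1e-12 * np.eye(q))
        sign, logdet_sigma = np.linalg.slogdet(sigma + 1e-12 * np.eye(q))
        eta_fix = Xmat @ beta
        if balanced:
            b, hess = self._newton_balanced(eta_fix[idx], yg, Zg, prec, b_start)
            ll_pts, _, _ = _loglik_terms(self.family, yg,
                                         eta_fix[idx] + np.einsum("gmq,gq->gm", Zg, b))
            ll_data = float(ll_pts.sum())
            quad = float(np.einsum("gq,qr,gr->", b, prec, b))
            _, logdet_h = np.linalg.slogdet(hess)
            logdet_h_sum = float(logdet_h.sum())
        else:
            ll_data = 0.0
            quad = 0.0
            logdet_h_sum = 0.0
            b = np.empty_like(b_start)
            for g in range(n_groups):
                bg, hg = self._newton_single(eta_fix[idx[g]], yg[g], Zg[g], prec, b_start[g])
                b[g] = bg
                ll_pts, _, _ = _loglik_terms(self.family, yg[g], eta_fix[idx[g]] + Zg[g] @ bg)
                ll_data += float(ll_pts.sum())
                quad += float(bg @ prec @ bg)
                logdet_h_sum += float(np.linalg.slogdet(hg)[1])
        ll = ll_data - 0.5 * quad - 0.5 * n_groups * logdet_sigma - 0.5 * logdet_h_sum
        return ll, b

    def _newton_balanced(self, eta_fix, yg, Zg, prec, b0):
        """Penalized-likelihood Newton mode search, batched over groups."""
        b = b0.copy()
        q = b.shape[1]
        eye = np.eye(q)

        def pll(bb):
            eta = eta_fix + np.einsum("gmq,gq->gm", Zg, bb)
            ll, mu, w = _loglik_terms(self.family, yg, eta)
            pen = 0.5 * np.einsum("gq,qr,gr->g", bb, prec, bb)
            return ll.sum(axis=1) - pen, mu, w

        val, mu, w = pll(b)
        hess = None
        for _ in range(60):
            resid = yg - mu
            grad = np.einsum("gmq,gm->gq", Zg, resid) - b @ prec
            hess = np.einsum("gmi,gm,gmj->gij", Zg, w, Zg) + prec[None, :, :]
            hess = hess + 1e-10 * eye[None, :, :]
            step = np.linalg.solve(hess, grad[:, :, None])[:, :, 0]
            if np.max(np.abs(step)) < 1e-10:
                break
            scale = np.ones((b.shape[0], 1))
            for _ in range(12):
                cand = b + scale * step
                val_new, mu_new, w_new = pll(cand)
                worse = val_new < val - 1e-12
                if not worse.any():
                    break
                scale[worse] *= 0.5
            b = b + scale * step
            val, mu, w = pll(b)
            if np.max(np.abs(scale * step)) < 1e-9:
                break
        resid = yg - mu
        hess = np.einsum("gmi,gm,gmj->gij", Zg, w, Zg) + prec[None, :, :] + 1e-10 * eye[None, :, :]
        return b, hess

    def _newton_single(self, eta_fix, y, Z, prec, b0):
        b = b0.copy()
        q = len(b)
        eye = np.eye(q)

        def pll(bb):
            ll, mu, w = _loglik_terms(self.family, y, eta_fix + Z @ bb)
            return ll.sum() - 0.5 * bb @ prec @ bb, mu, w

        val, mu, w = pll(b)
        for _ in range(60):
            grad = Z.T @ (y - mu) - prec @ b
            hess = (Z * w[:, None]).T @ Z + prec + 1e-10 * eye
            step = np.linalg.solve(hess, grad)
            if np.max(np.abs(step)) < 1e-10:
                break
            scale = 1.0
            for _ in range(12):
                val_new, mu_new, w_new = pll(b + scale * step)
                if val_new >= val - 1e-12:
                    break
                scale *= 0.5
            b = b + scale * step
            val, mu, w = pll(b)
            if np.max(np.abs(scale * step)) < 1e-9:
                break
        hess = (Z * w[:, None]).T @ Z + prec + 1e-10 * eye
        return b, hess

    @staticmethod
    def _wald_cov(negll, theta):
        """Observed information by central finite differences, inverted."""
        k = len(theta)
        h = 1e-4 * (1.0 + np.abs(theta))
        hessian = np.zeros((k, k))
        f0 = negll(theta)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            fpp = negll(theta + ei)
            fmm = negll(theta - ei)
            hessian[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                fij = negll(theta + ei + ej)
                fi_j = negll(theta + ei - ej)
                f_ij = negll(theta - ei + ej)
                f__ = negll(theta - ei - ej)
                hessian[i, j] = hessian[j, i] = (fij - fi_j - f_ij + f__) / (4.0 * h[i] * h[j])
        try:
            return np.linalg.inv(hessian)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(hessian)

    # ------------------------------------------------------------------ #

    def report(self) -> GlmmFit:
        """Package the fitted attributes into a :class:`GlmmFit`."""
        table = pd.DataFrame(
            {
                "estimate": self.coef_,
                "se": self.se_,
                "z": self.coef_ / self.se_,
                "p_value": self.pvalues_,
            }
        )
        return GlmmFit(
            fixed_effects=table,
            random_variances=self.random_variances_,
            log_likelihood=self.loglik_,
            converged=self.converged_,
            boundary=self.boundary_,
            n_obs=self.n_obs_,
            n_params=self.n_params_,
            random_modes=self.random_modes_,
        )


def parse_formula(formula: str) -> tuple[str, list[str], list[str], str]:
    """Parse ``response ~ t1 + t2 + (1 + t1 | group)``.

    Returns (response, fixed_terms, random_terms, group); "1" in the random
    part denotes the intercept.
    """
    lhs, rhs = (part.strip() for part in formula.split("~", 1))
    random_terms: list[str] = []
    group = ""
    if "(" in rhs:
        start, end = rhs.index("("), rhs.index(")")
        inner = rhs[start + 1:end]
        terms_part, group = (s.strip() for s in inner.split("|"))
        random_terms = [
            "intercept" if t.strip() == "1" else t.strip()
            for t in terms_part.split("+") if t.strip()
        ]
        rhs = (rhs[:start] + rhs[end + 1:]).strip().strip("+").strip()
    fixed = [t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"]
    return lhs, fixed, random_terms, group


def fit_glmm(data: pd.DataFrame, response: str, spec: GlmmSpec, **kwargs) -> GlmmFit:
    """Fit a :class:`GlmmSpec` on a data frame; functional wrapper."""
    est = MixedGLM(
        family=spec.family,
        fixed_terms=spec.fixed_terms,
        random_terms=spec.random_terms,
        group=spec.random_group,
        independent_random_effects=spec.independent_random_effects,
        **kwargs,
    )
    est.fit(data, data[response])
    return est.report()


@dataclass
class LRTResult:
    chi2: float
    df: int
    p_value: float


def likelihood_ratio_test(fit_full: GlmmFit, fit_reduced: GlmmFit) -> LRTResult:
    """Likelihood ratio test between nested fits.

    chi2 is clipped at 0; df is the parameter-count difference. Testing a
    variance component places the null on the boundary of its parameter
    space, so the chi-square reference is conservative — reported as-is,
    matching common practice.
    """
    if fit_full.n_params <= fit_reduced.n_params:
        raise ValueError("full model must have more parameters than the reduced model")
    diff = 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood)
    if diff < -1e-4:
        import warnings

        warnings.warn(
            "full model has lower likelihood than reduced model; optimizer failure suspected",
            RuntimeWarning,
            stacklevel=2,
        )
    chi2 = max(diff, 0.0)
    df = fit_full.n_params - fit_reduced.n_params
    return LRTResult(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))
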