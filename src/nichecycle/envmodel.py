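"""Beta-binomial regression of ASV counts on environmental parameters.

Each ASV's count W_i out of the sample total M_i is modelled as
BetaBinomial(M_i, mu_i, phi) with logit mu_i = x_i' beta and a single
logit-scale dispersion intercept (logit phi = gamma0).  For every ASV x
parameter combination an intercept-only, a linear and a quadratic
(degree-2, standardized covariate) mean model are fitted by maximum
likelihood; the quadratic is kept when it beats the linear by a nested
likelihood-ratio test at 0.05, significance of the chosen model is the LRT
against the intercept-only fit, and Benjamini-Hochberg controls the FDR
across all models.  A variance-inflation-factor report justifies treating
the parameters one at a time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from nichecycle.seasonality import benjamini_hochberg

_MU_EPS = 1e-10
_PHI_LO, _PHI_HI = 1e-9, 1.0 - 1e-6


def vif(env: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per environmental parameter.

    Computed on complete cases; VIF_p = 1 / (1 - R^2_p) from regressing
    parameter p on all others (with intercept).  Perfect collinearity
    yields inf with a warning rather than an error.
    """
    complete = env.dropna()
    if complete.shape[1] < 2:
        raise ValueError("need >= 2 parameters for VIF")
    X = sm.add_constant(complete.to_numpy(dtype=float))
    out = {}
    for j, name in enumerate(complete.columns):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = variance_inflation_factor(X, j + 1)
        if not np.isfinite(v) or v > 5:
            warnings.warn(
                f"parameter {name!r} has VIF {v:.3g} (> 5): collinearity",
                stacklevel=2,
            )
        out[name] = float(v)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _mu_phi(theta: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, gamma0 = theta[:-1], theta[-1]
    mu = special.expit(X @ beta)
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    phi = float(np.clip(special.expit(gamma0), _PHI_LO, _PHI_HI))
    return mu, phi


def betabinom_loglik(W, M, beta, gamma0, X) -> float:
    """Beta-binomial log-likelihood with logit mean Xb and logit dispersion.

    Parametrized as a_i = mu_i (1-phi)/phi, b_i = (1-mu_i)(1-phi)/phi, so
    phi -> 0 recovers the binomial and phi -> 1 maximal overdispersion.
    """
    W = np.asarray(W, dtype=float)
    M = np.asarray(M, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(W < 0) or np.any(W > M):
        raise ValueError("require 0 <= W <= M elementwise")
    theta = np.append(np.asarray(beta, dtype=float), float(gamma0))
    return -_negloglik(theta, W, M, X)


def _negloglik(theta, W, M, X) -> float:
    mu, phi = _mu_phi(theta, X)
    r = (1.0 - phi) / phi
    a = mu * r
    b = (1.0 - mu) * r
    ll = (
        special.gammaln(M + 1)
        - special.gammaln(W + 1)
        - special.gammaln(M - W + 1)
        + special.betaln(W + a, M - W + b)
        - special.betaln(a, b)
    )
    return -float(ll.sum())


def _negloglik_grad(theta, W, M, X):
    mu, phi = _mu_phi(theta, X)
    r = (1.0 - phi) / phi
    a = mu * r
    b = (1.0 - mu) * r
    psi_ab = special.digamma(a + b)
    psi_Mab = special.digamma(M + a + b)
    g_a = special.digamma(W + a) - psi_Mab - special.digamma(a) + psi_ab
    g_b = special.digamma(M - W + b) - psi_Mab - special.digamma(b) + psi_ab
    dmu_deta = mu * (1.0 - mu)
    grad_beta = X.T @ ((g_a - g_b) * r * dmu_deta)
    # d a / d gamma0 = -mu (1-phi)/phi, d b / d gamma0 = -(1-mu)(1-phi)/phi
    grad_gamma = -r * float((g_a * mu + g_b * (1.0 - mu)).sum())
    return -np.append(grad_beta, grad_gamma)


@dataclass
class BetaBinomFit:
    """MLE of one beta-binomial model."""

    coefficients: np.ndarray
    se: np.ndarray
    gamma0: float
    gamma0_se: float
    loglik: float
    converged: bool
    degenerate: bool = False
    n: int = 0
    X: np.ndarray = field(default=None, repr=False)

    @property
    def phi(self) -> float:
        return float(special.expit(self.gamma0))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack(
            [self.coefficients - z * self.se, self.coefficients + z * self.se]
        )


def _starts(W, M, X) -> list[np.ndarray]:
    """Three deterministic starting points: binomial-GLM, moment, flat."""
    k = X.shape[1]
    p_bar = float(np.clip(W.sum() / M.sum(), 1e-6, 1.0 - 1e-6))
    # moment estimate of phi from Pearson overdispersion at constant mu
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.sum((W - M * p_bar) ** 2 / (M * p_bar * (1 - p_bar))))
    M_bar = float(M.mean())
    phi_mom = (chi2 / max(len(W) - 1, 1) - 1.0) / max(M_bar - 1.0, 1.0)
    phi_mom = float(np.clip(phi_mom, 1e-4, 0.9))
    gamma_mom = float(special.logit(phi_mom))

    starts = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(
                np.column_stack([W, M - W]), X, family=sm.families.Binomial()
            ).fit(maxiter=50)
        beta0 = np.asarray(glm.params, dtype=float)
        if np.isfinite(beta0).all():
            starts.append(np.append(np.clip(beta0, -20, 20), gamma_mom))
    except Exception:
        pass
    mom = np.zeros(k + 1)
    mom[0] = special.logit(p_bar)
    mom[-1] = gamma_mom
    starts.append(mom)
    flat = np.zeros(k + 1)
    flat[0] = special.logit(p_bar)
    flat[-1] = 0.0  # phi = 0.5
    starts.append(flat)
    return starts


def fit_betabinom(W, M, X) -> BetaBinomFit:
    """Maximum-likelihood beta-binomial fit with deterministic multi-start.

    Quasi-Newton (L-BFGS-B) from a binomial-GLM start, a moment start and
    a flat start; the best converged optimum wins.  Standard errors come
    from the observed information (numerical Hessian of the analytic
    gradient).  All-zero or all-saturated responses are flagged degenerate.
    """
    W = np.asarray(W, dtype=float)
    M = np.asarray(M, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    keep = M > 0
    if not keep.all():
        warnings.warn("dropping samples with zero total count", stacklevel=2)
        W, M, X = W[keep], M[keep], X[keep]
    n, k = X.shape
    if n < 10:
        raise ValueError("need >= 10 usable samples")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    if np.any(W < 0) or np.any(W > M):
        raise ValueError("require 0 <= W <= M elementwise")

    degenerate = bool(W.sum() == 0 or (W == M).all())

    bounds = [(-50.0, 50.0)] * k + [(-25.0, 5.0)]
    best = None
    for theta0 in _starts(W, M, X):
        res = optimize.minimize(
            _negloglik, theta0, args=(W, M, X), jac=_negloglik_grad,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best is not None and np.isfinite(best.fun))
    theta = best.x

    # observed information via central differences of the analytic gradient
    se = np.full(k + 1, np.nan)
    if converged and not degenerate:
        H = np.empty((k + 1, k + 1))
        h = 1e-5 * np.maximum(1.0, np.abs(theta))
        for j in range(k + 1):
            tp = theta.copy(); tp[j] += h[j]
            tm = theta.copy(); tm[j] -= h[j]
            H[:, j] = (_negloglik_grad(tp, W, M, X)
                       - _negloglik_grad(tm, W, M, X)) / (2 * h[j])
        H = (H + H.T) / 2.0
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        d = np.diag(cov)
        se = np.sqrt(np.where(d > 0, d, np.nan))

    return BetaBinomFit(
        coefficients=theta[:-1],
        se=se[:-1],
        gamma0=float(theta[-1]),
        gamma0_se=float(se[-1]),
        loglik=-float(best.fun),
        converged=converged,
        degenerate=degenerate,
        n=n,
        X=X,
    )


def lrt(full_fit: BetaBinomFit, null_fit: BetaBinomFit, df: int) -> float:
    """Likelihood-ratio p-value for nested beta-binomial fits."""
    delta = full_fit.loglik - null_fit.loglik
    if delta < -1e-6:
        raise RuntimeError(
            "full model log-likelihood below nested null: optimizer failure"
        )
    statistic = max(2.0 * delta, 0.0)
    return float(np.clip(stats.chi2.sf(statistic, df), 0.0, 1.0))


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def env_screen(
    counts: pd.DataFrame,
    env: pd.DataFrame,
    asv_set,
    parameters,
    q_threshold: float = 0.05,
    poly_alpha: float = 0.05,
) -> pd.DataFrame:
    """Beta-binomial response model per ASV x environmental parameter.

    For each combination, samples missing the parameter are dropped, the
    covariate standardized, and intercept-only / linear / quadratic mean
    models fitted.  The quadratic ("polynomial") form is chosen when its
    nested LRT against the linear fit has p <= ``poly_alpha``; significance
    is the LRT of the chosen form against intercept-only (df = number of
    added terms), with BH correction across all models.  The response sign
    is the sign of the chosen model's linear coefficient.
    """
    asv_set = [a for a in asv_set if a in counts.index]
    if len(asv_set) == 0:
        raise ValueError("empty ASV set")
    totals = counts.sum(axis=0)
    rows = []
    for param in parameters:
        if param not in env.columns:
            raise ValueError(f"unknown environmental parameter {param!r}")
        ok = env[param].notna().to_numpy()
        z_full = env[param].to_numpy(dtype=float)[ok]
        z = (z_full - z_full.mean()) / z_full.std(ddof=1)
        M = totals.to_numpy(dtype=float)[ok]
        ones = np.ones_like(z)
        X0 = ones[:, None]
        X1 = np.column_stack([ones, z])
        X2 = np.column_stack([ones, z, z**2])
        for asv in asv_set:
            W = counts.loc[asv].to_numpy(dtype=float)[ok]
            row = {"asv": asv, "parameter": param, "n": int(ok.sum())}
            try:
                f0 = fit_betabinom(W, M, X0)
                f1 = fit_betabinom(W, M, X1)
                f2 = fit_betabinom(W, M, X2)
            except (ValueError, RuntimeError) as exc:
                warnings.warn(f"{asv} x {param}: fit failed ({exc})",
                              stacklevel=2)
                row.update(form="failed", p=np.nan, converged=False)
                rows.append(row)
                continue
            if f0.degenerate:
                row.update(form="degenerate", p=np.nan, converged=False)
                rows.append(row)
                continue
            try:
                p_quad = lrt(f2, f1, df=1)
            except RuntimeError:
                p_quad = 1.0
            if p_quad <= poly_alpha:
                chosen, form, df = f2, "polynomial", 2
            else:
                chosen, form, df = f1, "linear", 1
            try:
                p_main = lrt(chosen, f0, df=df)
            except RuntimeError:
                row.update(form="failed", p=np.nan, converged=False)
                rows.append(row)
                continue
            ci = chosen.conf_int()
            row.update(
                form=form,
                intercept=chosen.coefficients[0],
                coef_linear=chosen.coefficients[1],
                coef_linear_se=chosen.se[1],
                coef_linear_lo=ci[1, 0],
                coef_linear_hi=ci[1, 1],
                coef_quadratic=(chosen.coefficients[2]
                                if form == "polynomial" else np.nan),
                dispersion_gamma0=chosen.gamma0,
                phi=chosen.phi,
                loglik=chosen.loglik,
                lrt_stat=max(2.0 * (chosen.loglik - f0.loglik), 0.0),
                p=p_main,
                sign=int(np.sign(chosen.coefficients[1])),
                converged=chosen.converged,
            )
            rows.append(row)
    fits = pd.DataFrame(rows)
    tested = fits["p"].notna()
    q = np.full(len(fits), np.nan)
    if tested.any():
        q[tested.to_numpy()] = benjamini_hochberg(
            fits.loc[tested, "p"].to_numpy()
        )
    fits["q"] = q
    fits["significant"] = fits["q"] <= q_threshold
    return fits
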