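import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from nichecycle.envmodel import (
    betabinom_loglik,
    env_screen,
    fit_betabinom,
    lrt,
    vif,
)


def simulate_bb(rng, n, beta, phi, z=None, M=20_000):
    """Draw beta-binomial counts at known parameters."""
    z = rng.normal(size=n) if z is None else z
    X = np.column_stack([np.ones(n), z])
    mu = expit(X @ np.asarray(beta))
    a = mu * (1 - phi) / phi
    b = (1 - mu) * (1 - phi) / phi
    M = np.full(n, float(M))
    W = rng.binomial(M.astype(int), rng.beta(a, b)).astype(float)
    return W, M, X, z


# ---------------------------------------------------------------------------
# vif
# ---------------------------------------------------------------------------

def test_vif_independent_columns_near_one():
    rng = np.random.default_rng(0)
    env = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
    assert (vif(env) < 1.1).all()


def test_vif_duplicated_column_infinite_with_warning():
    rng = np.random.default_rng(1)
    x = rng.normal(size=100)
    env = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
    with pytest.warns(UserWarning, match="collinearity"):
        v = vif(env)
    assert not np.isfinite(v["a"]) or v["a"] > 1e6


def test_vif_known_correlation_structure():
    """Three columns with exact pairwise correlation 0.5: R^2 of each on
    the others is 1/3, so VIF = 1.5 (closed-form regression oracle)."""
    rng = np.random.default_rng(2)
    raw = rng.normal(size=(2000, 3))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # exactly orthonormal
    corr = np.full((3, 3), 0.5)
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr)
    env = pd.DataFrame(q @ L.T, columns=list("abc"))
    assert np.allclose(vif(env), 1.5, atol=1e-6)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_loglik_hand_case():
    """M=2, W=1, mu=0.5, phi=1/3 -> a=b=1 -> P = 2 * B(2,2)/B(1,1) = 1/3."""
    ll = betabinom_loglik([1], [2], [0.0], logit(1.0 / 3.0), [[1.0]])
    assert ll == pytest.approx(np.log(1.0 / 3.0), abs=1e-12)


def test_loglik_matches_scipy_pmf():
    rng = np.random.default_rng(3)
    for _ in range(20):
        M = int(rng.integers(2, 200))
        W = int(rng.integers(0, M + 1))
        mu = float(rng.uniform(0.05, 0.95))
        phi = float(rng.uniform(0.01, 0.8))
        a = mu * (1 - phi) / phi
        b = (1 - mu) * (1 - phi) / phi
        ll = betabinom_loglik([W], [M], [logit(mu)], logit(phi), [[1.0]])
        assert ll == pytest.approx(stats.betabinom.logpmf(W, M, a, b),
                                   abs=1e-8)


def test_loglik_binomial_limit():
    """phi -> 0 recovers the binomial log-likelihood."""
    rng = np.random.default_rng(4)
    M = rng.integers(10, 100, size=25).astype(float)
    W = rng.binomial(M.astype(int), 0.3).astype(float)
    X = np.ones((25, 1))
    eta = logit(0.3)
    ll_bb = betabinom_loglik(W, M, [eta], logit(1e-8), X)
    ll_binom = float(stats.binom.logpmf(W, M, 0.3).sum())
    assert abs(ll_bb - ll_binom) < 1e-4


def test_loglik_certain_event_is_zero():
    ll = betabinom_loglik([5], [5], [25.0], logit(1e-8), [[1.0]])
    assert abs(ll) < 1e-4


def test_loglik_rejects_invalid_counts():
    with pytest.raises(ValueError):
        betabinom_loglik([3], [2], [0.0], 0.0, [[1.0]])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_recovers_known_parameters():
    rng = np.random.default_rng(5)
    errs = []
    for r in range(15):
        W, M, X, _ = simulate_bb(rng, 131, beta=(-6.0, 0.5), phi=0.02)
        fit = fit_betabinom(W, M, X)
        assert fit.converged and not fit.degenerate
        errs.append(fit.coefficients - np.array([-6.0, 0.5]))
    errs = np.array(errs)
    assert np.all(np.abs(np.median(errs, axis=0)) < 0.1)


def test_fit_all_zero_is_degenerate():
    n = 30
    fit = fit_betabinom(np.zeros(n), np.full(n, 100.0), np.ones((n, 1)))
    assert fit.degenerate


def test_fit_rank_deficient_design_rejected():
    n = 30
    X = np.column_stack([np.ones(n), np.full(n, 2.0)])  # zero-variance col
    with pytest.raises(ValueError, match="rank"):
        fit_betabinom(np.ones(n), np.full(n, 10.0), X)


def test_fit_needs_enough_samples():
    with pytest.raises(ValueError, match="10"):
        fit_betabinom(np.ones(5), np.full(5, 10.0), np.ones((5, 1)))


def test_chosen_loglik_dominates_nested():
    rng = np.random.default_rng(6)
    W, M, X, z = simulate_bb(rng, 131, beta=(-6.0, 0.4), phi=0.05)
    f0 = fit_betabinom(W, M, X[:, :1])
    f1 = fit_betabinom(W, M, X)
    f2 = fit_betabinom(W, M, np.column_stack([X, z**2]))
    assert f1.loglik >= f0.loglik - 1e-6
    assert f2.loglik >= f1.loglik - 1e-6


def test_sign_invariant_to_covariate_rescaling():
    rng = np.random.default_rng(7)
    W, M, X, z = simulate_bb(rng, 131, beta=(-6.0, 0.6), phi=0.02)
    fit1 = fit_betabinom(W, M, X)
    X2 = np.column_stack([np.ones(131), 10.0 * z + 3.0])
    fit2 = fit_betabinom(W, M, X2)
    assert np.sign(fit1.coefficients[1]) == np.sign(fit2.coefficients[1])


# ---------------------------------------------------------------------------
# LRT
# ---------------------------------------------------------------------------

def test_lrt_identical_fits_p_one():
    rng = np.random.default_rng(8)
    W, M, X, _ = simulate_bb(rng, 50, beta=(-5.0, 0.0), phi=0.05)
    f = fit_betabinom(W, M, X[:, :1])
    assert lrt(f, f, df=1) == 1.0


def test_lrt_384_is_five_percent():
    class Fake:
        def __init__(self, ll):
            self.loglik = ll
    assert lrt(Fake(1.92), Fake(0.0), df=1) == pytest.approx(0.05, abs=5e-4)


def test_lrt_detects_optimizer_failure():
    class Fake:
        def __init__(self, ll):
            self.loglik = ll
    with pytest.raises(RuntimeError):
        lrt(Fake(0.0), Fake(1.0), df=1)


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def _screen_dataset(rng, effect="linear"):
    n = 131
    z = rng.normal(size=n)
    if effect == "linear":
        eta = -6.0 + 0.6 * z
    elif effect == "quadratic":
        eta = -6.0 + 0.9 * (1.0 - z**2)
    else:
        eta = np.full(n, -6.0)
    mu = expit(eta)
    phi = 0.02
    a = mu * (1 - phi) / phi
    b = (1 - mu) * (1 - phi) / phi
    M = 20_000
    W = rng.binomial(M, rng.beta(a, b))
    other = np.full(n, M) - W
    counts = pd.DataFrame(
        [W, other], index=["focal", "rest"],
        columns=[f"S{i}" for i in range(n)],
    )
    env = pd.DataFrame({"temperature": z},
                       index=pd.Index(counts.columns))
    return counts, env


def test_env_screen_linear_effect_found_positive():
    rng = np.random.default_rng(9)
    hits = 0
    for _ in range(5):
        counts, env = _screen_dataset(rng, "linear")
        fits = env_screen(counts, env, ["focal"], ["temperature"])
        row = fits.iloc[0]
        hits += row["significant"] and row["sign"] > 0 and row["form"] == "linear"
    assert hits >= 4


def test_env_screen_quadratic_effect_polynomial():
    rng = np.random.default_rng(10)
    hits = 0
    for _ in range(5):
        counts, env = _screen_dataset(rng, "quadratic")
        fits = env_screen(counts, env, ["focal"], ["temperature"])
        hits += fits.iloc[0]["form"] == "polynomial"
    assert hits >= 4


def test_env_screen_null_rarely_significant():
    rng = np.random.default_rng(11)
    sig = 0
    for _ in range(10):
        counts, env = _screen_dataset(rng, "null")
        fits = env_screen(counts, env, ["focal"], ["temperature"])
        sig += bool(fits.iloc[0]["significant"])
    assert sig <= 2


def test_env_screen_drops_missing_parameter_values(small_sim):
    _, ds, _ = small_sim
    env = ds.env.copy()
    env.iloc[:10, env.columns.get_loc("no3")] = np.nan
    fits = env_screen(ds.counts, env, [ds.counts.index[0]], ["no3"])
    assert fits.iloc[0]["n"] == ds.n_samples - 10
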