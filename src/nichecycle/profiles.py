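"""Seasonal profile clustering and cyclic smoothing of CLR abundance.

Seasonal ASVs are summarized by their mean CLR abundance per calendar month
(12-dimensional profiles), the number of profile clusters is chosen by the
gap statistic, the clusters themselves by Ward-linkage hierarchical
clustering, and each ASV's annual trend is displayed by a penalized cyclic
cubic spline of CLR over the day of year (the same curve class a cyclic GAM
smooth would fit), with the smoothing parameter chosen by generalized
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

YEAR_DAYS = 365.25


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------

def clr_transform(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio per sample with an additive pseudocount.

    ``clr_i = log(x_i + pc) - mean_j log(x_j + pc)`` for each sample
    (column).  Columns of the result sum to zero by construction.
    """
    vals = np.asarray(counts, dtype=float)
    if np.any(vals < 0):
        raise ValueError("counts must be non-negative")
    logs = np.log(vals + pseudocount)
    return logs - logs.mean(axis=0, keepdims=True)


def monthly_profile(clr: np.ndarray, dates: pd.DatetimeIndex) -> np.ndarray:
    """Mean CLR per calendar month: (taxa x samples) -> (taxa x 12).

    Every month of the year must be observed at least once.
    """
    clr = np.atleast_2d(np.asarray(clr, dtype=float))
    months = pd.DatetimeIndex(dates).month.to_numpy()  # 1..12
    missing = sorted(set(range(1, 13)) - set(months.tolist()))
    if missing:
        raise ValueError(f"months with zero samples: {missing}")
    out = np.empty((clr.shape[0], 12))
    for m in range(1, 13):
        out[:, m - 1] = clr[:, months == m].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def hierarchical_cluster(profiles: np.ndarray, k: int) -> np.ndarray:
    """Ward-linkage agglomeration on Euclidean distances, cut at k groups.

    Labels are renumbered 0..k-1 in order of first appearance so the
    assignment is invariant to cluster-id permutation.
    """
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return np.arange(n)
    if k == 1:
        return np.zeros(n, dtype=int)
    Z = linkage(profiles, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    _, labels = np.unique(raw, return_inverse=True)
    order = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = order.setdefault(lab, len(order))
    return out


def _within_dispersion(profiles: np.ndarray, labels: np.ndarray) -> float:
    """Tibshirani W_k: sum over clusters of pairwise-squared-distance / 2n_r,
    equal to the total within-cluster sum of squares."""
    w = 0.0
    for lab in np.unique(labels):
        pts = profiles[labels == lab]
        centroid = pts.mean(axis=0)
        w += ((pts - centroid) ** 2).sum()
    return w


@dataclass
class GapResult:
    k: int
    gaps: np.ndarray
    sks: np.ndarray
    log_wk: np.ndarray


def gap_statistic(
    profiles: np.ndarray,
    k_max: int,
    n_ref: int = 50,
    seed: int = 0,
) -> GapResult:
    """Choose the number of clusters by the gap statistic.

    ``Gap(k) = E*[log W_k] - log W_k`` with reference sets drawn uniformly
    over each dimension's observed range and clustered by the same
    hierarchical procedure; the chosen k is the smallest with
    ``Gap(k) >= Gap(k+1) - s_{k+1}`` (falling back to k_max if none
    qualifies).
    """
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if n < k_max + 1:
        raise ValueError("need at least k_max + 1 profiles")
    if np.all(pdist(profiles) == 0):
        raise ValueError("all profiles identical; gap statistic undefined")

    lo = profiles.min(axis=0)
    hi = profiles.max(axis=0)
    rng = np.random.default_rng(seed)

    ks = np.arange(1, k_max + 2)  # need Gap at k_max + 1 for the rule
    log_wk = np.empty(len(ks))
    for i, k in enumerate(ks):
        labels = hierarchical_cluster(profiles, k)
        log_wk[i] = np.log(max(_within_dispersion(profiles, labels), 1e-300))

    ref_log = np.empty((n_ref, len(ks)))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=profiles.shape)
        for i, k in enumerate(ks):
            labels = hierarchical_cluster(ref, k)
            ref_log[b, i] = np.log(max(_within_dispersion(ref, labels), 1e-300))

    gaps = ref_log.mean(axis=0) - log_wk
    sks = ref_log.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_ref)

    chosen = k_max
    for i in range(k_max):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            chosen = int(ks[i])
            break
    return GapResult(k=chosen, gaps=gaps[:k_max], sks=sks[:k_max],
                     log_wk=log_wk[:k_max])


# ---------------------------------------------------------------------------
# cyclic penalized spline
# ---------------------------------------------------------------------------

def _cyclic_spline_matrices(knots_full: np.ndarray):
    """Penalty machinery of a periodic natural cubic spline through K knots.

    ``knots_full`` carries the K distinct knots plus the wrapped first knot
    (knot0 + period) as its last entry.  With knot values beta and knot
    second derivatives gamma, the periodic interpolation conditions read
    ``B gamma = D beta`` with the cyclic tridiagonal matrices below, and
    the curvature penalty is ``int f''(x)^2 dx = beta' D' B^-1 D beta``.
    """
    K = len(knots_full) - 1
    h = np.diff(knots_full)  # K interval widths, last wraps to knot0 + period
    B = np.zeros((K, K))
    D = np.zeros((K, K))
    for j in range(K):
        hm = h[j - 1]  # h_{j-1}, wraps for j = 0
        hj = h[j]
        B[j, j] = (hm + hj) / 3.0
        B[j, (j + 1) % K] += hj / 6.0
        B[(j + 1) % K, j] += hj / 6.0
        D[j, j] = -(1.0 / hm + 1.0 / hj)
        D[j, (j + 1) % K] += 1.0 / hj
        D[j, (j - 1) % K] += 1.0 / hm
    return B, D


def _cyclic_design(x: np.ndarray, knots_full: np.ndarray, BinvD: np.ndarray):
    """Model matrix mapping knot values to spline values at points x."""
    K = len(knots_full) - 1
    x0 = knots_full[0]
    period = knots_full[-1] - x0
    xm = x0 + np.mod(x - x0, period)
    j = np.clip(np.searchsorted(knots_full, xm, side="right") - 1, 0, K - 1)
    hj = knots_full[j + 1] - knots_full[j]
    r = (xm - knots_full[j]) / hj
    a1 = 1.0 - r
    a2 = r
    c1 = ((1 - r) ** 3 - (1 - r)) * hj**2 / 6.0
    c2 = (r**3 - r) * hj**2 / 6.0
    n = len(x)
    A = np.zeros((n, K))
    Cm = np.zeros((n, K))
    rows = np.arange(n)
    np.add.at(A, (rows, j), a1)
    np.add.at(A, (rows, (j + 1) % K), a2)
    np.add.at(Cm, (rows, j), c1)
    np.add.at(Cm, (rows, (j + 1) % K), c2)
    return A + Cm @ BinvD


@dataclass
class SmoothFit:
    """Fitted periodic smooth: CLR abundance as a function of day of year."""

    knots: np.ndarray
    coefficients: np.ndarray  # spline values at the knots
    lam: float
    edf: float
    gcv: float
    _knots_full: np.ndarray
    _BinvD: np.ndarray

    def predict(self, day) -> np.ndarray:
        day = np.atleast_1d(np.asarray(day, dtype=float))
        X = _cyclic_design(day, self._knots_full, self._BinvD)
        return X @ self.coefficients

    def __call__(self, day):
        return self.predict(day)


def cyclic_smooth(
    doy: np.ndarray,
    clr_values: np.ndarray,
    n_knots: int = 12,
    period: float = YEAR_DAYS,
    lambdas: np.ndarray | None = None,
) -> SmoothFit:
    """Penalized cyclic cubic spline of CLR values over day of year.

    Knots are equally spaced on [0, period); the fit minimizes
    ``||y - f||^2 + lambda int f''^2`` over periodic natural cubic splines,
    with lambda selected on a log grid by GCV(lambda) = n RSS / (n - edf)^2.
    The fitted curve and its first derivative are continuous across the
    year boundary by construction.
    """
    doy = np.asarray(doy, dtype=float)
    y = np.asarray(clr_values, dtype=float)
    if doy.shape != y.shape or doy.ndim != 1:
        raise ValueError("doy and values must be 1-D and equal length")
    n = len(y)
    if n < 2 * n_knots:
        raise ValueError(f"need >= {2 * n_knots} observations for {n_knots} knots")

    knots = np.arange(n_knots) * period / n_knots
    knots_full = np.append(knots, period)
    B, D = _cyclic_spline_matrices(knots_full)
    BinvD = np.linalg.solve(B, D)
    S = D.T @ BinvD
    S = (S + S.T) / 2.0
    X = _cyclic_design(doy, knots_full, BinvD)

    XtX = X.T @ X
    Xty = X.T @ y
    if lambdas is None:
        lambdas = np.logspace(-2, 8, 41)

    best = None
    for lam in lambdas:
        A = XtX + lam * S
        try:
            beta = np.linalg.solve(A, Xty)
            H_trace = np.trace(np.linalg.solve(A, XtX))
        except np.linalg.LinAlgError:
            continue
        resid = y - X @ beta
        rss = float(resid @ resid)
        edf = float(H_trace)
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf)
    if best is None:
        raise np.linalg.LinAlgError("cyclic smooth failed for all lambdas")
    gcv, lam, beta, edf = best
    return SmoothFit(
        knots=knots, coefficients=beta, lam=float(lam), edf=edf, gcv=gcv,
        _knots_full=knots_full, _BinvD=BinvD,
    )
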