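"""Seasonality detection by Lomb-Scargle periodogram with permutation nulls.

The classical variance-normalized Lomb-Scargle periodogram (LSP) estimates
spectral power on an unevenly sampled series; its maximum, the peak
normalized power (PN), is the seasonality-strength statistic.  Significance
comes from shuffling the observed values over the fixed sampling times, and
the per-ASV permutation p-values are corrected by Benjamini-Hochberg.  An
ASV is called seasonal when PN >= 10 and q <= 0.05.  The module also
implements the higher-rank coherence test: repeatedly aggregate a random
80% of a group's ASVs and ask whether the summed series is seasonal.

The LSP is implemented here directly (and vectorized over permutations)
because the permutation null needs thousands of periodogram evaluations on
a shared time axis; unit tests check it against an independent brute-force
evaluation and against the classical periodogram on even sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from nichecycle._utils import rng_for
from nichecycle.io import Dataset
from nichecycle.profiles import clr_transform


@dataclass
class TimeSeries:
    """Unevenly sampled real series: times in days since first sample."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if len(self.times) < 8:
            raise ValueError("time series must have length >= 8")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.isfinite(self.times).all() and np.isfinite(self.values).all()):
            raise ValueError("times and values must be finite")


@dataclass
class PeriodogramResult:
    """LSP on a frequency grid; PN is the peak normalized power."""

    frequency: np.ndarray  # cycles / day
    power: np.ndarray
    peak_period: float  # days
    pn: float


class ZeroVarianceError(ValueError):
    """The series has no variance; the normalized periodogram is undefined.

    Distinct from 'not seasonal': a flat series carries no information."""


# ---------------------------------------------------------------------------
# core LSP
# ---------------------------------------------------------------------------

def frequency_grid(
    times: np.ndarray,
    oversampling: int = 4,
    max_frequency_factor: float = 1.0,
) -> np.ndarray:
    """Standard LSP grid: 1/span up to ``hifac * n / (2 span)`` in steps of
    ``1 / (oversampling * span)`` (periods from ~2x mean spacing up to the
    observation span)."""
    times = np.asarray(times, dtype=float)
    span = times[-1] - times[0]
    if span <= 0:
        raise ValueError("zero observation span")
    n = len(times)
    f_min = 1.0 / span
    f_max = max_frequency_factor * n / (2.0 * span)
    step = 1.0 / (oversampling * span)
    n_step = max(int(np.floor((f_max - f_min) / step)) + 1, 2)
    return f_min + step * np.arange(n_step)


def _lsp_basis(times: np.ndarray, freqs: np.ndarray):
    """Per-frequency tau-shifted cosine/sine bases and their sums of squares.

    Precomputing these makes the power of any value-vector on the same time
    axis a pair of matrix products — the permutation null rides on this.
    """
    t = np.asarray(times, dtype=float)[:, None]
    w = 2.0 * np.pi * np.asarray(freqs, dtype=float)[None, :]
    wt = w * t
    tau_arg = np.arctan2(np.sin(2 * wt).sum(axis=0), np.cos(2 * wt).sum(axis=0))
    # w tau = tau_arg / 2
    arg = wt - tau_arg[None, :] / 2.0
    C = np.cos(arg)
    S = np.sin(arg)
    CC = (C * C).sum(axis=0)
    SS = (S * S).sum(axis=0)
    return C, S, CC, SS


def _batch_power(values: np.ndarray, C, S, CC, SS) -> np.ndarray:
    """Normalized LSP power for each row of ``values`` (B x n) -> (B x F)."""
    X = values - values.mean(axis=1, keepdims=True)
    var = X.var(axis=1, ddof=1)
    if np.any(var <= 0):
        raise ZeroVarianceError("zero-variance series")
    XC = X @ C
    XS = X @ S
    # guard degenerate basis columns (SS ~ 0 exactly when the sine component
    # vanishes on the sampling grid; its numerator vanishes too)
    eps = 1e-12
    pc = np.where(CC > eps, XC**2 / np.maximum(CC, eps), 0.0)
    ps = np.where(SS > eps, XS**2 / np.maximum(SS, eps), 0.0)
    return (pc + ps) / (2.0 * var[:, None])


def lomb_scargle_power(
    times: np.ndarray, values: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Variance-normalized classical LSP power at the given frequencies."""
    C, S, CC, SS = _lsp_basis(times, freqs)
    return _batch_power(np.asarray(values, float)[None, :], C, S, CC, SS)[0]


def lomb_scargle(
    ts: TimeSeries,
    oversampling: int = 4,
    max_frequency_factor: float = 1.0,
) -> PeriodogramResult:
    """Classical variance-normalized LSP of one series on the default grid."""
    freqs = frequency_grid(ts.times, oversampling, max_frequency_factor)
    power = lomb_scargle_power(ts.times, ts.values, freqs)
    i = int(np.argmax(power))
    return PeriodogramResult(
        frequency=freqs,
        power=power,
        peak_period=1.0 / freqs[i],
        pn=float(power[i]),
    )


def randomization_pvalue(
    ts: TimeSeries,
    n_rand: int = 1000,
    seed: int = 0,
    oversampling: int = 4,
    max_frequency_factor: float = 1.0,
) -> tuple[float, PeriodogramResult]:
    """Permutation p-value of the peak power: shuffle values, keep times.

    Add-one rule: p = (1 + #{perm peaks >= observed PN}) / (1 + n_rand),
    so p is never below 1/(1+n_rand).
    """
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99")
    freqs = frequency_grid(ts.times, oversampling, max_frequency_factor)
    C, S, CC, SS = _lsp_basis(ts.times, freqs)
    obs_power = _batch_power(ts.values[None, :], C, S, CC, SS)[0]
    i = int(np.argmax(obs_power))
    result = PeriodogramResult(
        frequency=freqs, power=obs_power,
        peak_period=1.0 / freqs[i], pn=float(obs_power[i]),
    )
    rng = np.random.default_rng(seed)
    perm = rng.permuted(
        np.broadcast_to(ts.values, (n_rand, len(ts.values))).copy(), axis=1
    )
    peaks = _batch_power(perm, C, S, CC, SS).max(axis=1)
    p = (1.0 + int((peaks >= result.pn).sum())) / (1.0 + n_rand)
    return p, result


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def _transform_counts(counts: pd.DataFrame, transform: str,
                      totals: np.ndarray | None = None) -> np.ndarray:
    """Per-sample relative abundance (default) or CLR of the count matrix."""
    vals = counts.to_numpy(dtype=float)
    if transform == "relabund":
        tot = totals if totals is not None else vals.sum(axis=0)
        return vals / tot[None, :]
    if transform == "clr":
        return clr_transform(vals)
    raise ValueError(f"unknown transform {transform!r}")


def seasonality_screen(
    dataset: Dataset,
    transform: str = "relabund",
    pn_threshold: float = 10.0,
    q_threshold: float = 0.05,
    n_rand: int = 1000,
    seed: int = 0,
    min_prevalence: int = 4,
    annual_window: tuple[float, float] = (300.0, 430.0),
    oversampling: int = 4,
    max_frequency_factor: float = 1.0,
) -> pd.DataFrame:
    """Per-ASV seasonality calls over the whole dataset.

    ASVs present (count > 0) in fewer than ``min_prevalence`` samples are
    not tested.  Per-ASV permutation seeds derive from the global seed and
    the ASV id, so results do not depend on evaluation order.  Returns a
    table with PN, peak period, permutation p, BH q, the seasonal flag
    (PN >= threshold and q <= threshold) and an `annual` flag marking peak
    periods inside the annual window.
    """
    times = dataset.times_days
    freqs = frequency_grid(times, oversampling, max_frequency_factor)
    C, S, CC, SS = _lsp_basis(times, freqs)

    X = _transform_counts(dataset.counts, transform)
    prevalence = (dataset.counts.to_numpy() > 0).sum(axis=1)
    tested = prevalence >= min_prevalence
    if not tested.any():
        raise ValueError("no ASV passes the prevalence filter")

    rows = []
    for i in np.flatnonzero(tested):
        asv = dataset.counts.index[i]
        x = X[i]
        obs = _batch_power(x[None, :], C, S, CC, SS)[0]
        k = int(np.argmax(obs))
        pn = float(obs[k])
        period = 1.0 / freqs[k]
        rng = rng_for(seed, "seasonality", asv)
        perm = rng.permuted(
            np.broadcast_to(x, (n_rand, len(x))).copy(), axis=1
        )
        peaks = _batch_power(perm, C, S, CC, SS).max(axis=1)
        p = (1.0 + int((peaks >= pn).sum())) / (1.0 + n_rand)
        rows.append((asv, pn, period, p))

    calls = pd.DataFrame(rows, columns=["asv", "pn", "peak_period", "p_rand"])
    calls["q"] = benjamini_hochberg(calls["p_rand"].to_numpy())
    calls["seasonal"] = (calls["pn"] >= pn_threshold) & (calls["q"] <= q_threshold)
    lo, hi = annual_window
    calls["annual"] = (calls["peak_period"] >= lo) & (calls["peak_period"] <= hi)
    return calls


def rank_eligibility(taxonomy: pd.DataFrame, min_asvs: int = 10) -> list[str]:
    """Classes worth testing at every rank: more than one order, family and
    genus, each subgroup holding at least ``min_asvs`` ASVs."""
    eligible = []
    for cls, sub in taxonomy.groupby("class"):
        ok = True
        for rank in ("order", "family", "genus"):
            sizes = sub.groupby(rank).size()
            if (sizes >= min_asvs).sum() <= 1:
                ok = False
                break
        if ok:
            eligible.append(cls)
    return sorted(eligible)


@dataclass
class RankSeasonality:
    """Resampled seasonality of an aggregated taxonomic group."""

    rank: str
    group: str
    pns: np.ndarray  # one PN per iteration
    pvalues: np.ndarray
    fraction_seasonal: float


def rank_aggregation_test(
    dataset: Dataset,
    rank: str,
    group: str,
    frac: float = 0.8,
    n_iter: int = 300,
    seed: int = 0,
    pn_threshold: float = 10.0,
    p_threshold: float = 0.05,
    n_rand: int = 1000,
    transform: str = "relabund",
    oversampling: int = 4,
    max_frequency_factor: float = 1.0,
) -> RankSeasonality:
    """Coherence of seasonality at a taxonomic rank by member resampling.

    Each iteration draws ``ceil(frac * n)`` of the group's ASVs without
    replacement, sums their counts, transforms the aggregate (relative to
    the full-sample totals) and evaluates LSP peak power plus its
    permutation p-value.  ``fraction_seasonal`` is the share of iterations
    with PN >= pn_threshold and p <= p_threshold.  Antiphase members cancel
    in the sum, so incoherent groups score low even when every member is
    individually seasonal.
    """
    if rank not in dataset.taxonomy.columns:
        raise ValueError(f"unknown rank {rank!r}")
    members = dataset.taxonomy.index[dataset.taxonomy[rank] == group]
    if len(members) == 0:
        raise ValueError(f"group {group!r} absent from taxonomy rank {rank!r}")
    if len(members) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 ASVs")

    counts = dataset.counts.loc[members].to_numpy(dtype=float)
    totals = dataset.counts.to_numpy().sum(axis=0).astype(float)
    times = dataset.times_days
    freqs = frequency_grid(times, oversampling, max_frequency_factor)
    C, S, CC, SS = _lsp_basis(times, freqs)

    n_take = math.ceil(frac * len(members))
    rng = rng_for(seed, "rank", rank, group)
    pns = np.empty(n_iter)
    pvals = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.choice(len(members), size=n_take, replace=False)
        agg = counts[idx].sum(axis=0)
        if transform == "relabund":
            x = agg / totals
        else:
            x = np.log(agg + 1.0)  # CLR of one aggregate reduces to log
        obs = _batch_power(x[None, :], C, S, CC, SS)[0]
        pn = float(obs.max())
        perm = rng.permuted(
            np.broadcast_to(x, (n_rand, len(x))).copy(), axis=1
        )
        peaks = _batch_power(perm, C, S, CC, SS).max(axis=1)
        pvals[it] = (1.0 + int((peaks >= pn).sum())) / (1.0 + n_rand)
        pns[it] = pn
    frac_seasonal = float(
        np.mean((pns >= pn_threshold) & (pvals <= p_threshold))
    )
    return RankSeasonality(
        rank=rank, group=group, pns=pns, pvalues=pvals,
        fraction_seasonal=frac_seasonal,
    )
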