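"""Rho proportionality on CLR data and the niche-vs-divergence regression.

Rho measures proportional change of two compositional parts:
``rho = 1 - var(clr_x - clr_y) / (var clr_x + var clr_y)``, a
correlation-like statistic on the CLR scale (1 = perfectly proportional,
-1 = perfectly anti-proportional).  Pairs are screened over all ASVs, an
empirical FDR is estimated by shuffling every taxon independently across
samples, and within each genus Rho is regressed on pairwise nucleotide
divergence: a significant negative slope means close relatives share more
of their temporal niche than distant ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nichecycle.profiles import clr_transform


def rho(clr_x, clr_y) -> float:
    """Proportionality of change between two CLR series."""
    x = np.asarray(clr_x, dtype=float)
    y = np.asarray(clr_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be 1-D, equal length >= 3")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx + vy == 0:
        raise ValueError("rho undefined: both series constant")
    return float(1.0 - (x - y).var(ddof=1) / (vx + vy))


def _rho_matrix(clr: np.ndarray) -> np.ndarray:
    """All-pairs rho from a CLR matrix (taxa x samples), vectorized via
    ``rho_ij = 2 cov_ij / (var_i + var_j)``."""
    cov = np.cov(clr, ddof=1)
    var = np.diag(cov)
    denom = var[:, None] + var[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 2.0 * cov / denom
    return r


def rho_screen(
    counts: pd.DataFrame,
    pseudocount: float = 1.0,
    taxonomy: pd.DataFrame | None = None,
    within_genus: bool = False,
) -> pd.DataFrame:
    """Rho for every ASV pair after CLR transform of the count table.

    Returns a long table (asv_a, asv_b, rho[, genus]).  With
    ``within_genus=True`` only pairs sharing a genus are emitted (the unit
    of the niche analysis); rho values are computed on the full-community
    CLR either way.
    """
    if counts.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    ids = list(counts.index)
    clr = clr_transform(counts.to_numpy(), pseudocount)
    r = _rho_matrix(clr)
    genus = taxonomy["genus"] if taxonomy is not None else None
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            g_i = genus.get(ids[i]) if genus is not None else None
            g_j = genus.get(ids[j]) if genus is not None else None
            same = g_i is not None and g_i == g_j
            if within_genus and not same:
                continue
            rows.append((ids[i], ids[j], r[i, j], g_i if same else None))
    out = pd.DataFrame(rows, columns=["asv_a", "asv_b", "rho", "genus"])
    if genus is None:
        out = out.drop(columns="genus")
    return out


@dataclass
class FdrCurve:
    """Empirical FDR per rho cutoff and the selected cutoff."""

    cutoffs: np.ndarray
    fdr: np.ndarray
    n_observed: np.ndarray
    selected_cutoff: float | None  # None when no cutoff reaches the target


def permutation_fdr(
    counts: pd.DataFrame,
    cutoff_grid: np.ndarray | None = None,
    n_perm: int = 100,
    seed: int = 0,
    target_fdr: float = 0.05,
    pseudocount: float = 1.0,
    pairs: pd.DataFrame | None = None,
) -> tuple[FdrCurve, pd.DataFrame]:
    """Permutation-based FDR for the rho screen.

    Each permutation shuffles every taxon's counts independently across
    samples (destroying all pairwise association while keeping marginals),
    re-applies CLR and recomputes all-pairs rho.  For a cutoff c,
    ``FDR(c) = mean_perm #null pairs with rho >= c / #observed pairs with
    rho >= c``; the selected cutoff is the smallest grid value with
    FDR <= target.  Returns the curve plus the observed pair table with a
    ``passes_fdr`` column (all False when no cutoff qualifies).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if cutoff_grid is None:
        cutoff_grid = np.arange(0.0, 1.0, 0.05)
    cutoff_grid = np.asarray(cutoff_grid, dtype=float)
    if pairs is None:
        pairs = rho_screen(counts, pseudocount)
    obs = pairs["rho"].to_numpy()
    obs_sorted = np.sort(obs)
    n_obs_ge = len(obs) - np.searchsorted(obs_sorted, cutoff_grid, side="left")

    vals = counts.to_numpy()
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(vals.shape[0], k=1)
    null_ge = np.zeros((n_perm, len(cutoff_grid)))
    for b in range(n_perm):
        shuffled = rng.permuted(vals, axis=1)
        r = _rho_matrix(clr_transform(shuffled, pseudocount))[iu]
        r_sorted = np.sort(r)
        null_ge[b] = len(r) - np.searchsorted(r_sorted, cutoff_grid, side="left")

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_obs_ge > 0, null_ge.mean(axis=0) / n_obs_ge, 0.0)
    ok = np.flatnonzero((fdr <= target_fdr) & (n_obs_ge > 0))
    selected = float(cutoff_grid[ok[0]]) if len(ok) else None
    pairs = pairs.copy()
    pairs["passes_fdr"] = (
        pairs["rho"] >= selected if selected is not None else False
    )
    return FdrCurve(cutoffs=cutoff_grid, fdr=fdr, n_observed=n_obs_ge,
                    selected_cutoff=selected), pairs


def niche_regression(
    rho_pairs: pd.DataFrame,
    divergence: pd.DataFrame,
    min_close_asvs: int = 10,
    max_nt: int = 5,
    fdr_filtered_only: bool = False,
) -> pd.DataFrame:
    """Per-genus OLS of rho on nucleotide divergence.

    A genus enters the analysis when at least ``min_close_asvs`` of its
    ASVs participate in one or more pairs at <= ``max_nt`` mismatches;
    the regression itself then uses ALL the genus's pairs (divergence
    beyond max_nt included).  Degenerate designs (fewer than 3 pairs, or
    constant divergence) are recorded as untestable rather than fitted.
    """
    pairs = rho_pairs.dropna(subset=["genus"]).copy()
    if fdr_filtered_only and "passes_fdr" in pairs.columns:
        pairs = pairs[pairs["passes_fdr"]]
    pairs["divergence"] = [
        int(divergence.loc[a, b]) for a, b in zip(pairs["asv_a"], pairs["asv_b"])
    ]
    rows = []
    for gname, sub in pairs.groupby("genus"):
        close = sub[sub["divergence"] <= max_nt]
        n_close = len(set(close["asv_a"]) | set(close["asv_b"]))
        if n_close < min_close_asvs:
            continue
        row = {
            "genus": gname,
            "n_pairs": len(sub),
            "n_close_asvs": n_close,
        }
        if len(sub) < 3 or sub["divergence"].nunique() < 2:
            row.update(slope=np.nan, intercept=np.nan, p_value=np.nan,
                       r_squared=np.nan, significant=False, testable=False)
        else:
            fit = stats.linregress(sub["divergence"], sub["rho"])
            row.update(
                slope=fit.slope,
                intercept=fit.intercept,
                p_value=fit.pvalue,
                r_squared=fit.rvalue**2,
                significant=bool(fit.pvalue <= 0.05),
                testable=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)
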