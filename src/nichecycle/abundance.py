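"""Occurrence/abundance classification and conditionally rare taxa (CRT).

An ASV is *abundant* when it reaches >= 1% relative abundance in at least
one sample, otherwise permanently rare; its occurrence class is broad
(detected in >= 75% of samples), narrow (<= 10%) or intermediate.
Conditionally rare taxa — usually rare, occasionally blooming — are flagged
when Sarle's sample-corrected bimodality coefficient of the relative-
abundance series reaches 0.9 and the ASV is abundant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from nichecycle.io import Dataset


def relative_abundance(counts) -> np.ndarray:
    """Per-sample proportions; every sample must have a positive total."""
    vals = np.asarray(counts, dtype=float)
    totals = vals.sum(axis=0)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0).tolist()
        raise ValueError(f"all-zero samples at column indices {bad}")
    return vals / totals[None, :]


def classify_occurrence(occurrence: float, broad: float = 0.75,
                        narrow: float = 0.10) -> str:
    """broad iff occurrence >= 0.75; narrow iff <= 0.10; else intermediate."""
    if not 0.0 <= occurrence <= 1.0:
        raise ValueError(f"occurrence must be in [0, 1], got {occurrence}")
    if occurrence >= broad:
        return "broad"
    if occurrence <= narrow:
        return "narrow"
    return "intermediate"


def classify_abundance(max_rel: float, cutoff: float = 1.0) -> str:
    """abundant iff the max per-sample relative abundance (%) >= cutoff."""
    if max_rel < 0:
        raise ValueError("max_rel must be >= 0")
    return "abundant" if max_rel >= cutoff else "rare"


def bimodality_coefficient(series) -> float:
    """Sarle's sample-corrected bimodality coefficient.

    b = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3))) with g1 the sample
    skewness and g2 the sample excess kurtosis (both bias-corrected).
    A balanced two-point mass approaches 1; a large-sample Gaussian is 5/9.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("bimodality needs n >= 4")
    if np.allclose(x, x[0]):
        raise ValueError("bimodality undefined for a constant series")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, bias=False)  # excess kurtosis
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def detect_crt(bimodality: float, max_rel: float,
               bimodality_threshold: float = 0.9,
               abundance_cutoff: float = 1.0) -> bool:
    """CRT iff bimodality >= 0.9 and max relative abundance >= 1%."""
    return bool(bimodality >= bimodality_threshold
                and max_rel >= abundance_cutoff)


def classify_asvs(
    dataset: Dataset,
    broad: float = 0.75,
    narrow: float = 0.10,
    abundant_cutoff: float = 1.0,
    bimodality_threshold: float = 0.9,
) -> pd.DataFrame:
    """One AbundanceRecord row per ASV.

    Occurrence counts presence (count > 0); relative abundances are in
    percent; bimodality is computed on the relative-abundance series (not
    raw counts) so sequencing-depth artifacts cannot fake a bloom.  The
    CRT flag is evaluated for every ASV (constant or near-constant series,
    where the coefficient is undefined, are not CRT) and is by definition
    confined to the abundant class.
    """
    rel = relative_abundance(dataset.counts.to_numpy()) * 100.0
    present = dataset.counts.to_numpy() > 0
    rows = []
    for i, asv in enumerate(dataset.counts.index):
        occ = float(present[i].mean())
        max_rel = float(rel[i].max())
        mean_rel = float(rel[i].mean())
        try:
            b = bimodality_coefficient(rel[i])
        except ValueError:
            b = np.nan
        rows.append(
            {
                "asv": asv,
                "occurrence": occ,
                "max_rel": max_rel,
                "mean_rel": mean_rel,
                "occ_class": classify_occurrence(occ, broad, narrow),
                "abund_class": classify_abundance(max_rel, abundant_cutoff),
                "bimodality": b,
                "crt": (not np.isnan(b))
                and detect_crt(b, max_rel, bimodality_threshold, abundant_cutoff),
            }
        )
    return pd.DataFrame(rows)


def plot_occurrence_abundance(records: pd.DataFrame, path=None):
    """Minimal occurrence vs mean relative abundance scatter (log y)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, sub in records.groupby("abund_class"):
        ax.scatter(sub["occurrence"] * 100, sub["mean_rel"].clip(lower=1e-4),
                   s=8, alpha=0.6, label=cls)
    ax.set_yscale("log")
    ax.set_xlabel("occurrence (% of samples)")
    ax.set_ylabel("mean relative abundance (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
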