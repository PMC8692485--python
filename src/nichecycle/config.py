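"""Configuration objects: the synthetic-data design and pipeline thresholds.

``SimConfig`` encodes the study design emulated by the generator: roughly a
decade of monthly coastal samples, thousands of ASVs organized into genera
with controlled sequence divergence, an annual-cycle seasonal fraction,
occasional bloomers (CRT), and seasonally structured environmental
covariates.  ``RunConfig`` aggregates every analysis threshold with the
study's published defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic community generator.

    Defaults emulate the sampling design of the emulated study: 11 years of
    monthly surface-water samples (one month lost to failed sequencing on
    average), fixed sequencing depth, V3-V4-length (420 nt) ASVs grouped
    into genera, ~30% of ASVs with an annual abundance cycle of log-scale
    amplitude 1.0-2.5 (peak normalized powers in the detected 10-43 range),
    and a handful of conditionally rare bloomers.
    """

    n_years: int = 11
    samples_per_month: int = 1
    reads_per_sample: int = 50_000
    n_genera: int = 25
    asvs_per_genus: int | Sequence[int] = 8
    seq_length: int = 420
    frac_seasonal: float = 0.3
    amplitude_range: tuple[float, float] = (1.0, 2.5)
    baseline_sd: float = 1.2
    latent_noise_sd: float = 0.5
    # within-genus substitutions per ASV drawn from this inclusive range
    within_divergence_range: tuple[int, int] = (1, 10)
    # phase-divergence coupling: first `coupled_genera` genera are built as a
    # substitution ladder with phase shifted `phase_rate_per_sub` days per
    # substitution (all their ASVs seasonal, shared base phase)
    coupled_genera: int = 0
    phase_rate_per_sub: float = 8.0
    # environmental responsiveness of the latent model
    frac_env_responsive: float = 0.0
    env_beta_range: tuple[float, float] = (0.5, 1.5)
    # conditionally rare taxa: resting level, occasional blooms at a
    # characteristic level (baseline + magnitude) with modest variability
    n_crt: int = 5
    crt_spike_prob: float = 0.05
    crt_spike_magnitude: float = 4.0
    crt_baseline: float = 0.0
    crt_bloom_sd: float = 0.15
    env_noise_sd: dict[str, float] = field(default_factory=dict)
    missing_month_prob: float = 1.0 / 132.0
    depth_distribution: str = "fixed"  # or "lognormal"
    depth_lognorm_sigma: float = 0.3
    start_year: int = 2004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years <= 0 or self.samples_per_month <= 0:
            raise ValueError("n_years and samples_per_month must be positive")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.seq_length <= 0 or self.n_genera <= 0:
            raise ValueError("seq_length and n_genera must be positive")
        for name in ("frac_seasonal", "crt_spike_prob", "missing_month_prob",
                     "frac_env_responsive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.within_divergence_range
        if lo < 0 or hi < lo:
            raise ValueError("within_divergence_range must be 0 <= lo <= hi")
        if hi >= self.seq_length:
            raise ValueError(
                "requested within-genus divergence exceeds sequence length"
            )
        if self.depth_distribution not in ("fixed", "lognormal"):
            raise ValueError("depth_distribution must be 'fixed' or 'lognormal'")

    def asv_counts(self) -> list[int]:
        """Number of ASVs per genus as an explicit list."""
        if isinstance(self.asvs_per_genus, int):
            return [self.asvs_per_genus] * self.n_genera
        counts = list(self.asvs_per_genus)
        if len(counts) != self.n_genera:
            raise ValueError("asvs_per_genus list length must equal n_genera")
        return counts


@dataclass
class RunConfig:
    """All pipeline thresholds, with the study's published defaults."""

    # seasonality
    pn_threshold: float = 10.0
    q_threshold: float = 0.05
    n_rand: int = 1000
    min_prevalence: int = 4
    annual_window: tuple[float, float] = (300.0, 430.0)
    oversampling: int = 4
    max_frequency_factor: float = 1.0
    transform: str = "relabund"  # or "clr"
    # occurrence / abundance classes
    broad_occurrence: float = 0.75
    narrow_occurrence: float = 0.10
    abundant_cutoff: float = 1.0  # percent relative abundance
    bimodality_threshold: float = 0.9
    # rank-level resampling
    rank_frac: float = 0.8
    rank_n_iter: int = 300
    rank_min_asvs: int = 10
    rank_p_threshold: float = 0.05
    # sequences
    otu_identity: float = 0.99
    close_nt: int = 5
    min_close_asvs: int = 10
    # proportionality
    rho_fdr: float = 0.05
    rho_n_perm: int = 100
    pseudocount: float = 1.0
    # env models
    env_fdr: float = 0.05
    env_parameters: tuple[str, ...] = (
        "temperature", "chlorophyll", "no3", "no2", "nh4", "po4", "sio2",
        "pnf", "hnf",
    )
    # profiles
    n_knots: int = 12
    gap_k_max: int = 8
    gap_n_ref: int = 50
    seed: int = 0
    simulate: Optional[SimConfig] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_threshold <= 1.0:
            raise ValueError(f"q_threshold must be in [0, 1], got {self.q_threshold}")
        if not 0.0 <= self.rho_fdr <= 1.0 or not 0.0 <= self.env_fdr <= 1.0:
            raise ValueError("FDR thresholds must be in [0, 1]")
        if not 0.0 <= self.narrow_occurrence <= self.broad_occurrence <= 1.0:
            raise ValueError("occurrence cuts must satisfy 0 <= narrow <= broad <= 1")
        if not 0.0 < self.otu_identity <= 1.0:
            raise ValueError("otu_identity must be in (0, 1]")
        if not 0.0 < self.rank_frac <= 1.0:
            raise ValueError("rank_frac must be in (0, 1]")
        if self.pn_threshold < 0 or self.n_rand < 99:
            raise ValueError("pn_threshold >= 0 and n_rand >= 99 required")
        if self.transform not in ("relabund", "clr"):
            raise ValueError("transform must be 'relabund' or 'clr'")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig (with optional nested ``simulate`` block) from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulate", None)
    sim = SimConfig(**_tupled(sim_raw)) if sim_raw is not None else None
    cfg = RunConfig(**_tupled(raw), simulate=sim)
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back to YAML (round-trips with load_config)."""
    data = asdict(cfg)
    sim = data.pop("simulate", None)
    data = {k: _listed(v) for k, v in data.items()}
    if sim is not None:
        data["simulate"] = {k: _listed(v) for k, v in sim.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _tupled(d: dict | None) -> dict:
    """YAML lists -> tuples for the tuple-typed fields."""
    if not d:
        return {}
    out = {}
    for k, v in d.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def _listed(v):
    return list(v) if isinstance(v, tuple) else v
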