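"""Ground-truthed synthetic community generator.

Emulates the study design the analysis assumes: roughly a decade of monthly
coastal samples at uneven calendar dates, thousands of ASVs grouped into
genera with controlled nucleotide divergence, a seasonal fraction whose
latent log-abundance follows an annual cosine, conditionally rare taxa with
occasional log-scale spikes, seasonally structured environmental covariates,
and compositional (multinomial) read sampling at fixed depth.

Every stochastic draw is governed by a single seed, and the generator emits
the full ground truth (per-ASV amplitudes, phases, environmental
coefficients, CRT flags, exact pairwise substitution counts), so each
downstream analysis stage can be scored against what was actually planted.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nichecycle.config import SimConfig
from nichecycle.io import Dataset, ENV_PARAMETERS

YEAR_DAYS = 365.25
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default observation noise per environmental parameter.  Temperature and
#: nutrients get additive Gaussian noise (natural units); PNF/HNF are
#: log-normal so they stay positive.
DEFAULT_ENV_NOISE = {
    "temperature": 0.8,
    "chlorophyll": 0.12,
    "no3": 0.35,
    "no2": 0.05,
    "nh4": 0.08,
    "po4": 0.03,
    "sio2": 0.40,
    "pnf": 0.30,  # sd of log
    "hnf": 0.25,  # sd of log
}

# deterministic annual component per parameter: (mean, amplitude, peak month
# index 0-11).  Temperature is anchored at the observed February minimum of
# 12.6 C and August maximum of 24.5 C; inorganic nutrients peak in winter
# (anti-phase with temperature); chlorophyll peaks at the winter-spring
# transition near 1 mg m-3; nanoflagellates are modelled on the log scale.
_ENV_CYCLE = {
    "temperature": (18.55, 5.95, 7),   # Feb 12.6, Aug 24.5
    "chlorophyll": (0.55, 0.45, 2),    # ~1 mg m-3 in early spring
    "no3": (2.2, 1.8, 1),
    "no2": (0.25, 0.20, 0),
    "nh4": (0.50, 0.30, 9),   # regeneration peak in autumn
    "po4": (0.15, 0.10, 11),
    "sio2": (1.5, 1.0, 2),
    "pnf": (np.log(1000.0), 0.5, 5),   # log cells / ml
    "hnf": (np.log(800.0), 0.3, 7),
}
_LOG_SCALE_PARAMS = ("pnf", "hnf")


# ---------------------------------------------------------------------------
# dates
# ---------------------------------------------------------------------------

def simulate_dates(config: SimConfig, rng: np.random.Generator) -> pd.DatetimeIndex:
    """Monthly sampling dates with within-month day jitter and missing months.

    The sampling day is uniform within each calendar month, so the resulting
    time axis is genuinely uneven — the regime the Lomb-Scargle periodogram
    exists for.  Whole months are dropped with ``missing_month_prob``
    (mimicking failed sequencing), never individual taxa.
    """
    dates: list[pd.Timestamp] = []
    for year in range(config.start_year, config.start_year + config.n_years):
        for month in range(1, 13):
            if rng.random() < config.missing_month_prob:
                continue
            n_days = calendar.monthrange(year, month)[1]
            days = rng.choice(
                np.arange(1, n_days + 1),
                size=config.samples_per_month,
                replace=False,
            )
            for day in np.sort(days):
                dates.append(pd.Timestamp(year=year, month=month, day=int(day)))
    if not dates:
        raise ValueError("no sampling dates generated")
    return pd.DatetimeIndex(dates)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]

def _substitute(seq: np.ndarray, pos: int, rng: np.random.Generator) -> None:
    choices = BASES[BASES != seq[pos]]
    seq[pos] = rng.choice(choices)


def simulate_sequences(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], pd.Series, pd.DataFrame, pd.Series]:
    """Generate per-genus ancestors and derived ASV sequences.

    Each genus has one random ancestor; any two ancestors differ at more
    than 10% of positions (re-drawn otherwise).  Within a genus each ASV is
    the ancestor plus k point substitutions, k in the configured range.
    For phase-coupled genera the substitutions form a nested ladder (ASV j
    carries the first k_j substitutions of one ordered list), so the
    pairwise substitution count is exactly ``|k_i - k_j|``.

    Returns ``(sequences, genus_of_asv, true_divergence, subs_from_ancestor)``
    where the divergence matrix holds exact substitution counts per pair
    (no indels are simulated, so this is also the Hamming distance).
    """
    L = config.seq_length
    if L < 100:
        raise ValueError("seq_length must be >= 100")
    lo, hi = config.within_divergence_range
    if hi >= L:
        raise ValueError("within-genus divergence must be below seq_length")

    asv_counts = config.asv_counts()
    if min(asv_counts) < 1:
        raise ValueError("asvs_per_genus must be >= 1")

    ancestors: list[np.ndarray] = []
    for _ in range(config.n_genera):
        while True:
            cand = _random_sequence(L, rng)
            if all((cand != a).sum() > 0.10 * L for a in ancestors):
                ancestors.append(cand)
                break

    sequences: dict[str, str] = {}
    genus_of: dict[str, str] = {}
    subs_from_anc: dict[str, int] = {}
    seq_rows: list[np.ndarray] = []
    asv_idx = 0
    for g, (anc, n_asv) in enumerate(zip(ancestors, asv_counts)):
        genus = f"Genus{g + 1:02d}"
        coupled = g < config.coupled_genera
        if coupled:
            if n_asv > hi + 1:
                raise ValueError(
                    f"coupled genus needs asvs_per_genus <= {hi + 1} distinct "
                    "ladder depths"
                )
            ladder_pos = rng.permutation(L)[:hi]
            ladder_base = anc.copy()
            # pre-draw the substituted base at every ladder position
            ladder_seq = anc.copy()
            for p in ladder_pos:
                _substitute(ladder_seq, int(p), rng)
            ks = np.sort(rng.choice(np.arange(0, hi + 1), size=n_asv, replace=False))
        for j in range(n_asv):
            asv_idx += 1
            asv = f"ASV{asv_idx:05d}"
            if coupled:
                k = int(ks[j])
                seq = ladder_base.copy()
                for p in ladder_pos[:k]:
                    seq[p] = ladder_seq[p]
            else:
                k = int(rng.integers(lo, hi + 1))
                seq = anc.copy()
                for p in rng.permutation(L)[:k]:
                    _substitute(seq, int(p), rng)
            sequences[asv] = seq.tobytes().decode("ascii")
            genus_of[asv] = genus
            subs_from_anc[asv] = k
            seq_rows.append(seq)

    ids = list(sequences)
    mat = np.stack(seq_rows)
    div = _hamming_matrix(mat)
    divergence = pd.DataFrame(div, index=ids, columns=ids)
    return (
        sequences,
        pd.Series(genus_of, name="genus"),
        divergence,
        pd.Series(subs_from_anc, name="subs_from_ancestor"),
    )


def _hamming_matrix(mat: np.ndarray, chunk: int = 200) -> np.ndarray:
    n = mat.shape[0]
    out = np.zeros((n, n), dtype=np.int64)
    for i0 in range(0, n, chunk):
        block = mat[i0:i0 + chunk]
        out[i0:i0 + chunk] = (block[:, None, :] != mat[None, :, :]).sum(axis=2)
    return out


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def simulate_environment(
    dates: pd.DatetimeIndex,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Seasonally structured environmental covariates at the given dates.

    The deterministic component of each parameter is a sinusoid in the
    calendar-month index (period 12 months), anchored so that with zero
    noise temperature is exactly 12.6 C in February and 24.5 C in August,
    nutrients peak in winter (anti-phase with temperature) and chlorophyll
    reaches ~1 mg m-3 at the winter-spring transition.  Observation noise
    per parameter comes from ``config.env_noise_sd`` (falling back to
    realistic defaults); PNF/HNF are exponentiated so they stay positive.
    """
    if len(dates) == 0:
        raise ValueError("empty date list")
    d = np.asarray(dates.to_numpy())
    if len(d) > 1 and not (np.diff(d) > np.timedelta64(0, "s")).all():
        raise ValueError("dates must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    month = dates.month.to_numpy() - 1  # 0..11, Jan = 0
    noise_sd = {**DEFAULT_ENV_NOISE, **config.env_noise_sd}
    cols = {}
    for param in ENV_PARAMETERS:
        mean, amp, peak = _ENV_CYCLE[param]
        series = mean + amp * np.cos(2 * np.pi * (month - peak) / 12.0)
        series = series + rng.normal(0.0, noise_sd[param], size=len(dates))
        if param in _LOG_SCALE_PARAMS:
            series = np.exp(series)
        elif param != "temperature":
            # concentrations cannot go negative
            series = np.maximum(series, 0.0)
        cols[param] = series
    sample_ids = [f"S{ts:%Y%m%d}" for ts in dates]
    return pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample"))


# ---------------------------------------------------------------------------
# ground truth + counts
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator planted, per ASV and per pair.

    ``table`` has one row per ASV: genus, baseline log-abundance,
    seasonal amplitude (0 for non-seasonal), phase in days, CRT flag,
    substitutions from the genus ancestor and one ``beta_<param>`` column
    per environmental parameter.  ``divergence`` holds exact pairwise
    substitution counts.
    """

    table: pd.DataFrame
    divergence: pd.DataFrame

    @property
    def seasonal_asvs(self) -> pd.Index:
        return self.table.index[self.table["seasonal"]]

    @property
    def crt_asvs(self) -> pd.Index:
        return self.table.index[self.table["crt"]]


def build_truth(
    config: SimConfig,
    genus_of: pd.Series,
    subs_from_anc: pd.Series,
    divergence: pd.DataFrame,
    rng: np.random.Generator,
) -> GroundTruth:
    """Assign baselines, seasonal amplitudes/phases, CRT status, env betas."""
    asvs = genus_of.index
    n = len(asvs)
    genera = genus_of.to_numpy()
    coupled_names = {f"Genus{g + 1:02d}" for g in range(config.coupled_genera)}
    is_coupled = np.array([g in coupled_names for g in genera])

    baseline = rng.normal(0.0, config.baseline_sd, size=n)

    # seasonal assignment: coupled genera are seasonal by construction; the
    # remaining ASVs are drawn so the expected overall fraction matches
    seasonal = is_coupled.copy()
    n_coupled = int(is_coupled.sum())
    rest = n - n_coupled
    if rest > 0:
        target = config.frac_seasonal * n - n_coupled
        p_rest = min(max(target / rest, 0.0), 1.0)
        seasonal[~is_coupled] = rng.random(rest) < p_rest

    lo_a, hi_a = config.amplitude_range
    amplitude = np.where(seasonal, rng.uniform(lo_a, hi_a, size=n), 0.0)

    phase = rng.uniform(0.0, YEAR_DAYS, size=n)
    for gname in sorted(coupled_names):
        sel = genera == gname
        base_phase = rng.uniform(0.0, YEAR_DAYS)
        ks = subs_from_anc.to_numpy()[sel]
        phase[sel] = np.mod(base_phase + config.phase_rate_per_sub * ks, YEAR_DAYS)

    # CRT taxa: rare baseline, no seasonal cycle, occasional spikes
    crt = np.zeros(n, dtype=bool)
    eligible = np.flatnonzero(~seasonal)
    n_crt = min(config.n_crt, len(eligible))
    if n_crt > 0:
        picks = rng.choice(eligible, size=n_crt, replace=False)
        crt[picks] = True
        baseline[picks] = config.crt_baseline
        amplitude[picks] = 0.0

    betas = np.zeros((n, len(ENV_PARAMETERS)))
    if config.frac_env_responsive > 0:
        resp = rng.random(n) < config.frac_env_responsive
        resp &= ~crt
        for i in np.flatnonzero(resp):
            p = rng.integers(0, len(ENV_PARAMETERS))
            mag = rng.uniform(*config.env_beta_range)
            betas[i, p] = mag * (1 if rng.random() < 0.5 else -1)

    table = pd.DataFrame(
        {
            "genus": genera,
            "baseline": baseline,
            "amplitude": amplitude,
            "phase_day": phase,
            "seasonal": seasonal,
            "crt": crt,
            "subs_from_ancestor": subs_from_anc.loc[asvs].to_numpy(),
        },
        index=asvs,
    )
    for j, param in enumerate(ENV_PARAMETERS):
        table[f"beta_{param}"] = betas[:, j]
    return GroundTruth(table=table, divergence=divergence)


def latent_log_abundance(
    truth: GroundTruth,
    env: pd.DataFrame,
    dates: pd.DatetimeIndex,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent log-abundance matrix (taxa x samples) including noise and spikes.

    lambda_it = a_i + s_i cos(2 pi (doy_t - phi_i) / 365.25)
                + sum_p beta_ip z(env_pt) + eps_it,  eps ~ N(0, sigma^2),
    plus additive log-scale spikes for CRT taxa in Bernoulli-selected samples.
    """
    t = truth.table
    doy = dates.dayofyear.to_numpy().astype(float)
    a = t["baseline"].to_numpy()[:, None]
    s = t["amplitude"].to_numpy()[:, None]
    phi = t["phase_day"].to_numpy()[:, None]
    lam = a + s * np.cos(2 * np.pi * (doy[None, :] - phi) / YEAR_DAYS)

    z = (env - env.mean()) / env.std(ddof=1)
    betas = t[[f"beta_{p}" for p in ENV_PARAMETERS]].to_numpy()
    lam = lam + betas @ z[list(ENV_PARAMETERS)].to_numpy().T

    if config.latent_noise_sd > 0:
        lam = lam + rng.normal(0.0, config.latent_noise_sd, size=lam.shape)

    crt_rows = np.flatnonzero(t["crt"].to_numpy())
    if len(crt_rows):
        spikes = rng.random((len(crt_rows), lam.shape[1])) < config.crt_spike_prob
        # blooms reach a characteristic level (resting + magnitude) with
        # their own modest variability: conditionally rare dynamics are a
        # distinct bloom state, not a scaled-up resting state
        bloom = (
            t["baseline"].to_numpy()[crt_rows, None]
            + config.crt_spike_magnitude
            + rng.normal(0.0, config.crt_bloom_sd, size=spikes.shape)
        )
        lam[crt_rows] = np.where(spikes, bloom, lam[crt_rows])
    return lam


def simulate_counts(
    truth: GroundTruth,
    env: pd.DataFrame,
    dates: pd.DatetimeIndex,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Multinomial read sampling of the latent composition (closure to depth)."""
    if config.reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be positive")
    if len(env) != len(dates):
        raise ValueError("environment and dates are not aligned")
    lam = latent_log_abundance(truth, env, dates, config, rng)
    lam = lam - lam.max(axis=0, keepdims=True)
    w = np.exp(lam)
    probs = w / w.sum(axis=0, keepdims=True)

    n_samples = lam.shape[1]
    if config.depth_distribution == "lognormal":
        depths = np.round(
            config.reads_per_sample
            * np.exp(rng.normal(0, config.depth_lognorm_sigma, n_samples))
        ).astype(int)
        depths = np.maximum(depths, 1)
    else:
        depths = np.full(n_samples, config.reads_per_sample, dtype=int)

    counts = np.empty(lam.shape, dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(depths[j], probs[:, j])
    return pd.DataFrame(counts, index=truth.table.index, columns=env.index)


# ---------------------------------------------------------------------------
# taxonomy + full bundle
# ---------------------------------------------------------------------------

def build_taxonomy(genus_of: pd.Series) -> pd.DataFrame:
    """Deterministic 4-rank taxonomy: 2 genera/family, 2 families/order,
    2 orders/class."""
    genera = sorted(genus_of.unique())
    rank_of = {}
    for i, g in enumerate(genera):
        fam = f"Family{i // 2 + 1:02d}"
        order = f"Order{i // 4 + 1:02d}"
        cls = f"Class{i // 8 + 1:02d}"
        rank_of[g] = (cls, order, fam)
    rows = {
        asv: (*rank_of[g], g) for asv, g in genus_of.items()
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["class", "order", "family", "genus"]
    ).rename_axis("asv")


def simulate_dataset(config: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a complete, validated Dataset plus its ground truth.

    All randomness flows from ``config.seed``; two calls with the same
    config produce byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    dates = simulate_dates(config, rng)
    sequences, genus_of, divergence, subs = simulate_sequences(config, rng)
    env = simulate_environment(dates, config, rng)
    truth = build_truth(config, genus_of, subs, divergence, rng)
    counts = simulate_counts(truth, env, dates, config, rng)
    taxonomy = build_taxonomy(genus_of)
    dataset = Dataset(
        counts=counts,
        dates=dates,
        env=env,
        taxonomy=taxonomy,
        sequences=sequences,
    )
    return dataset, truth


def write_truth(truth: GroundTruth, outdir) -> None:
    """Write the ground-truth table and divergence matrix as TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.table.rename_axis("asv").to_csv(outdir / "truth.tsv", sep="\t")
    truth.divergence.rename_axis("asv").to_csv(
        outdir / "true_divergence.tsv", sep="\t"
    )


# ---------------------------------------------------------------------------
# reference constructions for coherence / cancellation studies
# ---------------------------------------------------------------------------

def coherent_genus_dataset(
    seed: int = 0, n_background_genera: int = 3, asvs_per_genus: int = 10
) -> tuple[Dataset, GroundTruth]:
    """A community whose first genus is perfectly coherent: every member
    seasonal with the same phase (a phase-coupled genus with zero phase
    shift per substitution)."""
    cfg = SimConfig(
        n_genera=1 + n_background_genera,
        asvs_per_genus=asvs_per_genus,
        coupled_genera=1,
        phase_rate_per_sub=0.0,
        frac_seasonal=0.25,
        n_crt=0,
        seed=seed,
    )
    return simulate_dataset(cfg)


def antiphase_class_dataset(
    seed: int = 0, asvs_per_genus: int = 10, amplitude: float = 0.15
) -> tuple[Dataset, GroundTruth]:
    """A class of two equal-abundance genera in exact seasonal antiphase.

    The amplitude defaults to 0.15 log units: small enough that the
    exponential latent model is effectively linear, so the two groups'
    annual signals genuinely cancel in the aggregated counts and the
    residual imbalance of member resampling stays below the taxon-level
    noise.  Each genus on its own remains clearly seasonal (coherent
    members average their noise away).
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_genera=2, asvs_per_genus=asvs_per_genus,
        frac_seasonal=1.0, n_crt=0, seed=seed,
    )
    dates = simulate_dates(cfg, rng)
    sequences, genus_of, divergence, subs = simulate_sequences(cfg, rng)
    env = simulate_environment(dates, cfg, rng)
    truth = build_truth(cfg, genus_of, subs, divergence, rng)
    t = truth.table
    t.loc[t["genus"] == "Genus01", "phase_day"] = 100.0
    t.loc[t["genus"] == "Genus02", "phase_day"] = 100.0 + YEAR_DAYS / 2.0
    t["baseline"] = 0.0
    t["amplitude"] = amplitude
    counts = simulate_counts(truth, env, dates, cfg, rng)
    dataset = Dataset(
        counts=counts, dates=dates, env=env,
        taxonomy=build_taxonomy(genus_of), sequences=sequences,
    )
    return dataset, truth
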