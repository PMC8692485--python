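"""End-to-end orchestration of all analysis stages from one RunConfig.

Stage order: simulate (optional) -> classify -> seasonality -> profiles ->
divergence -> niche -> envfit -> rank-seasonality.  Every stage consumes
only upstream outputs, draws its randomness from a stage-scoped generator
derived from the global seed, writes its result table(s) under the output
directory, and reports row counts and wall time into a run manifest that is
emitted whether the run succeeds or aborts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from nichecycle import __version__
from nichecycle._utils import derive_seed
from nichecycle.abundance import classify_asvs
from nichecycle.config import RunConfig, SimConfig
from nichecycle.divergence import (
    closely_related_pairs,
    cluster_otus,
    pairwise_divergence,
)
from nichecycle.envmodel import env_screen, vif
from nichecycle.io import Dataset, write_dataset, write_table
from nichecycle.niche import niche_regression, permutation_fdr, rho_screen
from nichecycle.profiles import (
    clr_transform,
    cyclic_smooth,
    gap_statistic,
    hierarchical_cluster,
    monthly_profile,
)
from nichecycle.seasonality import (
    rank_aggregation_test,
    rank_eligibility,
    seasonality_screen,
)
from nichecycle.simulate import simulate_dataset, write_truth

log = logging.getLogger("nichecycle")

STAGES = (
    "simulate",
    "classify",
    "seasonality",
    "profiles",
    "divergence",
    "niche",
    "envfit",
    "rank-seasonality",
)


def run_all(config: RunConfig, outdir: str | Path,
            dataset: Dataset | None = None) -> dict:
    """Run every stage; returns the manifest (also written as JSON).

    Either ``config.simulate`` provides a synthetic dataset or ``dataset``
    must be passed.  Reruns with the same config and seed are
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_snapshot(config),
        "stages": [],
    }
    try:
        _run_stages(config, outdir, dataset, manifest)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed at stage {manifest['stages'][-1]['name'] if manifest['stages'] else '?'}: {exc}"
        raise
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _stage(manifest: dict, name: str, seed: int | None = None):
    entry = {"name": name, "seed": seed, "t0": time.time()}
    manifest["stages"].append(entry)
    log.info("stage %s (seed=%s)", name, seed)
    return entry


def _finish(entry: dict, **rowcounts) -> None:
    entry["wall_s"] = round(time.time() - entry.pop("t0"), 3)
    entry["rows"] = {k: int(v) for k, v in rowcounts.items()}


def _config_snapshot(config: RunConfig) -> dict:
    from dataclasses import asdict

    snap = asdict(config)
    return json.loads(json.dumps(snap, default=str))


def _run_stages(config: RunConfig, outdir: Path,
                dataset: Dataset | None, manifest: dict) -> None:
    seed = config.seed

    # -- simulate -------------------------------------------------------
    entry = _stage(manifest, "simulate",
                   derive_seed(seed, "stage", "simulate"))
    if dataset is None:
        if config.simulate is None:
            raise ValueError("no dataset given and no simulate block in config")
        sim_cfg = SimConfig(**{**config.simulate.__dict__,
                               "seed": derive_seed(seed, "stage", "simulate")})
        dataset, truth = simulate_dataset(sim_cfg)
        write_dataset(dataset, outdir / "data")
        write_truth(truth, outdir / "data")
        _finish(entry, asvs=dataset.n_asvs, samples=dataset.n_samples)
    else:
        _finish(entry, asvs=dataset.n_asvs, samples=dataset.n_samples)

    # -- classify -------------------------------------------------------
    entry = _stage(manifest, "classify")
    records = classify_asvs(
        dataset,
        broad=config.broad_occurrence,
        narrow=config.narrow_occurrence,
        abundant_cutoff=config.abundant_cutoff,
        bimodality_threshold=config.bimodality_threshold,
    )
    write_table(records, outdir / "abundance_classes.tsv")
    _finish(entry, records=len(records))

    # -- seasonality ----------------------------------------------------
    entry = _stage(manifest, "seasonality",
                   derive_seed(seed, "stage", "seasonality"))
    calls = seasonality_screen(
        dataset,
        transform=config.transform,
        pn_threshold=config.pn_threshold,
        q_threshold=config.q_threshold,
        n_rand=config.n_rand,
        seed=derive_seed(seed, "stage", "seasonality"),
        min_prevalence=config.min_prevalence,
        annual_window=config.annual_window,
        oversampling=config.oversampling,
        max_frequency_factor=config.max_frequency_factor,
    )
    write_table(calls, outdir / "seasonality_calls.tsv")
    _finish(entry, tested=len(calls), seasonal=int(calls["seasonal"].sum()))

    seasonal_asvs = calls.loc[calls["seasonal"], "asv"].tolist()

    # -- profiles -------------------------------------------------------
    entry = _stage(manifest, "profiles", derive_seed(seed, "stage", "profiles"))
    n_clusters = 0
    if len(seasonal_asvs) >= 3:
        clr = clr_transform(dataset.counts.to_numpy(), config.pseudocount)
        idx = [dataset.counts.index.get_loc(a) for a in seasonal_asvs]
        profiles = monthly_profile(clr[idx], dataset.dates)
        k_max = min(config.gap_k_max, len(seasonal_asvs) - 1)
        gap = gap_statistic(profiles, k_max=k_max, n_ref=config.gap_n_ref,
                            seed=derive_seed(seed, "stage", "profiles"))
        labels = hierarchical_cluster(profiles, gap.k)
        n_clusters = gap.k
        write_table(
            pd.DataFrame({"asv": seasonal_asvs, "cluster": labels}),
            outdir / "seasonal_clusters.tsv",
        )
        doy = dataset.dates.dayofyear.to_numpy().astype(float)
        grid = np.arange(0.0, 366.0, 5.0)
        curves = []
        for a, i in zip(seasonal_asvs, idx):
            if len(doy) >= 2 * config.n_knots:
                fit = cyclic_smooth(doy, clr[i], n_knots=config.n_knots)
                curves.append(pd.DataFrame(
                    {"asv": a, "day": grid, "fitted_clr": fit.predict(grid)}
                ))
        if curves:
            write_table(pd.concat(curves, ignore_index=True),
                        outdir / "smooth_curves.tsv")
    else:
        log.warning("fewer than 3 seasonal ASVs; skipping profile clustering")
        write_table(pd.DataFrame(columns=["asv", "cluster"]),
                    outdir / "seasonal_clusters.tsv")
    _finish(entry, seasonal_asvs=len(seasonal_asvs), clusters=n_clusters)

    # -- divergence -----------------------------------------------------
    entry = _stage(manifest, "divergence")
    div = pairwise_divergence(dataset.sequences)
    write_table(div.to_long(), outdir / "divergence.tsv")
    otus = cluster_otus(div, identity=config.otu_identity)
    write_table(otus.reset_index(), outdir / "otus.tsv")
    close_pairs, per_genus = closely_related_pairs(
        div, dataset.taxonomy, max_nt=config.close_nt
    )
    write_table(close_pairs, outdir / "close_pairs.tsv")
    _finish(entry, pairs=len(div.to_long()), otus=otus.nunique(),
            close_pairs=len(close_pairs))

    # -- niche ----------------------------------------------------------
    entry = _stage(manifest, "niche", derive_seed(seed, "stage", "niche"))
    pairs = rho_screen(dataset.counts, config.pseudocount,
                       taxonomy=dataset.taxonomy)
    curve, pairs = permutation_fdr(
        dataset.counts,
        n_perm=config.rho_n_perm,
        seed=derive_seed(seed, "stage", "niche"),
        target_fdr=config.rho_fdr,
        pseudocount=config.pseudocount,
        pairs=pairs,
    )
    write_table(pairs, outdir / "rho_pairs.tsv")
    regression = niche_regression(
        pairs, div.mismatches,
        min_close_asvs=config.min_close_asvs, max_nt=config.close_nt,
    )
    write_table(regression, outdir / "niche_regression.tsv")
    _finish(entry, rho_pairs=len(pairs), genera_tested=len(regression))

    # -- envfit ---------------------------------------------------------
    entry = _stage(manifest, "envfit")
    env_params = [p for p in config.env_parameters if p in dataset.env.columns]
    vif_report = vif(dataset.env[env_params])
    write_table(vif_report.rename_axis("parameter").reset_index(),
                outdir / "vif.tsv")
    focal_genera = set(regression["genus"]) if len(regression) else set()
    focal_asvs = [
        a for a in seasonal_asvs
        if not focal_genera
        or dataset.taxonomy.loc[a, "genus"] in focal_genera
    ]
    n_models = 0
    if focal_asvs:
        fits = env_screen(dataset.counts, dataset.env, focal_asvs,
                          env_params, q_threshold=config.env_fdr)
        write_table(fits, outdir / "env_models.tsv")
        n_models = len(fits)
    else:
        log.warning("no focal ASVs for environmental models")
        write_table(pd.DataFrame(columns=["asv", "parameter", "p", "q"]),
                    outdir / "env_models.tsv")
    _finish(entry, models=n_models)

    # -- rank-seasonality ----------------------------------------------
    entry = _stage(manifest, "rank-seasonality",
                   derive_seed(seed, "stage", "rank"))
    eligible = rank_eligibility(dataset.taxonomy, min_asvs=config.rank_min_asvs)
    rows = []
    long_rows = []
    for cls in eligible:
        members = dataset.taxonomy[dataset.taxonomy["class"] == cls]
        groups = [("class", cls)]
        for rank in ("order", "family", "genus"):
            sizes = members.groupby(rank).size()
            groups += [(rank, g) for g in
                       sizes.index[sizes >= config.rank_min_asvs]]
        for rank, group in groups:
            res = rank_aggregation_test(
                dataset, rank, group,
                frac=config.rank_frac,
                n_iter=config.rank_n_iter,
                seed=derive_seed(seed, "stage", "rank"),
                pn_threshold=config.pn_threshold,
                p_threshold=config.rank_p_threshold,
                n_rand=config.n_rand,
                transform=config.transform,
                oversampling=config.oversampling,
                max_frequency_factor=config.max_frequency_factor,
            )
            rows.append({
                "class": cls, "rank": rank, "group": group,
                "n_iter": len(res.pns),
                "pn_median": float(np.median(res.pns)),
                "fraction_seasonal": res.fraction_seasonal,
            })
            long_rows.append(pd.DataFrame({
                "class": cls, "rank": rank, "group": group,
                "iteration": np.arange(len(res.pns)),
                "pn": res.pns, "p_rand": res.pvalues,
            }))
    write_table(pd.DataFrame(
        rows, columns=["class", "rank", "group", "n_iter", "pn_median",
                       "fraction_seasonal"]), outdir / "rank_seasonality.tsv")
    if long_rows:
        write_table(pd.concat(long_rows, ignore_index=True),
                    outdir / "rank_seasonality_iterations.tsv")
    _finish(entry, eligible_classes=len(eligible), groups=len(rows))
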