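import numpy as np
import pandas as pd
import pytest

from nichecycle.config import SimConfig
from nichecycle.simulate import (
    YEAR_DAYS,
    build_truth,
    latent_log_abundance,
    simulate_counts,
    simulate_dataset,
    simulate_dates,
    simulate_environment,
    simulate_sequences,
)

ZERO_NOISE = {p: 0.0 for p in
              ("temperature", "chlorophyll", "no3", "no2", "nh4", "po4",
               "sio2", "pnf", "hnf")}


def test_deterministic_given_seed():
    cfg = SimConfig(n_genera=3, asvs_per_genus=3, reads_per_sample=5000, seed=9)
    ds1, tr1 = simulate_dataset(cfg)
    ds2, tr2 = simulate_dataset(cfg)
    pd.testing.assert_frame_equal(ds1.counts, ds2.counts)
    pd.testing.assert_frame_equal(ds1.env, ds2.env)
    pd.testing.assert_frame_equal(tr1.table, tr2.table)
    assert ds1.sequences == ds2.sequences


def test_column_sums_equal_depth(small_sim):
    cfg, ds, _ = small_sim
    assert (ds.counts.sum(axis=0) == cfg.reads_per_sample).all()


def test_single_asv_genus_divergence_is_zero():
    cfg = SimConfig(n_genera=2, asvs_per_genus=1, seed=0)
    rng = np.random.default_rng(0)
    _, genus_of, div, _ = simulate_sequences(cfg, rng)
    for g, members in genus_of.groupby(genus_of):
        sub = div.loc[members.index, members.index]
        assert sub.shape == (1, 1) and sub.iloc[0, 0] == 0


def test_disjoint_substitution_sets_add():
    """Two ASVs derived from one ancestor by disjoint substitution sets of
    sizes 2 and 3 differ at exactly 5 positions (set-union oracle)."""
    rng = np.random.default_rng(1)
    anc = np.frombuffer(b"ACGT" * 105, dtype=np.uint8).copy()
    pos = rng.permutation(len(anc))[:5]
    a, b = anc.copy(), anc.copy()
    for p in pos[:2]:
        a[p] = {65: 67, 67: 71, 71: 84, 84: 65}[a[p]]
    for p in pos[2:]:
        b[p] = {65: 67, 67: 71, 71: 84, 84: 65}[b[p]]
    assert int((a != b).sum()) == 5


def test_five_nt_pairs_give_988_identity():
    """5 substitutions over 420 nt = 98.8% identity."""
    cfg = SimConfig(n_genera=1, asvs_per_genus=2, seq_length=420,
                    coupled_genera=1, within_divergence_range=(5, 5), seed=3)
    rng = np.random.default_rng(3)
    seqs, _, div, _ = simulate_sequences(cfg, rng)
    ids = list(seqs)
    # ladder depths drawn from {0..5}: force the 5-apart pair by checking
    d = div.loc[ids[0], ids[1]]
    identity = 100.0 * (1 - d / 420)
    assert d <= 5
    if d == 5:
        assert round(identity, 1) == 98.8
    assert round(100.0 * (1 - 5 / 420), 1) == 98.8


def test_excessive_divergence_rejected():
    with pytest.raises(ValueError):
        SimConfig(seq_length=120, within_divergence_range=(1, 150))


def test_true_divergence_matches_emitted_sequences(small_sim):
    """Recomputing Hamming distances from the FASTA reproduces the truth."""
    _, ds, truth = small_sim
    ids = list(ds.sequences)
    mat = np.stack([np.frombuffer(ds.sequences[a].encode(), dtype=np.uint8)
                    for a in ids])
    recomputed = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    assert (recomputed == truth.divergence.loc[ids, ids].to_numpy()).all()


def test_coupled_phase_monotone_in_divergence():
    cfg = SimConfig(n_genera=2, asvs_per_genus=8, coupled_genera=1,
                    phase_rate_per_sub=8.0, seed=5)
    _, truth = simulate_dataset(cfg)
    t = truth.table[truth.table["genus"] == "Genus01"]
    assert t["seasonal"].all() and (t["amplitude"] > 0).all()
    ks = t["subs_from_ancestor"].to_numpy()
    phases = t["phase_day"].to_numpy()
    div = truth.divergence.loc[t.index, t.index].to_numpy()
    for i in range(len(t)):
        for j in range(len(t)):
            assert div[i, j] == abs(ks[i] - ks[j])
    # phase offset exactly linear in pairwise substitution count
    order = np.argsort(ks)
    dphi = np.diff(phases[order]) % YEAR_DAYS
    dk = np.diff(ks[order])
    assert np.allclose(dphi, 8.0 * dk)


def test_environment_anchors_without_noise():
    cfg = SimConfig(env_noise_sd=ZERO_NOISE, seed=0, n_years=2,
                    missing_month_prob=0.0)
    rng = np.random.default_rng(0)
    dates = simulate_dates(cfg, rng)
    env = simulate_environment(dates, cfg, rng)
    temp = pd.Series(env["temperature"].to_numpy(), index=dates)
    assert np.allclose(temp[dates.month == 8], 24.5)
    assert np.allclose(temp[dates.month == 2], 12.6)
    assert temp.idxmin().month == 2
    januaries = temp[dates.month == 1]
    assert np.allclose(januaries.to_numpy(), januaries.iloc[0])
    # nutrients anti-phase with temperature, chlorophyll ~1 in early spring
    assert env["no3"][dates.month == 2].mean() > env["no3"][dates.month == 8].mean()
    assert abs(env["chlorophyll"].max() - 1.0) < 0.05
    assert (env["pnf"] > 0).all() and (env["hnf"] > 0).all()


def test_environment_empty_dates_error():
    cfg = SimConfig(seed=0)
    with pytest.raises(ValueError):
        simulate_environment(pd.DatetimeIndex([]), cfg)


def test_single_taxon_closure():
    cfg = SimConfig(n_genera=1, asvs_per_genus=1, reads_per_sample=777,
                    n_crt=0, seed=1)
    ds, _ = simulate_dataset(cfg)
    assert (ds.counts.to_numpy() == 777).all()


def test_equal_latent_gives_half_shares():
    """Two taxa with equal constant latent abundance converge to 50:50
    (softmax-limit oracle)."""
    cfg = SimConfig(n_genera=2, asvs_per_genus=1, reads_per_sample=200_000,
                    frac_seasonal=0.0, latent_noise_sd=0.0, n_crt=0, seed=2)
    rng = np.random.default_rng(2)
    dates = simulate_dates(cfg, rng)
    seqs, genus_of, div, subs = simulate_sequences(cfg, rng)
    env = simulate_environment(dates, cfg, rng)
    truth = build_truth(cfg, genus_of, subs, div, rng)
    truth.table["baseline"] = 1.234
    counts = simulate_counts(truth, env, dates, cfg, rng)
    rel = counts.to_numpy() / counts.sum(axis=0).to_numpy()
    assert np.allclose(rel.mean(axis=1), 0.5, atol=0.005)


def test_stationary_config_has_constant_composition():
    cfg = SimConfig(n_genera=3, asvs_per_genus=2, frac_seasonal=0.0,
                    latent_noise_sd=0.0, n_crt=0, frac_env_responsive=0.0,
                    seed=4)
    rng = np.random.default_rng(4)
    dates = simulate_dates(cfg, rng)
    _, genus_of, div, subs = simulate_sequences(cfg, rng)
    env = simulate_environment(dates, cfg, rng)
    truth = build_truth(cfg, genus_of, subs, div, rng)
    lam = latent_log_abundance(truth, env, dates, cfg, rng)
    assert np.allclose(lam, lam[:, [0]])


def test_mean_share_converges_to_softmax():
    """Monte-Carlo mean relative abundance approaches softmax of the latent
    mean as replicates accumulate."""
    cfg = SimConfig(n_genera=2, asvs_per_genus=2, reads_per_sample=10_000,
                    frac_seasonal=0.0, latent_noise_sd=0.0, n_crt=0, seed=6)
    ds, truth = simulate_dataset(cfg)
    lam = truth.table["baseline"].to_numpy()
    expected = np.exp(lam) / np.exp(lam).sum()
    rel = ds.counts.to_numpy() / ds.counts.sum(axis=0).to_numpy()
    n = ds.n_samples * cfg.reads_per_sample
    assert np.allclose(rel.mean(axis=1), expected, atol=5.0 / np.sqrt(n))


def test_reads_must_be_positive():
    with pytest.raises(ValueError):
        SimConfig(reads_per_sample=0)
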