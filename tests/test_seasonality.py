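import numpy as np
import pandas as pd
import pytest

from nichecycle.io import Dataset
from nichecycle.seasonality import (
    TimeSeries,
    ZeroVarianceError,
    benjamini_hochberg,
    frequency_grid,
    lomb_scargle,
    lomb_scargle_power,
    randomization_pvalue,
    rank_aggregation_test,
    rank_eligibility,
    seasonality_screen,
)

def lsp_direct(t, x, freqs):
    """Independent brute-force evaluation of the classical normalized LSP,
    one frequency at a time, straight from the defining formula."""
    t = np.asarray(t, float)
    x = np.asarray(x, float) - np.mean(x)
    var = np.var(x, ddof=1)
    out = []
    for f in freqs:
        w = 2 * np.pi * f
        tau = np.arctan2(np.sum(np.sin(2 * w * t)),
                         np.sum(np.cos(2 * w * t))) / (2 * w)
        c = np.cos(w * (t - tau))
        s = np.sin(w * (t - tau))
        out.append(((x @ c) ** 2 / (c @ c) + (x @ s) ** 2 / (s @ s))
                   / (2 * var))
    return np.array(out)


def bh_stepup(p):
    """Brute-force Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


# ---------------------------------------------------------------------------
# core LSP
# ---------------------------------------------------------------------------

def test_timeseries_validation():
    with pytest.raises(ValueError):
        TimeSeries(np.arange(5.0), np.ones(5))  # too short
    with pytest.raises(ValueError):
        TimeSeries(np.array([3.0, 2, 1, 4, 5, 6, 7, 8]), np.zeros(8))


def test_zero_variance_is_a_distinct_error(uneven_times):
    with pytest.raises(ZeroVarianceError):
        lomb_scargle(TimeSeries(uneven_times, np.full(131, 3.0)))


def test_pure_annual_sinusoid_peaks_at_365(uneven_times):
    x = np.cos(2 * np.pi * uneven_times / 365.0)
    res = lomb_scargle(TimeSeries(uneven_times, x))
    freqs = res.frequency
    step = freqs[1] - freqs[0]
    assert abs(1.0 / res.peak_period - 1.0 / 365.0) <= step
    assert res.pn == res.power.max()


def test_matches_brute_force_oracle(uneven_times):
    rng = np.random.default_rng(3)
    freqs = frequency_grid(uneven_times)
    for _ in range(5):
        x = rng.normal(size=131)
        fast = lomb_scargle_power(uneven_times, x, freqs)
        assert np.max(np.abs(fast - lsp_direct(uneven_times, x, freqs))) < 1e-10


def test_even_sampling_equals_classical_periodogram():
    rng = np.random.default_rng(4)
    n = 64
    t = np.arange(n, dtype=float)
    x = rng.normal(size=n)
    ks = np.arange(1, n // 2)
    freqs = ks / n
    lsp = lomb_scargle_power(t, x, freqs)
    xc = x - x.mean()
    dft = np.abs(np.exp(-2j * np.pi * freqs[:, None] * t[None, :]) @ xc) ** 2
    classical = dft / (n * xc.var(ddof=1))
    assert np.max(np.abs(lsp - classical)) < 1e-10


def test_power_invariant_to_shift_and_scale(uneven_times):
    rng = np.random.default_rng(5)
    x = rng.normal(size=131)
    freqs = frequency_grid(uneven_times)
    base = lomb_scargle_power(uneven_times, x, freqs)
    assert np.max(np.abs(
        lomb_scargle_power(uneven_times, 7.5 * x - 3.0, freqs) - base)) < 1e-10


def test_white_noise_mean_power_near_one(uneven_times):
    """Classical-normalization null: power at a fixed frequency is
    approximately Exp(1)."""
    rng = np.random.default_rng(6)
    freqs = frequency_grid(uneven_times)[20:25]
    powers = np.array([
        lomb_scargle_power(uneven_times, rng.normal(size=131), freqs)
        for _ in range(400)
    ])
    assert abs(powers.mean() - 1.0) < 0.1


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_add_one_rule_floor(uneven_times):
    x = np.cos(2 * np.pi * uneven_times / 365.0)
    p, res = randomization_pvalue(TimeSeries(uneven_times, x), n_rand=999,
                                  seed=0)
    assert p == 1.0 / 1000.0  # stronger than every permutation
    assert p >= 1.0 / (1 + 999)


def test_nrand_minimum_enforced(uneven_times):
    with pytest.raises(ValueError):
        randomization_pvalue(TimeSeries(uneven_times, np.random.default_rng(0)
                                        .normal(size=131)), n_rand=50)


def test_null_rejection_rate_quick(uneven_times):
    rng = np.random.default_rng(7)
    rejections = 0
    n_sim = 60
    for i in range(n_sim):
        p, _ = randomization_pvalue(
            TimeSeries(uneven_times, rng.normal(size=131)),
            n_rand=99, seed=1000 + i,
        )
        rejections += p <= 0.05
    assert rejections / n_sim < 0.15  # coarse guard; tight band in acceptance


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def test_bh_hand_example():
    assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                       [0.03, 0.03, 0.03])


def test_bh_trivial_cases():
    assert benjamini_hochberg([0.2]) == pytest.approx([0.2])
    assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)


def test_bh_rejects_bad_pvalues():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.5])


def test_bh_matches_brute_force_oracle():
    rng = np.random.default_rng(8)
    for _ in range(200):
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(benjamini_hochberg(p), bh_stepup(p), atol=1e-12)


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def screened(small_sim):
    _, ds, truth = small_sim
    calls = seasonality_screen(ds, n_rand=199, seed=17)
    return ds, truth, calls


def test_screen_flag_consistency(screened):
    _, _, calls = screened
    expect = (calls["pn"] >= 10.0) & (calls["q"] <= 0.05)
    assert (calls["seasonal"] == expect).all()
    assert calls["q"].between(0, 1).all()
    assert (calls["p_rand"] >= 1.0 / 200.0).all()


def test_screen_below_pn_threshold_never_seasonal(screened):
    _, _, calls = screened
    assert not calls.loc[calls["pn"] < 10.0, "seasonal"].any()


def test_screen_deterministic_and_order_independent(small_sim):
    _, ds, _ = small_sim
    calls1 = seasonality_screen(ds, n_rand=99, seed=5)
    shuffled = Dataset(
        counts=ds.counts.iloc[::-1].copy(), dates=ds.dates,
        env=ds.env.copy(), taxonomy=ds.taxonomy.iloc[::-1].copy(),
        sequences=ds.sequences,
    )
    calls2 = seasonality_screen(shuffled, n_rand=99, seed=5)
    merged = calls1.merge(calls2, on="asv", suffixes=("_a", "_b"))
    assert len(merged) == len(calls1)
    assert np.allclose(merged["pn_a"], merged["pn_b"])
    assert np.allclose(merged["p_rand_a"], merged["p_rand_b"])


def test_screen_recovers_planted_seasonality(screened):
    _, truth, calls = screened
    calls = calls.set_index("asv")
    seasonal_truth = truth.table["seasonal"]
    called = calls["seasonal"].reindex(truth.table.index).fillna(False)
    sens = (called & seasonal_truth).sum() / max(seasonal_truth.sum(), 1)
    assert sens >= 0.7  # small community; full-size bound in acceptance


# ---------------------------------------------------------------------------
# ranks
# ---------------------------------------------------------------------------

def test_rank_eligibility_rules():
    tax = pd.DataFrame({
        "class": ["A"] * 40 + ["B"] * 18,
        "order": ["Ao1"] * 20 + ["Ao2"] * 20 + ["Bo1"] * 9 + ["Bo2"] * 9,
        "family": ["Af1"] * 10 + ["Af2"] * 10 + ["Af3"] * 10 + ["Af4"] * 10
                  + ["Bf1"] * 9 + ["Bf2"] * 9,
        "genus": [f"Ag{i // 10 + 1}" for i in range(40)]
                 + ["Bg1"] * 9 + ["Bg2"] * 9,
    }, index=[f"ASV{i}" for i in range(58)])
    # class A: 2 orders / 4 families / 4 genera with >= 10 ASVs each
    # class B: all subgroups have only 9 ASVs
    assert rank_eligibility(tax, min_asvs=10) == ["A"]


def test_rank_aggregation_identical_members(small_sim):
    """A group of identical copies of one series has zero resampling
    variance: every iteration reproduces the single-series PN."""
    _, ds, _ = small_sim
    row = ds.counts.iloc[[0]].to_numpy()
    background = ds.counts.iloc[1:6].to_numpy()
    counts = pd.DataFrame(
        np.vstack([row] * 5 + [background]),
        index=[f"X{i}" for i in range(5)] + [f"B{i}" for i in range(5)],
        columns=ds.counts.columns,
    )
    tax = pd.DataFrame({"class": "C", "order": "O", "family": "F",
                        "genus": ["G"] * 5 + ["H"] * 5}, index=counts.index)
    seqs = {a: ds.sequences[ds.counts.index[0]] for a in counts.index}
    clone = Dataset(counts=counts, dates=ds.dates, env=ds.env.copy(),
                    taxonomy=tax, sequences=seqs)
    res = rank_aggregation_test(clone, "genus", "G", n_iter=20, n_rand=99,
                                seed=3)
    assert np.allclose(res.pns, res.pns[0])


def test_rank_full_sample_single_iteration_equals_plain_lsp(small_sim):
    _, ds, _ = small_sim
    genus = ds.taxonomy["genus"].iloc[0]
    members = ds.taxonomy.index[ds.taxonomy["genus"] == genus]
    res = rank_aggregation_test(ds, "genus", genus, frac=1.0, n_iter=1,
                                n_rand=99, seed=0)
    agg = ds.counts.loc[members].sum(axis=0).to_numpy()
    x = agg / ds.counts.sum(axis=0).to_numpy()
    direct = lomb_scargle(TimeSeries(ds.times_days, x))
    assert res.pns[0] == pytest.approx(direct.pn, rel=1e-12)


def test_rank_unknown_group_errors(small_sim):
    _, ds, _ = small_sim
    with pytest.raises(ValueError, match="absent"):
        rank_aggregation_test(ds, "genus", "Nonexistent", n_iter=5, n_rand=99)
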