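# nichecycle

Seasonal niche analysis of long-term, monthly-sampled amplicon (16S rRNA
ASV) time series — the kind of decade-scale coastal microbial observatory
dataset in which a fraction of the community returns every year in the
same season, close relatives may or may not share that timing, and the
question is which environmental conditions drive the differences.

The package is a reusable, tested implementation of the full analysis
chain for such data:

1. **Occurrence/abundance classes and conditionally rare taxa (CRT).**
   An ASV is *abundant* if it reaches ≥ 1% relative abundance in at least
   one sample, otherwise permanently rare; occurrence is *broad* (≥ 75% of
   samples), *narrow* (≤ 10%) or *intermediate*. CRT — usually rare taxa
   that occasionally bloom — are flagged when Sarle's sample-corrected
   bimodality coefficient

   b = (g₁² + 1) / (g₂ + 3(n−1)²/((n−2)(n−3)))

   of the relative-abundance series reaches 0.9 together with ≥ 1% maximum
   relative abundance.

2. **Seasonality by Lomb–Scargle periodogram (LSP).** For an unevenly
   sampled series x(tⱼ), the classical variance-normalized LSP is

   P(ω) = 1/(2σ²) { [Σⱼ(xⱼ−x̄)cos ω(tⱼ−τ)]² / Σⱼcos²ω(tⱼ−τ)
                  + [Σⱼ(xⱼ−x̄)sin ω(tⱼ−τ)]² / Σⱼsin²ω(tⱼ−τ) },
   tan(2ωτ) = Σⱼ sin 2ωtⱼ / Σⱼ cos 2ωtⱼ.

   The peak normalized power PN = max P is tested by shuffling values over
   the fixed times (add-one permutation p-value), p-values are BH-corrected,
   and an ASV is called seasonal when **PN ≥ 10 and q ≤ 0.05**. A separate
   flag records whether the peak period is annual (300–430 d).

3. **Seasonal profile clusters and cyclic smooths.** Seasonal ASVs are
   summarized by mean CLR abundance per calendar month; the number of
   clusters comes from the gap statistic, the clusters from Ward-linkage
   hierarchical clustering, and each ASV's annual trend from a penalized
   cyclic cubic spline (12 knots over the year, smoothing by GCV) of CLR
   over day of year.

4. **Nucleotide divergence, OTUs, and within-genus niche similarity.**
   Pairwise divergence is the mismatch count of a global alignment
   (match +1, mismatch −1, gap open −4, extend −1, terminal gaps free;
   internal gap columns count as mismatches). ASVs cluster into OTUs by
   UPGMA at 99% identity. Niche similarity between two ASVs is the Rho
   proportionality of their CLR series,

   ρ = 1 − var(clrₓ − clr_y) / (var clrₓ + var clr_y)  ∈ [−1, 1],

   filtered by a permutation-based FDR, and regressed on nucleotide
   divergence within each genus that has ≥ 10 closely related ASVs
   (≤ 5 nt apart): a significant negative slope means close relatives
   share more of their temporal niche.

5. **Environmental response models.** Each ASV's count Wᵢ out of the
   sample total Mᵢ is modelled as BetaBinomial(Mᵢ, μᵢ, φ) with
   logit μᵢ = β₀ + β₁zᵢ (+ β₂zᵢ²) on the standardized parameter and a
   logit-scale dispersion intercept; the quadratic form is kept when a
   nested LRT prefers it, significance is the LRT against the
   intercept-only model, and BH controls the FDR across all ASV ×
   parameter models. A VIF report justifies interpreting parameters one at
   a time.

6. **Seasonality at higher ranks.** For a class/order/family/genus, 80% of
   its ASVs are drawn, their counts summed, and the aggregate tested by
   LSP + permutation; over 300 iterations the *fraction seasonal* measures
   coherence — antiphase subgroups cancel in the aggregate even when every
   member is individually seasonal.

A fully ground-truthed **synthetic community generator** (monthly dates
with day jitter and missing months, genera with controlled substitution
ladders, annual latent cycles, characteristic-state bloomers, seasonally
anchored environmental covariates, multinomial read sampling) makes every
stage testable without the original field data.

## Worked example

```bash
nichecycle run-all --config configs/demo.yaml --out demo_run --seed 123
```

generates a 36-ASV, 132-sample community (one genus built with
phase–divergence coupling: its members' seasonal timing drifts 8 days per
substitution) and runs all eight stages. The run prints `8 stages ok` and
writes one TSV per stage; `niche_regression.tsv` contains

```
genus    n_pairs  n_close_asvs  slope      intercept  p_value      r_squared  significant
Genus01  15       6             -0.097845  0.974311   2.55349e-08  0.914621   True
Genus03  15       4             -0.014414  0.351336   0.134447     0.163879   False
```

Genus01 is the coupled genus: Rho falls by ≈ 0.10 per nucleotide of
divergence (R² = 0.91, p ≈ 3·10⁻⁸) — close relatives share their seasonal
niche, distant ones do not — while the uncoupled Genus03 shows no
relationship. `seasonality_calls.tsv` reports PN, peak period, permutation
p and q per ASV; `rank_seasonality.tsv` the resampled coherence of every
eligible group; `env_models.tsv` the beta-binomial fits (form, coefficient,
95% CI, q, sign).

Every subcommand (`simulate`, `classify`, `seasonality`, `profiles`,
`divergence`, `niche`, `envfit`, `rank-seasonality`) also runs standalone
on a directory holding `counts.tsv`, `metadata.csv`, `taxonomy.tsv`,
`sequences.fasta`.

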