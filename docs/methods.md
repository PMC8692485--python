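# Methods

This note documents the statistical models implemented in `nichecycle`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions a maintainer would
want written down.

## Seasonality: Lomb–Scargle with a permutation null

The classical variance-normalized Lomb–Scargle periodogram is evaluated on
a frequency grid from 1/span to `max_frequency_factor · n/(2·span)`
(a mean-Nyquist-like limit) in steps of `1/(oversampling · span)`;
defaults `oversampling = 4`, `max_frequency_factor = 1`. For ~131 monthly
samples over 11 years this gives ≈ 260 frequencies with the annual line
well inside the grid and a period resolution of a few days near 365 d.
The normalization uses the sample variance (ddof = 1), under which the
power at a fixed frequency of white noise is approximately Exp(1) — the
basis of the null-calibration test.

Significance is a value-shuffling permutation test on the *peak* power
(times fixed, values permuted), with the add-one rule
`p = (1 + #{peak* ≥ PN}) / (1 + n_rand)`; `n_rand` defaults to 1000 (the
permutation count is an implementation choice; the add-one rule keeps p
strictly positive and conservative). Because the permuted series share
the time axis, the tau-shifted cosine/sine bases are precomputed once and
each permutation's full periodogram is two matrix products — this is why
screening 1000 ASVs with hundreds of permutations each takes seconds, not
hours. Per-ASV permutation seeds are derived from the global seed and the
ASV id (CRC32), so results are independent of evaluation order.

An ASV is *seasonal* when PN ≥ 10 and BH-corrected q ≤ 0.05. The PN
threshold is applied as ≥ (a boundary of measure zero); the flag does not
require the peak period to be annual — a separate `annual` flag marks
peaks in the 300–430 d window, since the period distribution is
interpreted on its own.

The input series defaults to per-sample relative abundance; CLR is
available by configuration and the choice is recorded in the outputs.

### Rank-level aggregation

For a taxonomic group, each of 300 iterations draws ⌈0.8·n⌉ members
without replacement, sums their counts, converts to relative abundance
against the full-sample totals, and computes PN plus its permutation p.
The *raw* per-iteration p is compared to 0.05 (a multiplicity correction
across 300 strongly dependent iterations of the same group is not
well-defined); the reported statistic is the fraction of iterations with
PN ≥ 10 and p ≤ 0.05. Classes are eligible for full rank profiling when
they contain more than one order, family and genus each holding ≥ 10 ASVs.

A caution about aggregation in count space: log-scale seasonal signals do
not cancel linearly. Two equal-abundance groups in exact antiphase with
log-amplitude s contribute `cosh(s·cosθ)` to the aggregate — a
frequency-doubled component of relative magnitude ≈ s²/4. Cancellation in
the aggregate therefore only occurs when s is small enough that the
exponential is effectively linear; the packaged antiphase reference
construction (`antiphase_class_dataset`) uses s = 0.15 log units, chosen
so that the residual annual leakage of the 80% resampling (proportional
to s·sd(Δn)/(σ√n), with Δn the group imbalance of a draw and σ the
taxon-level noise) stays below the noise floor while each genus on its
own remains unambiguously seasonal.

## Abundance classes and conditionally rare taxa

Occurrence counts presence (count > 0), matching an occurrence axis in
percent of samples detected; relative abundance is in percent. The
bimodality coefficient is Sarle's sample-corrected form computed on the
relative-abundance series (not raw counts), so sequencing-depth artifacts
cannot fake a bloom. For a Gaussian series it averages ≈ 1/3 (the uniform
benchmark is 5/9), so the 0.9 cut is far from unimodal behavior; a
balanced two-point series approaches 1. CRT = bimodality ≥ 0.9 AND
max relative abundance ≥ 1%; the flag is computed for all ASVs and is by
construction confined to the abundant class.

## Profiles, gap statistic, cyclic smooth

Profile space is the 12-vector of monthly mean CLR (pseudocount 1, i.e.
`log(x+1)` centered per sample). Distances are Euclidean with Ward
linkage (compact seasonal groups; configurable). The gap statistic uses
uniform reference draws over each dimension's range, `Gap(k) =
E*[log Wₖ] − log Wₖ` with Wₖ the within-cluster sum of squares of the
hierarchical k-cut, and Tibshirani's one-standard-error rule
(`s_k = sd·√(1+1/B)`, B = 50 reference sets by default).

The annual trend display is a penalized periodic natural cubic spline:
12 equally spaced knots on [0, 365.25), penalty ∫f″², smoothing parameter
chosen by GCV(λ) = n·RSS/(n−edf)² over a 41-point log grid spanning
10⁻² – 10⁸. Periodicity of value and first derivative across the year
boundary holds by construction of the basis. Two numerical notes: (i) the
λ→∞ limit is the sample mean (the penalty null space is the constants);
(ii) GCV is *not* exactly invariant under duplicating every observation —
the effective degrees of freedom halve relative to n — so duplicated data
give a nearly, not exactly, identical curve; the test asserts closeness
within 5% of the data range.

## Divergence and OTUs

Pairwise divergence uses a global alignment with match +1, mismatch −1,
gap open −4, gap extend −1 and free terminal gaps (amplicons from one
primer set differ mainly by a few terminal bases). Divergence is the
count of mismatching aligned columns, with internal gap columns counted
as mismatches and terminal overhangs ignored; N matches nothing,
including another N. Five mismatches over a 420-column alignment is
98.8% identity. For equal-length pairs the ungapped alignment is used
whenever the optimal alignment score cannot beat it (checked against the
aligner's score), which keeps the common indel-free case fast and exact.
Unrelated sequences (random, ≈ 75% divergent) may align to nothing under
this scoring; such pairs are reported at maximal divergence, which is the
correct behavior for OTU clustering (they can never co-cluster at 99%).

OTUs come from average-linkage (UPGMA) agglomeration on fractional
distance (mismatches / alignment length), cut at 1 − identity; complete
linkage is available by flag. Closely related pairs are within-genus
pairs at ≤ 5 mismatches.

## Rho proportionality and the niche regression

ρ = 1 − var(clrₓ−clr_y)/(var clrₓ + var clr_y), computed for all pairs
from the covariance identity ρ = 2cov/(varₓ+var_y) (the equivalence is
asserted to 1e−12 in tests). The permutation FDR shuffles every taxon's
counts independently across samples, re-applies CLR, and recomputes all
pairs; FDR(c) is the mean null exceedance count over the observed
exceedance count on a 0.05-spaced cutoff grid, and the selected cutoff is
the smallest with FDR ≤ 5% (100 permutations by default).

The per-genus regression of ρ on nucleotide divergence uses *all* the
genus's pairs — the ≤ 5 nt rule governs eligibility only (≥ 10 ASVs
participating in close pairs; configurable, and deliberately so: the
source analyses report both a 10-ASV and a >3-ASV variant of this rule).
Pairs are not restricted to FDR-passing ones by default (a flag enables
that restriction). Genera with fewer than 3 pairs or constant divergence
are recorded as untestable rather than fitted.

## Beta-binomial environmental models

W ~ BetaBinomial(M, μ, φ) with logit μ = Xβ, logit φ = γ₀ (dispersion is
intercept-only; no dispersion covariates are modelled), parametrized
a = μ(1−φ)/φ, b = (1−μ)(1−φ)/φ so φ→0 is the binomial limit. The
log-likelihood and its analytic gradient are evaluated with log-gamma /
digamma; optimization is L-BFGS-B from three deterministic starts
(binomial-GLM, moment, flat), and standard errors come from the observed
information (central differences of the analytic gradient). "Polynomial"
means degree 2 in the standardized covariate, selected by a nested LRT at
0.05 against the linear fit; overall significance is the LRT of the
chosen form against intercept-only with matching df, BH-corrected across
all ASV × parameter models (FDR ≤ 5%). One parameter per model; the VIF
report (complete cases, warning above 5) is what justifies reading the
parameters separately. All-zero or saturated responses are flagged
degenerate and excluded from the FDR; non-convergent fits are flagged and
excluded with a warning.

Calibration at the study's sample size (n = 131, depth 2·10⁴, φ = 0.02):
95% CI coverage ≈ 0.95 and LRT type-I error ≈ 0.05 (measured by the
acceptance script and tests).

## The synthetic-data generator

The generator emulates the study design end to end:

* **Dates** — 11 years × 12 months, sampling day uniform within each
  month (the LSP is always exercised on uneven spacing), whole months
  dropped with probability 1/132 (failed sequencing loses samples, not
  taxa).
* **Sequences** — 420 nt; one random ancestor per genus (> 10% inter-genus
  divergence enforced), members derived by 1–10 point substitutions.
  Phase-coupled genera use a nested substitution ladder (member j carries
  the first kⱼ substitutions of one ordered list), making the pairwise
  substitution count exactly |kᵢ−kⱼ| and the seasonal phase offset exactly
  linear in divergence (default 8 days per substitution) — the generative
  counterpart of niche divergence among close relatives. The emitted
  truth matrix is the exact substitution count (= Hamming distance; no
  indels are simulated).
* **Latent abundance** — λᵢₜ = aᵢ + sᵢ·cos(2π(doyₜ−φᵢ)/365.25) +
  Σₚ βᵢₚ·z(envₚₜ) + εᵢₜ with aᵢ ~ N(0, 1.2), seasonal amplitudes
  sᵢ ~ U(1.0, 2.5) log units for a 30% seasonal fraction (yielding peak
  powers in the empirically reported 10–43 range), ε ~ N(0, 0.5).
  Covariates are standardized inside the model so β are comparable.
* **CRT** — bloomers rest at baseline 0 and, in 5% of samples, jump to a
  characteristic bloom state baseline + 4 log units with N(0, 0.15)
  variability *replacing* the resting noise. Blooms are modelled as a
  distinct state rather than a scaled-up resting level deliberately:
  conditionally rare dynamics as operationally defined (bimodality ≥ 0.9)
  presuppose well-separated, consistent bloom levels, and bloom heights
  inheriting the full 0.5-log resting noise would produce kurtosis that
  no bimodality detector of this family would call bimodal.
* **Environment** — each parameter is a sinusoid in the calendar-month
  index plus noise: temperature anchored at 12.6 °C (February) / 24.5 °C
  (August), nutrients peaking in winter (peaks staggered across
  parameters), chlorophyll ≈ 1 mg m⁻³ at the winter–spring transition,
  nanoflagellates log-normal and positive. Using the month index (not the
  jittered day) for the deterministic part makes the anchors exact at
  zero noise.
* **Reads** — multinomial over softmax(λ) at fixed depth 5·10⁴ (column
  sums exactly equal the depth; a lognormal depth option exists, since
  the real within-sample depth distribution is not published).

What the generator does **not** emulate — and hence what passing tests do
not show about field data: indels and chimeras (divergence truth is
substitution-only), realistic phylogenetic tree shapes (star-like genera
only), interannual trends or regime shifts (every year has the same
expected cycle), taxon interactions beyond shared drivers, and
environmental covariates with independent dynamics — all synthetic
covariates share one annual harmonic, so their mutual VIF is higher than
in the field data (the VIF machinery is exercised, but "no collinearity"
is a property of the real environment, not of this emulation). In small
synthetic communities (tens of taxa) compositional closure also couples
every taxon to the seasonal ones — a non-seasonal taxon's *share* cycles
because the seasonal taxa's does — so apparent seasonality of relative
abundance is overstated at small community size; recovery benchmarks
therefore use 1000-taxon communities, where the closure effect is
diluted.

## Reproducibility and seeds

Every stochastic stage draws from a generator seeded by
CRC32(global_seed, stage_name) — stages can be rerun independently and
reproduce byte-identical outputs; per-ASV permutation streams are keyed
by ASV id. The pipeline writes a manifest (config snapshot, package
version, per-stage seeds, row counts, wall times) on success and failure.

## Problem sizes used by the acceptance script

Oracle and calibration checks use 50 series (LSP brute force), 500 series
× 199 permutations (null calibration), 1000 random p-vectors (BH), 1000
random pairs (Rho identity); recovery checks use one 1000-ASV community
(seasonality screen at 299 permutations per ASV, CRT), 2 × 50 replicate
communities of 66 ASVs (niche regression), 200 + 500 replicates
(beta-binomial coverage and type-I error), 20 seeds (gap statistic) and
300 resampling iterations × 199 permutations (rank coherence and
cancellation). These sizes give Monte-Carlo noise comfortably below every
decision band while keeping the full script around a minute on one CPU.
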