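# Methods

This note documents the statistical models behind `dieltx`, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Sampling design and time conventions

All times-of-day are real hours on a 24-h clock in [0, 24) (11 a.m. =
11.0, 11 p.m. = 23.0). The default `Timeline` mirrors the drift design
the toolkit targets: 16 samples at 4-h spacing starting at 10:00 local,
spanning ~2.6 days, with dawn at 6.9 h (06:54) and dusk at 19.0 h —
late-September values at a mid-latitude eastern Pacific site. Because
2.6 days do not tile the clock evenly, day 1 contributes more samples
than day 3; every fit therefore uses the actual clock times, never an
interpolated balanced grid.

## Lineage Probability Index

Only the semantics of the score are fixed by its definition — a value
in [0, 1] expressing lineage commonality among a query's top hits by
bit score. The concrete procedure here is this package's documented
choice, isolated in `compute_lpi`:

* **Window.** Hits with bit score ≥ 0.95 × the query's maximum.
  "Top 95-percentile by bit score" admits a second reading (the top 5%
  of hits by count); the score-window reading matches common best-hit
  practice and the fraction is an exposed parameter, so the other
  reading is one argument away.
* **Consensus scan.** At each rank r from the root, f_r = (hits whose
  rank-r prefix equals the modal prefix) / (window size); the
  assignment extends while f_r ≥ 0.5 (the consensus floor). LPI is the
  mean of f_r over assigned ranks.
* **Ties.** A modal-count tie at the first rank means the window is
  split at the domain level: the query is reported `unresolved` with
  LPI 0.0 rather than guessed. Deeper ties are broken by higher summed
  bit score within the window, then lexicographically — determinism
  over cleverness.
* Queries whose hits all lack lineage mappings, or with no hits at
  all, are reported `no_match` with LPI NaN.

Whether the index should weight ranks unequally or use percent
identity is deliberately left out: both are plausible refinements with
no basis for choosing here, and the aggregation lives in one function
so either can be swapped in.

## Harmonic regression (cosinor)

For series y at clock times t (hours), OLS on
y = M + a·cos(ωt) + b·sin(ωt), ω = 2π/24. Amplitude √(a²+b²), peak
time (24/2π)·atan2(b, a) mod 24, and the F test of the harmonic pair
against the intercept-only model (2 and n−3 df). A label-permutation
p-value is available (`test="permutation"`); the parametric F test is
the default because it is deterministic and the two agree within
Monte-Carlo error on the fixtures tested. The period is fixed at 24 h;
there is no period scanning and no 12-h component.

Conventions: a constant series has amplitude 0, undefined (NaN) peak
and p = 1; eligibility for the matrix-level caller requires ≥ 5
nonzero observations (3 parameters need residual df) and nonzero
variance; a design matrix that is rank-deficient (all samples at the
same phase) is a hard error. The modulus that maps acrophases into
[0, 24) can round a vanishingly small negative angle to exactly 24.0
in floating point; such values are mapped to 0.0.

Periodicity calling runs on the taxon-group-normalized matrix, which
removes whole-taxon abundance swings so the per-ORF harmonic reflects
within-taxon scheduling. Benjamini–Hochberg FDR is applied **within
each taxon group** by default — the natural companion of per-taxon
periodic-fraction summaries, and robust to one deeply-sampled taxon
dominating the p-value pool — with a `global` option exposed since
neither scope is canonical. The call threshold defaults to q ≤ 0.1.

## Circular statistics

Peak times map to angles θ = 2πt/24. The four day-phase bins — early
day [6, 12), late day [12, 18), early night [18, 24), late night
[0, 6) — are half-open on the left so they partition the circle
exactly; 6.0 is early day, 5.999 is late night.

**Watson–Wheeler.** The pooled sample is circularly ranked; rank r
becomes the uniform score 2πr/N; W = 2·Σ_j |R_j|²/n_j over groups is
referred to χ² with 2(k−1) df. The statistic depends only on the
ordering, so it is rotation-invariant and distribution-free. Exact
ties break the ranking: they are resolved by adding seeded uniform
jitter of ± 0.001 h (far below any realistic acrophase resolution) and
averaging statistic and p over 1000 draws; with ≤ 30% ties the
between-seed standard deviation of the averaged p stays ≤ 0.005. For
small two-group designs `exact=True` enumerates all group-label
permutations instead of using the χ² approximation (which is also
flagged as unreliable below N = 8).

**Watson–Williams.** The classical F statistic
K·(N−k)(ΣR_j − R) / ((k−1)(N − ΣR_j)) with the correction factor
K = 1 + 3/(8κ̂), κ̂ obtained from the within-group mean resultant
length by the standard piecewise inversion. The test assumes
von-Mises-like groups with a common, fairly high concentration; when
the within-group mean resultant length is below 0.45 the result
carries a warning flag rather than being suppressed.

**Cascade test.** For each functional category, Watson–Wheeler of
that category's peak times against the pooled *other* categories, BH
at FDR 0.05. Testing against a pool that includes the category itself
drags the reference toward the category and biases toward the null,
so pooled-others is the default (`include_self` exists for
comparison). Circular means are unweighted by default;
expression-weighted means are available where abundance-weighted
timing is wanted.

## Seasonal adaptation window

The dawn-relative phase of a peak is (peak − dawn) mod 24. The window
defaults to [9.9, 14.4) h after dawn — the span in which, under
translational coincidence, a transcript's peak falls in daylight
during long photoperiods but after dusk during short ones. The
endpoints are configuration values, not re-derived: the derivation
requires solstice photoperiods for the study site and a day/night
translation-rate contrast that this package does not model. Membership
is half-open for consistency with the bins. The drift spans ~2.6 days
over which dawn moves by a few minutes, so one representative dawn per
analysis is used (per-day dawns, if supplied, are averaged by the
caller). Window classification is restricted to called periodic
*nuclear* ORFs: organellar transcription is not under the nuclear
clock machinery the mechanism presumes.

Marker ratios are plain count ratios (numerator set sum / denominator
set sum) per timepoint and pooled, with zero-denominator timepoints
flagged rather than silently dropped. They are scale-invariant, so
they can be computed on raw or normalized counts.

## Synthetic community generator

The generator emulates the *statistical* structure of a drift
metatranscriptome, not its sequences:

* Cyclic ORF means follow baseline · (1 + A·cos(2π(t − φ)/24)) with
  relative amplitude A ∈ [0, 1] (A > 1 would give negative means and
  is rejected). Default A ~ Uniform(0.2, 0.8).
* Peak phases come from a von Mises mixture: 55% early day (mean
  11.0 h, κ = 8), 31% early night (mean 23.0 h, κ = 8), remainder
  uniform — the early-day/early-night split observed for periodic
  transcripts in situ, used as a realistic default rather than a
  target.
* The default community is dinoflagellate-dominated with strongly
  contrasting cyclic fractions (prasinophyte 25%, dinoflagellate 1%),
  heavy-tailed lognormal baselines, and ~10–15% organellar ORFs in
  phototroph taxa.
* Noise is lognormal with CV 0.3 by default (mean-preserving), or
  negative binomial with var = μ + 0.09 μ² (CV ≈ 0.3 at high μ); no
  in-situ noise model is established, so both are config-exposed.
* Compositional coupling: expected column totals are rescaled to a
  fixed library size before noise, reproducing the closure constraint
  of sequencing. This matters: a strongly oscillating taxon induces
  apparent anti-phase rhythm in truly constant taxa after library
  normalization, and the test suite demonstrates this hazard
  explicitly (`test_compositional_artifact_demonstrated`) instead of
  hiding it. `library_size=None` disables closure, the correct mode
  for noise-free phase-recovery checks.

What the generator does **not** emulate — and hence what passing tests
do not establish about field data: reads, assembly and ORF-calling
artifacts; cross-taxon correlated noise (water-mass changes,
advection); non-sinusoidal waveforms (sharp dawn spikes, dusk
shoulders); trends from nutrient drawdown over the drift; tides or
semidiurnal components; and virus–host dynamics. Detection power on
real data will be lower for transcripts whose waveform departs from a
single harmonic.

## Problem sizes and runtimes

The shipped analyses use: 2000 ORFs for null-calibration runs, 500
planted cyclic ORFs for phase-recovery error, 100 fixtures against a
0.001-h grid-search oracle, 2000 replicates for Watson–Wheeler type-I
calibration, 200 replicates for planted-cascade recovery, and the
1350-ORF default community for end-to-end runs. These sizes give
3-SE-tight binomial checks while keeping the full suite under half a
minute on one CPU; all of them scale linearly if larger runs are
wanted.

## Known limitations

* The F test assumes roughly Gaussian residuals on the analyzed scale;
  taxon-normalized relative abundances are bounded and mildly
  heteroskedastic, which the permutation mode sidesteps at the price
  of seed-dependence.
* With 16 timepoints the harmonic fit cannot distinguish a 24-h
  rhythm from some non-stationary patterns (e.g. a single broad pulse
  on day 2); the caller reports what fits a sinusoid, not causality.
* LPI quality degrades gracefully but uninformatively when reference
  databases are sparse: a unanimous window over one mapped hit gives
  LPI 1 with n = 1, so `n_hits_considered` should be consulted
  alongside the score.
* The Watson–Williams correction is inaccurate for strongly
  non-von-Mises or low-concentration groups; the warning flag marks,
  but does not fix, such cases.
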