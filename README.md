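# dieltx

Analysis toolkit for **diel (24-h) transcriptional dynamics in marine
microbial communities**, built around the kind of dataset an in situ
robotic sampler produces: ORF-level metatranscriptome counts from a
multi-day Lagrangian drift sampled every ~4 h (16 libraries over ~2.6
days), spanning a mixed community of dinoflagellates, ciliates,
diatoms, haptophytes, prasinophytes, cyanobacteria and heterotrophic
prokaryotes.

It is written for microbial oceanographers and computational
biologists who need to go from a count matrix plus homology hits to
statements like "a quarter of this prasinophyte's transcriptome
cycles with the day", "photosynthesis transcripts peak in a morning
cascade", or "iron-stress markers peak inside the photoperiodically
sensitive window".

## What it computes

**Taxonomy from homology hits (LPI).** Each query's hits within 95% of
its best bit score form a consensus window; the assignment follows the
modal lineage rank by rank and the Lineage Probability Index in [0, 1]
is the mean rank-wise agreement — robust to contaminated references
where a best-BLAST call is not.

**Normalization.** Per-library (each timepoint sums to 1, the
compositional view of sequencing depth) and per-taxon-group (each
taxon's column sums to 1), plus in-group synchrony (mean pairwise
Pearson *r*) and taxon aggregate series.

**Harmonic regression (cosinor).** For each ORF, ordinary least
squares on the actual sample clock times *t*:

    y(t) = M + a cos(2πt/24) + b sin(2πt/24)

with amplitude A = √(a² + b²), acrophase (peak time)
φ = (24/2π)·atan2(b, a) mod 24, an F test of the two harmonic degrees
of freedom (permutation alternative available), and Benjamini–Hochberg
FDR within each taxon group; ORFs with q ≤ 0.1 are called periodic.

**Circular phase statistics.** Peak times are binned into early day
[6, 12), late day [12, 18), early night [18, 24) and late night
[0, 6); group timing is compared with the Watson–Wheeler uniform-scores
test (tie-broken by averaging over seeded jitter draws, exact
enumeration for small samples) and the Watson–Williams F test. The
cascade test asks, category by category, whether a functional group's
peak times differ from the pooled rest at FDR 0.05.

**Seasonal adaptation window.** Under translational coincidence
(protein synthesis is several-fold faster in daylight), transcripts
peaking 9.9–14.4 h after local dawn fall before dusk in long days but
after dusk in short days, making their protein pools
photoperiod-dependent. The classifier flags called periodic nuclear
ORFs whose dawn-relative peak lies in that (configurable) window.
Marker ratios (e.g. flavodoxin:ferredoxin for iron stress) complete
the physiological readout.

**Synthetic community generator.** All of the above is testable
without sequencing data: the generator produces a mixed-taxon count
matrix with known cyclic fractions per taxon, early-day/early-night
peak-phase mixture, lognormal or negative-binomial noise, and
compositional sampling to a fixed library size, alongside the ground
truth table.

## Worked example

Run the full pipeline on the default synthetic community (1350 ORFs,
10 taxa, 16 timepoints at 4-h spacing):

```bash
dieltx run --seed 1 --out-dir demo_out
```

The summary (also written to `demo_out/summary.json`) includes, among
others:

```json
"per_taxon": {
  "ostreococcus": {"pct_orfs_periodic": 19.0, "pct_expression_periodic": 25.916, "n_called": 19, "n_tested": 100},
  "dinophyta":    {"pct_orfs_periodic": 1.25, "pct_expression_periodic": 1.3177, "n_called": 5,  "n_tested": 400},
  ...
},
"window": {"dawn": 6.9, "start_after_dawn": 9.9, "end_after_dawn": 14.4,
           "n_called_nuclear": 66, "n_in_window": 6},
"marker_ratio": {"numerator": "flavodoxin", "denominator": "ferredoxin", "pooled": 0.826918}
```

Reading this: of the 100 simulated prasinophyte (*Ostreococcus*-like)
ORFs, 19% were called significantly periodic at FDR ≤ 0.1, carrying
~26% of that taxon's expression — versus 1.25% of the dinoflagellate
ORFs, matching the planted contrast between a transcriptionally
clocked phototroph and a taxon that barely regulates transcription
over the day. Six of the 66 called nuclear ORFs peak inside the
seasonal adaptation window (9.9–14.4 h after a 06:54 dawn), and the
community-wide flavodoxin:ferredoxin expression ratio is ~0.83 (the
generator plants no iron-stress signal, so a ratio near 1 is
expected). Intermediate TSVs (`hra_fits.tsv`, `cascade.tsv`,
`window.tsv`, ...) let every summary number be recomputed with shell
tools, and a rerun with the same seed is byte-identical.

Each stage is also exposed separately:
`dieltx simulate | assign-taxonomy | normalize | hra | phase | window | markers`.

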