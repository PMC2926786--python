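# Methods

## Measurement model and coordinate conventions

The unit of measurement is a tiling-array probe: a 60-bp feature every
~250 bp, reporting the log2 IP/input enrichment of PolII ChIP at one time
point. Arrays are normalized so every sample's mean log2 enrichment over
non-missing probes is zero; all downstream spread-based statistics
(dynamic range, histograms) assume this convention, under which global PolII
loss appears as histogram narrowing rather than a level shift. Missing
values propagate as missing and are excluded from every mean; they are never
imputed as zero.

All internal coordinates are 0-based half-open (BED convention). GFF3 input
(1-based closed) is converted at the read boundary. Probe→gene membership is
decided by the probe midpoint, `floor((start+end)/2)`: a 60-bp probe
straddling a window boundary belongs to exactly one region, and a probe may
belong to several genes (the assay is strand-blind) but to at most one region
per gene.

## CDS granularization

Genes longer than 1 kb are partitioned, strand-aware from the translation
start, into 5′ CDS (first 500 bp), 3′ CDS (last 500 bp) and mid-CDS (the
remainder); the three windows tile the gene body exactly. Genes of 1 kb or
less are split at their midpoint into 5′/3′ halves and never carry a mid-CDS
entry. Region summaries are unweighted arithmetic means of assigned probes'
non-missing values — probes are not weighted by overlap length, since
membership is already by midpoint.

Polarity analyses require a non-missing 5′, mid and 3′ CDS summary; this is
the stricter of the two readable eligibility rules (gene > 1 kb vs actually
having a mid-CDS probe) and excludes long genes that the sparse tiling
happens to miss in the middle.

## Polarity and running windows

Polarity is `mean(5′ CDS) − mean(3′ CDS)` in log2 units — equivalently the
log2 of the 5′/3′ linear-enrichment ratio; the data never leave log space.
Genes are ranked descending with ties broken lexicographically by id so ranks
are reproducible. Ordered profiles use a centered running-window mean of
width 80 genes, truncated at the series ends (so output length equals input
length); for even widths the extra element is taken from the left, and
missing values are excluded per window.

## mRNA excess per PolII change

Per gene, `ΔPolII` is the mid-CDS summary difference between a stress time
point and the pre-stress baseline; `ΔmRNA` is the matched column of a
gene-level log2 mRNA-change matrix. The matrix is already baseline-relative,
so the column is used directly; a time-mapping option pairs a PolII sample
with a differently-timed mRNA column explicitly (e.g. a 15-minute array with
a 20-minute mRNA measurement) rather than silently.

The typical yield is a LOWESS fit (locally weighted linear regression with
tricube weights, statsmodels implementation) of `ΔmRNA` on `ΔPolII` with
span 0.3 and 2 robustifying iterations — a smooth-but-robust default for a
few thousand genes; both are exposed as parameters. The fit is computed per
time-point pair, not pooled across times. Residuals beyond ±0.5 log2 define
the excess/dearth classes; the boundary is strict (a residual of exactly 0.5
is typical), and the threshold is in log2 mRNA-change units like both axes.
Variance explained is the squared Pearson correlation of the two deltas.
Class-vs-overlap comparisons use the Mann–Whitney test of excess genes
against all others.

Degenerate inputs raise rather than guess: fewer than 10 points, a constant
predictor, or zero variance in a correlation.

## Overlap engine

Overlap of a gene with CUT/SUT/ORF transcripts is union coverage in bp —
per class, and totalled across classes over the whole gene body — so a
transcript spanning the entire gene, or two transcripts covering the same
bases, never double-count; records whose id equals the gene's are excluded.
Overlap is strand-agnostic because antisense noncoding transcription is
exactly what the polarity analysis is looking for. The 3′-overlap flag
restricts to the strand-aware 3′ CDS window.

The rank-sum test uses mid-rank ties throughout; p-values come from full
enumeration of rank assignments when n1+n2 ≤ 10 and from the normal
approximation with tie and continuity corrections otherwise (scipy). When
every pooled value is tied the test returns p = 1. Mann–Whitney was chosen
because overlap lengths are zero-inflated and far from normal.

## Temporal dynamics

Response groups use |Δlog2 mRNA| ≥ 1 ("at least two-fold"), boundary
inclusive. Clustering is Euclidean k-means on the log2 change profiles
without row standardization (a config choice), k-means++ initialization,
best of 10 restarts, fixed seed; rows with missing values are dropped and
counted. Cluster ids are renumbered by decreasing size so runs and
permutations of the input are comparable. Per-cluster PolII profiles are
member means of t0-subtracted region summaries, so the t0 entry is zero by
construction.

## PolII-loss diagnostics

Dynamic range is reported two ways — SD and the central 90% spread
(p95 − p5) of probe values per sample — with density histograms on bin edges
shared across samples, so narrowing is testable and visible bin-for-bin.
Retention profiles are computed at the probe level within region classes:
probes ordered by initial abundance (descending), final-time values smoothed
with the 80-wide running window. Histograms and spreads use all probes, not
genic probes only. Recruitment at listed genes is a mid-CDS delta (whole-body
mean for sub-1-kb genes) against a configurable threshold, default 1 log2.

## The synthetic-study generator

The generator emulates the structure the analysis assumes, with every planted
effect recorded in a ground-truth table. Defaults are the study conditions
the test-suite recovery checks run under; each was chosen once:

- **Genome**: 2,000 genes on 4 chromosomes, log-normal lengths
  (median ≈ 1.3 kb, log-sd 0.45, clipped to 0.3–8 kb — yeast-like), random
  strands, intergenic gaps 200–600 bp; genes never overlap.
- **Probes**: 60 bp every 250 bp, tiled across each chromosome.
- **Occupancy**: probe value = gene baseline (Normal(1, 0.5)) + temporal
  archetype amplitude + polarity term (±δ_pol on the 5′/3′ windows,
  δ_pol = 1 log2, sign random per gene) + 1 log2 boost wherever a planted
  transcript covers the probe midpoint + Normal(0, σ) noise with σ = 0.3.
  Probes under neither gene nor transcript are pure noise. The overlap boost
  applies over the transcript's whole extent, including the short stretch
  beyond the gene end — the transcript itself is transcribed — so "intergenic
  = noise" holds only away from planted transcripts.
- **Overlapping transcripts**: 20% of genes get one CUT/SUT/ORF
  (weights 0.5/0.35/0.15) intersecting the gene's 3′ end by 100–400 bp and
  extending 150 bp beyond it; 150 bp is kept below the minimum gap so a
  planted transcript never reaches a neighboring gene and planted overlap
  lengths are exact.
- **Time courses**: five points (0–120 min) with three archetypes —
  sustained induction (peak +2 log2), sustained repression (−2), and
  unresponsive — matching the coarse shapes of a stress response.
- **mRNA**: ΔmRNA = β·ΔPolII + e·1[excess] − e·1[dearth] + ε with β = 1,
  e = 1 log2, ε-sd = 0.2, excess and dearth fractions 0.1 each. Setting
  `calibrate_r2` instead derives ε-sd per time point as
  `β·sd(ΔPolII)·sqrt(1/R² − 1)` so the population R² is exact. Excess genes
  are drawn, with coupling probability 0.8, from the pool of 3′-overlapped
  negative-polarity genes (dearth genes from the complementary pool) — one
  knob plants both the overlap and the polarity association.
- **PolII-loss mode**: per-time multiplicative shrinkage of all signal before
  noise, default series (1, 1, 0.8, 0.4, 0.2); optional per-region retention
  r maps a factor f to `f + (1−f)·r`, so at full shrinkage a region keeps
  fraction r of its signal.

Everything is a deterministic function of the seed (bit-identical files on
re-runs).

What the generator does **not** emulate: probe GC/affinity effects, dye
biases, spatial array artifacts, overlapping genes, multiple transcripts per
gene, mRNA half-life dynamics, or any sequence-level signal. Passing the
recovery tests therefore shows the estimators are correct and well-calibrated
under the assumed noise model — not that real arrays meet that model.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale studies: 2,000 genes
for the excess/overlap/polarity-association analyses, 600 for cluster
recovery, 500 for polarity-sign recovery and PolII-loss checks, 50–200
random instances for the brute-force oracle comparisons, and 1,000 replicates
for rank-sum type-I-error calibration. TSV intermediates that downstream
stages re-read are written at 10 significant digits; derived profile tables
at 6. Pipeline outputs avoid timestamps so identical seeds give byte-identical
result directories.

## Known limitations

- The LOWESS curve is only evaluated at observed ΔPolII values; there is no
  extrapolation API.
- The overlap engine is quadratic in (genes × transcripts) per chromosome —
  ample for yeast-scale annotation, not for mammalian genomes.
- k is fixed by the user (default 8); no model selection is attempted.
- Recruitment scanning reports per-gene deltas against a single threshold;
  it does not model probe-level significance.
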