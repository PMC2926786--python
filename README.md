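# poldyn

Genome-wide RNA polymerase II (PolII) occupancy dynamics from tiling-array
ChIP data, for researchers studying how transcription relates to mRNA output
during stress responses in budding yeast (or any compact genome profiled with
sparse tiling arrays).

A tiling ChIP-chip experiment reports a log2 IP/input enrichment for each
60-bp probe, spaced roughly every 250 bp, at each time point of a stress time
course. `poldyn` turns those probe values into gene-level biology:

- **CDS granularization** — each gene body is partitioned into the first
  500 bp (5′ CDS), last 500 bp (3′ CDS) and the remainder (mid-CDS); probe
  values are averaged per window (probes are assigned by midpoint; genes
  ≤ 1 kb are split at their midpoint into 5′/3′ halves).
- **Polarity** — the 5′/3′ travel index
  `polarity(g) = mean log2 enrichment(5′ CDS) − mean log2 enrichment(3′ CDS)`,
  i.e. the log2 of the 5′/3′ enrichment ratio. High polarity marks
  promoter-proximal accumulation or premature termination; negative polarity
  marks 3′-end occupancy, the signature of overlapping downstream
  transcription. Gene orderings are profiled with centered 80-gene
  running-window averages.
- **mRNA excess per PolII change** — the headline statistic. For matched
  per-gene changes `x = Δlog2 PolII (mid-CDS)` and `y = Δlog2 mRNA`, a LOWESS
  curve `ŷ = f(x)` (span 0.3, 2 robustifying iterations) defines the typical
  mRNA yield per PolII change; genes with residual `y − ŷ > +0.5` produce
  *excess* mRNA, genes below `−0.5` a *dearth*. The squared Pearson
  correlation of `x` and `y` is reported as variance explained.
- **Noncoding-overlap scoring** — per-gene bp of overlap with cryptic
  unstable transcripts (CUTs), stable unannotated transcripts (SUTs) and
  other ORFs, strand-agnostic (the assay cannot see PolII orientation), as
  union coverage plus 3′-window flags; group comparisons by Mann–Whitney
  rank-sum (exact enumeration for tiny samples, tie/continuity-corrected
  normal approximation otherwise).
- **Temporal dynamics** — two-fold activated/repressed/unchanged groups with
  per-region profiles, and Euclidean k-means (k = 8 default) of mRNA time
  courses with matched per-cluster mean PolII courses.
- **PolII-loss diagnostics** — on mean-zero-normalized arrays, genome-wide
  PolII loss appears as *narrowing* of the probe-value histogram; `poldyn`
  tracks the SD and central 90% spread per time point, retention-vs-initial-
  abundance running profiles per region class, and recruitment flags for
  condition-specific gene lists.

Because the published array datasets require downloads, the package ships a
first-class synthetic-study generator (`poldyn.simulate`) that plants every
effect the analysis is meant to recover — polarity signs, 3′-overlapping
transcripts, excess/dearth offsets coupled to overlap and polarity, temporal
archetypes, and global shrinkage — and records the ground truth alongside.

## Worked example

```python
from poldyn import SimulationConfig, generate_study, MrnaExcessModel, compute_deltas
from poldyn.overlap import overlap_table

study = generate_study(SimulationConfig(seed=42, n_genes=1000))
t0, t30 = study.config.sample_names[0], study.config.sample_names[2]
deltas = compute_deltas(study.summary, study.mrna, t30, t0)
res = MrnaExcessModel.from_deltas(deltas).fit()
print(res.summary())
```

```
mRNA excess per PolII change (LOWESS residual classification)
==============================================================
Genes:               635
LOWESS span:         0.3   robust iterations: 2
Residual threshold:  +/-0.5 log2
Variance explained (R^2, Pearson): 0.919
--------------------------------------------------------------
  excess  (residual > +0.5):     63
  typical                  :    498
  dearth  (residual < -0.5):     74
==============================================================
```

635 of the 1,000 simulated genes are long enough to carry a mid-CDS window
and enter the analysis; the planted 10%/10% excess/dearth fractions come back
as 63 and 74 called genes. Asking whether excess genes sit under noncoding
transcription:

```python
ov = overlap_table(study.annotation, study.transcripts)
means, u, p = res.class_overlap_report(ov)
print(means)                                  # mean overlap bp per class
print(f"rank-sum p (excess vs rest): {p:.3g}")
```

```
cls
excess     186.476190
typical     35.648594
dearth      11.581081
Name: total_bp, dtype: float64
rank-sum p (excess vs rest): 4.14e-33
```

Excess-mRNA genes carry ~5× the transcript overlap of typical genes — the
planted coupling between relieved nonproductive transcription and excess
mRNA yield, recovered end to end.

The same stages are available from a shell:

```sh
poldyn simulate --seed 42 --n-genes 1000 --outdir demo/inputs
poldyn run-all --config demo.yaml --seed 42 --outdir demo/out
```

where `demo.yaml` may simply contain `simulate: {n_genes: 1000}`. `run-all`
writes every stage's TSV plus `manifest.json`, and is byte-identical across
runs with the same seed.

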