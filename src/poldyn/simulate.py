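"""Synthetic tiling-array study generator with planted ground truth.

Emulates a yeast PolII ChIP-chip stress time course: genes tiled by 60-bp
probes every ~250 bp, per-probe log2 enrichment built from a gene baseline,
a temporal cluster archetype, a 5'/3' polarity term, extra occupancy under
planted 3'-overlapping CUT/SUT transcripts, and Gaussian probe noise.  A
matched gene-level log2 mRNA-change matrix follows a linear-in-ΔPolII model
with additive "excess"/"dearth" offsets.  An optional global shrinkage series
emulates progressive PolII loss in a temperature-sensitive polymerase mutant.

Everything is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .overlap import TranscriptSet
from .tiling import (
    GenomeAnnotation,
    OccupancyMatrix,
    ProbeSet,
    assign_probe_regions,
    summarize_regions,
)

# Default temporal archetypes (log2 amplitude per time point): sustained
# induction, sustained repression, and an unresponsive profile — the coarse
# shapes of a stress-response time course.
DEFAULT_ARCHETYPES = (
    (0.0, 1.5, 2.0, 2.0, 1.5),
    (0.0, -1.5, -2.0, -2.0, -1.5),
    (0.0, 0.0, 0.0, 0.0, 0.0),
)


@dataclass
class SimulationConfig:
    """All planted-structure parameters of the synthetic study.

    Defaults are the study conditions the analysis is exercised under:
    2,000 genes with log-normal lengths (median ~1.3 kb), 60-bp probes every
    250 bp, probe noise sd 0.3, polarity effect ±1 log2, 20% of genes with a
    3'-overlapping transcript, 10% excess / 10% dearth genes coupled to
    overlap and low polarity with probability 0.8, and five time points.
    """

    seed: int = 0
    n_genes: int = 2000
    n_chroms: int = 4
    gene_len_meanlog: float = math.log(1300.0)
    gene_len_sdlog: float = 0.45
    gene_len_min: int = 300
    gene_len_max: int = 8000
    intergap_min: int = 200
    intergap_max: int = 600
    chrom_size: int | None = None  # fixed size cap; None derives from content
    probe_spacing: int = 250
    probe_length: int = 60
    # planted 3'-overlapping transcripts
    overlap_fraction: float = 0.2
    overlap_len_min: int = 100
    overlap_len_max: int = 400
    # kept below intergap_min so a planted transcript never reaches a neighbor
    transcript_extra_len: int = 150
    class_weights: tuple = (("CUT", 0.5), ("SUT", 0.35), ("ORF", 0.15))
    overlap_boost: float = 1.0  # extra log2 occupancy under a transcript
    # occupancy model
    delta_pol: float = 1.0  # polarity effect: +δ on 5CDS, -δ on 3CDS (or flipped)
    baseline_mean: float = 1.0
    baseline_sd: float = 0.5
    noise_sd: float = 0.3
    time_points: tuple = (0, 15, 30, 60, 120)
    sample_prefix: str = "HS"
    archetypes: tuple = DEFAULT_ARCHETYPES
    # mRNA model: dmRNA = beta * dPolII + e * 1[excess] - e * 1[dearth] + eps
    beta: float = 1.0
    excess_effect: float = 1.0
    mrna_noise_sd: float = 0.2
    excess_fraction: float = 0.1
    dearth_fraction: float = 0.1
    coupling: float = 0.8  # P(excess gene drawn from overlap & low-polarity pool)
    calibrate_r2: float | None = None  # sets mrna_noise_sd from sd(dPolII)
    # PolII-loss mode: per-time multiplicative shrinkage of all enrichments
    shrinkage: tuple | None = None
    region_retention: dict | None = None  # e.g. {"5CDS": 0.3, "midCDS": 0.6, "3CDS": 0.6}

    def __post_init__(self) -> None:
        for name in ("overlap_fraction", "excess_fraction", "dearth_fraction", "coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0 or self.excess_effect < 0:
            raise ValueError("noise_sd and excess_effect must be >= 0")
        if len(self.archetypes) == 0:
            raise ValueError("at least one temporal archetype is required")
        for prof in self.archetypes:
            if len(prof) != len(self.time_points):
                raise ValueError("archetype length must match time_points")
        if self.shrinkage is not None and len(self.shrinkage) != len(self.time_points):
            raise ValueError("shrinkage length must match time_points")

    @property
    def sample_names(self) -> list:
        return [f"{self.sample_prefix}-{t:03d}" for t in self.time_points]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["archetypes"] = [list(p) for p in self.archetypes]
        d["class_weights"] = [list(p) for p in self.class_weights]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("time_points", "shrinkage"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if "archetypes" in d:
            d["archetypes"] = tuple(tuple(p) for p in d["archetypes"])
        if "class_weights" in d:
            d["class_weights"] = tuple(tuple(p) for p in d["class_weights"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-gene planted structure: polarity sign, excess class, temporal
    cluster, and the overlapping transcript (id + planted overlap length)."""

    table: pd.DataFrame  # indexed by gene_id

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path) -> "GroundTruth":
        t = pd.read_csv(path, sep="\t", index_col="gene_id",
                        keep_default_na=False, na_values=[])
        return cls(table=t)


def generate_annotation(cfg: SimulationConfig):
    """Lay out non-overlapping genes along chromosomes and plant one
    3'-overlapping CUT/SUT/ORF transcript at the designated fraction of genes.

    Returns ``(GenomeAnnotation, TranscriptSet, GroundTruth)``.  The ground
    truth also carries polarity signs, temporal cluster ids and excess/dearth
    classes so the occupancy and mRNA simulators and every downstream test can
    refer to one table.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    lengths = np.exp(rng.normal(cfg.gene_len_meanlog, cfg.gene_len_sdlog, n))
    lengths = np.clip(lengths, cfg.gene_len_min, cfg.gene_len_max).astype(int)
    gaps = rng.integers(cfg.intergap_min, cfg.intergap_max + 1, n)
    strands = rng.choice(["+", "-"], size=n)

    per_chrom = int(np.ceil(n / cfg.n_chroms))
    records = []
    chrom_sizes = {}
    gi = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1:02d}"
        pos = int(gaps[gi % n])
        while gi < n and gi < (ci + 1) * per_chrom:
            start = pos
            end = start + int(lengths[gi])
            if cfg.chrom_size is not None and end + cfg.intergap_min > cfg.chrom_size:
                raise ValueError(
                    f"genome too small to place {n} genes "
                    f"(chromosome size {cfg.chrom_size})"
                )
            records.append((f"g{gi:05d}", chrom, start, end, strands[gi]))
            pos = end + int(gaps[gi])
            gi += 1
        chrom_sizes[chrom] = cfg.chrom_size if cfg.chrom_size is not None else pos + 1000
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    ann = GenomeAnnotation(genes=genes, chrom_sizes=chrom_sizes)

    # planted 3'-overlapping transcripts
    n_overlap = int(round(cfg.overlap_fraction * n))
    overlap_idx = rng.choice(n, size=n_overlap, replace=False)
    has_overlap = np.zeros(n, dtype=bool)
    has_overlap[overlap_idx] = True
    classes, weights = zip(*cfg.class_weights)
    t_records = []
    ov_id = np.array([""] * n, dtype=object)
    ov_len = np.zeros(n, dtype=int)
    ov_class = np.array([""] * n, dtype=object)
    for k, idx in enumerate(sorted(overlap_idx)):
        gene = genes.iloc[idx]
        olen = int(rng.integers(cfg.overlap_len_min, cfg.overlap_len_max + 1))
        olen = min(olen, gene["end"] - gene["start"])
        tclass = str(rng.choice(classes, p=np.asarray(weights) / sum(weights)))
        if gene["strand"] == "+":
            ts, te = gene["end"] - olen, gene["end"] + cfg.transcript_extra_len
        else:
            ts, te = gene["start"] - cfg.transcript_extra_len, gene["start"] + olen
        ts = max(ts, 0)
        tid = f"nc{k:05d}"
        tstrand = "-" if gene["strand"] == "+" else "+"
        t_records.append((tid, gene["chrom"], ts, te, tstrand, tclass))
        ov_id[idx], ov_len[idx], ov_class[idx] = tid, olen, tclass
    transcripts = TranscriptSet(
        records=pd.DataFrame(
            t_records, columns=["transcript_id", "chrom", "start", "end", "strand", "tclass"]
        )
    )

    pol_sign = rng.choice([1, -1], size=n)
    cluster_id = rng.integers(0, len(cfg.archetypes), size=n)

    planted = _plant_excess_classes(cfg, rng, has_overlap, pol_sign)

    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "polarity_sign": pol_sign,
                "planted_class": planted,
                "cluster_id": cluster_id,
                "has_overlap": has_overlap,
                "overlap_transcript": ov_id,
                "overlap_len": ov_len,
                "overlap_class": ov_class,
            },
            index=pd.Index(genes["gene_id"], name="gene_id"),
        )
    )
    return ann, transcripts, truth


def _plant_excess_classes(cfg, rng, has_overlap, pol_sign):
    """Draw excess/dearth genes, preferring (with probability ``coupling``)
    3'-overlapped low-polarity genes for excess and their complement for
    dearth — the planted analogue of nonproductive transcription being
    relieved under stress."""
    n = len(has_overlap)
    planted = np.array(["typical"] * n, dtype=object)
    n_exc = int(round(cfg.excess_fraction * n))
    n_dea = int(round(cfg.dearth_fraction * n))
    idx = np.arange(n)

    exc_pool = idx[has_overlap & (pol_sign < 0)]
    taken = np.zeros(n, dtype=bool)
    n_from_pool = min(int(round(cfg.coupling * n_exc)), len(exc_pool))
    chosen = rng.choice(exc_pool, size=n_from_pool, replace=False) if n_from_pool else []
    for i in chosen:
        planted[i] = "excess"
        taken[i] = True
    rest = idx[~taken]
    extra = rng.choice(rest, size=n_exc - n_from_pool, replace=False)
    for i in extra:
        planted[i] = "excess"
        taken[i] = True

    dea_pool = idx[~taken & ~has_overlap & (pol_sign > 0)]
    n_from_pool = min(int(round(cfg.coupling * n_dea)), len(dea_pool))
    chosen = rng.choice(dea_pool, size=n_from_pool, replace=False) if n_from_pool else []
    for i in chosen:
        planted[i] = "dearth"
        taken[i] = True
    rest = idx[~taken]
    extra = rng.choice(rest, size=n_dea - n_from_pool, replace=False)
    for i in extra:
        planted[i] = "dearth"
    return planted


def make_probes(cfg: SimulationConfig, ann: GenomeAnnotation) -> ProbeSet:
    """Tile every chromosome with fixed-length probes at the config spacing."""
    rows = []
    for chrom, size in ann.chrom_sizes.items():
        starts = np.arange(0, max(size - cfg.probe_length, 1), cfg.probe_spacing)
        for s in starts:
            rows.append((f"{chrom}_{int(s):07d}", chrom, int(s), int(s) + cfg.probe_length))
    return ProbeSet(
        probes=pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"]),
        probe_length=cfg.probe_length,
        spacing=cfg.probe_spacing,
    )


def simulate_occupancy(
    cfg: SimulationConfig,
    ann: GenomeAnnotation,
    transcripts: TranscriptSet,
    truth: GroundTruth,
    probes: ProbeSet | None = None,
) -> OccupancyMatrix:
    """Per-probe log2 enrichment over the time course.

    probe value = gene baseline + cluster amplitude(t) + polarity term
    (+δ_pol·sign on 5CDS, −δ_pol·sign on 3CDS) + overlap boost where a planted
    transcript covers the probe midpoint + N(0, σ).  Probes outside any gene
    or transcript carry pure noise.  In PolII-loss mode all signal is
    multiplied by the per-time shrinkage factor (region-specific retention
    optional) before noise is added.
    """
    if probes is None:
        probes = make_probes(cfg, ann)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    assignment = assign_probe_regions(probes, ann)

    n_probes = len(probes)
    n_times = len(cfg.time_points)
    pid_index = pd.Index(probes.probes["probe_id"])
    pid_pos = pd.Series(np.arange(n_probes), index=pid_index)

    gt = truth.table
    baseline = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, len(gt)), index=gt.index
    )
    arche = np.asarray(cfg.archetypes, dtype=float)

    signal = np.zeros((n_probes, n_times))
    region_of_probe = np.array([""] * n_probes, dtype=object)
    for _, row in assignment.iterrows():
        i = pid_pos[row["probe_id"]]
        g = row["gene_id"]
        sign = gt.at[g, "polarity_sign"]
        pol = {"5CDS": cfg.delta_pol * sign, "3CDS": -cfg.delta_pol * sign}.get(
            row["region"], 0.0
        )
        prof = baseline[g] + arche[gt.at[g, "cluster_id"]] + pol
        signal[i, :] += prof
        region_of_probe[i] = row["region"]

    # transcript-overlap occupancy: boost every probe whose midpoint a planted
    # transcript covers (the transcript is itself transcribed)
    mids = probes.midpoints().to_numpy()
    pchrom = probes.probes["chrom"].to_numpy()
    for _, t in transcripts.records.iterrows():
        sel = (pchrom == t["chrom"]) & (mids >= t["start"]) & (mids < t["end"])
        signal[sel, :] += cfg.overlap_boost

    if cfg.shrinkage is not None:
        factors = np.ones((n_probes, n_times))
        shr = np.asarray(cfg.shrinkage, dtype=float)
        factors[:] = shr[None, :]
        if cfg.region_retention:
            for region, retention in cfg.region_retention.items():
                sel = region_of_probe == region
                factors[sel, :] = shr[None, :] + (1.0 - shr[None, :]) * retention
        signal = signal * factors

    values = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    vdf = pd.DataFrame(values, index=pid_index, columns=cfg.sample_names)
    return OccupancyMatrix(probes=probes.probes.copy(), values=vdf)


def simulate_mrna(
    cfg: SimulationConfig, truth: GroundTruth, d_polii: pd.DataFrame
) -> pd.DataFrame:
    """Gene × time log2 mRNA-change matrix from the planted linear model.

    ``d_polii``: gene × sample mid-CDS ΔPolII (t − t0) from the simulated
    occupancy; the t0 column (all zeros) is carried through so mRNA columns
    align with occupancy samples.  ΔmRNA = β·ΔPolII + e·1[excess] −
    e·1[dearth] + N(0, ε-sd); when ``calibrate_r2`` is set the noise sd is
    derived per column so the population R² of ΔmRNA on ΔPolII equals it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    gt = truth.table.loc[truth.table.index.intersection(d_polii.index)]
    d = d_polii.loc[gt.index]
    offset = np.where(
        gt["planted_class"] == "excess", cfg.excess_effect,
        np.where(gt["planted_class"] == "dearth", -cfg.excess_effect, 0.0),
    )
    out = {}
    for j, col in enumerate(d.columns):
        x = d[col].to_numpy(dtype=float)
        if j == 0:
            out[col] = np.zeros(len(x))
            continue
        if cfg.calibrate_r2 is not None:
            r2 = cfg.calibrate_r2
            eps_sd = abs(cfg.beta) * np.nanstd(x) * math.sqrt(1.0 / r2 - 1.0)
        else:
            eps_sd = cfg.mrna_noise_sd
        out[col] = cfg.beta * x + offset + rng.normal(0.0, eps_sd, len(x))
    return pd.DataFrame(out, index=d.index)


@dataclass
class SyntheticStudy:
    """One complete simulated study: annotation, transcripts, probes,
    occupancy, region summary, mRNA changes and the planted ground truth."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    transcripts: TranscriptSet
    probes: ProbeSet
    occupancy: OccupancyMatrix
    assignment: pd.DataFrame
    summary: pd.DataFrame
    mrna: pd.DataFrame
    truth: GroundTruth


def generate_study(cfg: SimulationConfig, outdir=None) -> SyntheticStudy:
    """Run the full generator and (optionally) write the file bundle that the
    pipeline readers consume: genes.bed, transcripts.bed, occupancy.tsv,
    mrna.tsv, truth.tsv, config.yaml."""
    ann, transcripts, truth = generate_annotation(cfg)
    probes = make_probes(cfg, ann)
    occ = simulate_occupancy(cfg, ann, transcripts, truth, probes)
    assignment = assign_probe_regions(probes, ann)
    summary = summarize_regions(occ, assignment)

    t0 = cfg.sample_names[0]
    mid = summary.xs("midCDS", level="region")
    d_polii = mid.sub(mid[t0], axis=0)
    # genes too short for a mid-CDS window fall back to the whole-body mean
    whole = summary.groupby(level="gene_id").mean()
    d_whole = whole.sub(whole[t0], axis=0)
    d_polii = d_polii.reindex(whole.index).fillna(d_whole)
    mrna = simulate_mrna(cfg, truth, d_polii)

    study = SyntheticStudy(
        config=cfg, annotation=ann, transcripts=transcripts, probes=probes,
        occupancy=occ, assignment=assignment, summary=summary, mrna=mrna,
        truth=truth,
    )
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ann.to_bed6(outdir / "genes.bed")
        transcripts.to_bed6(outdir / "transcripts.bed")
        occ.write_tsv(outdir / "occupancy.tsv")
        from .tiling import write_mrna_matrix

        write_mrna_matrix(mrna, outdir / "mrna.tsv")
        truth.to_tsv(outdir / "truth.tsv")
        cfg.to_yaml(outdir / "config.yaml")
    return study
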