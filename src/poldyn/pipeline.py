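"""End-to-end orchestration of the occupancy-dynamics analysis.

A single YAML config drives: (optional) synthetic-study generation →
normalization → CDS granularization → polarity → transcript overlap → mRNA
excess → response groups / temporal clustering → PolII-loss diagnostics.
All outputs are flat TSVs plus a ``manifest.json`` recording parameters,
seed, software version and the headline numbers; logging goes to stderr.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import dynamics as dyn
from . import pol_loss
from .excess import MrnaExcessModel
from .overlap import TranscriptSet, overlap_table
from .polarity import compute_polarity, ordered_association
from .simulate import SimulationConfig, generate_study
from .tiling import (
    OccupancyMatrix,
    assign_probe_regions,
    ProbeSet,
    normalize_samples,
    read_annotation,
    read_mrna_matrix,
    summarize_regions,
    write_region_summary,
)

logger = logging.getLogger("poldyn")

DEFAULT_PARAMS = {
    "sample0": None,        # baseline sample; default: first column
    "sample": None,         # analysis time point; default: third column
    "mrna_col": None,       # mRNA column paired with `sample` (time map)
    "window": 80,
    "excess_threshold": 0.5,
    "twofold_threshold": 1.0,
    "lowess_span": 0.3,
    "robust_iterations": 2,
    "k": 8,
    "kmeans_restarts": 10,
    "kmeans_seed": 0,
}


@dataclasses.dataclass
class PipelineConfig:
    """Paths, analysis parameters and the output directory for one run."""

    outdir: str = "poldyn_out"
    seed: int = 0
    simulate: dict | None = None          # SimulationConfig overrides; None = read files
    genes: str | None = None
    transcripts: str | None = None
    occupancy: str | None = None
    mrna: str | None = None
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params or {})
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


class StageError(RuntimeError):
    """An identifiable pipeline stage failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require(path, stage):
    if path is None:
        raise StageError(stage, "required input path missing from config")
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"input file not found: {p}")
    return p


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory.

    Outputs are deterministic functions of the config (fixed float formats,
    no timestamps), so two runs with the same seed are byte-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params": p,
        "outputs": {},
        "stats": {},
    }

    def emit(name, fname):
        manifest["outputs"][name] = fname

    t_start = time.perf_counter()

    # --- load or simulate -------------------------------------------------
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim_cfg = SimulationConfig(**sim_kwargs)
        logger.info("simulate: n_genes=%d seed=%d", sim_cfg.n_genes, sim_cfg.seed)
        study = generate_study(sim_cfg, outdir / "inputs")
        ann, transcripts = study.annotation, study.transcripts
        occ, mrna = study.occupancy, study.mrna
    else:
        ann = read_annotation(_require(config.genes, "load"), format="bed6")
        transcripts = TranscriptSet.read_bed6(_require(config.transcripts, "load"))
        occ = OccupancyMatrix.read_tsv(_require(config.occupancy, "load"))
        mrna = read_mrna_matrix(_require(config.mrna, "load"))

    samples = occ.samples
    sample0 = p["sample0"] or samples[0]
    sample = p["sample"] or (samples[2] if len(samples) > 2 else samples[-1])
    mrna_col = p["mrna_col"] or sample

    # --- normalize + granularize -----------------------------------------
    try:
        occ = normalize_samples(occ)
    except ValueError as exc:
        raise StageError("normalize", str(exc)) from exc
    occ.write_tsv(outdir / "occupancy_normalized.tsv")
    emit("occupancy_normalized", "occupancy_normalized.tsv")

    probes = ProbeSet(probes=occ.probes)
    assignment = assign_probe_regions(probes, ann)
    summary = summarize_regions(occ, assignment)
    write_region_summary(summary, outdir / "region_summary.tsv")
    emit("region_summary", "region_summary.tsv")
    logger.info("granularize: %d probe-region assignments", len(assignment))

    # --- polarity ---------------------------------------------------------
    try:
        pol = compute_polarity(summary, sample0)
    except ValueError as exc:
        raise StageError("polarity", str(exc)) from exc
    pol.to_csv(outdir / "polarity.tsv", sep="\t", index_label="gene_id",
               float_format="%.6g")
    emit("polarity", "polarity.tsv")

    # --- overlap ----------------------------------------------------------
    ov = overlap_table(ann, transcripts)
    ov.to_csv(outdir / "overlap.tsv", sep="\t", index_label="gene_id")
    emit("overlap", "overlap.tsv")

    # --- excess -----------------------------------------------------------
    try:
        model = MrnaExcessModel.from_summaries(
            summary, mrna, sample, sample0, mrna_col=mrna_col
        )
        res = model.fit(span=p["lowess_span"],
                        robust_iterations=p["robust_iterations"],
                        threshold=p["excess_threshold"])
    except ValueError as exc:
        raise StageError("excess", str(exc)) from exc
    res.to_tsv(outdir / "excess.tsv")
    emit("excess", "excess.tsv")
    for cls in ("excess", "dearth"):
        genes = sorted(res.table.index[res.table["cls"] == cls])
        (outdir / f"genes_{cls}.txt").write_text("".join(g + "\n" for g in genes))
        emit(f"genes_{cls}", f"genes_{cls}.txt")
    means, u_stat, p_val = res.class_overlap_report(ov)
    manifest["stats"]["excess_counts"] = res.counts
    manifest["stats"]["variance_explained"] = round(res.r_squared, 6)
    manifest["stats"]["excess_overlap_p"] = None if np.isnan(p_val) else float(p_val)

    prof = ordered_association(pol, res.table["residual"], w=p["window"])
    prof.to_csv(outdir / "residual_by_polarity.tsv", sep="\t",
                float_format="%.6g")
    emit("residual_by_polarity", "residual_by_polarity.tsv")

    # --- dynamics ---------------------------------------------------------
    groups = dyn.response_groups(mrna, mrna_col, threshold=p["twofold_threshold"])
    groups.to_csv(outdir / "response_groups.tsv", sep="\t", index_label="gene_id")
    emit("response_groups", "response_groups.tsv")
    gprof = dyn.group_region_profiles(summary, groups, [sample0, sample])
    gprof.reset_index().to_csv(outdir / "group_region_profiles.tsv", sep="\t",
                               index=False, na_rep="NA", float_format="%.6g")
    emit("group_region_profiles", "group_region_profiles.tsv")

    k = min(p["k"], max(1, len(mrna.dropna()) // 10))
    cm = dyn.kmeans_profiles(mrna, k=k, seed=p["kmeans_seed"],
                             restarts=p["kmeans_restarts"])
    cm.labels.to_csv(outdir / "clusters.tsv", sep="\t", index_label="gene_id")
    emit("clusters", "clusters.tsv")
    cm.mrna_means.to_csv(outdir / "cluster_mrna_profiles.tsv", sep="\t",
                         float_format="%.6g")
    emit("cluster_mrna_profiles", "cluster_mrna_profiles.tsv")
    cp = dyn.cluster_polii_profiles(cm, summary, "midCDS", sample0)
    cp.to_csv(outdir / "cluster_polii_profiles.tsv", sep="\t", float_format="%.6g")
    emit("cluster_polii_profiles", "cluster_polii_profiles.tsv")
    manifest["stats"]["k"] = k

    # --- PolII loss -------------------------------------------------------
    dr = pol_loss.dynamic_range(occ)
    dr.spread.to_csv(outdir / "dynamic_range.tsv", sep="\t", float_format="%.6g")
    emit("dynamic_range", "dynamic_range.tsv")
    dr.histogram.to_csv(outdir / "probe_histograms.tsv", sep="\t", index=False,
                        float_format="%.6g")
    emit("probe_histograms", "probe_histograms.tsv")
    retention = []
    for region in ("5CDS", "midCDS", "3CDS"):
        rp = pol_loss.retention_profile(occ, assignment, region, samples[0],
                                        samples[-1], w=p["window"])
        rp.insert(0, "region", region)
        retention.append(rp)
    pd.concat(retention, ignore_index=True).to_csv(
        outdir / "retention_profiles.tsv", sep="\t", index=False,
        float_format="%.6g")
    emit("retention_profiles", "retention_profiles.tsv")

    logger.info("run-all finished in %.1f s", time.perf_counter() - t_start)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
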