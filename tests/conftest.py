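"""Shared fixtures: small random instances and independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from poldyn.simulate import SimulationConfig, generate_study
from poldyn.tiling import GenomeAnnotation, ProbeSet


def random_annotation(rng, n_genes=200, chrom="chrI", min_len=300, max_len=4000):
    """Non-overlapping random genes on one chromosome, both strands,
    including sub-1-kb genes."""
    records = []
    pos = int(rng.integers(0, 500))
    for i in range(n_genes):
        length = int(rng.integers(min_len, max_len))
        strand = str(rng.choice(["+", "-"]))
        records.append((f"t{i:04d}", chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(100, 800))
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GenomeAnnotation(genes=genes, chrom_sizes={chrom: pos + 1000})


def random_probes(rng, ann, spacing=250, length=60):
    rows = []
    for chrom, size in ann.chrom_sizes.items():
        for s in range(0, size - length, spacing):
            jitter = int(rng.integers(-40, 41))
            start = max(0, s + jitter)
            rows.append((f"p{chrom}_{start:07d}_{len(rows)}", chrom, start, start + length))
    return ProbeSet(probes=pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"]))


def per_bp_region_oracle(probes, ann):
    """Independent assignment oracle: label every genomic position of every
    gene by its strand-aware distance from the translation start, then look
    up each probe midpoint.  O(genome); shares no interval code with the
    implementation."""
    labels = {}  # (chrom, pos) -> list of (gene, region)
    for _, g in ann.genes.iterrows():
        length = g["end"] - g["start"]
        for pos in range(g["start"], g["end"]):
            # distance from the translation start in transcription direction
            d = pos - g["start"] if g["strand"] == "+" else g["end"] - 1 - pos
            if length > 1000:
                region = "5CDS" if d < 500 else ("3CDS" if d >= length - 500 else "midCDS")
            else:
                # midpoint split: first half of the *coordinate* interval is
                # 5CDS on + and 3CDS on -
                first_half = pos < (g["start"] + g["end"]) // 2
                if g["strand"] == "+":
                    region = "5CDS" if first_half else "3CDS"
                else:
                    region = "3CDS" if first_half else "5CDS"
            labels.setdefault((g["chrom"], pos), []).append((g["gene_id"], region))
    rows = []
    for _, p in probes.probes.iterrows():
        mid = (p["start"] + p["end"]) // 2
        for gene, region in labels.get((p["chrom"], mid), []):
            rows.append((p["probe_id"], gene, region))
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "region"])


def per_bp_overlap_oracle(gene, transcripts):
    """Set-membership overlap oracle: one Python set of covered positions per
    transcript class."""
    covered = {cls: set() for cls in ("CUT", "SUT", "ORF")}
    for _, t in transcripts.records.iterrows():
        if t["chrom"] != gene["chrom"] or t["transcript_id"] == gene["gene_id"]:
            continue
        span = set(range(t["start"], t["end"])) & set(range(gene["start"], gene["end"]))
        covered[t["tclass"]] |= span
    out = {cls: len(pos) for cls, pos in covered.items()}
    out["total"] = len(covered["CUT"] | covered["SUT"] | covered["ORF"])
    return out


@pytest.fixture(scope="session")
def study_small():
    """Default-condition synthetic study at a desk-scale gene count."""
    return generate_study(SimulationConfig(seed=101, n_genes=300))


@pytest.fixture(scope="session")
def study_noise_free():
    """Noise-free study with flat temporal profiles: planted effects exact."""
    cfg = SimulationConfig(
        seed=5, n_genes=120, noise_sd=0.0, mrna_noise_sd=0.0,
        archetypes=((0, 0, 0, 0, 0),),
    )
    return generate_study(cfg)
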