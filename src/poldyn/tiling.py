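"""Tiling-array core: annotations, probe sets, occupancy matrices, and CDS granularization.

The measurement unit is a 60-bp microarray probe tiled roughly every 250 bp,
reporting log2 IP/input PolII enrichment.  Genes are partitioned into three
windows for region-level averaging: the first 500 bp of coding sequence
(5CDS), the last 500 bp (3CDS), and whatever lies between (midCDS).  All
internal coordinates are 0-based half-open (BED convention); GFF3 input is
converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGIONS = ("5CDS", "midCDS", "3CDS")
END_WINDOW = 500  # bp defining the 5'/3' CDS windows

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class GenomeAnnotation:
    """Gene coordinates on named chromosomes.

    ``genes`` columns: gene_id, chrom, start, end, strand; 0-based half-open.
    ``chrom_sizes`` maps chromosome name to length in bp (inferred as the
    maximum gene end when not supplied).
    """

    genes: pd.DataFrame
    chrom_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes.reset_index(drop=True)[GENE_COLUMNS].copy()
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise AnnotationError(f"duplicate gene id: {dup!r}")
        bad_strand = ~g["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise AnnotationError(
                f"invalid strand for gene {g.loc[bad_strand, 'gene_id'].iloc[0]!r}"
            )
        if (g["start"] < 0).any() or (g["start"] >= g["end"]).any():
            bad = g[(g["start"] < 0) | (g["start"] >= g["end"])].iloc[0]
            raise AnnotationError(
                f"invalid interval for gene {bad['gene_id']!r}: "
                f"[{bad['start']}, {bad['end']})"
            )
        if not self.chrom_sizes:
            self.chrom_sizes = g.groupby("chrom")["end"].max().astype(int).to_dict()
        for _, row in g.iterrows():
            size = self.chrom_sizes.get(row["chrom"])
            if size is not None and row["end"] > size:
                raise AnnotationError(
                    f"gene {row['gene_id']!r} exceeds {row['chrom']} size {size}"
                )
        self.genes = g

    def __len__(self) -> int:
        return len(self.genes)

    def lengths(self) -> pd.Series:
        s = (self.genes["end"] - self.genes["start"]).astype(int)
        s.index = self.genes["gene_id"]
        return s

    def to_bed6(self, path) -> None:
        bed = pd.DataFrame(
            {
                "chrom": self.genes["chrom"],
                "start": self.genes["start"],
                "end": self.genes["end"],
                "name": self.genes["gene_id"],
                "score": 0,
                "strand": self.genes["strand"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)


def read_annotation(path, format: str = "bed6") -> GenomeAnnotation:
    """Read gene annotation from BED6 or GFF3.

    GFF3 1-based closed coordinates are converted to 0-based half-open;
    BED6 is taken as-is.  Malformed lines raise ``AnnotationError`` naming
    the line number; duplicate gene ids raise as well.
    """
    if format not in ("bed6", "gff3"):
        raise ValueError(f"unknown annotation format: {format!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "bed6":
                    chrom, start, end, name, _score, strand = fields[:6]
                    records.append(
                        (name, chrom, int(start), int(end), strand)
                    )
                else:
                    chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields[:9]
                    if ftype not in ("gene", "ORF", "CDS", "mRNA"):
                        continue
                    gid = _gff3_attribute(attrs, ("ID", "Name", "gene_id"))
                    if gid is None:
                        raise ValueError("no ID attribute")
                    records.append((gid, chrom, int(start) - 1, int(end), strand))
            except (ValueError, IndexError) as exc:
                raise AnnotationError(
                    f"{path}: malformed {format} line {lineno}: {exc}"
                ) from exc
    genes = pd.DataFrame(records, columns=GENE_COLUMNS)
    return GenomeAnnotation(genes)


def _gff3_attribute(attrs: str, keys) -> str | None:
    for item in attrs.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            if k.strip() in keys:
                return v.strip()
    return None


@dataclass
class ProbeSet:
    """Tiling-array probes: probe_id, chrom, start, end (0-based half-open)."""

    probes: pd.DataFrame
    probe_length: int = 60
    spacing: int = 250

    def __post_init__(self) -> None:
        p = self.probes.reset_index(drop=True)[["probe_id", "chrom", "start", "end"]].copy()
        if p["probe_id"].duplicated().any():
            dup = p.loc[p["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if (p["start"] < 0).any() or (p["start"] >= p["end"]).any():
            raise ValueError("probe intervals must satisfy 0 <= start < end")
        self.probes = p

    def midpoints(self) -> pd.Series:
        return ((self.probes["start"] + self.probes["end"]) // 2).astype(int)

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class OccupancyMatrix:
    """Probe-by-sample log2 enrichment with probe coordinates.

    ``probes``: DataFrame (probe_id, chrom, start, end); ``values``: DataFrame
    indexed by probe_id with one float column per sample, NaN for missing.
    """

    probes: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        if not self.values.index.equals(pd.Index(self.probes["probe_id"])):
            self.values = self.values.reindex(self.probes["probe_id"])
        self.values = self.values.astype(float)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def write_tsv(self, path, float_format: str = "%.10g") -> None:
        out = self.probes.copy()
        for col in self.values.columns:
            out[col] = self.values[col].to_numpy()
        out.to_csv(path, sep="\t", index=False, na_rep="NA",
                   float_format=float_format)

    @classmethod
    def read_tsv(cls, path) -> "OccupancyMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        probes = df[["probe_id", "chrom", "start", "end"]]
        values = df.drop(columns=["chrom", "start", "end"]).set_index("probe_id")
        return cls(probes=probes, values=values)


def read_mrna_matrix(path) -> pd.DataFrame:
    """Gene-by-sample log2 mRNA change matrix (TSV, ``gene_id`` first column)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], index_col="gene_id")


def write_mrna_matrix(mrna: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    mrna.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id",
                float_format=float_format)


def write_region_summary(summary: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a (gene_id, region)-indexed summary table as TSV."""
    summary.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA",
                                 float_format=float_format)


def read_region_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df.set_index(["gene_id", "region"])


def normalize_samples(m: OccupancyMatrix) -> OccupancyMatrix:
    """Center every sample to mean log2 enrichment zero over non-missing probes.

    Missing entries are preserved.  A sample with no observed values raises.
    """
    values = m.values.copy()
    for sample in values.columns:
        col = values[sample]
        if col.isna().all():
            raise ValueError(f"sample {sample!r} has no non-missing values")
        values[sample] = col - col.mean()
    return OccupancyMatrix(probes=m.probes.copy(), values=values)


def region_windows(start: int, end: int, strand: str) -> dict:
    """Strand-aware 5CDS/midCDS/3CDS windows of a gene body.

    Genes longer than 1 kb: first 500 bp from the translation start -> 5CDS,
    last 500 bp -> 3CDS, remainder -> midCDS.  Genes of 1 kb or less are split
    at their midpoint into 5CDS/3CDS halves (no midCDS).
    """
    length = end - start
    if length > 2 * END_WINDOW:
        if strand == "+":
            return {
                "5CDS": (start, start + END_WINDOW),
                "midCDS": (start + END_WINDOW, end - END_WINDOW),
                "3CDS": (end - END_WINDOW, end),
            }
        return {
            "5CDS": (end - END_WINDOW, end),
            "midCDS": (start + END_WINDOW, end - END_WINDOW),
            "3CDS": (start, start + END_WINDOW),
        }
    mid = (start + end) // 2
    if strand == "+":
        return {"5CDS": (start, mid), "3CDS": (mid, end)}
    return {"5CDS": (mid, end), "3CDS": (start, mid)}


def assign_probe_regions(probes: ProbeSet, ann: GenomeAnnotation) -> pd.DataFrame:
    """Map probes to (gene, region) by probe midpoint.

    A probe belongs to a gene iff its midpoint floor((start+end)/2) lies inside
    the gene body; the region is the strand-aware window containing the
    midpoint.  Probes may map to several genes (tiling is strand-blind) but to
    at most one region per gene.  Returns a DataFrame with columns
    (probe_id, gene_id, region); probes absent from it are intergenic.
    """
    mids = probes.midpoints().to_numpy()
    pids = probes.probes["probe_id"].to_numpy()
    pchrom = probes.probes["chrom"].to_numpy()

    rows = []
    for chrom, sub in ann.genes.groupby("chrom", sort=False):
        sel = pchrom == chrom
        if not sel.any():
            continue
        cmids = mids[sel]
        cpids = pids[sel]
        order = np.argsort(cmids, kind="stable")
        cmids_sorted = cmids[order]
        cpids_sorted = cpids[order]
        for _, gene in sub.iterrows():
            lo = np.searchsorted(cmids_sorted, gene["start"], side="left")
            hi = np.searchsorted(cmids_sorted, gene["end"] - 1, side="right")
            if lo >= hi:
                continue
            windows = region_windows(gene["start"], gene["end"], gene["strand"])
            for mid, pid in zip(cmids_sorted[lo:hi], cpids_sorted[lo:hi]):
                for region, (ws, we) in windows.items():
                    if ws <= mid < we:
                        rows.append((pid, gene["gene_id"], region))
                        break
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "region"])


def summarize_regions(m: OccupancyMatrix, assignment: pd.DataFrame) -> pd.DataFrame:
    """Mean log2 enrichment per (gene, region, sample).

    Arithmetic mean over assigned probes' non-missing values; a gene-region
    with no probes (or all values missing) is absent/NaN.  Returns a DataFrame
    indexed by (gene_id, region) with one column per sample.
    """
    merged = assignment.merge(
        m.values, left_on="probe_id", right_index=True, how="left"
    )
    summary = merged.groupby(["gene_id", "region"])[m.samples].mean()
    return summary


def correlate_samples(m: OccupancyMatrix, s1: str, s2: str) -> float:
    """Pearson correlation of two samples over pairwise-complete probes."""
    a = m.values[s1]
    b = m.values[s2]
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError(
            f"fewer than 3 complete probe pairs between {s1!r} and {s2!r}"
        )
    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return r
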