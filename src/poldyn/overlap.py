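"""Gene / alternative-transcript overlap scoring.

Scores each gene for overlap with noncoding or alternative transcription
units — cryptic unstable transcripts (CUTs), stable unannotated transcripts
(SUTs) and other ORFs — both over the whole gene body and restricted to the
strand-aware 3' CDS window.  Overlap is strand-agnostic: a tiling ChIP assay
cannot distinguish the orientation of PolII movement, so antisense transcripts
count.  Group comparisons use the Mann-Whitney rank-sum test, appropriate for
zero-inflated overlap-length distributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tiling import GenomeAnnotation, region_windows

TRANSCRIPT_CLASSES = ("CUT", "SUT", "ORF")


@dataclass
class TranscriptSet:
    """Alternative-transcript records: transcript_id, chrom, start, end,
    strand, tclass ∈ {CUT, SUT, ORF}."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.records.reset_index(drop=True)[
            ["transcript_id", "chrom", "start", "end", "strand", "tclass"]
        ].copy()
        bad = ~r["tclass"].isin(TRANSCRIPT_CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown transcript class {r.loc[bad, 'tclass'].iloc[0]!r}"
            )
        if (r["start"] < 0).any() or (r["start"] >= r["end"]).any():
            raise ValueError("transcript intervals must satisfy 0 <= start < end")
        self.records = r

    def __len__(self) -> int:
        return len(self.records)

    def to_bed6(self, path) -> None:
        bed = pd.DataFrame(
            {
                "chrom": self.records["chrom"],
                "start": self.records["start"],
                "end": self.records["end"],
                "name": self.records["tclass"] + "|" + self.records["transcript_id"],
                "score": 0,
                "strand": self.records["strand"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bed6(cls, path) -> "TranscriptSet":
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        tclass = bed["name"].str.split("|").str[0]
        tid = bed["name"].str.split("|").str[1].fillna(bed["name"])
        return cls(
            records=pd.DataFrame(
                {
                    "transcript_id": tid,
                    "chrom": bed["chrom"],
                    "start": bed["start"],
                    "end": bed["end"],
                    "strand": bed["strand"],
                    "tclass": tclass,
                }
            )
        )


def _union_coverage(intervals, lo: int, hi: int) -> int:
    """bp of [lo, hi) covered by the union of the intervals."""
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in intervals if max(s, lo) < min(e, hi)
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def overlap_lengths(gene, ts: TranscriptSet) -> dict:
    """Overlap (bp) of a gene body with each transcript class and with the
    union across classes, self-records excluded.

    ``gene``: mapping with gene_id, chrom, start, end.  Returns
    ``{"CUT": bp, "SUT": bp, "ORF": bp, "total": bp}`` where total is union
    coverage over the whole gene body (never double-counts a base covered by
    transcripts of several classes).
    """
    recs = ts.records
    sub = recs[
        (recs["chrom"] == gene["chrom"])
        & (recs["transcript_id"] != gene["gene_id"])
    ]
    out = {}
    all_iv = []
    for cls in TRANSCRIPT_CLASSES:
        iv = list(
            zip(sub.loc[sub["tclass"] == cls, "start"],
                sub.loc[sub["tclass"] == cls, "end"])
        )
        out[cls] = _union_coverage(iv, gene["start"], gene["end"])
        all_iv.extend(iv)
    out["total"] = _union_coverage(all_iv, gene["start"], gene["end"])
    return out


def has_3prime_overlap(gene, ts: TranscriptSet) -> dict:
    """Per-class flag: does any non-self transcript of that class overlap the
    gene's strand-aware 3' CDS window (last 500 bp; midpoint half if < 1 kb)?"""
    w3 = region_windows(gene["start"], gene["end"], gene["strand"])["3CDS"]
    recs = ts.records
    sub = recs[
        (recs["chrom"] == gene["chrom"])
        & (recs["transcript_id"] != gene["gene_id"])
    ]
    out = {}
    for cls in TRANSCRIPT_CLASSES:
        iv = zip(sub.loc[sub["tclass"] == cls, "start"],
                 sub.loc[sub["tclass"] == cls, "end"])
        out[cls] = any(max(s, w3[0]) < min(e, w3[1]) for s, e in iv)
    return out


def overlap_table(ann: GenomeAnnotation, ts: TranscriptSet) -> pd.DataFrame:
    """Per-gene overlap summary: bp by class, total union bp, and 3'-overlap
    flags by class.  Indexed by gene_id."""
    rows = []
    for _, gene in ann.genes.iterrows():
        lens = overlap_lengths(gene, ts)
        flags = has_3prime_overlap(gene, ts)
        rows.append(
            {
                "gene_id": gene["gene_id"],
                **{f"{c}_bp": lens[c] for c in TRANSCRIPT_CLASSES},
                "total_bp": lens["total"],
                **{f"has3_{c}": flags[c] for c in TRANSCRIPT_CLASSES},
                "has3_any": any(flags.values()),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _midrank_u(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a, with mid-rank ties."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def rank_sum_test(a, b, alternative: str = "two-sided"):
    """Mann-Whitney rank-sum test with mid-rank ties.

    Exact p by full enumeration of rank assignments when n1 + n2 <= 10,
    otherwise the normal approximation with tie and continuity corrections.
    Returns ``(U, p)`` with U the statistic of sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        # every pooled value tied: no evidence either way
        return float(len(a) * len(b) / 2.0), 1.0
    if len(a) + len(b) <= 10:
        return _exact_rank_sum(a, b, alternative)
    res = stats.mannwhitneyu(a, b, alternative=alternative,
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _exact_rank_sum(a, b, alternative):
    u_obs = _midrank_u(a, b)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    n1 = len(a)
    us = []
    for comb in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        us.append(_midrank_u(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    if alternative == "less":
        p = p_le
    elif alternative == "greater":
        p = p_ge
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(u_obs), float(p)


def overlap_ecdf(groups: dict) -> pd.DataFrame:
    """Empirical CDFs of overlap lengths, one column per group, evaluated on
    the pooled sorted support (column ``length``)."""
    if not groups:
        raise ValueError("at least one group is required")
    support = np.unique(np.concatenate([np.asarray(v, dtype=float) for v in groups.values()]))
    out = {"length": support}
    for name, vals in groups.items():
        vals = np.sort(np.asarray(vals, dtype=float))
        out[name] = np.searchsorted(vals, support, side="right") / len(vals)
    return pd.DataFrame(out)
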