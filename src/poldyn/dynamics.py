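"""Stress-response grouping and temporal clustering.

Genes are partitioned into activated / repressed / unchanged by a two-fold
(|log2| >= 1) mRNA-change rule, and their 5'/mid/3' CDS PolII profiles
compared before and after stress.  mRNA time courses are clustered with
Euclidean k-means (k = 8 by default) and each cluster's mean mRNA profile is
matched against its members' mean t0-subtracted PolII profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

RESPONSE_GROUPS = ("activated", "repressed", "unchanged")


def response_groups(mrna: pd.DataFrame, sample: str, threshold: float = 1.0) -> pd.Series:
    """Three-way partition by log2 mRNA change at one time point.

    activated ⇔ change >= +threshold; repressed ⇔ change <= −threshold
    (boundaries inclusive: "at least two-fold"); else unchanged.
    """
    if sample not in mrna.columns:
        raise KeyError(f"sample {sample!r} not in mRNA matrix")
    x = mrna[sample]
    grp = pd.Series(
        np.where(x >= threshold, "activated",
                 np.where(x <= -threshold, "repressed", "unchanged")),
        index=mrna.index, name="group",
    )
    grp[x.isna()] = "unchanged"
    return grp


def group_region_profiles(
    summary: pd.DataFrame, groups: pd.Series, samples
) -> pd.DataFrame:
    """Mean 5CDS/midCDS/3CDS occupancy per response group at chosen samples.

    Returns a DataFrame indexed by (group, region) with one column per
    sample; empty groups are skipped with a warning.
    """
    joined = summary.reset_index().merge(
        groups.rename("group"), left_on="gene_id", right_index=True, how="inner"
    )
    present = set(joined["group"])
    for g in set(groups.unique()) - present:
        warnings.warn(f"group {g!r} has no genes with region summaries; skipped",
                      stacklevel=2)
    return joined.groupby(["group", "region"])[list(samples)].mean()


@dataclass
class ClusterModel:
    """k-means clustering of mRNA time courses.

    ``labels``: per-gene cluster id in 1..k (1 = largest cluster);
    ``mrna_means``: cluster × time mean profiles; ``inertia``: within-cluster
    sum of squares of the best run.
    """

    k: int
    labels: pd.Series
    mrna_means: pd.DataFrame
    inertia: float
    n_dropped: int

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def kmeans_profiles(
    mrna: pd.DataFrame, k: int = 8, seed: int = 0, restarts: int = 10
) -> ClusterModel:
    """Euclidean k-means on mRNA log2-change profiles.

    k-means++ initialization, best of ``restarts`` runs, deterministic under a
    fixed seed.  Rows with missing values are dropped (counted and logged).
    Cluster ids are renumbered 1..k in decreasing-size order so runs are
    comparable.
    """
    complete = mrna.dropna()
    n_dropped = len(mrna) - len(complete)
    if n_dropped:
        logger.info("kmeans_profiles: dropped %d rows with missing values", n_dropped)
    if k > len(complete):
        raise ValueError(f"k={k} exceeds the {len(complete)} complete rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    raw = km.fit_predict(complete.to_numpy(dtype=float))
    # canonicalize: 1 = largest cluster; ties broken by original label
    counts = pd.Series(raw).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=complete.index, name="cluster")
    means = complete.groupby(labels).mean()
    means.index.name = "cluster"
    return ClusterModel(k=k, labels=labels, mrna_means=means,
                        inertia=float(km.inertia_), n_dropped=n_dropped)


def cluster_polii_profiles(
    model: ClusterModel, summary: pd.DataFrame, region: str, sample0: str
) -> pd.DataFrame:
    """Per-cluster mean t0-subtracted PolII time course for one region.

    For each cluster member with a non-missing summary in ``region``, the
    profile is (value at t − value at t0); cluster profiles are member means.
    """
    if region not in ("5CDS", "midCDS", "3CDS"):
        raise ValueError(f"unknown region {region!r}")
    reg = summary.xs(region, level="region")
    delta = reg.sub(reg[sample0], axis=0)
    joined = delta.join(model.labels, how="inner").dropna()
    prof = joined.groupby("cluster").mean()
    return prof
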