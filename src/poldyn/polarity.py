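"""5'/3' PolII polarity index and running-window ordered-association profiles.

Polarity is the difference of mean log2 enrichment between the 5' CDS and
3' CDS windows of a gene (equivalently, the log2 of the 5'/3' linear
enrichment ratio).  High polarity marks promoter-proximal accumulation or
premature termination; low (negative) polarity marks 3'-end occupancy, the
signature of overlapping downstream transcription.  Gene orderings by
polarity (or any other score) are profiled with centered, edge-truncated
80-gene running-window averages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 80


def compute_polarity(summary: pd.DataFrame, sample: str) -> pd.DataFrame:
    """Per-gene polarity (5CDS mean − 3CDS mean) for one sample.

    Only genes with non-missing 5CDS, midCDS and 3CDS summaries are eligible
    (genes must be long enough to carry a mid-CDS window).  Returns a
    DataFrame indexed by gene_id with columns ``polarity`` and ``rank``
    (1 = highest polarity), sorted descending; ties broken by gene id.
    """
    wide = summary[sample].unstack("region")
    for region in ("5CDS", "midCDS", "3CDS"):
        if region not in wide.columns:
            wide[region] = np.nan
    eligible = wide.dropna(subset=["5CDS", "midCDS", "3CDS"])
    if eligible.empty:
        raise ValueError(f"no eligible genes for sample {sample!r}")
    pol = (eligible["5CDS"] - eligible["3CDS"]).rename("polarity")
    table = pol.to_frame()
    # descending polarity, ties broken lexicographically by gene id
    order = np.lexsort((table.index.to_numpy(), -table["polarity"].to_numpy()))
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def running_window_mean(values, w: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered running-window mean with edge truncation.

    Output i is the mean of the values in a window of nominal width ``w``
    centered on i, truncated at the series ends; for even ``w`` the extra
    element is taken from the left.  Missing values are excluded from each
    window's mean.  Same length as the input.
    """
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window=w, center=True, min_periods=1).mean().to_numpy()


def ordered_association(order, values: pd.Series, w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Running-window profile of a per-gene quantity along a gene ordering.

    ``order``: a polarity table (ranked index) or any sequence of gene ids in
    the desired order.  Genes without a value are dropped before windowing.
    Returns a DataFrame (gene_id, value, windowed) in the given order.
    """
    if isinstance(order, pd.DataFrame):
        gene_order = list(order.index)
    else:
        gene_order = list(order)
    values = values.dropna()
    kept = [g for g in gene_order if g in values.index]
    if len(kept) < w / 4:
        warnings.warn(
            f"only {len(kept)} genes carry a value for a window of {w}; "
            "profile will be noisy",
            stacklevel=2,
        )
    v = values.loc[kept].to_numpy(dtype=float)
    return pd.DataFrame(
        {"gene_id": kept, "value": v, "windowed": running_window_mean(v, w)}
    ).set_index("gene_id")
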