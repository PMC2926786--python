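"""mRNA excess per PolII change: LOWESS fit, residual classes, diagnostics.

The central question: when a gene's PolII occupancy changes under stress, how
much mRNA change does that buy?  A LOWESS curve of log2 mRNA change on log2
mid-CDS PolII change defines the typical yield; genes whose residual exceeds
+0.5 log2 produce *excess* mRNA per PolII change, genes below −0.5 a *dearth*.
Excess genes are then compared with the rest for overlap with noncoding
transcription.

Organised as a statsmodels-style model/results pair:

>>> res = MrnaExcessModel(d_polii, d_mrna).fit()
>>> res.table.head(); res.counts; res.r_squared; print(res.summary())
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .overlap import rank_sum_test

EXCESS_CLASSES = ("excess", "typical", "dearth")
DEFAULT_SPAN = 0.3
DEFAULT_ROBUST_ITERATIONS = 2
DEFAULT_THRESHOLD = 0.5


def compute_deltas(
    summary: pd.DataFrame,
    mrna: pd.DataFrame,
    sample: str,
    sample0: str,
    mrna_col: str | None = None,
    mrna_col0: str | None = None,
) -> pd.DataFrame:
    """Per-gene ΔPolII (mid-CDS, sample − sample0) and matched ΔmRNA.

    The mRNA matrix holds log2 changes versus the unstressed baseline, so by
    default ΔmRNA is simply its ``mrna_col`` column (``mrna_col`` defaults to
    ``sample``, accommodating time-point maps such as a 15-minute array paired
    with a 20-minute mRNA column); pass ``mrna_col0`` to difference two mRNA
    columns instead.  Genes missing the mid-CDS summary at either time are
    dropped.  Returns a DataFrame (d_polii, d_mrna) indexed by gene_id.
    """
    mid = summary.xs("midCDS", level="region")
    d_pol = (mid[sample] - mid[sample0]).dropna()
    col = sample if mrna_col is None else mrna_col
    d_m = mrna[col]
    if mrna_col0 is not None:
        d_m = d_m - mrna[mrna_col0]
    d_m = d_m.dropna()
    genes = d_pol.index.intersection(d_m.index)
    if len(genes) == 0:
        raise ValueError("no genes shared between PolII summary and mRNA matrix")
    return pd.DataFrame({"d_polii": d_pol.loc[genes], "d_mrna": d_m.loc[genes]})


def lowess_fit(
    x,
    y,
    span: float = DEFAULT_SPAN,
    robust_iterations: int = DEFAULT_ROBUST_ITERATIONS,
) -> np.ndarray:
    """Locally weighted linear regression of y on x, evaluated at each x.

    Tricube weights over the span·n nearest x-neighbours with the given number
    of robustifying iterations (bisquare reweighting of outliers).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError(f"need at least 10 points for a LOWESS fit, got {len(x)}")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all x values are equal")
    fitted = sm.nonparametric.lowess(
        y, x, frac=span, it=robust_iterations, return_sorted=False
    )
    return np.asarray(fitted, dtype=float)


def classify_excess(residuals, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Three-way residual classes: > +threshold → excess, < −threshold →
    dearth, else typical.  Boundaries are strict ("more than 0.5")."""
    r = np.asarray(residuals, dtype=float)
    return np.where(r > threshold, "excess", np.where(r < -threshold, "dearth", "typical"))


def variance_explained(x, y) -> float:
    """Squared Pearson correlation of ΔPolII and ΔmRNA — the fraction of mRNA
    change variance accounted for by PolII change."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


class MrnaExcessModel:
    """Model of log2 mRNA change as a smooth function of log2 PolII change.

    Parameters
    ----------
    d_polii, d_mrna : array-like or pandas Series
        Matched per-gene changes; rows with a missing value in either are
        dropped.
    genes : sequence, optional
        Gene identifiers; taken from a Series index when available.
    """

    def __init__(self, d_polii, d_mrna, genes=None):
        if genes is None and isinstance(d_polii, pd.Series):
            genes = d_polii.index
        x = np.asarray(d_polii, dtype=float)
        y = np.asarray(d_mrna, dtype=float)
        if len(x) != len(y):
            raise ValueError("d_polii and d_mrna must have equal length")
        genes = pd.Index(genes) if genes is not None else pd.RangeIndex(len(x))
        ok = ~(np.isnan(x) | np.isnan(y))
        self.exog = x[ok]
        self.endog = y[ok]
        self.genes = genes[ok]
        self.n_dropped = int((~ok).sum())

    @classmethod
    def from_deltas(cls, deltas: pd.DataFrame) -> "MrnaExcessModel":
        """Build from a :func:`compute_deltas` table."""
        return cls(deltas["d_polii"], deltas["d_mrna"], genes=deltas.index)

    @classmethod
    def from_summaries(
        cls, summary, mrna, sample, sample0, mrna_col=None, mrna_col0=None
    ) -> "MrnaExcessModel":
        """Build directly from a region summary and an mRNA-change matrix."""
        return cls.from_deltas(
            compute_deltas(summary, mrna, sample, sample0, mrna_col, mrna_col0)
        )

    def fit(
        self,
        span: float = DEFAULT_SPAN,
        robust_iterations: int = DEFAULT_ROBUST_ITERATIONS,
        threshold: float = DEFAULT_THRESHOLD,
    ) -> "MrnaExcessResults":
        fitted = lowess_fit(self.exog, self.endog, span, robust_iterations)
        return MrnaExcessResults(self, fitted, span, robust_iterations, threshold)


class MrnaExcessResults:
    """Fitted LOWESS curve, residuals and excess/typical/dearth classes."""

    def __init__(self, model, fitted, span, robust_iterations, threshold):
        self.model = model
        self.span = span
        self.robust_iterations = robust_iterations
        self.threshold = threshold
        residual = model.endog - fitted
        self.table = pd.DataFrame(
            {
                "d_polii": model.exog,
                "d_mrna": model.endog,
                "fitted": fitted,
                "residual": residual,
                "cls": classify_excess(residual, threshold),
            },
            index=pd.Index(model.genes, name="gene_id"),
        )

    @property
    def nobs(self) -> int:
        return len(self.table)

    @property
    def counts(self) -> dict:
        c = self.table["cls"].value_counts()
        return {k: int(c.get(k, 0)) for k in EXCESS_CLASSES}

    @property
    def r_squared(self) -> float:
        return variance_explained(self.model.exog, self.model.endog)

    def gene_classes(self) -> pd.Series:
        return self.table["cls"]

    def class_overlap_report(self, overlaps: pd.DataFrame):
        """Mean total transcript overlap per residual class, plus a rank-sum
        test of excess genes against everyone else.

        ``overlaps``: per-gene table with a ``total_bp`` column (see
        :func:`poldyn.overlap.overlap_table`).  Returns ``(means, U, p)``;
        when a class is empty the test is skipped with a warning and
        ``(means, nan, nan)`` is returned.
        """
        joined = self.table.join(overlaps["total_bp"], how="inner")
        means = joined.groupby("cls")["total_bp"].mean().reindex(EXCESS_CLASSES)
        exc = joined.loc[joined["cls"] == "excess", "total_bp"].to_numpy()
        rest = joined.loc[joined["cls"] != "excess", "total_bp"].to_numpy()
        if len(exc) == 0 or len(rest) == 0:
            warnings.warn("empty class: excess-vs-rest comparison skipped", stacklevel=2)
            return means, float("nan"), float("nan")
        u, p = rank_sum_test(exc, rest)
        return means, u, p

    def summary(self) -> str:
        c = self.counts
        lines = [
            "mRNA excess per PolII change (LOWESS residual classification)",
            "=" * 62,
            f"Genes:               {self.nobs}",
            f"LOWESS span:         {self.span}   robust iterations: {self.robust_iterations}",
            f"Residual threshold:  +/-{self.threshold} log2",
            f"Variance explained (R^2, Pearson): {self.r_squared:.3f}",
            "-" * 62,
            f"  excess  (residual > +{self.threshold}): {c['excess']:6d}",
            f"  typical                  : {c['typical']:6d}",
            f"  dearth  (residual < -{self.threshold}): {c['dearth']:6d}",
            "=" * 62,
        ]
        return "\n".join(lines)

    def to_tsv(self, path, float_format: str = "%.6g") -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id",
                          float_format=float_format)
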