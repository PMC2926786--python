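"""LOWESS mRNA-excess model: deltas, fit, classification, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from poldyn.excess import (
    MrnaExcessModel,
    classify_excess,
    compute_deltas,
    lowess_fit,
    variance_explained,
)


def toy_summary(genes, mid_t0, mid_t):
    idx = pd.MultiIndex.from_tuples(
        [(g, "midCDS") for g in genes], names=["gene_id", "region"])
    return pd.DataFrame({"t0": mid_t0, "t1": mid_t}, index=idx)


class TestComputeDeltas:
    def test_subtraction(self):
        s = toy_summary(["g"], [0.5], [1.5])
        mrna = pd.DataFrame({"t1": [2.0]}, index=pd.Index(["g"], name="gene_id"))
        d = compute_deltas(s, mrna, "t1", "t0")
        assert d.loc["g", "d_polii"] == pytest.approx(1.0)
        assert d.loc["g", "d_mrna"] == pytest.approx(2.0)

    def test_same_time_all_zero(self):
        s = toy_summary(["a", "b"], [0.5, 1.0], [1.5, 0.2])
        mrna = pd.DataFrame({"t0": [0.0, 0.0]}, index=pd.Index(["a", "b"], name="gene_id"))
        d = compute_deltas(s, mrna, "t0", "t0")
        assert np.allclose(d["d_polii"], 0.0)

    def test_no_shared_genes_raises(self):
        s = toy_summary(["a"], [0.0], [1.0])
        mrna = pd.DataFrame({"t1": [1.0]}, index=pd.Index(["z"], name="gene_id"))
        with pytest.raises(ValueError):
            compute_deltas(s, mrna, "t1", "t0")

    def test_matches_recomputation_from_raw_probes(self, study_small):
        s = study_small
        sam = s.config.sample_names
        d = compute_deltas(s.summary, s.mrna, sam[2], sam[0])
        merged = s.assignment.merge(
            s.occupancy.values, left_on="probe_id", right_index=True)
        mid = merged[merged["region"] == "midCDS"].groupby("gene_id")
        for gid in list(d.index)[:50]:
            grp = mid.get_group(gid)
            expected = grp[sam[2]].mean() - grp[sam[0]].mean()
            assert d.loc[gid, "d_polii"] == pytest.approx(expected)


def tricube_local_linear(x, y, span):
    """Independent single-pass local-linear oracle with tricube weights."""
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.sort(d)[k - 1]
        w = np.clip(1 - (d / max(h, 1e-12)) ** 3, 0, 1) ** 3
        X = np.column_stack([np.ones(n), x - x[i]])
        W = np.diag(w)
        beta = np.linalg.lstsq(W @ X, W @ y, rcond=None)[0]
        fitted[i] = beta[0]
    return fitted


class TestLowess:
    def test_reproduces_a_line(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-3, 3, 80)
        y = 2.0 * x - 1.0
        assert np.allclose(lowess_fit(x, y, span=0.5), y, atol=1e-8)

    def test_recovers_smooth_curve(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(-1, 1, 200))
        y = x**2
        fitted = lowess_fit(x, y, span=0.2, robust_iterations=0)
        assert np.max(np.abs(fitted - y)) < 0.02
        oracle = tricube_local_linear(x, y, span=0.2)
        assert np.max(np.abs(oracle - y)) < 0.02  # oracle agrees on the bound

    def test_robust_iterations_resist_outliers(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(-2, 2, 120))
        y = np.sin(x)
        clean = lowess_fit(x, y, span=0.4, robust_iterations=0)
        y_out = y.copy()
        y_out[60] += 25.0
        robust = lowess_fit(x, y_out, span=0.4, robust_iterations=2)
        plain = lowess_fit(x, y_out, span=0.4, robust_iterations=0)
        others = np.arange(120) != 60
        assert np.abs(robust - clean)[others].max() < np.abs(plain - clean)[others].max()

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(ValueError):
            lowess_fit(np.ones(50), np.arange(50.0))
        with pytest.raises(ValueError):
            lowess_fit(np.arange(5.0), np.arange(5.0))

    def test_residuals_locally_centered_on_null_data(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        y = 0.8 * x + rng.normal(0, 0.5, 2000)
        resid = y - lowess_fit(x, y)
        deciles = pd.qcut(x, 10, labels=False)
        for d in range(10):
            r = resid[deciles == d]
            assert abs(r.mean()) < 2 * r.std(ddof=1) / np.sqrt(len(r))


class TestClassify:
    def test_three_way_rule(self):
        assert list(classify_excess([0.6, -0.7, 0.1])) == ["excess", "dearth", "typical"]

    def test_boundary_is_strict(self):
        assert list(classify_excess([0.5, -0.5])) == ["typical", "typical"]

    def test_threshold_monotone(self):
        rng = np.random.default_rng(4)
        r = rng.normal(0, 1, 500)
        lo = classify_excess(r, threshold=0.3)
        hi = classify_excess(r, threshold=0.8)
        moved = (lo == "typical") & (hi != "typical")
        assert not moved.any()


class TestVarianceExplained:
    def test_perfect_line(self):
        x = np.arange(10.0)
        assert variance_explained(x, 3 * x + 1) == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(5)
        assert variance_explained(rng.normal(size=10000), rng.normal(size=10000)) < 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            variance_explained(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            variance_explained([1.0, 2.0], [1.0, 2.0])


class TestModelResults:
    def fit_small(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 300)
        y = x + rng.normal(0, 0.2, 300)
        y[:20] += 1.0
        genes = [f"g{i}" for i in range(300)]
        return MrnaExcessModel(pd.Series(x, index=genes), y).fit()

    def test_counts_and_table_shape(self):
        res = self.fit_small()
        c = res.counts
        assert sum(c.values()) == res.nobs == 300
        assert set(res.table.columns) == {"d_polii", "d_mrna", "fitted", "residual", "cls"}
        assert c["excess"] >= 15  # the 20 shifted genes dominate the class

    def test_summary_text(self):
        res = self.fit_small()
        text = res.summary()
        assert "Variance explained" in text and str(res.nobs) in text

    def test_nan_rows_dropped(self):
        x = pd.Series([1.0, np.nan] + list(np.linspace(-1, 1, 20)))
        y = pd.Series([1.0, 2.0] + list(np.linspace(-1, 1, 20)))
        m = MrnaExcessModel(x, y)
        assert m.n_dropped == 1 and len(m.exog) == 21

    def test_class_overlap_report_all_zero(self):
        res = self.fit_small()
        ov = pd.DataFrame({"total_bp": 0}, index=res.table.index)
        means, _, p = res.class_overlap_report(ov)
        assert (means.fillna(0) == 0).all() and p == 1.0

    def test_class_overlap_report_skips_empty_class(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 50)
        res = MrnaExcessModel(x, x).fit()  # perfect fit: no excess genes
        ov = pd.DataFrame({"total_bp": rng.integers(0, 100, 50)},
                          index=res.table.index)
        with pytest.warns(UserWarning):
            _, u, p = res.class_overlap_report(ov)
        assert np.isnan(p) and np.isnan(u)
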