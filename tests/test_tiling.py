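"""Annotation I/O, normalization, region assignment and summarization."""

import numpy as np
import pandas as pd
import pytest

from poldyn.tiling import (
    AnnotationError,
    GenomeAnnotation,
    OccupancyMatrix,
    ProbeSet,
    assign_probe_regions,
    correlate_samples,
    normalize_samples,
    read_annotation,
    region_windows,
    summarize_regions,
)
from conftest import per_bp_region_oracle, random_annotation, random_probes


def make_matrix(values, samples=None, chrom="chrI"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * 250,
            "end": np.arange(n) * 250 + 60,
        }
    )
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    vals = pd.DataFrame(values, index=pd.Index(probes["probe_id"]), columns=samples)
    return OccupancyMatrix(probes=probes, values=vals)


class TestReadAnnotation:
    def test_gff3_converts_to_zero_based_half_open(self, tmp_path):
        p = tmp_path / "ann.gff3"
        p.write_text("chrI\tsrc\tgene\t1001\t3000\t.\t+\t.\tID=YAL001W\n")
        ann = read_annotation(p, format="gff3")
        row = ann.genes.iloc[0]
        assert (row["start"], row["end"], row["strand"]) == (1000, 3000, "+")

    def test_bed6_taken_as_is(self, tmp_path):
        p = tmp_path / "ann.bed"
        p.write_text("chrI\t1000\t3000\tYAL001W\t0\t+\n")
        ann = read_annotation(p, format="bed6")
        row = ann.genes.iloc[0]
        assert (row["gene_id"], row["start"], row["end"], row["strand"]) == (
            "YAL001W", 1000, 3000, "+")

    def test_duplicate_gene_id_raises(self, tmp_path):
        p = tmp_path / "dup.bed"
        p.write_text(
            "chrI\t1000\t3000\tYAL001W\t0\t+\nchrI\t5000\t6000\tYAL001W\t0\t-\n")
        with pytest.raises(AnnotationError, match="YAL001W"):
            read_annotation(p, format="bed6")

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chrI\t1000\t3000\tok\t0\t+\nchrI\tnotanumber\t9\tbad\t0\t+\n")
        with pytest.raises(AnnotationError, match="line 2"):
            read_annotation(p, format="bed6")


class TestNormalize:
    def test_mean_subtraction(self):
        m = normalize_samples(make_matrix([[1.0], [2.0], [3.0]]))
        assert np.allclose(m.values["s0"], [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = normalize_samples(make_matrix(rng.normal(2, 1, (50, 3))))
        m2 = normalize_samples(m)
        assert np.allclose(m.values, m2.values, atol=1e-12)

    def test_missing_excluded_and_preserved(self):
        m = normalize_samples(make_matrix([[5.0], [np.nan], [7.0]]))
        col = m.values["s0"].to_numpy()
        assert col[0] == -1.0 and col[2] == 1.0 and np.isnan(col[1])

    def test_all_missing_sample_named_in_error(self):
        with pytest.raises(ValueError, match="s0"):
            normalize_samples(make_matrix([[np.nan], [np.nan], [np.nan]]))


class TestRegionAssignment:
    def test_plus_strand_windows(self):
        ann = GenomeAnnotation(genes=pd.DataFrame(
            [("g", "chrI", 1000, 3000, "+")],
            columns=["gene_id", "chrom", "start", "end", "strand"]))
        probes = ProbeSet(probes=pd.DataFrame(
            {"probe_id": ["a", "b", "c"], "chrom": "chrI",
             "start": [1070, 1970, 2670], "end": [1130, 2030, 2730]}))
        a = assign_probe_regions(probes, ann).set_index("probe_id")["region"]
        assert a["a"] == "5CDS" and a["b"] == "midCDS" and a["c"] == "3CDS"

    def test_minus_strand_symmetry(self):
        ann = GenomeAnnotation(genes=pd.DataFrame(
            [("g", "chrI", 1000, 3000, "-")],
            columns=["gene_id", "chrom", "start", "end", "strand"]))
        probes = ProbeSet(probes=pd.DataFrame(
            {"probe_id": ["a", "c"], "chrom": "chrI",
             "start": [1070, 2670], "end": [1130, 2730]}))
        a = assign_probe_regions(probes, ann).set_index("probe_id")["region"]
        assert a["a"] == "3CDS" and a["c"] == "5CDS"

    def test_region_windows_tile_gene_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            start = int(rng.integers(0, 10000))
            end = start + int(rng.integers(1001, 8000))
            for strand in "+-":
                w = region_windows(start, end, strand)
                ivs = sorted(w.values())
                assert ivs[0][0] == start and ivs[-1][1] == end
                assert all(ivs[i][1] == ivs[i + 1][0] for i in range(len(ivs) - 1))

    def test_matches_per_bp_oracle(self):
        rng = np.random.default_rng(42)
        ann = random_annotation(rng, n_genes=60, max_len=3000)
        probes = random_probes(rng, ann)
        got = assign_probe_regions(probes, ann)
        expected = per_bp_region_oracle(probes, ann)
        key = ["probe_id", "gene_id", "region"]
        got = got.sort_values(key).reset_index(drop=True)
        expected = expected.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expected)


class TestSummaries:
    def test_singleton_and_pair_means(self):
        m = make_matrix([[2.0], [1.0], [3.0]])
        assignment = pd.DataFrame(
            {"probe_id": ["p0", "p1", "p2"],
             "gene_id": ["g", "g", "g"],
             "region": ["5CDS", "midCDS", "midCDS"]})
        s = summarize_regions(m, assignment)
        assert s.loc[("g", "5CDS"), "s0"] == 2.0
        assert s.loc[("g", "midCDS"), "s0"] == 2.0

    def test_matches_independent_groupby(self, study_small):
        s = study_small
        merged = s.assignment.merge(
            s.occupancy.values, left_on="probe_id", right_index=True)
        for (gene, region), grp in list(merged.groupby(["gene_id", "region"]))[:200]:
            expected = grp[s.occupancy.samples].mean()
            got = s.summary.loc[(gene, region)]
            assert np.allclose(got, expected, equal_nan=True)

    def test_probe_order_permutation_invariant(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(20, 2)))
        assignment = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(20)],
             "gene_id": ["g1"] * 10 + ["g2"] * 10,
             "region": (["5CDS"] * 5 + ["3CDS"] * 5) * 2})
        s1 = summarize_regions(m, assignment)
        s2 = summarize_regions(m, assignment.sample(frac=1, random_state=9))
        pd.testing.assert_frame_equal(s1, s2)


class TestCorrelate:
    def test_self_and_sign_flip(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        m = make_matrix(np.column_stack([x, -x]), samples=["a", "b"])
        assert correlate_samples(m, "a", "a") == pytest.approx(1.0)
        assert correlate_samples(m, "a", "b") == pytest.approx(-1.0)

    def test_recovers_planted_correlation(self):
        rng = np.random.default_rng(7)
        n, rho = 2000, 0.76
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        m = make_matrix(np.column_stack([x, y]), samples=["a", "b"])
        assert correlate_samples(m, "a", "b") == pytest.approx(rho, abs=0.05)

    def test_too_few_complete_pairs(self):
        vals = np.full((5, 2), np.nan)
        vals[:2] = [[1, 2], [3, 4]]
        m = make_matrix(vals, samples=["a", "b"])
        with pytest.raises(ValueError):
            correlate_samples(m, "a", "b")
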