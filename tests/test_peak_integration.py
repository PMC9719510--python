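"""Consensus peaks, size factors, differential statistics, gene aggregations."""

import numpy as np
import pandas as pd
import pytest

from epilink.genome_model import (
    GENEBODY,
    INTERGENIC,
    PROMOTER,
    GeneModel,
    GenomicInterval,
    partition_regions,
)
from epilink.peak_integration import (
    annotate_peaks,
    build_consensus_peaks,
    gene_region_avg_log2fc,
    gene_summed_fc,
    map_counts_to_consensus,
    peak_log2fc,
    size_factors,
)


class TestConsensusPeaks:
    def test_overlap_merges_with_joint_provenance(self):
        cons = build_consensus_peaks(
            {
                "ctrl": [GenomicInterval("chr1", 100, 200)],
                "ko": [GenomicInterval("chr1", 150, 250)],
            }
        )
        assert [(p.start, p.end) for p in cons.peaks] == [(100, 250)]
        assert cons.provenance == [("ctrl", "ko")]

    def test_condition_specific_peak_kept_with_singleton_provenance(self):
        cons = build_consensus_peaks(
            {
                "ctrl": [GenomicInterval("chr1", 100, 200)],
                "ko": [GenomicInterval("chr1", 500, 600)],
            }
        )
        assert cons.provenance == [("ctrl",), ("ko",)]

    def test_idempotent_and_order_invariant(self):
        a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 300, 400)]
        b = [GenomicInterval("chr1", 50, 150)]
        c1 = build_consensus_peaks({"x": a, "y": b})
        c2 = build_consensus_peaks({"y": b, "x": a})
        assert [(p.start, p.end) for p in c1.peaks] == [(p.start, p.end) for p in c2.peaks]
        assert c1.provenance == c2.provenance
        again = build_consensus_peaks({"x": c1.peaks, "y": c1.peaks})
        assert [(p.start, p.end) for p in again.peaks] == [(p.start, p.end) for p in c1.peaks]


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_splits_geometrically(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        np.testing.assert_allclose(
            size_factors(counts), [2 ** -0.5, 2 ** 0.5], rtol=1e-12
        )

    def test_all_rows_with_zero_fall_back_to_library_size(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 40]})
        with pytest.warns(UserWarning, match="library-size"):
            f = size_factors(counts)
        expected = np.array([10.0, 40.0]) / np.sqrt(10.0 * 40.0)
        np.testing.assert_allclose(f, expected)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))


COND = {"c1": "ctrl", "c2": "ctrl", "k1": "ko", "k2": "ko"}


class TestPeakLog2fc:
    def test_equal_means_give_zero(self):
        counts = pd.DataFrame({"c1": [10], "c2": [10], "k1": [10], "k2": [10]})
        d = peak_log2fc(counts, size_factors(counts), COND, ("ctrl", "ko"))
        assert d.table["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_pseudocount_arithmetic(self):
        # normalized means 4 (ctrl) and 9 (ko), pc=1 -> log2(10/5) = 1
        counts = pd.DataFrame({"c1": [4], "c2": [4], "k1": [9], "k2": [9]})
        f = pd.Series(1.0, index=counts.columns)
        d = peak_log2fc(counts, f, COND, ("ctrl", "ko"))
        assert d.table["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_variance_guard(self):
        # identical replicate vectors within condition, different between:
        # zero-variance Welch path must not produce NaN
        counts = pd.DataFrame({"c1": [4, 7], "c2": [4, 7], "k1": [9, 7], "k2": [9, 7]})
        f = pd.Series(1.0, index=counts.columns)
        d = peak_log2fc(counts, f, COND, ("ctrl", "ko"))
        assert d.table["pvalue"].iloc[0] == 0.0  # means differ, no variance
        assert d.table["pvalue"].iloc[1] == 1.0  # identical groups

    def test_single_replicate_uses_fold_change_proxy(self):
        counts = pd.DataFrame({"c1": [4, 10], "k1": [9, 11]})
        f = pd.Series(1.0, index=counts.columns)
        d = peak_log2fc(counts, f, {"c1": "ctrl", "k1": "ko"}, ("ctrl", "ko"))
        assert d.pvalue_proxy
        assert d.table["pvalue"].isna().all()
        assert bool(d.table["significant_up"].iloc[0])  # log2fc = 1 >= 1
        assert not bool(d.table["significant_up"].iloc[1])

    def test_missing_condition_errors(self):
        counts = pd.DataFrame({"c1": [4], "c2": [5]})
        with pytest.raises(ValueError):
            peak_log2fc(counts, pd.Series(1.0, index=counts.columns),
                        {"c1": "ctrl", "c2": "ctrl"}, ("ctrl", "ko"))

    def test_sample_scaling_invariance(self):
        """Scaling one sample's counts by k scales its size factor by k
        (relative to the others) and leaves every log2fc unchanged.
        Exact at pseudocount 0: the pseudocount deliberately breaks strict
        scale invariance for near-zero counts."""
        rng = np.random.default_rng(21)
        counts = pd.DataFrame(
            rng.poisson(50, size=(60, 4)) + 1, columns=list(COND)
        )
        f0 = size_factors(counts)
        d0 = peak_log2fc(counts, f0, COND, ("ctrl", "ko"), pseudocount=0.0)
        scaled = counts.copy()
        scaled["k1"] = scaled["k1"] * 3
        f1 = size_factors(scaled)
        d1 = peak_log2fc(scaled, f1, COND, ("ctrl", "ko"), pseudocount=0.0)
        assert f1["k1"] / f0["k1"] == pytest.approx(3.0 * f1["c1"] / f0["c1"])
        np.testing.assert_allclose(d1.table["log2fc"], d0.table["log2fc"], rtol=1e-9)

    def test_bh_adjustment_is_monotone_and_dominates_p(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(40, size=(40, 4)) + 1, columns=list(COND))
        d = peak_log2fc(counts, size_factors(counts), COND, ("ctrl", "ko"))
        assert (d.table["padj"] >= d.table["pvalue"] - 1e-15).all()


def annotation_frame(rows):
    return pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "region_class", "gene_id"]
    ).set_index("peak_id")


class TestGeneSummedFc:
    def test_summed_counts_worked_example(self):
        # peaks with ko sums {4, 6} and ctrl sums {2, 3}, pc=0 -> log2(10/5) = 1
        counts = pd.DataFrame({"c1": [2, 3], "k1": [4, 6]}, index=["p1", "p2"])
        ann = annotation_frame(
            [("p1", "chr1", 0, 10, PROMOTER, "g"), ("p2", "chr1", 20, 30, GENEBODY, "g")]
        )
        f = pd.Series(1.0, index=counts.columns)
        out = gene_summed_fc(ann, counts, f, {"c1": "ctrl", "k1": "ko"},
                             ("ctrl", "ko"), pseudocount=0.0)
        assert out.loc[out.gene_id == "g", "summed_log2fc"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out.gene_id == "g", "n_peaks"].iloc[0] == 2

    def test_single_peak_reduces_to_peak_statistic(self):
        counts = pd.DataFrame({"c1": [5], "k1": [20]}, index=["p1"])
        ann = annotation_frame([("p1", "chr1", 0, 10, PROMOTER, "g")])
        f = pd.Series(1.0, index=counts.columns)
        out = gene_summed_fc(ann, counts, f, {"c1": "ctrl", "k1": "ko"},
                             ("ctrl", "ko"), pseudocount=0.0)
        assert out["summed_log2fc"].iloc[0] == pytest.approx(np.log2(20 / 5))

    def test_all_zero_counts_with_pseudocount_give_zero(self):
        counts = pd.DataFrame({"c1": [0], "k1": [0]}, index=["p1"])
        ann = annotation_frame([("p1", "chr1", 0, 10, GENEBODY, "g")])
        f = pd.Series(1.0, index=counts.columns)
        out = gene_summed_fc(ann, counts, f, {"c1": "ctrl", "k1": "ko"},
                             ("ctrl", "ko"), pseudocount=1.0)
        assert out["summed_log2fc"].iloc[0] == pytest.approx(0.0)

    def test_intergenic_peaks_do_not_enter_the_locus(self):
        counts = pd.DataFrame({"c1": [5, 5], "k1": [20, 999]}, index=["p1", "p2"])
        ann = annotation_frame(
            [("p1", "chr1", 0, 10, PROMOTER, "g"), ("p2", "chr1", 50, 60, INTERGENIC, "g")]
        )
        f = pd.Series(1.0, index=counts.columns)
        out = gene_summed_fc(ann, counts, f, {"c1": "ctrl", "k1": "ko"},
                             ("ctrl", "ko"), pseudocount=0.0)
        assert out["n_peaks"].iloc[0] == 1
        assert out["summed_log2fc"].iloc[0] == pytest.approx(2.0)


class TestGeneRegionAvg:
    def make_diff(self, log2fc, ids):
        table = pd.DataFrame({"log2fc": log2fc}, index=ids)
        for col in ("pvalue", "padj"):
            table[col] = 0.5
        table["significant_up"] = False
        table["significant_down"] = False
        from epilink.peak_integration import PeakDifferential

        return PeakDifferential(table=table, alpha=0.05, conditions=("ctrl", "ko"))

    def test_mean_of_peak_log2fc_per_class(self):
        diff = self.make_diff([1.0, 3.0, -0.5], ["p1", "p2", "p3"])
        ann = annotation_frame(
            [
                ("p1", "chr1", 0, 10, PROMOTER, "g"),
                ("p2", "chr1", 20, 30, PROMOTER, "g"),
                ("p3", "chr1", 40, 50, GENEBODY, "g"),
            ]
        )
        out = gene_region_avg_log2fc(diff, ann).set_index("region_class")
        assert out.loc[PROMOTER, "avg_log2fc"] == pytest.approx(2.0)
        assert out.loc[GENEBODY, "avg_log2fc"] == pytest.approx(-0.5)
        assert out.loc[PROMOTER, "n_peaks"] == 2

    def test_absent_classes_are_absent_not_zero(self):
        diff = self.make_diff([0.7], ["p1"])
        ann = annotation_frame([("p1", "chr1", 0, 10, INTERGENIC, "g")])
        out = gene_region_avg_log2fc(diff, ann)
        assert set(out["region_class"]) == {INTERGENIC}

    def test_alternative_reading_log2_of_mean_ratio(self):
        diff = self.make_diff([0.0, 2.0], ["p1", "p2"])
        ann = annotation_frame(
            [("p1", "chr1", 0, 10, PROMOTER, "g"), ("p2", "chr1", 20, 30, PROMOTER, "g")]
        )
        out = gene_region_avg_log2fc(diff, ann, mode="log2_mean_ratio")
        # mean of linear folds (1 + 4)/2 = 2.5
        assert out["avg_log2fc"].iloc[0] == pytest.approx(np.log2(2.5))

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(33)
        classes = [PROMOTER, GENEBODY, INTERGENIC]
        for _ in range(30):
            n = int(rng.integers(5, 60))
            ids = [f"p{i}" for i in range(n)]
            log2fc = rng.normal(size=n)
            genes = [f"g{int(rng.integers(0, 6))}" for _ in range(n)]
            cls = [classes[int(rng.integers(0, 3))] for _ in range(n)]
            ann = annotation_frame(
                [(ids[i], "chr1", i * 10, i * 10 + 5, cls[i], genes[i]) for i in range(n)]
            )
            out = gene_region_avg_log2fc(self.make_diff(log2fc, ids), ann)
            # brute force: list peaks per (gene, class) and average
            expected = {}
            for i in range(n):
                expected.setdefault((genes[i], cls[i]), []).append(log2fc[i])
            assert len(out) == len(expected)
            for _, row in out.iterrows():
                vals = expected[(row["gene_id"], row["region_class"])]
                assert row["avg_log2fc"] == pytest.approx(np.mean(vals), rel=1e-12)
                assert row["n_peaks"] == len(vals)


class TestAnnotateAndMap:
    def test_intergenic_peaks_get_nearest_tss_gene(self):
        g1 = GeneModel("g1", "chr1", "+", [GenomicInterval("chr1", 50_000, 60_000)])
        g2 = GeneModel("g2", "chr1", "+", [GenomicInterval("chr1", 200_000, 210_000)])
        part = partition_regions([g1, g2], (3000, 3000))
        peaks = [GenomicInterval("chr1", 30_000, 30_500)]
        ann = annotate_peaks(peaks, part)
        assert ann["region_class"].iloc[0] == INTERGENIC
        assert ann["gene_id"].iloc[0] == "g1"
        off = annotate_peaks(peaks, part, intergenic_nearest=False)
        assert off["gene_id"].iloc[0] is None

    def test_map_counts_sums_constituents_onto_consensus(self):
        cons = build_consensus_peaks(
            {"a": [GenomicInterval("chr1", 100, 300)], "b": [GenomicInterval("chr1", 250, 400)]}
        )
        raw = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [100, 250, 900],
                "end": [300, 400, 950],
                "s1": [5, 7, 100],
            },
            index=["x", "y", "z"],
        )
        with pytest.warns(UserWarning, match="no consensus"):
            mapped = map_counts_to_consensus(raw, cons)
        assert mapped.loc["chr1:100-400", "s1"] == 12
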