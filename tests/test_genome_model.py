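"""Annotation parsing, interval merging, and region assignment."""

import io

import numpy as np
import pytest

from epilink.genome_model import (
    GENEBODY,
    INTERGENIC,
    PROMOTER,
    AnnotationParseError,
    GeneModel,
    GenomicInterval,
    assign_region,
    merge_intervals,
    partition_regions,
    read_gene_annotation,
)
from tests.conftest import random_toy_genome

GTF_SMALL = """\
chr1\tsrc\tgene\t1001\t8000\t.\t+\t.\tgene_id "gX"; gene_biotype "protein_coding";
chr1\tsrc\texon\t1001\t1100\t.\t+\t.\tgene_id "gX"; transcript_id "gX.t1";
chr1\tsrc\texon\t5001\t8000\t.\t+\t.\tgene_id "gX"; transcript_id "gX.t1";
chr1\tsrc\tfive_prime_utr\t1001\t1050\t.\t+\t.\tgene_id "gX"; transcript_id "gX.t1";
chr2\tsrc\texon\t5001\t8000\t.\t-\t.\tgene_id "gY"; transcript_id "gY.t1";
"""


class TestAnnotationParsing:
    def test_gtf_coordinates_become_zero_based_half_open(self):
        genes = {g.gene_id: g for g in read_gene_annotation(io.StringIO(GTF_SMALL))}
        gx = genes["gX"]
        assert gx.exons[0].start == 1000 and gx.exons[0].end == 1100
        assert gx.biotype == "protein_coding"
        assert gx.utr5[0].start == 1000 and gx.utr5[0].end == 1050

    def test_minus_strand_tss_is_span_end(self):
        genes = {g.gene_id: g for g in read_gene_annotation(io.StringIO(GTF_SMALL))}
        gy = genes["gY"]
        assert gy.tss == 8000 and gy.tes == 5000

    def test_empty_stream_gives_empty_collection(self):
        assert read_gene_annotation(io.StringIO("")) == []
        assert read_gene_annotation(io.StringIO("# only a comment\n")) == []

    def test_malformed_line_error_names_line_number(self):
        bad = GTF_SMALL + "chr1\tonly\tthree\n"
        with pytest.raises(AnnotationParseError, match="line 6"):
            read_gene_annotation(io.StringIO(bad), fmt="gtf")

    def test_inverted_record_rejected_with_warning(self):
        bad = 'chr1\tsrc\texon\t500\t100\t.\t+\t.\tgene_id "gZ"; transcript_id "t";\n'
        with pytest.warns(UserWarning, match="end <= start"):
            genes = read_gene_annotation(io.StringIO(GTF_SMALL + bad))
        assert "gZ" not in {g.gene_id for g in genes}

    def test_longest_span_transcript_is_chosen(self):
        gtf = (
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "short";\n'
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "long";\n'
            'chr1\tsrc\texon\t901\t1000\t.\t+\t.\tgene_id "g"; transcript_id "long";\n'
        )
        (g,) = read_gene_annotation(io.StringIO(gtf))
        assert g.span == (100, 1000) and len(g.exons) == 2

    def test_bed12_blocks_and_utrs(self):
        # two blocks; CDS spans [150, 850): left exon piece before 150 is 5'UTR,
        # right piece after 850 is 3'UTR on + strand
        bed = "chr1\t100\t1000\tmyGene\t0\t+\t150\t850\t0\t2\t200,300\t0,600\n"
        (g,) = read_gene_annotation(io.StringIO(bed))
        assert g.gene_id == "myGene"
        assert [(e.start, e.end) for e in g.exons] == [(100, 300), (700, 1000)]
        assert [(u.start, u.end) for u in g.utr5] == [(100, 150)]
        assert [(u.start, u.end) for u in g.utr3] == [(850, 1000)]
        assert g.tss == 100 and g.tes == 1000

    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)


class TestMergeIntervals:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(0, 10), (5, 15)], [(0, 15)]),
            ([(0, 10), (10, 20)], [(0, 20)]),  # bookended intervals merge
            ([(0, 10), (11, 20)], [(0, 10), (11, 20)]),
            ([], []),
        ],
    )
    def test_examples(self, pairs, expected):
        ivs = [GenomicInterval("chr1", s, e) for s, e in pairs]
        out = merge_intervals(ivs)
        assert [(iv.start, iv.end) for iv in out] == expected

    def test_matches_per_base_union_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(0, 11))
            ivs = []
            for _ in range(n):
                chrom = "chr" + str(rng.integers(1, 3))
                s = int(rng.integers(0, 990))
                e = s + int(rng.integers(1, 1000 - s + 1))
                ivs.append(GenomicInterval(chrom, s, e))
            out = merge_intervals(ivs)
            # brute-force per-base union
            truth = {(iv.chrom, b) for iv in ivs for b in range(iv.start, iv.end)}
            covered = {(o.chrom, b) for o in out for b in range(o.start, o.end)}
            assert covered == truth
            # total covered length preserved
            assert sum(o.length for o in out) == len(truth)
            # sorted, disjoint, non-bookended
            for a, b in zip(out, out[1:]):
                assert (a.chrom, a.start) <= (b.chrom, b.start)
                assert a.chrom != b.chrom or b.start > a.end


class TestRegionPartition:
    def test_promoter_window_arithmetic(self):
        g = GeneModel(
            gene_id="g",
            chrom="chr1",
            strand="+",
            exons=[GenomicInterval("chr1", 10_000, 20_000)],
        )
        part = partition_regions([g], (3000, 3000))
        assert part.promoter["g"] == [(7000, 13_000)]
        assert part.genebody["g"] == [(13_000, 20_000)]

    def test_zero_genes_leaves_only_intergenic(self):
        part = partition_regions([], (3000, 3000))
        peak = GenomicInterval("chr1", 0, 100)
        with pytest.warns(UserWarning):
            assert assign_region(peak, part) == (INTERGENIC, None)

    def test_classes_disjoint_per_gene(self, three_gene_partition):
        _, part = three_gene_partition
        for gid in part.genes:
            prom = {b for s, e in part.promoter[gid] for b in range(s, e)}
            body = {b for s, e in part.genebody[gid] for b in range(s, e)}
            assert not prom & body

    def test_minus_strand_promoter_is_downstream_shifted(self, three_gene_partition):
        _, part = three_gene_partition
        # gB: - strand, tss = 48000 -> window [48000-3000, 48000+3000)
        assert part.promoter["gB"] == [(45_000, 51_000)]


class TestAssignRegion:
    def test_promoter_hit_by_midpoint(self, three_gene_partition):
        _, part = three_gene_partition
        peak = GenomicInterval("chr1", 8900, 9100)  # midpoint 9000, gA tss 10000
        assert assign_region(peak, part) == (PROMOTER, "gA")

    def test_far_peak_is_intergenic_without_gene(self, three_gene_partition):
        _, part = three_gene_partition
        peak = GenomicInterval("chr1", 99_000, 99_500)
        assert assign_region(peak, part) == (INTERGENIC, None)

    def test_promoter_takes_precedence_over_other_genes_body(self):
        # gene A body covers 13000..30000; gene B promoter covers 19000..25000
        a = GeneModel("A", "chr1", "+", [GenomicInterval("chr1", 10_000, 30_000)])
        b = GeneModel("B", "chr1", "+", [GenomicInterval("chr1", 22_000, 40_000)])
        part = partition_regions([a, b], (3000, 3000))
        peak = GenomicInterval("chr1", 19_900, 20_100)  # midpoint 20000
        assert assign_region(peak, part) == (PROMOTER, "B")

    def test_unknown_chromosome_warns_and_is_intergenic(self, three_gene_partition):
        _, part = three_gene_partition
        with pytest.warns(UserWarning, match="absent"):
            cls, gid = assign_region(GenomicInterval("chrM", 0, 100), part)
        assert cls == INTERGENIC and gid is None

    def test_matches_bruteforce_oracle_on_random_genomes(self):
        """Explicit per-base oracle: promoter > genebody > intergenic, nearest
        TSS then lexicographic gene_id within a class."""
        rng = np.random.default_rng(7)
        total_checked = 0
        for _ in range(20):
            genes = random_toy_genome(rng, n_genes=int(rng.integers(2, 9)))
            window = (int(rng.integers(50, 300)), int(rng.integers(50, 300)))
            part = partition_regions(genes, window)
            # independent per-base class sets built straight from gene models
            prom_bases, body_bases = {}, {}
            up, down = window
            for g in genes:
                tss = g.tss
                if g.strand == "+":
                    w = set(range(max(0, tss - up), tss + down))
                else:
                    w = set(range(max(0, tss - down), tss + up))
                for u in g.utr5:
                    w |= set(range(u.start, u.end))
                span = set(range(g.span[0], g.span[1]))
                for u in g.utr3:
                    span |= set(range(u.start, u.end))
                prom_bases[g.gene_id] = w
                body_bases[g.gene_id] = span - w
            for _ in range(50):
                s = int(rng.integers(0, 5500))
                peak = GenomicInterval("chr1", s, s + int(rng.integers(1, 200)))
                mid = peak.midpoint
                hits = [g for g in genes if mid in prom_bases[g.gene_id]]
                if hits:
                    expected_cls = PROMOTER
                else:
                    hits = [g for g in genes if mid in body_bases[g.gene_id]]
                    expected_cls = GENEBODY if hits else INTERGENIC
                if hits:
                    best = min(hits, key=lambda g: (abs(mid - g.tss), g.gene_id))
                    expected = (expected_cls, best.gene_id)
                else:
                    expected = (INTERGENIC, None)
                assert assign_region(peak, part) == expected
                total_checked += 1
        assert total_checked >= 1000
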