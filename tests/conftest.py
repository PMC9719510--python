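import numpy as np
import pytest

from epilink.genome_model import GeneModel, GenomicInterval, partition_regions


@pytest.fixture
def three_gene_partition():
    """A small hand-built genome: two + strand genes and one - strand gene."""
    genes = [
        GeneModel(
            gene_id="gA",
            chrom="chr1",
            strand="+",
            exons=[GenomicInterval("chr1", 10_000, 12_000), GenomicInterval("chr1", 15_000, 20_000)],
            utr5=[GenomicInterval("chr1", 10_000, 10_200)],
            utr3=[GenomicInterval("chr1", 19_500, 20_000)],
            biotype="protein_coding",
        ),
        GeneModel(
            gene_id="gB",
            chrom="chr1",
            strand="-",
            exons=[GenomicInterval("chr1", 40_000, 43_000), GenomicInterval("chr1", 45_000, 48_000)],
            biotype="protein_coding",
        ),
        GeneModel(
            gene_id="gC",
            chrom="chr2",
            strand="+",
            exons=[GenomicInterval("chr2", 5_000, 9_000)],
            biotype="lincRNA",
        ),
    ]
    return genes, partition_regions(genes, (3000, 3000))


def random_toy_genome(rng, n_genes=8, coord_max=5000):
    """Random small single-exon genes (possibly overlapping) for oracle tests."""
    genes = []
    for i in range(n_genes):
        s = int(rng.integers(0, coord_max - 400))
        e = s + int(rng.integers(200, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"g{i}",
                chrom="chr1",
                strand=strand,
                exons=[GenomicInterval("chr1", s, e, strand)],
            )
        )
    return genes
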