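import pytest

from lmseq.models import GeneModel, GenomeAnnotation
from lmseq.synthetic_data import SimConfig, simulate_genome, simulate_sample


@pytest.fixture(scope="session")
def sim_small():
    """A 40-gene genome with one uniform sample, reused across modules."""
    cfg = SimConfig(seed=5, n_genes=40, n_contigs=2, contig_length=200_000,
                    reads_per_sample=40_000, n_rate=0.0)
    genome, truth = simulate_genome(cfg)
    sample = simulate_sample(genome, truth, 0, 0, cfg)
    return cfg, genome, truth, sample


def make_gene(gene_id="g1", contig="chr1", strand="+", exons=((0, 1000),),
              cds=None, utr5=None, utr3=None):
    """Hand-built gene model for targeted fixtures."""
    exons = tuple(tuple(e) for e in exons)
    if cds is None:
        cds = (exons[0][0], exons[-1][1])
    gene = GeneModel(gene_id=gene_id, contig=contig, strand=strand,
                     exons=exons, cds=tuple(cds), utr5=utr5, utr3=utr3)
    gene.validate()
    return gene


def make_annotation(genes, contig_length=100_000):
    contigs = {g.contig: contig_length for g in genes}
    ann = GenomeAnnotation(contigs=contigs, genes=list(genes))
    ann.validate()
    return ann
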