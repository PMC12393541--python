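import numpy as np
import pytest

from orgate.annotation import GeneModel, GenomeAnnotation


def make_gene(gene_id, start, end, strand="+", biotype="other", chrom="chr1",
              exons=None, cds=None, pseudogene=False):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=end,
        exons=exons or [(start, end)], cds=cds if cds is not None else [],
        biotype=biotype, pseudogene=pseudogene,
    )


def make_annotation(genes, chrom_lengths=None):
    ann = GenomeAnnotation(chrom_lengths=dict(chrom_lengths or {}))
    for g in genes:
        ann.add(g)
    return ann


def random_toy_annotation(rng, n_genes=12, chrom="chr1", or_prob=0.4):
    """Random non-overlapping toy genome for filter/chaining oracles."""
    genes = []
    x = int(rng.integers(0, 2000))
    for i in range(n_genes):
        length = int(rng.integers(50, 4000))
        biotype = "OR" if rng.random() < or_prob else "other"
        strand = "+" if rng.random() < 0.5 else "-"
        cds_len = int(rng.integers(20, length + 1))
        genes.append(
            make_gene(
                f"g{i}", x, x + length, strand=strand, biotype=biotype, chrom=chrom,
                cds=[(x, x + cds_len)],
            )
        )
        x += length + int(rng.integers(10, 15_000))
    return make_annotation(genes)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
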