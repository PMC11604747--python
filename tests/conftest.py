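import pytest
from hypothesis import settings

from collinearity_qc import AnnotationSet, GeneRecord, match_genes

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def make_annotation(label, genes):
    """genes: iterable of (gene_id, seq_id, start, end[, strand])."""
    records = [
        GeneRecord(seq_id=g[1], start=g[2], end=g[3], gene_id=g[0],
                   strand=g[4] if len(g) > 4 else ".", source_tag=label)
        for g in genes
    ]
    return AnnotationSet(genome_label=label, records=records)


def make_matched(ref_genes, tgt_genes):
    """Build a MatchedSet from two (gene_id, seq_id, start, end) lists."""
    return match_genes(
        make_annotation("reference", ref_genes),
        make_annotation("target", tgt_genes),
    )


@pytest.fixture
def identity_genes():
    """Two chromosomes, five genes each, 1 kb genes with 1 kb gaps."""
    genes = []
    for chrom in ("chrA", "chrB"):
        for i in range(5):
            start = 1 + i * 2000
            genes.append((f"{chrom}_g{i + 1}", chrom, start, start + 999))
    return genes


@pytest.fixture
def identity_matched(identity_genes):
    return make_matched(identity_genes, identity_genes)
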