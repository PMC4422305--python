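import numpy as np
import pytest

from cubkit import SyntheticConfig, compute_gene_metrics, generate, qc_filter
from cubkit.cds_io import CodingSequence
from cubkit.codon_metrics import CodonCountTable


def make_cds(codons, gene_id="g1", start="ATG", stop="TAA"):
    """Build a valid CDS from a list of payload codons."""
    return CodingSequence(id=gene_id, seq=start + "".join(codons) + stop)


def random_count_table(rng, n_codons=50):
    """Random codon count table drawn uniformly over the 64 codons."""
    from cubkit.genetic_code import ALL_CODONS

    draws = rng.choice(len(ALL_CODONS), size=n_codons)
    counts = {}
    for i in draws:
        counts[ALL_CODONS[i]] = counts.get(ALL_CODONS[i], 0) + 1
    return CodonCountTable(counts)


@pytest.fixture(scope="session")
def uniform_genes():
    """30 long genes with uniform synonymous usage (the no-bias limit)."""
    cfg = SyntheticConfig(n_genes=30, length_range_codons=(500, 600), seed=7)
    seqs, _ = generate(cfg)
    return [compute_gene_metrics(s) for s in seqs]


@pytest.fixture(scope="session")
def gc_biased_genes():
    """40 genes sampled at a high silent-site G+C target."""
    cfg = SyntheticConfig(n_genes=40, gc3_target=0.8, seed=3)
    seqs, _ = generate(cfg)
    return [compute_gene_metrics(s) for s in seqs]


@pytest.fixture(scope="session")
def planted_run():
    """Synthetic set with a planted optimal-codon class, QC'd and measured."""
    cfg = SyntheticConfig(
        n_genes=300, high_expr_fraction=0.1, enrichment_factor=3.0, seed=11
    )
    seqs, truth = generate(cfg)
    passed, reports = qc_filter(seqs)
    genes = [compute_gene_metrics(s) for s in passed]
    return cfg, seqs, truth, genes
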