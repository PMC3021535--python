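"""Shared fixtures: small synthetic studies and hand-built gene models."""

import dataclasses

import pytest

from hsfchip import synthetic
from hsfchip.annotation import GeneModel, GenomeAnnotation, Isoform


SMALL_CONFIG = synthetic.SyntheticConfig(
    genome_length=900_000,
    n_chromosomes=2,
    n_genes=120,
    n_segments=40,
    seed=5,
)

NOISE_FREE_CONFIG = dataclasses.replace(
    SMALL_CONFIG,
    fold_noise_sigma=0.0,
    pxbar_noise_sigma=0.0,
    expression_noise_sigma=0.0,
    rt_ratio_sigma=0.0,
    background_fp_rate=0.0,
    n_segments=60,
    seed=3,
)


@pytest.fixture(scope="session")
def small_study():
    """A modest noisy study: 40 segments over a 1.8 Mb two-chromosome genome."""
    return synthetic.simulate_study(SMALL_CONFIG)


@pytest.fixture(scope="session")
def noise_free_study():
    """Noise-free limit: every stochastic dispersion parameter zeroed."""
    return synthetic.simulate_study(NOISE_FREE_CONFIG)


def make_gene(
    gene_id: str,
    chrom: str = "chr1",
    strand: str = "+",
    start: int = 10_000,
    exon_lengths=(300, 400, 300),
    intron_lengths=(2_000, 1_500),
) -> GeneModel:
    """A single-isoform gene with the given exon/intron layout."""
    exons = []
    pos = start
    for i, elen in enumerate(exon_lengths):
        exons.append((pos, pos + elen))
        pos += elen
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    end = exons[-1][1]
    iso = Isoform(f"{gene_id}.t1", start, end, strand, exons)
    return GeneModel(gene_id, chrom, strand, [iso])


@pytest.fixture
def simple_annotation():
    """Two + strand genes and one - strand gene on a 100 kb chromosome."""
    g1 = make_gene("geneA", start=10_000)
    g2 = make_gene("geneB", start=40_000, strand="-")
    g3 = make_gene("geneC", start=70_000)
    return GenomeAnnotation([g1, g2, g3], {"chr1": 100_000})
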