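import pytest

from alu_cis_edit.simulate import SyntheticConfig, simulate_genome, simulate_sites
from alu_cis_edit.types import AluElement, EditingSite, GeneModel, GenomicInterval


@pytest.fixture
def small_config() -> SyntheticConfig:
    """Compact genome: 1 chromosome, 10 genes, 100 Alus — fast to simulate."""
    return SyntheticConfig(
        n_chroms=1, chrom_length=2_000_000, n_genes=10, n_alu_pairs_per_gene=5,
        n_sites=300, pool_size=900, seed=42,
    )


@pytest.fixture
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture
def small_sites(small_config, small_genome):
    sites, truth = simulate_sites(small_config, small_genome)
    return sites, truth


def make_site(chrom="chr1", pos=100, strand="+", **kw) -> EditingSite:
    return EditingSite(chrom=chrom, pos=pos, strand=strand, **kw)


def make_alu(chrom="chr1", start=0, end=300, strand="+", name="alu", edited=True) -> AluElement:
    return AluElement(
        interval=GenomicInterval(chrom, start, end, strand, name), family="AluSx",
        edited=edited,
    )


def make_gene(chrom="chr1", exons=((0, 1000),), strand="+", gene_id="g") -> GeneModel:
    return GeneModel(
        gene_id=gene_id, strand=strand,
        exons=[GenomicInterval(chrom, s, e, strand, gene_id) for s, e in exons],
    )
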