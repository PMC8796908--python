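"""Shared fixtures: tiny handwritten format files and one small simulated
species pair reused by integration-level tests."""
from __future__ import annotations

import textwrap

import pytest

from poolscan.synthetic_data import SimulationConfig, simulate_species_pair
from poolscan.types import PopulationMeta

TOY_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=10000>
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpoolN\tpoolS
    chr1\t101\t.\tA\tT\t55.5\tPASS\t.\tDP:AD\t60:40,20\t50:30,20
    chr1\t205\t.\tG\tC\t33\tPASS\t.\tDP:AD\t80:80,0\t90:45,45
    chr1\t900\t.\tC\tA,G\t70\tPASS\t.\tDP:AD\t30:10,15,5\t40:20,15,5
    """
)

VARSCAN_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=10000>
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Ref read depth">
    ##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt read depth">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpoolN\tpoolS
    chr1\t150\t.\tA\tG\t42\tPASS\t.\tDP:RD:AD\t60:40:20\t50:25:25
    """
)

TOY_GFF = textwrap.dedent(
    """\
    ##gff-version 3
    chr1\ttoy\tgene\t101\t200\t.\t+\t.\tID=gA
    chr1\ttoy\tmRNA\t101\t200\t.\t+\t.\tID=gA.t1;Parent=gA
    chr1\ttoy\texon\t101\t150\t.\t+\t.\tParent=gA.t1
    chr1\ttoy\tgene\t301\t600\t.\t-\t.\tID=gB
    chr1\ttoy\tgene\t1001\t1500\t.\t+\t.\tID=gC
    chr2\ttoy\tgene\t51\t250\t.\t+\t.\tID=gD
    chr2\ttoy\tgene\t400\t450\t.\t-\t.\tID=gE
    """
)

TOY_ORTHOLOGS = textwrap.dedent(
    """\
    gene_a\tgene_b\tmapping_quality\tpercent_identity\trelation
    gA\thA\t95\t98.2\tone2one
    gB\thB\t85\t92.0\tone2one
    gC\thC\t60\t95.0\tone2one
    gD\thD\t90\t89.9\tone2one
    """
)


@pytest.fixture
def toy_meta() -> list[PopulationMeta]:
    return [
        PopulationMeta("poolN", "toyfish", 30, "north"),
        PopulationMeta("poolS", "toyfish", 25, "south"),
    ]


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def varscan_vcf(tmp_path):
    p = tmp_path / "varscan.vcf"
    p.write_text(VARSCAN_VCF)
    return p


@pytest.fixture
def toy_gff(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF)
    return p


@pytest.fixture
def toy_ortholog_tsv(tmp_path):
    p = tmp_path / "orth.tsv"
    p.write_text(TOY_ORTHOLOGS)
    return p


def small_pair_cfg(species: str, seed: int) -> SimulationConfig:
    return SimulationConfig(
        species=species,
        n_chromosomes=2,
        chromosome_length=500_000,
        n_genes=200,
        gene_length=2_000,
        n_snps=8_000,
        baseline_fst=0.12,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def small_pair():
    """One modest two-species dataset with planted convergent genes."""
    return simulate_species_pair(
        small_pair_cfg("spA", 7),
        small_pair_cfg("spB", 8),
        convergent_fraction=0.02,
        seed=7,
        convergent_fst=0.6,
    )
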