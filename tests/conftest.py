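import numpy as np
import pytest

from candigene.bundle import ReferenceBundle
from candigene.models import (
    DomainHit,
    Gene,
    GeneSet,
    InteractionEdge,
    Marker,
    PhenotypeRecord,
    ProteinRecord,
)


def make_gene(gid, chrom="chr1", start=0, end=1000, strand="+", symbol=None):
    return Gene(gid, symbol or gid, chrom, start, end, strand)


@pytest.fixture
def tiny_bundle():
    """Ten genes on one chromosome, two pathways, edges, domains, markers.

    Layout (chr1): G01..G10 at starts 1000, 11000, 21000, ... (length 5000),
    alternating strands starting '+'. Pathway PW1 = {G01,G03,G05,G09};
    PW2 = {G02,G04}. Edges: G01-G02, G01-G05, G03-G04.
    G01/G03 proteins share family FA; G02 carries FB.
    """
    genes = [
        make_gene(f"G{i:02d}", start=1000 + (i - 1) * 10_000,
                  end=6000 + (i - 1) * 10_000, strand="+" if i % 2 else "-")
        for i in range(1, 11)
    ]
    proteins = [
        ProteinRecord("G01_P1", "G01", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        ProteinRecord("G03_P1", "G03", "MKTAYIAKQRQISFVKSHFSRQAPRKLEERLG"),
        ProteinRecord("G02_P1", "G02", "WWNPGRRQCCLLAMHETSWW"),
    ]
    hits = [
        DomainHit("G01_P1", "FA", 0, 20, 55.0),
        DomainHit("G03_P1", "FA", 0, 20, 52.0),
        DomainHit("G02_P1", "FB", 2, 18, 30.0),
    ]
    sets = [
        GeneSet("PW1", "pathway one", "toypath", frozenset({"G01", "G03", "G05", "G09"})),
        GeneSet("PW2", "pathway two", "toypath", frozenset({"G02", "G04"})),
    ]
    edges = [
        InteractionEdge.make("G01", "G02"),
        InteractionEdge.make("G01", "G05"),
        InteractionEdge.make("G03", "G04"),
    ]
    markers = [
        Marker("m_left", "sts", "chr1", 2000),
        Marker("m_right", "sts", "chr1", 52_000),
        Marker("snp_a", "snp", "chr1", 23_000),
        Marker("snp_b", "snp", "chr1", 43_000),
    ]
    phenotypes = [
        PhenotypeRecord("PH1", "toy disease 1", frozenset({"G01"})),
    ]
    return ReferenceBundle(
        genes=genes, proteins=proteins, domain_hits=hits, gene_sets=sets,
        edges=edges, markers=markers, phenotypes=phenotypes,
    )


@pytest.fixture
def random_gene_layout():
    """Factory for random gene layouts used by mapping-oracle tests."""

    def build(seed, n_genes=40, n_chrom=2, max_pos=400_000):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(n_genes):
            chrom = f"chr{int(rng.integers(1, n_chrom + 1))}"
            start = int(rng.integers(0, max_pos))
            length = int(rng.integers(500, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"R{i:03d}", f"R{i:03d}", chrom, start, start + length, strand))
        return genes, ReferenceBundle(genes=genes)

    return build
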