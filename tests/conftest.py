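"""Shared fixtures: a small enriched reference, gene models, call builders."""

from __future__ import annotations

import pytest

from radmut.filtering import HET, FilteredCall
from radmut.io import ReferenceGenome, VariantCall
from radmut.simulate import generate_gene_models, generate_reference


@pytest.fixture(scope="session")
def genome() -> ReferenceGenome:
    """60 kb, 2 chromosomes, AT-rich, homopolymer-enriched reference."""
    return generate_reference(
        60_000, n_chromosomes=2, gc_fraction=0.36,
        homopolymer_enrichment=2.0, seed=7,
    )


@pytest.fixture(scope="session")
def genome_with_genes():
    g = generate_reference(
        120_000, n_chromosomes=2, gc_fraction=0.40,
        homopolymer_enrichment=1.0, seed=11,
    )
    genes = generate_gene_models(g, 25, cds_length_codons=(50, 120), seed=12)
    return g, genes


def make_call(
    chrom="chr1", pos=100, ref="A", alt="T", mutant=15, depth=30,
    sample="s1", sv_end=None,
) -> VariantCall:
    return VariantCall(
        sample_id=sample, chromosome=chrom, position=pos, ref_allele=ref,
        alt_allele=alt, mutant_reads=mutant, depth=depth, sv_end=sv_end,
    )


def make_filtered(call: VariantCall, zygosity: str = HET) -> FilteredCall:
    return FilteredCall(call, zygosity)
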