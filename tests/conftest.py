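import pytest

from sbkit import simulate as sim
from sbkit.genome import (
    AnnotationSet,
    GenomicInterval,
    ReferenceGenome,
    build_ta_index,
)


@pytest.fixture(scope="session")
def small_genome() -> ReferenceGenome:
    """10 kb single-chromosome random genome."""
    return sim.random_genome({"chr1": 10_000}, seed=7)


@pytest.fixture(scope="session")
def small_ta_index(small_genome):
    return build_ta_index(small_genome)


@pytest.fixture(scope="session")
def two_chrom_genome() -> ReferenceGenome:
    return sim.random_genome({"chr1": 200_000, "chr2": 200_000}, seed=11)


@pytest.fixture(scope="session")
def two_chrom_ta_index(two_chrom_genome):
    return build_ta_index(two_chrom_genome)


@pytest.fixture()
def toy_annotation() -> AnnotationSet:
    """One gene [100, 1000) with exon [100, 300) and intron [300, 1000)."""
    return AnnotationSet(
        [
            GenomicInterval("chr1", 100, 1000, "gene", "geneA"),
            GenomicInterval("chr1", 100, 300, "exon", "geneA"),
            GenomicInterval("chr1", 300, 1000, "intron", "geneA"),
        ],
        sequence_names=["chr1"],
    )
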