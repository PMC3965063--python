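"""Shared fixtures: the generated toy world, built once per session."""

import pytest
from hypothesis import settings

from nectar.fixtures import FixtureSpec, generate_fixture_set
from nectar.pipeline import NectarIndex
from nectar.transcript_model import CodonRecord, canonical_by_gene, load_reference

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    return generate_fixture_set(tmp_path_factory.mktemp("fixtures"), FixtureSpec())


@pytest.fixture(scope="session")
def models(fixture_set):
    return load_reference(fixture_set.fasta, fixture_set.gff3)


@pytest.fixture(scope="session")
def canonical(models):
    return canonical_by_gene(models)


@pytest.fixture(scope="session")
def index(fixture_set):
    return NectarIndex.build(
        fixture_set.fasta,
        fixture_set.gff3,
        fixture_set.annotations,
        fixture_set.paralogues,
    )


def make_record(codon: str, codon_index: int = 1, strand: str = "+") -> CodonRecord:
    """A free-standing codon record on a notional plus-strand single exon.

    Genomic coordinates are 100 + CDS offset (decreasing from 300 for minus
    strand), enough for exercising the codon engine without a transcript.
    """
    from nectar.genetic_code import translate_codon

    lo = 3 * codon_index - 2
    if strand == "+":
        coords = tuple(("chrT", 100 + lo + k) for k in range(3))
    else:
        coords = tuple(("chrT", 300 - (lo + k)) for k in range(3))
    return CodonRecord(
        transcript_id="T.t1",
        gene_symbol="T",
        chrom="chrT",
        strand=strand,
        codon_index=codon_index,
        ref_codon=codon,
        ref_aa=translate_codon(codon),
        base_coords=coords,
    )
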