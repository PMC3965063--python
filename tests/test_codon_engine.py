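"""Same-codon allele expansion: partitions, HGVS names, strand and oracle."""

from collections import Counter

import pytest

from nectar.codon_engine import (
    alternative_alleles,
    enumerate_substitutions,
    hgvs_name,
    non_synonymous_substitutions,
    splice_and_retranslate,
)
from nectar.genetic_code import (
    SENSE_CODONS,
    STOP,
    Consequence,
    UnsupportedReferenceError,
)

from conftest import make_record

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def consequence_counts(codon):
    changes = enumerate_substitutions(make_record(codon))
    return Counter(c.consequence for c in changes)


@pytest.mark.parametrize(
    "codon,missense,nonsense,synonymous",
    [
        ("TTC", 8, 0, 1),  # Phe: the codon-18 worked example
        ("GAG", 7, 1, 1),  # Glu: one stop (TAG), one synonymous (GAA)
        ("TGG", 7, 2, 0),  # Trp: single-codon residue, no synonymous escape
        ("ATG", 9, 0, 0),  # Met is encoded once and no substitution reaches a stop
    ],
)
def test_partition_of_known_codons(codon, missense, nonsense, synonymous):
    counts = consequence_counts(codon)
    assert counts[Consequence.MISSENSE] == missense
    assert counts[Consequence.NONSENSE] == nonsense
    assert counts[Consequence.SYNONYMOUS] == synonymous


def test_partition_sums_to_nine_for_every_sense_codon():
    for codon in SENSE_CODONS:
        counts = consequence_counts(codon)
        assert sum(counts.values()) == 9
        # degeneracy: distinct alt residues never exceed non-synonymous alleles
        changes = non_synonymous_substitutions(make_record(codon))
        assert len({c.alt_aa for c in changes}) <= len(changes)


def test_stop_reference_codon_rejected():
    with pytest.raises(UnsupportedReferenceError):
        enumerate_substitutions(make_record("TAA"))


def test_enumeration_order_is_deterministic():
    a = [(c.offset, c.alt_base) for c in enumerate_substitutions(make_record("TTC"))]
    b = [(c.offset, c.alt_base) for c in enumerate_substitutions(make_record("TTC"))]
    assert a == b
    assert a == sorted(a)


def test_phe18_expansion_matches_reported_alleles(canonical):
    """Codon 18 of the MYL2-like fixture: the classic degenerate-Leu example."""
    rec = canonical["MYL2_FIX"].codon_record(18)
    changes = non_synonymous_substitutions(rec)
    assert len(changes) == 8
    assert all(c.consequence is Consequence.MISSENSE for c in changes)

    leu = [c for c in changes if c.alt_aa == "L"]
    assert {c.hgvs_c for c in leu} == {"c.52T>C", "c.54C>A", "c.54C>G"}
    assert len({c.cds_pos for c in leu}) == 2  # two distinct CDS positions

    by_name = {c.hgvs_c: c.alt_aa for c in changes}
    assert by_name["c.52T>A"] == "I"
    assert by_name["c.52T>G"] == "V"
    assert by_name["c.53T>A"] == "Y"
    assert by_name["c.53T>G"] == "C"
    assert by_name["c.53T>C"] == "S"
    assert {c.alt_aa for c in changes} == {"L", "I", "V", "Y", "C", "S"}


def test_glu22_expansion_has_one_nonsense(canonical):
    rec = canonical["MYL2_FIX"].codon_record(22)
    changes = non_synonymous_substitutions(rec)
    assert len(changes) == 8
    nonsense = [c for c in changes if c.consequence is Consequence.NONSENSE]
    assert len(nonsense) == 1
    assert nonsense[0].hgvs_c == "c.64G>T"
    assert nonsense[0].hgvs_p == "p.Glu22Ter"


@pytest.mark.parametrize(
    "codon_index,codon,offset,alt,expected_c,expected_p",
    [
        (18, "TTC", 1, "C", "c.52T>C", "p.Phe18Leu"),
        (18, "TTC", 3, "T", "c.54C>T", "p.Phe18Phe"),
        (22, "GAG", 1, "T", "c.64G>T", "p.Glu22Ter"),
        (1, "ATG", 2, "C", "c.2T>C", "p.Met1Thr"),
    ],
)
def test_hgvs_names(codon_index, codon, offset, alt, expected_c, expected_p):
    rec = make_record(codon, codon_index)
    assert hgvs_name(rec, offset, alt) == (expected_c, expected_p)


def test_alternative_alleles_exclude_the_anchor():
    rec = make_record("TTC", 18)
    reported = next(
        c for c in enumerate_substitutions(rec) if c.hgvs_c == "c.52T>C"
    )
    alts = alternative_alleles(reported)
    assert len(alts) == 7
    assert all((a.offset, a.alt_base) != (1, "C") for a in alts)


def test_alternative_alleles_regenerate_the_same_set():
    """Anchoring on any member recovers the codon's full non-synonymous set."""
    for codon in ("TTC", "GAG", "TGG"):
        rec = make_record(codon, 5)
        full = {(c.offset, c.alt_base) for c in non_synonymous_substitutions(rec)}
        for anchor in non_synonymous_substitutions(rec):
            regenerated = {(c.offset, c.alt_base) for c in alternative_alleles(anchor)}
            assert regenerated == full - {(anchor.offset, anchor.alt_base)}


def test_minus_strand_genomic_alleles_are_complemented(models):
    rev = next(m for m in models if m.strand == "-")
    for rec in rev.codon_records():
        for c in enumerate_substitutions(rec):
            assert c.genomic_ref == _COMPLEMENT[c.ref_base]
            assert c.genomic_alt == _COMPLEMENT[c.alt_base]


def test_splice_and_retranslate_oracle_on_all_fixture_codons(models):
    """Every predicted change equals the full-CDS retranslation, both strands."""
    for m in models:
        ref_protein = m.protein_sequence
        for rec in m.codon_records():
            for change in enumerate_substitutions(rec):
                mutant = splice_and_retranslate(m.cds_sequence, change)
                mutant = mutant[: len(ref_protein)]
                if change.consequence is Consequence.SYNONYMOUS:
                    assert mutant == ref_protein
                else:
                    i = rec.codon_index - 1
                    assert mutant[:i] == ref_protein[:i]
                    assert mutant[i] == change.alt_aa
                    assert mutant[i + 1 :] == ref_protein[i + 1 :]
                    if change.consequence is Consequence.NONSENSE:
                        assert change.alt_aa == STOP


def test_genomic_positions_come_from_the_codon_record(canonical):
    myl2 = canonical["MYL2_FIX"]
    rec = myl2.codon_record(18)
    for change in enumerate_substitutions(rec):
        assert (change.chrom, change.genomic_pos) == rec.base_coords[change.offset - 1]
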