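"""Same-codon allele expansion: the core codon-centric method.

Because the genetic code is degenerate, one amino-acid substitution can be
produced by several distinct DNA alleles, and one codon harbours up to nine
distinct single-base substitutions. This module enumerates, classifies and
names all of them for a given :class:`~nectar.transcript_model.CodonRecord`:
replace the first, second and third base of the codon one by one with each
of the three alternative bases, classify each resulting codon
(synonymous / missense / nonsense), and express each change both as HGVS
c./p. names and as a concrete forward-strand genomic variant.

Worked example (the classic one): codon 18 of the MYL2 regulatory light
chain reads TTC (Phe) at c.52-54. Its nine substitutions split into one
synonymous change (c.54C>T) and eight non-synonymous ones, of which three
distinct alleles at two CDS positions (c.52T>C, c.54C>A, c.54C>G) all give
p.Phe18Leu — so a reported Phe18Leu variant has two sibling alleles with the
identical protein consequence, plus five further reachable residues
(Ile, Val, Tyr, Cys, Ser).

Nonsense changes are retained in the expansion with an explicit consequence
label (consumers can filter); multi-base changes and indels are outside this
layer's contract. Enumeration order is deterministic: codon offset
ascending, then alternative base in A<C<G<T order.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genetic_code import (
    BASES,
    STOP,
    Consequence,
    UnsupportedReferenceError,
    classify_substitution,
    translate_codon,
)
from .transcript_model import CodonRecord, protein_pos_to_cds_span

__all__ = [
    "CodonChange",
    "enumerate_substitutions",
    "non_synonymous_substitutions",
    "alternative_alleles",
    "hgvs_name",
    "aa3",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def aa3(symbol: str) -> str:
    """Three-letter amino-acid code for a one-letter symbol ('*' -> 'Ter')."""
    return "Ter" if symbol == STOP else seq3(symbol)


@dataclass(frozen=True)
class CodonChange:
    """One single-base substitution of one codon.

    ``ref_base``/``alt_base`` are on the CDS (coding) strand; the ``genomic``
    tuple carries the same change on the forward genomic strand (complemented
    for minus-strand transcripts), ready for VCF-style comparison.
    """

    codon_record: CodonRecord
    offset: int  # 1..3, position within the codon
    ref_base: str
    alt_base: str
    alt_codon: str
    consequence: Consequence
    alt_aa: str
    chrom: str
    genomic_pos: int
    genomic_ref: str
    genomic_alt: str
    hgvs_c: str
    hgvs_p: str

    @property
    def genomic(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.genomic_pos, self.genomic_ref, self.genomic_alt)

    @property
    def cds_pos(self) -> int:
        return 3 * self.codon_record.codon_index - 3 + self.offset

    @property
    def substitution(self) -> tuple[str, int, str]:
        """(ref_aa, residue index, alt_aa) — the protein-level change."""
        rec = self.codon_record
        return (rec.ref_aa, rec.codon_index, self.alt_aa)


def hgvs_name(record: CodonRecord, offset: int, alt_base: str) -> tuple[str, str]:
    """HGVS c. and p. names of a single-base codon substitution.

    Returns e.g. ``("c.52T>C", "p.Phe18Leu")``; synonymous changes are named
    with the repeated residue (``p.Phe18Phe``), stops as ``Ter``.
    """
    lo, _ = protein_pos_to_cds_span(record.codon_index)
    cds_pos = lo + offset - 1
    ref_base = record.ref_codon[offset - 1]
    alt_codon = record.ref_codon[: offset - 1] + alt_base + record.ref_codon[offset:]
    alt_aa = translate_codon(alt_codon)
    hgvs_c = f"c.{cds_pos}{ref_base}>{alt_base}"
    hgvs_p = f"p.{aa3(record.ref_aa)}{record.codon_index}{aa3(alt_aa)}"
    return hgvs_c, hgvs_p


def _build_change(record: CodonRecord, offset: int, alt_base: str) -> CodonChange:
    ref_base = record.ref_codon[offset - 1]
    alt_codon = record.ref_codon[: offset - 1] + alt_base + record.ref_codon[offset:]
    consequence = classify_substitution(record.ref_codon, alt_codon)
    chrom, gpos = record.base_coords[offset - 1]
    if record.strand == "-":
        g_ref, g_alt = _COMPLEMENT[ref_base], _COMPLEMENT[alt_base]
    else:
        g_ref, g_alt = ref_base, alt_base
    hgvs_c, hgvs_p = hgvs_name(record, offset, alt_base)
    return CodonChange(
        codon_record=record,
        offset=offset,
        ref_base=ref_base,
        alt_base=alt_base,
        alt_codon=alt_codon,
        consequence=consequence,
        alt_aa=translate_codon(alt_codon),
        chrom=chrom,
        genomic_pos=gpos,
        genomic_ref=g_ref,
        genomic_alt=g_alt,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
    )


def enumerate_substitutions(record: CodonRecord) -> list[CodonChange]:
    """All nine single-base substitutions of a codon, classified and named.

    The output order is deterministic (offset ascending, then alt base in
    A<C<G<T order) and the consequence labels partition the nine changes.

    Raises
    ------
    UnsupportedReferenceError
        If the record's reference codon is a stop codon.
    """
    if record.ref_aa == STOP:
        raise UnsupportedReferenceError(
            f"{record.transcript_id} codon {record.codon_index}: stop reference"
        )
    changes = []
    for offset in (1, 2, 3):
        ref_base = record.ref_codon[offset - 1]
        for alt_base in BASES:
            if alt_base != ref_base:
                changes.append(_build_change(record, offset, alt_base))
    assert len(changes) == 9
    return changes


def non_synonymous_substitutions(record: CodonRecord) -> list[CodonChange]:
    """The non-synonymous subset of :func:`enumerate_substitutions`.

    Includes nonsense changes, each carrying its consequence label so
    consumers can filter.
    """
    return [
        c
        for c in enumerate_substitutions(record)
        if c.consequence is not Consequence.SYNONYMOUS
    ]


def alternative_alleles(reported: CodonChange) -> list[CodonChange]:
    """All other non-synonymous changes of the reported change's codon.

    This is the same-codon expansion of one known variant: every
    non-synonymous single-base substitution of the same codon except the
    reported change itself (compared by offset and alternative base).
    """
    return [
        c
        for c in non_synonymous_substitutions(reported.codon_record)
        if (c.offset, c.alt_base) != (reported.offset, reported.alt_base)
    ]


def splice_and_retranslate(cds_sequence: str, change: CodonChange) -> str:
    """Retranslate the full CDS with the change's alt base spliced in.

    Independent consistency check used by callers and tests: the codon-local
    classification must agree with what full-protein retranslation says.
    Returns the mutant protein (stop translated as ``*``, translation not
    truncated at internal stops).
    """
    pos = change.cds_pos
    mutated = cds_sequence[: pos - 1] + change.alt_base + cds_sequence[pos:]
    return str(Seq(mutated).translate())
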