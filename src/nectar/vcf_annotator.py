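"""On-the-fly annotation of user-supplied VCF variants.

Queries are read from a VCF 4.x file (multi-allelic records are split into
one query per alternative allele; anything that is not a single-base
substitution goes to a skipped-records report — the method only covers
single-base substitutions in protein-coding regions). Each query is then
intersected with the enriched codon-level index: a query hitting a
non-synonymous change of an annotated codon receives one hit per anchor on
that codon, labelled with the annotation section (disease / function /
paralogue) and with ``match_kind`` distinguishing a query that realizes the
anchor's reported substitution (``exact-substitution``) from one that merely
alters the same codon (``same-codon``). Synonymous, intronic and intergenic
queries yield zero hits — a valid outcome, not an error.

Queries are interpreted against canonical transcripts only, with VCF
conventions throughout: 1-based positions, forward-strand alleles
(complementation for minus-strand transcripts happened upstream when the
index was built). Output is a spreadsheet-style TSV and, optionally, a copy
of the input VCF with ``NECTAR_*`` INFO keys added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from cyvcf2 import VCF, Writer

from .annotation_store import EnrichedVariant

__all__ = [
    "QueryVariant",
    "AnnotationHit",
    "read_vcf",
    "build_variant_index",
    "annotate",
    "write_tsv",
    "write_annotated_vcf",
]

logger = logging.getLogger(__name__)

_BASES = set("ACGT")

_SECTION_BY_CLASS = {
    "reported": "disease",
    "alternative-same-codon": "disease",
    "functional-site": "function",
    "para-disease": "paralogue",
    "para-function": "paralogue",
}

_INFO_HEADERS = [
    {"ID": "NECTAR_CLASS", "Number": ".", "Type": "String",
     "Description": "Annotation class per hit (reported/alternative-same-codon/functional-site/para-disease/para-function)"},
    {"ID": "NECTAR_MATCH", "Number": ".", "Type": "String",
     "Description": "exact-substitution or same-codon, per hit"},
    {"ID": "NECTAR_ANCHOR", "Number": ".", "Type": "String",
     "Description": "Originating annotation as source|source_id, per hit"},
    {"ID": "NECTAR_HGVSP", "Number": ".", "Type": "String",
     "Description": "Protein consequence of the query allele, per hit"},
]


@dataclass(frozen=True)
class QueryVariant:
    """One single-base substitution from the user's VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    record_index: int  # 0-based input record number (pre-split)
    vcf_id: str = "."

    @property
    def genomic(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotationHit:
    """One (query, anchor) intersection."""

    query: QueryVariant
    section: str
    nectar_class: str
    match_kind: str
    source: str
    source_id: str
    gene: str
    transcript: str
    codon_index: int
    hgvs_c: str
    hgvs_p: str
    consequence: str
    description: str = ""
    sift: str | None = None
    polyphen: str | None = None


def read_vcf(path) -> tuple[list[QueryVariant], pd.DataFrame]:
    """Read queries from a VCF; split multi-allelics; report skipped alleles.

    Returns ``(queries, skipped)`` where ``skipped`` is a DataFrame with
    columns record_index, chrom, pos, ref, alt, reason.
    """
    queries: list[QueryVariant] = []
    skipped: list[dict] = []
    vcf = VCF(str(path))
    try:
        for idx, rec in enumerate(vcf):
            ref = rec.REF.upper()
            for alt in rec.ALT:
                alt = alt.upper()
                reason = None
                if alt.startswith("<") or alt in ("*", "."):
                    reason = "symbolic or missing allele"
                elif len(ref) != 1 or len(alt) != 1:
                    reason = "not a single-base substitution"
                elif ref not in _BASES or alt not in _BASES:
                    reason = "non-ACGT allele"
                elif ref == alt:
                    reason = "ref equals alt"
                if reason is None:
                    queries.append(
                        QueryVariant(
                            chrom=rec.CHROM,
                            pos=rec.POS,
                            ref=ref,
                            alt=alt,
                            record_index=idx,
                            vcf_id=rec.ID or ".",
                        )
                    )
                else:
                    skipped.append(
                        {
                            "record_index": idx,
                            "chrom": rec.CHROM,
                            "pos": rec.POS,
                            "ref": rec.REF,
                            "alt": alt,
                            "reason": reason,
                        }
                    )
    finally:
        vcf.close()
    skipped_frame = pd.DataFrame(
        skipped, columns=["record_index", "chrom", "pos", "ref", "alt", "reason"]
    )
    if len(skipped_frame):
        logger.info("skipped %d non-SNV allele(s)", len(skipped_frame))
    return queries, skipped_frame


def build_variant_index(
    enriched: list[EnrichedVariant],
) -> dict[tuple[str, int, str, str], list[EnrichedVariant]]:
    """Index enriched variants by forward-strand genomic (chrom,pos,ref,alt).

    The enrichment already enumerates *every* non-synonymous single-base
    change of every annotated codon, so membership in this index is exactly
    the condition "this query non-synonymously alters an annotated codon".
    """
    index: dict[tuple[str, int, str, str], list[EnrichedVariant]] = {}
    for ev in enriched:
        index.setdefault(ev.genomic, []).append(ev)
    return index


def annotate(
    queries: list[QueryVariant],
    enriched: list[EnrichedVariant] | dict,
) -> list[AnnotationHit]:
    """Intersect queries with the enriched index; one hit per matching anchor.

    A query on a codon carrying several anchors yields several hits (one per
    anchor, preserving source provenance); queries off any annotated codon,
    or synonymous on it, yield none.
    """
    index = enriched if isinstance(enriched, dict) else build_variant_index(enriched)
    hits: list[AnnotationHit] = []
    for q in queries:
        for ev in index.get(q.genomic, ()):
            ch = ev.change
            rec = ch.codon_record
            anchor = ev.anchor
            hits.append(
                AnnotationHit(
                    query=q,
                    section=_SECTION_BY_CLASS[ev.nectar_class],
                    nectar_class=ev.nectar_class,
                    match_kind=ev.match_kind,
                    source=anchor.source,
                    source_id=anchor.source_id,
                    gene=rec.gene_symbol,
                    transcript=rec.transcript_id,
                    codon_index=rec.codon_index,
                    hgvs_c=ch.hgvs_c,
                    hgvs_p=ch.hgvs_p,
                    consequence=ch.consequence.value,
                    description=anchor.description,
                    sift=anchor.sift,
                    polyphen=anchor.polyphen,
                )
            )
    hits.sort(
        key=lambda h: (
            h.query.record_index, h.query.chrom, h.query.pos, h.query.alt,
            h.section, h.nectar_class, h.gene, h.source, h.source_id,
        )
    )
    return hits


def hits_to_frame(hits: list[AnnotationHit]) -> pd.DataFrame:
    rows = [
        {
            "chrom": h.query.chrom,
            "pos": h.query.pos,
            "ref": h.query.ref,
            "alt": h.query.alt,
            "vcf_id": h.query.vcf_id,
            "section": h.section,
            "class": h.nectar_class,
            "match_kind": h.match_kind,
            "gene": h.gene,
            "transcript": h.transcript,
            "codon_index": h.codon_index,
            "hgvs_c": h.hgvs_c,
            "hgvs_p": h.hgvs_p,
            "consequence": h.consequence,
            "source": h.source,
            "source_id": h.source_id,
            "description": h.description,
            "sift": h.sift if h.sift else ".",
            "polyphen": h.polyphen if h.polyphen else ".",
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "vcf_id", "section", "class",
            "match_kind", "gene", "transcript", "codon_index", "hgvs_c",
            "hgvs_p", "consequence", "source", "source_id", "description",
            "sift", "polyphen",
        ],
    )


def write_tsv(hits: list[AnnotationHit], path) -> None:
    """Spreadsheet-style output: one row per hit, header always present."""
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_annotated_vcf(hits: list[AnnotationHit], vcf_in, vcf_out) -> None:
    """Copy the input VCF adding NECTAR_* INFO keys to annotated records.

    Values are comma-joined per hit (in hit order); records with no hits are
    copied unchanged. Header lines for the four keys are always declared.
    """
    by_record: dict[int, list[AnnotationHit]] = {}
    for h in hits:
        by_record.setdefault(h.query.record_index, []).append(h)
    vcf = VCF(str(vcf_in))
    for header in _INFO_HEADERS:
        vcf.add_info_to_header(header)
    writer = Writer(str(vcf_out), vcf)
    try:
        for idx, rec in enumerate(vcf):
            rec_hits = by_record.get(idx, [])
            if rec_hits:
                rec.INFO["NECTAR_CLASS"] = ",".join(h.nectar_class for h in rec_hits)
                rec.INFO["NECTAR_MATCH"] = ",".join(h.match_kind for h in rec_hits)
                rec.INFO["NECTAR_ANCHOR"] = ",".join(
                    f"{h.source}|{h.source_id}" for h in rec_hits
                )
                rec.INFO["NECTAR_HGVSP"] = ",".join(h.hgvs_p for h in rec_hits)
            writer.write_record(rec)
    finally:
        writer.close()
        vcf.close()
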