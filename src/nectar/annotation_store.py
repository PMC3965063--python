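"""Annotation ingestion, codon anchoring and the enrichment pipeline.

Input annotations come as one flat TSV (all sources normalized upstream to
a single schema) with the columns::

    gene  residue_pos  ref_aa  alt_aa  category  source  source_id
    description  [transcript]  [sift]  [polyphen]

``alt_aa`` is "." for functional-residue annotations; ``category`` is either
``disease`` or one of the twelve UniProt functional-residue categories
(ACT_SITE, METAL, DISULFID, ...). ``sift``/``polyphen`` are optional
pass-through score columns — never computed here.

Each row is *anchored*: resolved to the canonical transcript of its gene and
verified against the canonical protein (the stated reference residue must
match). Rows failing any check are quarantined with a reason, never silently
dropped — input rows always equal anchored rows plus quarantined rows.

Enrichment then expands every anchored annotation through the codon engine:

* a disease annotation emits every DNA variant realizing its reported
  substitution (class ``reported``) plus every other non-synonymous change
  of the same codon (class ``alternative-same-codon``);
* a functional-residue annotation emits every non-synonymous change of its
  codon (class ``functional-site``);
* paralogue-transferred annotations emit ``para-disease`` / ``para-function``
  variants the same way.

Per anchored codon the reported and alternative classes together always
account for exactly the codon's non-synonymous substitutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .codon_engine import CodonChange, non_synonymous_substitutions
from .transcript_model import TranscriptModel, canonical_by_gene

__all__ = [
    "FUNCTIONAL_CATEGORIES",
    "AMINO_ACIDS",
    "SiteAnnotation",
    "EnrichedVariant",
    "ingest_annotations",
    "enrich",
    "summarize",
    "enriched_to_frame",
]

logger = logging.getLogger(__name__)

#: The twelve UniProt sequence-annotation categories marking functional residues.
FUNCTIONAL_CATEGORIES: frozenset[str] = frozenset(
    {
        "CA_BIND",
        "ZN_FING",
        "DNA_BIND",
        "NP_BIND",
        "ACT_SITE",
        "METAL",
        "BINDING",
        "MOD_RES",
        "LIPID",
        "CARBOHYD",
        "DISULFID",
        "CROSSLNK",
    }
)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ANNOTATION_COLUMNS = [
    "gene",
    "residue_pos",
    "ref_aa",
    "alt_aa",
    "category",
    "source",
    "source_id",
    "description",
]


@dataclass(frozen=True)
class SiteAnnotation:
    """A disease variant or functional residue anchored to a protein position.

    ``alt_aa`` is ``None`` for functional residues (they annotate a position,
    not a substitution). ``transcript_id`` is filled in during anchoring with
    the canonical transcript the position was verified against.
    """

    gene_symbol: str
    residue_pos: int
    ref_aa: str
    alt_aa: str | None
    category: str
    source: str
    source_id: str
    description: str = ""
    sift: str | None = None
    polyphen: str | None = None
    transcript_id: str | None = None

    @property
    def is_disease(self) -> bool:
        return self.category == "disease"


@dataclass(frozen=True)
class EnrichedVariant:
    """One concrete DNA variant produced by enrichment.

    ``nectar_class`` is one of ``reported``, ``alternative-same-codon``,
    ``functional-site``, ``para-disease``, ``para-function``. ``match_kind``
    records whether the variant realizes the anchor's own reported
    substitution (``exact-substitution``) or merely shares its codon
    (``same-codon``).
    """

    change: CodonChange
    nectar_class: str
    anchor: object  # SiteAnnotation or ParalogueAnnotation
    match_kind: str

    @property
    def genomic(self) -> tuple[str, int, str, str]:
        return self.change.genomic


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or (
        isinstance(value, str) and value.strip() in ("", ".")
    )


def _parse_row(row: pd.Series) -> SiteAnnotation:
    """Validate one raw TSV row; raises ValueError with a reason."""
    gene = str(row["gene"]).strip()
    if not gene or _is_blank(gene):
        raise ValueError("malformed row: missing gene")
    try:
        pos = int(row["residue_pos"])
    except (TypeError, ValueError):
        raise ValueError("malformed row: residue_pos not an integer") from None
    if pos < 1:
        raise ValueError("malformed row: residue_pos must be >= 1")
    ref_aa = str(row["ref_aa"]).strip().upper()
    if ref_aa not in AMINO_ACIDS:
        raise ValueError(f"malformed row: bad ref_aa {ref_aa!r}")
    alt_aa = None if _is_blank(row["alt_aa"]) else str(row["alt_aa"]).strip().upper()
    if alt_aa is not None and alt_aa not in AMINO_ACIDS:
        raise ValueError(f"malformed row: bad alt_aa {alt_aa!r}")
    category = str(row["category"]).strip()
    if category != "disease" and category not in FUNCTIONAL_CATEGORIES:
        raise ValueError(f"malformed row: unknown category {category!r}")
    if category == "disease" and alt_aa is None:
        raise ValueError("malformed row: disease annotation requires alt_aa")
    if category in FUNCTIONAL_CATEGORIES and alt_aa is not None:
        raise ValueError("malformed row: functional annotation must have alt_aa='.'")
    return SiteAnnotation(
        gene_symbol=gene,
        residue_pos=pos,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        category=category,
        source=str(row["source"]).strip(),
        source_id=str(row["source_id"]).strip(),
        description="" if _is_blank(row.get("description")) else str(row["description"]),
        sift=None if _is_blank(row.get("sift")) else str(row["sift"]),
        polyphen=None if _is_blank(row.get("polyphen")) else str(row["polyphen"]),
    )


def ingest_annotations(
    tsv_path, models: list[TranscriptModel] | dict[str, TranscriptModel]
) -> tuple[list[SiteAnnotation], pd.DataFrame]:
    """Read an annotation TSV and anchor each row to a canonical transcript.

    Returns ``(anchored, quarantine)`` where ``quarantine`` is a DataFrame of
    the rejected input rows with an extra ``reason`` column. Always:
    ``len(anchored) + len(quarantine) == number of input rows``.
    """
    canonical = (
        models if isinstance(models, dict) else canonical_by_gene(models)
    )
    table = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation TSV missing required columns: {missing}")

    anchored: list[SiteAnnotation] = []
    quarantined: list[dict] = []
    for _, row in table.iterrows():
        reason = None
        ann = None
        try:
            ann = _parse_row(row)
        except ValueError as exc:
            reason = str(exc)
        if reason is None:
            model = canonical.get(ann.gene_symbol)
            if model is None:
                reason = "gene not found"
            elif "transcript" in table.columns and not _is_blank(row["transcript"]) \
                    and str(row["transcript"]).strip() != model.transcript_id:
                reason = "non-canonical anchor"
            elif ann.residue_pos > model.protein_length:
                reason = "position out of range"
            elif model.protein_sequence[ann.residue_pos - 1] != ann.ref_aa:
                reason = (
                    f"residue mismatch: canonical residue is "
                    f"{model.protein_sequence[ann.residue_pos - 1]}, row says {ann.ref_aa}"
                )
        if reason is None:
            anchored.append(replace(ann, transcript_id=model.transcript_id))
        else:
            rec = dict(row)
            rec["reason"] = reason
            quarantined.append(rec)
    quarantine = pd.DataFrame(
        quarantined, columns=list(table.columns) + ["reason"]
    )
    if quarantined:
        logger.warning("quarantined %d of %d annotation rows", len(quarantined), len(table))
    return anchored, quarantine


def _anchor_class_and_match(anchor, change: CodonChange) -> tuple[str, str]:
    para_category = getattr(anchor, "para_category", None) or None
    exact = anchor.alt_aa is not None and change.alt_aa == anchor.alt_aa
    match_kind = "exact-substitution" if exact else "same-codon"
    if para_category is not None:
        cls = "para-disease" if para_category == "Para-disease" else "para-function"
    elif anchor.category == "disease":
        cls = "reported" if exact else "alternative-same-codon"
    else:
        cls = "functional-site"
    return cls, match_kind


def enrich(
    annotations: list,
    models: list[TranscriptModel] | dict[str, TranscriptModel],
) -> list[EnrichedVariant]:
    """Expand anchored annotations into concrete DNA variants.

    Accepts native :class:`SiteAnnotation` objects and paralogue-transferred
    annotations alike (the latter carry a ``para_category`` attribute and are
    classed ``para-disease`` / ``para-function``). Output is deduplicated on
    (genomic variant, anchor) and deterministically ordered.
    """
    canonical = (
        models if isinstance(models, dict) else canonical_by_gene(models)
    )
    out: list[EnrichedVariant] = []
    seen: set[tuple] = set()
    for ann in annotations:
        model = canonical.get(ann.gene_symbol)
        if model is None:
            logger.warning("enrich: gene %s has no canonical model; skipped", ann.gene_symbol)
            continue
        record = model.codon_record(ann.residue_pos)
        for change in non_synonymous_substitutions(record):
            key = (change.genomic, id(ann))
            if key in seen:
                continue
            seen.add(key)
            cls, match_kind = _anchor_class_and_match(ann, change)
            out.append(
                EnrichedVariant(
                    change=change, nectar_class=cls, anchor=ann, match_kind=match_kind
                )
            )
    out.sort(
        key=lambda ev: (
            ev.change.codon_record.gene_symbol,
            ev.change.codon_record.transcript_id,
            ev.change.codon_record.codon_index,
            ev.change.offset,
            ev.change.alt_base,
            ev.anchor.source,
            ev.anchor.source_id,
            ev.nectar_class,
        )
    )
    return out


def enriched_to_frame(enriched: list[EnrichedVariant]) -> pd.DataFrame:
    """Flatten enriched variants to the exportable tabular form."""
    rows = []
    for ev in enriched:
        ch = ev.change
        rec = ch.codon_record
        anchor = ev.anchor
        rows.append(
            {
                "gene": rec.gene_symbol,
                "transcript": rec.transcript_id,
                "codon_index": rec.codon_index,
                "ref_codon": rec.ref_codon,
                "hgvs_c": ch.hgvs_c,
                "hgvs_p": ch.hgvs_p,
                "consequence": ch.consequence.value,
                "class": ev.nectar_class,
                "match_kind": ev.match_kind,
                "chrom": ch.chrom,
                "pos": ch.genomic_pos,
                "ref": ch.genomic_ref,
                "alt": ch.genomic_alt,
                "category": anchor.category,
                "source": anchor.source,
                "source_id": anchor.source_id,
                "anchor_pos": anchor.residue_pos,
                "anchor_alt_aa": anchor.alt_aa if anchor.alt_aa else ".",
                "description": anchor.description,
                "sift": anchor.sift if anchor.sift else ".",
                "polyphen": anchor.polyphen if anchor.polyphen else ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "transcript", "codon_index", "ref_codon", "hgvs_c", "hgvs_p",
            "consequence", "class", "match_kind", "chrom", "pos", "ref", "alt",
            "category", "source", "source_id", "anchor_pos", "anchor_alt_aa",
            "description", "sift", "polyphen",
        ],
    )


def summarize(enriched: list[EnrichedVariant]) -> pd.DataFrame:
    """Per-source, per-category tallies of the enrichment output.

    Because of codon degeneracy, distinct residue outcomes and distinct DNA
    alleles are different counts; both are reported:

    * ``n_genes`` — genes carrying at least one variant;
    * ``n_anchor_residues`` — distinct annotated (gene, position) anchors;
    * ``n_reported_substitutions`` — distinct reported amino-acid
      substitutions (disease-style anchors only);
    * ``n_alternative_residue_substitutions`` — distinct residue outcomes of
      the non-reported classes;
    * ``n_alternative_dna_variants`` — distinct DNA alleles of those classes;
    * ``n_dna_variants`` — all distinct DNA alleles, reported included.
    """
    groups: dict[tuple[str, str], list[EnrichedVariant]] = {}
    for ev in enriched:
        groups.setdefault((ev.anchor.source, ev.anchor.category), []).append(ev)
    rows = []
    for (source, category), evs in sorted(groups.items()):
        genes = {ev.change.codon_record.gene_symbol for ev in evs}
        anchors = {(ev.anchor.gene_symbol, ev.anchor.residue_pos) for ev in evs}
        reported = {
            (ev.anchor.gene_symbol, ev.anchor.residue_pos, ev.anchor.ref_aa, ev.anchor.alt_aa)
            for ev in evs
            if ev.nectar_class == "reported"
        }
        alt_evs = [ev for ev in evs if ev.nectar_class != "reported"]
        alt_residues = {
            (ev.change.codon_record.gene_symbol, ev.change.codon_record.codon_index, ev.change.alt_aa)
            for ev in alt_evs
        }
        rows.append(
            {
                "source": source,
                "category": category,
                "n_genes": len(genes),
                "n_anchor_residues": len(anchors),
                "n_reported_substitutions": len(reported),
                "n_alternative_residue_substitutions": len(alt_residues),
                "n_alternative_dna_variants": len({ev.genomic for ev in alt_evs}),
                "n_dna_variants": len({ev.genomic for ev in evs}),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "source", "category", "n_genes", "n_anchor_residues",
            "n_reported_substitutions", "n_alternative_residue_substitutions",
            "n_alternative_dna_variants", "n_dna_variants",
        ],
    )
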