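"""Annotation ingestion, quarantine accounting and enrichment classes."""

import pytest

from nectar.annotation_store import (
    FUNCTIONAL_CATEGORIES,
    SiteAnnotation,
    enrich,
    enriched_to_frame,
    ingest_annotations,
    summarize,
)
from nectar.codon_engine import non_synonymous_substitutions

HEADER = "gene\tresidue_pos\tref_aa\talt_aa\tcategory\tsource\tsource_id\tdescription\ttranscript\n"


def write_tsv(path, rows):
    path.write_text(HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


def test_fixture_annotations_all_anchor(fixture_set, canonical):
    anchored, quarantine = ingest_annotations(fixture_set.annotations, canonical)
    assert len(quarantine) == 0
    assert len(anchored) == fixture_set.manifest["annotations"]["n_rows"]
    for ann in anchored:
        model = canonical[ann.gene_symbol]
        assert ann.transcript_id == model.transcript_id
        assert model.protein_sequence[ann.residue_pos - 1] == ann.ref_aa
    categories = {a.category for a in anchored if a.category != "disease"}
    assert categories == FUNCTIONAL_CATEGORIES


def test_quarantine_reasons_and_conservation(tmp_path, canonical):
    rows = [
        ("MYL2_FIX", 18, "F", "L", "disease", "UniProt", "OK1", "fine", "."),
        ("MYL2_FIX", 18, "Q", "L", "disease", "UniProt", "BAD1", "wrong residue", "."),
        ("NO_SUCH_GENE", 3, "A", "V", "disease", "UniProt", "BAD2", "unknown gene", "."),
        ("MYL2_FIX", "x", "F", "L", "disease", "UniProt", "BAD3", "bad position", "."),
        ("MYL2_FIX", 18, "F", "L", "oddity", "UniProt", "BAD4", "bad category", "."),
        ("MYL2_FIX", 18, "F", "L", "disease", "UniProt", "BAD5", "wrong transcript", "MYL2_FIX.t2"),
        ("MYL2_FIX", 9999, "F", "L", "disease", "UniProt", "BAD6", "past the end", "."),
        ("MYL2_FIX", 18, "F", ".", "disease", "UniProt", "BAD7", "disease needs alt", "."),
    ]
    anchored, quarantine = ingest_annotations(write_tsv(tmp_path / "a.tsv", rows), canonical)
    assert len(anchored) + len(quarantine) == len(rows)
    assert len(anchored) == 1 and anchored[0].source_id == "OK1"
    reasons = dict(zip(quarantine["source_id"], quarantine["reason"]))
    assert reasons["BAD1"].startswith("residue mismatch")
    assert reasons["BAD2"] == "gene not found"
    assert reasons["BAD3"].startswith("malformed row")
    assert reasons["BAD4"].startswith("malformed row")
    assert reasons["BAD5"] == "non-canonical anchor"
    assert reasons["BAD6"] == "position out of range"
    assert reasons["BAD7"].startswith("malformed row")


def phe18leu(canonical):
    return SiteAnnotation(
        gene_symbol="MYL2_FIX", residue_pos=18, ref_aa="F", alt_aa="L",
        category="disease", source="UniProt", source_id="VAR_FIX001",
        transcript_id=canonical["MYL2_FIX"].transcript_id,
    )


def test_disease_anchor_splits_into_reported_and_alternatives(canonical):
    enriched = enrich([phe18leu(canonical)], canonical)
    assert len(enriched) == 8
    reported = [ev for ev in enriched if ev.nectar_class == "reported"]
    alternative = [ev for ev in enriched if ev.nectar_class == "alternative-same-codon"]
    assert {ev.change.hgvs_c for ev in reported} == {"c.52T>C", "c.54C>A", "c.54C>G"}
    assert all(ev.match_kind == "exact-substitution" for ev in reported)
    assert all(ev.match_kind == "same-codon" for ev in alternative)
    assert {ev.change.alt_aa for ev in alternative} == {"I", "V", "Y", "C", "S"}


def test_functional_anchor_expands_to_all_nonsynonymous(canonical):
    ann = SiteAnnotation(
        gene_symbol="MYL2_FIX", residue_pos=22, ref_aa="E", alt_aa=None,
        category="METAL", source="UniProt", source_id="METAL_X",
        transcript_id=canonical["MYL2_FIX"].transcript_id,
    )
    enriched = enrich([ann], canonical)
    assert len(enriched) == 8
    assert all(ev.nectar_class == "functional-site" for ev in enriched)
    assert sum(ev.change.consequence.value == "nonsense" for ev in enriched) == 1


def test_empty_annotation_list_gives_empty_output(canonical):
    assert enrich([], canonical) == []


def test_conservation_per_anchor(index):
    """reported + alternatives (or functional-site) = non-synonymous count of the codon."""
    per_anchor: dict[int, list] = {}
    for ev in index.enriched:
        per_anchor.setdefault(id(ev.anchor), []).append(ev)
    assert per_anchor
    for evs in per_anchor.values():
        anchor = evs[0].anchor
        model = index.canonical[anchor.gene_symbol]
        expected = len(non_synonymous_substitutions(model.codon_record(anchor.residue_pos)))
        assert len(evs) == expected <= 9
        genomic = {ev.genomic for ev in evs}
        assert len(genomic) == len(evs)  # deduplicated per anchor


def test_every_disease_anchor_contains_its_own_substitution(index):
    disease_anchors = {
        id(a): a
        for a in index.annotations
        if a.category == "disease"
    }
    for anchor in disease_anchors.values():
        own = [
            ev
            for ev in index.enriched
            if ev.anchor is anchor and ev.nectar_class == "reported"
        ]
        assert own, anchor
        assert all(ev.change.alt_aa == anchor.alt_aa for ev in own)


def test_summarize_single_anchor_counts(canonical):
    frame = summarize(enrich([phe18leu(canonical)], canonical))
    assert len(frame) == 1
    row = frame.iloc[0]
    assert row["source"] == "UniProt"
    assert row["n_genes"] == 1
    assert row["n_reported_substitutions"] == 1
    assert row["n_alternative_residue_substitutions"] == 5
    assert row["n_dna_variants"] == 8


def test_summarize_matches_brute_force_recount(index):
    """Tallies must equal an independent recount of the flattened output table."""
    frame = enriched_to_frame(index.enriched)
    summary = summarize(index.enriched)
    for _, row in summary.iterrows():
        sub = frame[(frame["source"] == row["source"]) & (frame["category"] == row["category"])]
        assert row["n_genes"] == sub["gene"].nunique()
        assert row["n_dna_variants"] == len(
            sub[["chrom", "pos", "ref", "alt"]].drop_duplicates()
        )
        alt = sub[sub["class"] != "reported"]
        assert row["n_alternative_dna_variants"] == len(
            alt[["chrom", "pos", "ref", "alt"]].drop_duplicates()
        )
        assert row["n_alternative_residue_substitutions"] == len(
            alt.assign(alt_aa=alt["hgvs_p"])[["gene", "codon_index", "alt_aa"]]
            .drop_duplicates()
        )


def test_two_anchors_on_one_codon_keep_provenance(canonical):
    a1 = phe18leu(canonical)
    a2 = SiteAnnotation(
        gene_symbol="MYL2_FIX", residue_pos=18, ref_aa="F", alt_aa="S",
        category="disease", source="ClinVar", source_id="RCV_X",
        transcript_id=canonical["MYL2_FIX"].transcript_id,
    )
    enriched = enrich([a1, a2], canonical)
    assert len(enriched) == 16  # 8 per anchor, one row per (variant, anchor)
    distinct_variants = {ev.genomic for ev in enriched}
    assert len(distinct_variants) == 8  # but only 8 distinct DNA variants
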