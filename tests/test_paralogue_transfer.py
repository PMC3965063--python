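"""Global protein alignment and paralogue annotation transfer."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from nectar.annotation_store import SiteAnnotation
from nectar.paralogue_transfer import (
    AlignmentError,
    align_proteins,
    equivalent_position,
    transfer_annotations,
)

proteins = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


def test_self_alignment_is_identity():
    amap = align_proteins("MKLV", "MKLV")
    assert amap.aligned_pairs == ((1, 1), (2, 2), (3, 3), (4, 4))
    assert amap.identity_fraction == 1.0
    assert all(amap.column_identical)


def test_single_deletion_alignment():
    # exhaustively checkable: aligning MKLV/MKV under BLOSUM62 with gap open
    # 10 / extend 1, the optimal alignment gaps the L and pairs V with V
    amap = align_proteins("MKLV", "MKV")
    assert amap.aligned_pairs == ((1, 1), (2, 2), (4, 3))
    assert amap.equivalent_position(3) is None
    assert amap.equivalent_position(4) == 3


def test_empty_sequence_rejected():
    with pytest.raises(AlignmentError):
        align_proteins("", "MKV")


def test_nonstandard_residues_warn_and_align(caplog):
    with caplog.at_level("WARNING"):
        amap = align_proteins("MKUV", "MKLV")
    assert any("non-standard" in r.message for r in caplog.records)
    assert len(amap.aligned_pairs) == 4


def test_out_of_range_position_rejected():
    amap = align_proteins("MKLV", "MKLV")
    with pytest.raises(AlignmentError):
        amap.equivalent_position(5)
    assert equivalent_position(amap, 2) == 2


@given(proteins, proteins)
def test_alignment_pairs_never_cross(seq_a, seq_b):
    amap = align_proteins(seq_a, seq_b)
    pairs = amap.aligned_pairs
    assert all(a1 < a2 and b1 < b2 for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]))
    assert 0.0 <= amap.identity_fraction <= 1.0


def test_symmetry_on_fixture_pairs(index, fixture_set):
    members = fixture_set.manifest["family"]["members"]
    seqs = {g: index.canonical[g].protein_sequence for g in members}
    amap = align_proteins(seqs[members[0]], seqs[members[1]], members[0], members[1])
    rev = amap.reversed()
    for a, b in amap.aligned_pairs:
        assert rev.equivalent_position(b) == a


def test_family_identity_matches_construction(index, fixture_set):
    fam = fixture_set.manifest["family"]
    seqs = {g: index.canonical[g].protein_sequence for g in fam["members"]}
    for i, a in enumerate(fam["members"]):
        for b in fam["members"][i + 1 :]:
            amap = align_proteins(seqs[a], seqs[b], a, b)
            assert amap.identity_fraction == pytest.approx(fam["identity"], abs=0.05)


def _family_annotations(index, fixture_set):
    members = set(fixture_set.manifest["family"]["members"])
    return [a for a in index.annotations if a.gene_symbol in members]


def test_blank_member_receives_planted_transfers(index, fixture_set):
    fam = fixture_set.manifest["family"]
    blank = fam["blank_member"]
    to_blank = [t for t in index.paralogue_annotations if t.gene_symbol == blank]
    assert len(to_blank) == fam["expected_total_transfers_to_blank"]
    assert all(t.para_category == "Para-disease" for t in to_blank)
    per_source = {}
    for t in to_blank:
        per_source.setdefault(t.origin_gene, []).append(t)
    assert set(per_source) == set(fam["annotated_members"])
    for transfers in per_source.values():
        assert len(transfers) == fam["expected_transfers_per_source"]
        assert sorted(t.residue_pos for t in transfers) == fam["conserved_columns"]
        assert all(t.aligned_column_identical for t in transfers)


def test_transfer_never_invents_sites(index, fixture_set):
    anns = _family_annotations(index, fixture_set)
    per_gene = {}
    for a in anns:
        per_gene.setdefault(a.gene_symbol, []).append(a)
    per_direction = {}
    for t in index.paralogue_annotations:
        per_direction.setdefault((t.origin_gene, t.gene_symbol), []).append(t)
    for (src, _tgt), transfers in per_direction.items():
        assert len(transfers) <= len(per_gene.get(src, []))


def test_self_transfer_is_identity(index, fixture_set):
    members = fixture_set.manifest["family"]["members"]
    src = members[0]
    anns = [a for a in index.annotations if a.gene_symbol == src]
    seqs = {src: index.canonical[src].protein_sequence}
    transfers = transfer_annotations(anns, [(src, src)], seqs)
    assert len(transfers) == len(anns)
    assert {(t.residue_pos, t.ref_aa) for t in transfers} == {
        (a.residue_pos, a.ref_aa) for a in anns
    }


def test_raising_identity_threshold_never_adds_transfers(index, fixture_set):
    fam = fixture_set.manifest["family"]
    members = fam["members"]
    pairs = [(a, b) for i, a in enumerate(members) for b in members[i + 1 :]]
    seqs = {g: index.canonical[g].protein_sequence for g in members}
    anns = _family_annotations(index, fixture_set)
    counts = [
        len(transfer_annotations(anns, pairs, seqs, min_identity=thr))
        for thr in (0.30, 0.80, 0.90)
    ]
    assert counts[0] >= counts[1] >= counts[2]
    assert counts[2] == 0  # family built at 0.85 identity
    assert counts[0] == counts[1]  # 0.85 >= 0.80 keeps every pair


def test_unknown_protein_pair_skipped(index, caplog):
    anns = [a for a in index.annotations if a.gene_symbol == "TPM_FIX_A"]
    seqs = {"TPM_FIX_A": index.canonical["TPM_FIX_A"].protein_sequence}
    with caplog.at_level("WARNING"):
        transfers = transfer_annotations(anns, [("TPM_FIX_A", "GHOST")], seqs)
    assert transfers == []
    assert any("unknown protein" in r.message for r in caplog.records)


def test_transferred_annotations_expand_like_native_ones(index):
    """Para-* anchors feed the codon engine on the target's canonical transcript."""
    para_variants = [
        ev for ev in index.enriched if ev.nectar_class in ("para-disease", "para-function")
    ]
    assert para_variants
    for ev in para_variants:
        rec = ev.change.codon_record
        assert rec.gene_symbol == ev.anchor.gene_symbol
        assert rec.codon_index == ev.anchor.residue_pos
        assert rec.ref_aa == ev.anchor.ref_aa
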