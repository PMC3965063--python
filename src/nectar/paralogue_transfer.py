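"""Annotation transfer between paralogous proteins via global alignment.

Proteins arising by duplication within a genome (paralogues) often conserve
the residues that matter, so a disease variant or functional residue known
in one family member is informative at the *equivalent aligned position* of
its relatives — e.g. an unannotated tropomyosin can inherit candidate sites
from its three heavily annotated paralogues. Transferred annotations are
labelled ``Para-disease`` / ``Para-function`` and then expand through the
codon engine on the target's canonical transcript exactly like native ones.

Paralogue pairs are an *input* (a two-column TSV of gene symbols, treated as
undirected); gene-tree construction is out of scope. Alignment is global
(Needleman-Wunsch, affine gaps) over full-length sequences: the declared
pairs are full-length homologues and a local alignment would silently drop
termini. Defaults: BLOSUM62, gap open 10, gap extend 1, and a minimum
whole-alignment identity of 0.30 for accepting a pair.

Transfers are emitted whether or not the aligned target residue equals the
source residue; ``aligned_column_identical`` is exposed so downstream users
can filter on strict conservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .annotation_store import SiteAnnotation

__all__ = [
    "AlignmentMap",
    "ParalogueAnnotation",
    "AlignmentError",
    "align_proteins",
    "equivalent_position",
    "transfer_annotations",
]

logger = logging.getLogger(__name__)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM_ALPHABET = set(str(_BLOSUM62.alphabet))

#: Documented defaults: BLOSUM62 with affine gap open 10, extend 1.
GAP_OPEN = 10.0
GAP_EXTEND = 1.0

#: Minimum whole-alignment identity for accepting a paralogue pair.
DEFAULT_MIN_IDENTITY = 0.30


class AlignmentError(ValueError):
    """Raised for sequences that cannot be aligned (e.g. empty input)."""


@dataclass(frozen=True)
class AlignmentMap:
    """Residue-level map between two globally aligned proteins.

    ``aligned_pairs`` holds 1-based (pos_a, pos_b) pairs from the non-gap
    columns, strictly increasing in both coordinates (alignments cannot
    cross); ``column_identical`` is the parallel per-column flag for
    identical residues. ``identity_fraction`` is identical columns over
    aligned (both-non-gap) columns.
    """

    protein_a: str
    protein_b: str
    length_a: int
    length_b: int
    aligned_pairs: tuple[tuple[int, int], ...]
    column_identical: tuple[bool, ...]
    identity_fraction: float

    def equivalent_position(self, pos_a: int) -> int | None:
        """Position in protein_b aligned with ``pos_a``; None in gap columns."""
        if not 1 <= pos_a <= self.length_a:
            raise AlignmentError(
                f"position {pos_a} outside 1..{self.length_a} of {self.protein_a}"
            )
        return self._forward().get(pos_a)

    def reversed(self) -> "AlignmentMap":
        """The same alignment viewed from protein_b."""
        return AlignmentMap(
            protein_a=self.protein_b,
            protein_b=self.protein_a,
            length_a=self.length_b,
            length_b=self.length_a,
            aligned_pairs=tuple((b, a) for a, b in self.aligned_pairs),
            column_identical=self.column_identical,
            identity_fraction=self.identity_fraction,
        )

    def _forward(self) -> dict[int, int]:
        return dict(self.aligned_pairs)

    def column_is_identical(self, pos_a: int) -> bool:
        for (a, _), ident in zip(self.aligned_pairs, self.column_identical):
            if a == pos_a:
                return ident
        return False


def _sanitize(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = sorted(set(seq) - _BLOSUM_ALPHABET)
    if bad:
        logger.warning(
            "%s: non-standard residue symbols %s treated as X (mismatch)", name, bad
        )
        seq = "".join(c if c in _BLOSUM_ALPHABET else "X" for c in seq)
    return seq


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def align_proteins(
    seq_a: str, seq_b: str, id_a: str = "A", id_b: str = "B"
) -> AlignmentMap:
    """Globally align two protein sequences and return the residue map.

    Needleman-Wunsch with affine gaps (BLOSUM62, open 10, extend 1). Among
    co-optimal alignments the first in the aligner's deterministic
    enumeration order is used, so results are reproducible for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise AlignmentError("cannot align an empty sequence")
    sa = _sanitize(seq_a, id_a)
    sb = _sanitize(seq_b, id_b)
    alignment = _aligner().align(sa, sb)[0]
    pairs: list[tuple[int, int]] = []
    identical: list[bool] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for k in range(a_end - a_start):
            pa, pb = a_start + k, b_start + k
            pairs.append((pa + 1, pb + 1))
            identical.append(sa[pa] == sb[pb])
    n_aligned = len(pairs)
    identity = (sum(identical) / n_aligned) if n_aligned else 0.0
    return AlignmentMap(
        protein_a=id_a,
        protein_b=id_b,
        length_a=len(sa),
        length_b=len(sb),
        aligned_pairs=tuple(pairs),
        column_identical=tuple(identical),
        identity_fraction=identity,
    )


def equivalent_position(alignment_map: AlignmentMap, pos_a: int) -> int | None:
    """Functional form of :meth:`AlignmentMap.equivalent_position`."""
    return alignment_map.equivalent_position(pos_a)


@dataclass(frozen=True)
class ParalogueAnnotation(SiteAnnotation):
    """A site annotation projected onto a paralogue.

    Inherits the anchored-annotation fields, re-anchored to the target
    protein: ``gene_symbol``/``residue_pos``/``ref_aa`` describe the target
    (``ref_aa`` is the target's actual residue), while ``origin`` keeps the
    source annotation. ``para_category`` is ``Para-disease`` iff the origin
    is a disease annotation, ``Para-function`` otherwise.
    """

    para_category: str = ""
    origin: SiteAnnotation | None = None
    origin_gene: str = ""
    origin_pos: int = 0
    aligned_column_identical: bool = False
    pair_identity: float = 0.0


def transfer_annotations(
    annotations: list[SiteAnnotation],
    paralogue_pairs: list[tuple[str, str]],
    sequences: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[ParalogueAnnotation]:
    """Project annotations onto their paralogues' equivalent positions.

    Parameters
    ----------
    annotations : list of SiteAnnotation
        Anchored native annotations (positions refer to canonical proteins).
    paralogue_pairs : list of (gene_a, gene_b)
        Declared paralogy, treated as undirected.
    sequences : dict
        gene symbol -> canonical protein sequence.
    min_identity : float
        Pairs whose whole-alignment identity falls below this are rejected.
        Raising the threshold can only remove transfers, never add them.

    Annotations falling in gap columns of the target are not transferred
    (transfer count per pair never exceeds the source annotation count).
    Pairs naming unknown proteins are skipped with a warning.
    """
    by_gene: dict[str, list[SiteAnnotation]] = {}
    for ann in annotations:
        by_gene.setdefault(ann.gene_symbol, []).append(ann)

    maps: dict[tuple[str, str], AlignmentMap | None] = {}

    def pair_map(a: str, b: str) -> AlignmentMap | None:
        key = (min(a, b), max(a, b))
        if key not in maps:
            amap = align_proteins(sequences[key[0]], sequences[key[1]], key[0], key[1])
            maps[key] = amap if amap.identity_fraction >= min_identity else None
            if maps[key] is None:
                logger.warning(
                    "pair (%s, %s) rejected: identity %.2f below %.2f",
                    key[0], key[1], amap.identity_fraction, min_identity,
                )
        amap = maps[key]
        if amap is None:
            return None
        return amap if amap.protein_a == a else amap.reversed()

    out: list[ParalogueAnnotation] = []
    seen_pairs: set[tuple[str, str]] = set()
    for gene_a, gene_b in paralogue_pairs:
        key = (min(gene_a, gene_b), max(gene_a, gene_b))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        if gene_a not in sequences or gene_b not in sequences:
            logger.warning(
                "pair (%s, %s) references an unknown protein; skipped", gene_a, gene_b
            )
            continue
        directions = (
            ((gene_a, gene_b),) if gene_a == gene_b
            else ((gene_a, gene_b), (gene_b, gene_a))
        )
        for source, target in directions:
            amap = pair_map(source, target)
            if amap is None:
                continue
            for ann in by_gene.get(source, ()):
                pos_b = amap.equivalent_position(ann.residue_pos)
                if pos_b is None:
                    continue
                out.append(
                    ParalogueAnnotation(
                        gene_symbol=target,
                        residue_pos=pos_b,
                        ref_aa=sequences[target][pos_b - 1],
                        alt_aa=ann.alt_aa,
                        category=ann.category,
                        source=ann.source,
                        source_id=ann.source_id,
                        description=ann.description,
                        sift=ann.sift,
                        polyphen=ann.polyphen,
                        para_category=(
                            "Para-disease" if ann.is_disease else "Para-function"
                        ),
                        origin=ann,
                        origin_gene=source,
                        origin_pos=ann.residue_pos,
                        aligned_column_identical=amap.column_is_identical(
                            ann.residue_pos
                        ),
                        pair_identity=amap.identity_fraction,
                    )
                )
    out.sort(
        key=lambda p: (p.gene_symbol, p.residue_pos, p.origin_gene, p.origin_pos,
                       p.source, p.source_id)
    )
    return out


def transfers_to_frame(transfers: list[ParalogueAnnotation]):
    """Tabular transfer report (origin, target, identity, conservation)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "origin_gene": t.origin_gene,
                "origin_pos": t.origin_pos,
                "source": t.source,
                "source_id": t.source_id,
                "target_gene": t.gene_symbol,
                "target_pos": t.residue_pos,
                "target_residue": t.ref_aa,
                "para_category": t.para_category,
                "aligned_column_identical": t.aligned_column_identical,
                "pair_identity": round(t.pair_identity, 4),
            }
            for t in transfers
        ],
        columns=[
            "origin_gene", "origin_pos", "source", "source_id", "target_gene",
            "target_pos", "target_residue", "para_category",
            "aligned_column_identical", "pair_identity",
        ],
    )
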