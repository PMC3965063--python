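"""Transcript models and exact genomic <-> CDS <-> codon <-> protein mapping.

A :class:`TranscriptModel` holds the exon and CDS structure of one
transcript plus its spliced, strand-oriented coding sequence, and answers
coordinate questions exactly: which genomic base is CDS position c.52, which
codon covers protein residue 18, which codon (if any) does a genomic query
position fall in. Reverse-strand transcripts and codons split across an
exon-exon junction are handled by construction, because the mapping is kept
as an explicit per-base table rather than interval arithmetic.

Conventions (fixed across the whole package):

* all genomic and CDS coordinates are 1-based inclusive (HGVS / VCF / GFF3);
* the CDS sequence is given on the coding strand; variant alleles exchanged
  with the outside world (VCF) are always on the forward genomic strand, and
  complementation for minus-strand transcripts happens inside this layer;
* a transcript's CDS may include its stop codon (the usual GFF3 convention);
  the stop codon is not part of the protein and has no codon record.

Transcripts whose CDS length is not divisible by 3, or whose translation
contains an internal stop, are skipped with a warning rather than repaired:
the method operates on curated canonical transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

from .genetic_code import STOP, translate_codon

__all__ = [
    "TranscriptModel",
    "CodonRecord",
    "TranscriptModelError",
    "load_reference",
    "select_canonical",
    "canonical_by_gene",
    "protein_pos_to_cds_span",
]

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class TranscriptModelError(ValueError):
    """Raised for transcript structures or coordinates that cannot be used."""


@dataclass(frozen=True)
class CodonRecord:
    """One codon of a protein, with the genomic coordinates of its bases.

    ``base_coords`` lists the three (chrom, pos) genomic positions in CDS
    order; for a minus-strand transcript the positions are strictly
    decreasing, and for a codon split across an exon junction they are not
    consecutive.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    codon_index: int
    ref_codon: str
    ref_aa: str
    base_coords: tuple[tuple[str, int], tuple[str, int], tuple[str, int]]


@dataclass
class TranscriptModel:
    """One transcript: exon/CDS structure plus the spliced coding sequence.

    ``exons`` and ``cds`` are stored in ascending genomic order; transcript
    (5'->3') order is the reverse of that for minus-strand models.
    ``cds_sequence`` is spliced and strand-oriented (it starts with the
    initiator codon regardless of strand).
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    cds_sequence: str

    # per-base genomic position of every CDS position, in CDS order
    _cds_positions: list[int] = field(repr=False, default_factory=list)
    _genomic_index: dict[int, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise TranscriptModelError(f"bad strand {self.strand!r}")
        intervals = sorted(self.cds)
        if any(intervals[i][1] >= intervals[i + 1][0] for i in range(len(intervals) - 1)):
            raise TranscriptModelError(
                f"{self.transcript_id}: overlapping CDS intervals"
            )
        positions: list[int] = []
        for start, end in intervals:
            positions.extend(range(start, end + 1))
        if self.strand == "-":
            positions.reverse()
        if len(positions) != len(self.cds_sequence):
            raise TranscriptModelError(
                f"{self.transcript_id}: CDS intervals cover {len(positions)} bp "
                f"but cds_sequence has {len(self.cds_sequence)} bp"
            )
        self._cds_positions = positions
        self._genomic_index = {g: i + 1 for i, g in enumerate(positions)}

    # -- basic size accessors ------------------------------------------------

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def has_terminal_stop(self) -> bool:
        return translate_codon(self.cds_sequence[-3:]) == STOP

    @property
    def protein_length(self) -> int:
        """Number of amino-acid residues (excluding any terminal stop)."""
        n = self.cds_length // 3
        return n - 1 if self.has_terminal_stop else n

    @property
    def protein_sequence(self) -> str:
        seq = str(Seq(self.cds_sequence).translate())
        return seq[:-1] if seq.endswith(STOP) else seq

    # -- coordinate mapping --------------------------------------------------

    def cds_to_genomic(self, cds_pos: int) -> tuple[str, int]:
        """Map a 1-based CDS position to its (chrom, genomic position).

        Bijective over the CDS; for minus-strand models increasing CDS
        positions map to decreasing genomic positions.
        """
        if not 1 <= cds_pos <= self.cds_length:
            raise TranscriptModelError(
                f"{self.transcript_id}: CDS position {cds_pos} outside "
                f"1..{self.cds_length}"
            )
        return self.chrom, self._cds_positions[cds_pos - 1]

    def genomic_to_cds(self, chrom: str, genomic_pos: int) -> int | None:
        """Inverse of :meth:`cds_to_genomic`; ``None`` off the CDS.

        Intronic, UTR, intergenic and wrong-chromosome positions all return
        ``None`` (they are valid queries with no coding interpretation).
        """
        if chrom != self.chrom:
            return None
        return self._genomic_index.get(genomic_pos)

    def codon_record(self, codon_index: int) -> CodonRecord:
        """Build the :class:`CodonRecord` for protein residue ``codon_index``."""
        if not 1 <= codon_index <= self.protein_length:
            raise TranscriptModelError(
                f"{self.transcript_id}: codon index {codon_index} outside "
                f"1..{self.protein_length}"
            )
        lo, hi = protein_pos_to_cds_span(codon_index)
        codon = self.cds_sequence[lo - 1 : hi]
        coords = tuple(self.cds_to_genomic(p) for p in range(lo, hi + 1))
        return CodonRecord(
            transcript_id=self.transcript_id,
            gene_symbol=self.gene_symbol,
            chrom=self.chrom,
            strand=self.strand,
            codon_index=codon_index,
            ref_codon=codon,
            ref_aa=translate_codon(codon),
            base_coords=coords,  # type: ignore[arg-type]
        )

    def codon_records(self):
        """Iterate codon records for every protein residue."""
        for i in range(1, self.protein_length + 1):
            yield self.codon_record(i)

    def codon_index_of_genomic(self, chrom: str, genomic_pos: int) -> int | None:
        """Protein residue whose codon covers a genomic position, if any."""
        cds_pos = self.genomic_to_cds(chrom, genomic_pos)
        if cds_pos is None:
            return None
        idx = (cds_pos + 2) // 3
        return idx if idx <= self.protein_length else None


def protein_pos_to_cds_span(codon_index: int) -> tuple[int, int]:
    """CDS span (1-based inclusive) of protein residue ``codon_index``.

    Residue i covers CDS positions 3i-2 .. 3i; e.g. residue 18 covers
    c.52-c.54.
    """
    if codon_index < 1:
        raise TranscriptModelError(f"codon index must be >= 1, got {codon_index}")
    return 3 * codon_index - 2, 3 * codon_index


def _fetch(fasta: Fasta, chrom: str, start: int, end: int) -> str:
    return str(fasta[chrom][start - 1 : end]).upper()


def load_reference(fasta_path, gff3_path) -> list[TranscriptModel]:
    """Load transcript models from a reference FASTA and a GFF3 file.

    Expects the usual gene -> mRNA -> exon/CDS feature hierarchy with
    ``ID``/``Parent`` attributes and a ``gene_name`` attribute on gene
    features (falling back to the gene ID). Models violating the contract
    (CDS length not divisible by 3, internal stop codons, CDS outside exons)
    are skipped with a warning. A CDS referencing a contig absent from the
    FASTA is a fatal error: it means the two inputs do not belong together.
    """
    fasta = Fasta(str(fasta_path), sequence_always_upper=True)
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_name = gene.attributes.get("gene_name", [gene.id])[0]
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = [
                (f.start, f.end)
                for f in db.children(mrna, featuretype="exon", order_by="start")
            ]
            cds = [
                (f.start, f.end)
                for f in db.children(mrna, featuretype="CDS", order_by="start")
            ]
            if not cds:
                logger.warning("%s: no CDS features; skipped", mrna.id)
                continue
            if mrna.seqid not in fasta:
                raise TranscriptModelError(
                    f"{mrna.id}: contig {mrna.seqid!r} not present in FASTA"
                )
            contig_len = len(fasta[mrna.seqid])
            if any(e > contig_len or s < 1 for s, e in cds):
                raise TranscriptModelError(
                    f"{mrna.id}: CDS outside contig bounds of {mrna.seqid}"
                )
            if not _cds_within_exons(cds, exons):
                logger.warning("%s: CDS not contained in exons; skipped", mrna.id)
                continue
            total = sum(e - s + 1 for s, e in cds)
            if total % 3 != 0:
                logger.warning(
                    "%s: CDS length %d not divisible by 3; skipped", mrna.id, total
                )
                continue
            seq = "".join(_fetch(fasta, mrna.seqid, s, e) for s, e in sorted(cds))
            if mrna.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            if _has_internal_stop(seq):
                logger.warning("%s: internal stop codon; skipped", mrna.id)
                continue
            models.append(
                TranscriptModel(
                    transcript_id=mrna.id,
                    gene_symbol=gene_name,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=sorted(exons),
                    cds=sorted(cds),
                    cds_sequence=seq,
                )
            )
    return models


def _cds_within_exons(cds: list[Interval], exons: list[Interval]) -> bool:
    if not exons:
        return True  # CDS-only annotations are acceptable
    return all(
        any(es <= s and e <= ee for es, ee in exons) for s, e in cds
    )


def _has_internal_stop(cds_sequence: str) -> bool:
    protein = str(Seq(cds_sequence).translate())
    return STOP in protein[:-1]


def select_canonical(models: list[TranscriptModel]) -> TranscriptModel:
    """Pick the canonical transcript among models of one gene.

    Rule: longest CDS, ties broken by lexicographically smallest transcript
    id. Deterministic by construction.
    """
    if not models:
        raise TranscriptModelError("select_canonical: empty model set")
    genes = {m.gene_symbol for m in models}
    if len(genes) > 1:
        raise TranscriptModelError(
            f"select_canonical: models span multiple genes {sorted(genes)}"
        )
    return min(models, key=lambda m: (-m.cds_length, m.transcript_id))


def canonical_by_gene(models: list[TranscriptModel]) -> dict[str, TranscriptModel]:
    """Map gene symbol -> canonical transcript model."""
    per_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        per_gene.setdefault(m.gene_symbol, []).append(m)
    return {g: select_canonical(ms) for g, ms in per_gene.items()}
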