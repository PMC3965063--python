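"""Deterministic generator of a complete toy input set.

Emulates, at desk scale, the reference/annotation resources the annotation
pipeline consumes in production (a genome, transcript models, curated
disease-variant and functional-residue tables, declared paralogue pairs and
a demo query VCF), with every planted truth recorded in a machine-readable
manifest so tests can check recovery rather than re-derive expectations.

The generated world contains:

* ``MYL2_FIX`` — a plus-strand two-exon gene carrying the classic worked
  example: codon 18 reads TTC (Phe) at c.52-54 and codon 22 reads GAG (Glu)
  at c.64-66, with a Phe18Leu and a Glu22Lys disease annotation. A second,
  shorter transcript of the same gene exercises canonical selection.
* ``SPLIT_FIX`` — a plus-strand gene with an intron inside codon 2.
* ``REV_FIX`` — a minus-strand gene with an intron splitting a codon.
* ``TPM_FIX_A..D`` — a tropomyosin-like paralogue family built at a target
  pairwise identity, with k annotated columns conserved across all members
  and one member (``_D``) left unannotated so transfers can be counted.
* an annotation TSV covering all twelve functional categories, a paralogue
  pair TSV (all pairs of the family) and a demo VCF exercising exact-match,
  same-codon, synonymous, intronic, multi-allelic, indel, minus-strand and
  paralogue queries.

All randomness flows from the single seed in :class:`FixtureSpec`; the same
seed reproduces byte-identical files. Gene names are namespaced with
``_FIX`` so no real genomic coordinates are implied; the worked-example
codons are positioned so the HGVS c. numbering is the familiar one.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .annotation_store import ingest_annotations
from .codon_engine import non_synonymous_substitutions
from .genetic_code import CODON_TABLE, SENSE_CODONS, STOP, translate_codon
from .transcript_model import TranscriptModel, canonical_by_gene, load_reference

__all__ = ["FixtureSpec", "FixtureSet", "FixtureBuilder", "generate_fixture_set",
           "DEFAULT_SEED"]

DEFAULT_SEED = 17

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    _CODONS_FOR_AA.setdefault(CODON_TABLE[_codon], []).append(_codon)

_FUNCTIONAL_PLAN = {
    # gene -> list of (category, residue_pos); DISULFID gets two positions
    "MYL2_FIX": [("METAL", 22), ("ACT_SITE", 5), ("BINDING", 9), ("CA_BIND", 12)],
    "SPLIT_FIX": [("CARBOHYD", 3), ("CROSSLNK", 7), ("DNA_BIND", 15)],
    "REV_FIX": [("LIPID", 4), ("MOD_RES", 8), ("NP_BIND", 17), ("ZN_FING", 25)],
}
_DISULFID_POSITIONS = ("SPLIT_FIX", 10, 20)  # two rows sharing one source_id


@dataclass(frozen=True)
class FixtureSpec:
    """All tunable knobs of the generated world (defaults are the study set)."""

    seed: int = DEFAULT_SEED
    myl2_protein_length: int = 40
    split_protein_length: int = 30
    rev_protein_length: int = 30
    family_size: int = 4
    family_protein_length: int = 100
    family_identity: float = 0.85
    family_conserved_sites: int = 5


@dataclass
class FixtureSet:
    """Paths of the generated files plus the manifest of planted truths."""

    out_dir: Path
    fasta: Path
    gff3: Path
    annotations: Path
    paralogues: Path
    vcf: Path
    manifest_path: Path
    manifest: dict = field(default_factory=dict)


@dataclass
class _GenePlan:
    name: str
    chrom: str
    strand: str
    protein: str           # residues, no stop
    cds_nt: str            # coding sequence incl. terminal stop codon
    utr5_len: int
    utr3_len: int
    intron_after: list[int]   # CDS positions after which an intron is inserted
    # filled during assembly:
    transcripts: list[dict] = field(default_factory=list)


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _random_protein(rng: random.Random, n: int) -> str:
    aas = sorted(_CODONS_FOR_AA)
    return "M" + "".join(rng.choice(aas) for _ in range(n - 1))


def _back_translate(rng: random.Random, protein: str) -> str:
    return "".join(rng.choice(_CODONS_FOR_AA[aa]) for aa in protein)


def _reachable_missense(codon: str) -> list[str]:
    """Residues reachable from ``codon`` by one base change (missense only)."""
    out = set()
    for offset in range(3):
        for base in "ACGT":
            if base == codon[offset]:
                continue
            alt = codon[:offset] + base + codon[offset + 1 :]
            aa = translate_codon(alt)
            if aa != STOP and aa != translate_codon(codon):
                out.add(aa)
    return sorted(out)


class FixtureBuilder:
    """Build the full fixture set under one output directory."""

    def __init__(self, spec: FixtureSpec | None = None):
        self.spec = spec or FixtureSpec()
        self.rng = random.Random(self.spec.seed)
        self.contigs: dict[str, str] = {}
        self.gff_lines: list[str] = []
        self.plans: dict[str, _GenePlan] = {}
        self.family_members: list[str] = []
        self.conserved_columns: list[int] = []
        self.annotation_rows: list[dict] = []

    # -- gene construction ---------------------------------------------------

    def _plan_coding_genes(self) -> None:
        sp = self.spec
        rng = self.rng

        def make(name, chrom, strand, length, planted, utr5, utr3, introns):
            protein = _random_protein(rng, length)
            codons = [rng.choice(_CODONS_FOR_AA[aa]) for aa in protein]
            codons[0] = "ATG"
            for idx, codon in planted.items():
                codons[idx - 1] = codon
                protein = protein[: idx - 1] + translate_codon(codon) + protein[idx:]
            cds_nt = "".join(codons) + "TAA"
            plan = _GenePlan(
                name=name, chrom=chrom, strand=strand, protein=protein,
                cds_nt=cds_nt, utr5_len=utr5, utr3_len=utr3, intron_after=introns,
            )
            self.plans[name] = plan
            return plan

        make("MYL2_FIX", "chrFIX1", "+", sp.myl2_protein_length,
             {18: "TTC", 22: "GAG"}, utr5=20, utr3=15, introns=[30])
        make("SPLIT_FIX", "chrFIX1", "+", sp.split_protein_length,
             {}, utr5=0, utr3=0, introns=[4])           # intron inside codon 2
        make("REV_FIX", "chrFIX1", "-", sp.rev_protein_length,
             {}, utr5=12, utr3=0, introns=[49])         # intron inside codon 17

    def _plan_family(self) -> None:
        sp = self.spec
        rng = self.rng
        L = sp.family_protein_length
        base = _random_protein(rng, L)
        n_variable = round((1 - sp.family_identity) * L)
        candidates = list(range(2, L + 1))
        self.conserved_columns = sorted(rng.sample(candidates, sp.family_conserved_sites))
        remaining = [p for p in candidates if p not in self.conserved_columns]
        variable = sorted(rng.sample(remaining, n_variable))
        aas = sorted(_CODONS_FOR_AA)
        self.family_members = [
            f"TPM_FIX_{chr(ord('A') + i)}" for i in range(sp.family_size)
        ]
        for i, name in enumerate(self.family_members):
            protein = list(base)
            for col in variable:
                # distinct residue per member at every variable column, so
                # pairwise identity is exactly 1 - |variable|/L
                choices = [a for a in aas if a != base[col - 1]]
                protein[col - 1] = choices[i % len(choices)]
            protein = "".join(protein)
            cds_nt = _back_translate(rng, protein) + "TAA"
            self.plans[name] = _GenePlan(
                name=name, chrom="chrFIX2", strand="+", protein=protein,
                cds_nt=cds_nt, utr5_len=0, utr3_len=0, intron_after=[],
            )

    # -- genomic assembly ----------------------------------------------------

    def _assemble_block(self, plan: _GenePlan) -> tuple[str, list[dict]]:
        """Build the genomic block of one gene and its transcript intervals.

        Returns (block sequence, transcripts) where each transcript dict has
        block-local 1-based ``exons`` and ``cds`` interval lists (ascending).
        """
        rng = self.rng
        cds = plan.cds_nt
        cuts = sorted(plan.intron_after)
        segments = []
        prev = 0
        for cut in cuts:
            segments.append(cds[prev:cut])
            prev = cut
        segments.append(cds[prev:])
        introns = ["GT" + _random_seq(rng, rng.randint(36, 76)) + "AG" for _ in cuts]

        # transcript-sense layout
        pieces: list[tuple[str, str]] = []
        if plan.utr5_len:
            pieces.append(("utr", _random_seq(rng, plan.utr5_len)))
        for i, seg in enumerate(segments):
            pieces.append(("cds", seg))
            if i < len(introns):
                pieces.append(("intron", introns[i]))
        if plan.utr3_len:
            pieces.append(("utr", _random_seq(rng, plan.utr3_len)))

        sense_seq = "".join(s for _, s in pieces)
        length = len(sense_seq)

        # walk pieces to get sense-local exon/CDS intervals
        exons: list[list[int]] = []
        cds_iv: list[tuple[int, int]] = []
        cursor = 0
        for kind, seq in pieces:
            start, end = cursor + 1, cursor + len(seq)
            cursor = end
            if kind == "intron":
                exons.append(None)  # breaks exon runs
                continue
            if kind == "cds":
                cds_iv.append((start, end))
            if exons and exons[-1] is not None:
                exons[-1][1] = end
            else:
                if exons and exons[-1] is None:
                    exons.pop()
                exons.append([start, end])
        exon_iv = [tuple(e) for e in exons if e is not None]

        def orient(iv: tuple[int, int]) -> tuple[int, int]:
            if plan.strand == "+":
                return iv
            s, e = iv
            return (length - e + 1, length - s + 1)

        block_seq = (
            sense_seq if plan.strand == "+"
            else str(Seq(sense_seq).reverse_complement())
        )
        t1 = {
            "transcript_id": f"{plan.name}.t1",
            "exons": sorted(orient(iv) for iv in exon_iv),
            "cds": sorted(orient(iv) for iv in cds_iv),
        }
        transcripts = [t1]

        if plan.name == "MYL2_FIX":
            # a shorter second transcript (CDS = first 90 coding bases) so
            # canonical selection has something to decide
            t2_cds: list[tuple[int, int]] = []
            budget = 90
            for s, e in cds_iv:
                take = min(budget, e - s + 1)
                t2_cds.append((s, s + take - 1))
                budget -= take
                if budget == 0:
                    break
            t2_exons = [exon_iv[0]] + [iv for iv in t2_cds[1:]]
            t2 = {
                "transcript_id": f"{plan.name}.t2",
                "exons": sorted(orient(iv) for iv in t2_exons),
                "cds": sorted(orient(iv) for iv in t2_cds),
            }
            transcripts.append(t2)
        return block_seq, transcripts

    def _assemble_genome(self) -> None:
        layout = {
            "chrFIX1": ["MYL2_FIX", "SPLIT_FIX", "REV_FIX"],
            "chrFIX2": self.family_members,
        }
        for chrom, genes in layout.items():
            seq_parts: list[str] = []
            cursor = 0
            for name in genes:
                plan = self.plans[name]
                flank = _random_seq(self.rng, 100)
                seq_parts.append(flank)
                cursor += len(flank)
                block_seq, transcripts = self._assemble_block(plan)
                offset = cursor  # block-local p -> genomic offset + p
                for t in transcripts:
                    t["exons"] = [(s + offset, e + offset) for s, e in t["exons"]]
                    t["cds"] = [(s + offset, e + offset) for s, e in t["cds"]]
                plan.transcripts = transcripts
                seq_parts.append(block_seq)
                cursor += len(block_seq)
            seq_parts.append(_random_seq(self.rng, 100))
            self.contigs[chrom] = "".join(seq_parts)
        self._emit_gff()

    def _emit_gff(self) -> None:
        lines = ["##gff-version 3"]
        for chrom, seq in self.contigs.items():
            lines.append(f"##sequence-region {chrom} 1 {len(seq)}")
        for name, plan in self.plans.items():
            starts = [s for t in plan.transcripts for s, _ in t["exons"]]
            ends = [e for t in plan.transcripts for _, e in t["exons"]]
            g_start, g_end = min(starts), max(ends)
            gid = f"gene:{name}"
            lines.append(
                "\t".join(
                    [plan.chrom, "fixture", "gene", str(g_start), str(g_end), ".",
                     plan.strand, ".", f"ID={gid};gene_name={name}"]
                )
            )
            for t in plan.transcripts:
                tid = t["transcript_id"]
                t_start = min(s for s, _ in t["exons"])
                t_end = max(e for _, e in t["exons"])
                lines.append(
                    "\t".join(
                        [plan.chrom, "fixture", "mRNA", str(t_start), str(t_end),
                         ".", plan.strand, ".", f"ID={tid};Parent={gid}"]
                    )
                )
                for i, (s, e) in enumerate(t["exons"], 1):
                    lines.append(
                        "\t".join(
                            [plan.chrom, "fixture", "exon", str(s), str(e), ".",
                             plan.strand, ".", f"ID={tid}.exon{i};Parent={tid}"]
                        )
                    )
                # phases in transcript order
                cds_tx_order = (
                    t["cds"] if plan.strand == "+" else list(reversed(t["cds"]))
                )
                cum = 0
                phased = []
                for s, e in cds_tx_order:
                    phase = (3 - cum % 3) % 3
                    phased.append((s, e, phase))
                    cum += e - s + 1
                for s, e, phase in sorted(phased):
                    lines.append(
                        "\t".join(
                            [plan.chrom, "fixture", "CDS", str(s), str(e), ".",
                             plan.strand, str(phase), f"ID={tid}.cds;Parent={tid}"]
                        )
                    )
        self.gff_lines = lines

    # -- annotations ---------------------------------------------------------

    def _plan_annotations(self) -> None:
        rows = self.annotation_rows

        def add(gene, pos, ref_aa, alt_aa, category, source, source_id, desc):
            rows.append(
                {
                    "gene": gene, "residue_pos": pos, "ref_aa": ref_aa,
                    "alt_aa": alt_aa, "category": category, "source": source,
                    "source_id": source_id, "description": desc,
                    "sift": ".", "polyphen": ".",
                }
            )

        myl2 = self.plans["MYL2_FIX"].protein
        assert myl2[17] == "F" and myl2[21] == "E"
        assert "L" in _reachable_missense("TTC") and "K" in _reachable_missense("GAG")
        add("MYL2_FIX", 18, "F", "L", "disease", "UniProt", "VAR_FIX001",
            "cardiomyopathy-like fixture variant")
        add("MYL2_FIX", 22, "E", "K", "disease", "UniProt", "VAR_FIX002",
            "cardiomyopathy-like fixture variant")

        rev = self.plans["REV_FIX"]
        rev_codon17 = rev.cds_nt[48:51]
        rev_alt = _reachable_missense(rev_codon17)[0]
        add("REV_FIX", 17, rev.protein[16], rev_alt, "disease", "ClinVar",
            "RCV_FIX001", "minus-strand split-codon fixture variant")

        for gene, entries in _FUNCTIONAL_PLAN.items():
            protein = self.plans[gene].protein
            for i, (category, pos) in enumerate(entries, 1):
                add(gene, pos, protein[pos - 1], ".", category, "UniProt",
                    f"{category}_FIX{i:03d}", f"{category} fixture residue")
        dgene, p1, p2 = _DISULFID_POSITIONS
        protein = self.plans[dgene].protein
        for pos in (p1, p2):
            add(dgene, pos, protein[pos - 1], ".", "DISULFID", "UniProt",
                "DISULFID_FIX001", "disulfide bridge fixture (two residues)")

        # paralogue family: members A..C annotated at every conserved column
        for member in self.family_members[:-1]:
            protein = self.plans[member].protein
            for j, col in enumerate(self.conserved_columns, 1):
                codon = self.plans[member].cds_nt[3 * col - 3 : 3 * col]
                alt = _reachable_missense(codon)[0]
                add(member, col, protein[col - 1], alt, "disease", "HGMD",
                    f"CM_{member[-1]}{j:03d}", "family conserved-column variant")

    # -- demo VCF ------------------------------------------------------------

    def _plan_vcf(self, models: dict[str, TranscriptModel]) -> tuple[list[dict], list[dict]]:
        """Build demo VCF records and their expected annotation outcomes."""
        myl2 = models["MYL2_FIX"]
        rev = models["REV_FIX"]
        blank = models[self.family_members[-1]]

        records: list[dict] = []
        expect: list[dict] = []

        def rec(qid, chrom, pos, ref, alts):
            records.append(
                {"id": qid, "chrom": chrom, "pos": pos, "ref": ref, "alt": alts}
            )

        # exact-substitution / same-codon / synonymous trio at codon 18
        for qid, cds_pos, alt, hits, exact, sections in (
            ("q1", 52, "C", 1, 1, ["disease"]),
            ("q2", 53, "A", 1, 0, ["disease"]),
            ("q3", 54, "T", 0, 0, []),
        ):
            chrom, gpos = myl2.cds_to_genomic(cds_pos)
            ref = self.contigs[chrom][gpos - 1]
            rec(qid, chrom, gpos, ref, [alt])
            expect.append(
                {"id": qid, "alt": alt, "expected_hits": hits,
                 "expected_exact": exact, "sections": sections}
            )

        # intronic query inside MYL2 intron 1
        exon1_end = myl2.exons[0][1]
        ipos = exon1_end + 5
        iref = self.contigs[myl2.chrom][ipos - 1]
        ialt = "A" if iref != "A" else "G"
        rec("q4", myl2.chrom, ipos, iref, [ialt])
        expect.append({"id": "q4", "alt": ialt, "expected_hits": 0,
                       "expected_exact": 0, "sections": []})

        # multi-allelic record at codon 22 first base (c.64): G>A (Lys, exact
        # for the planted Glu22Lys) and G>T (Ter); both also hit the METAL
        # functional anchor at residue 22
        chrom, gpos = myl2.cds_to_genomic(64)
        ref = self.contigs[chrom][gpos - 1]
        assert ref == "G"
        rec("q5", chrom, gpos, ref, ["A", "T"])
        expect.append({"id": "q5", "alt": "A", "expected_hits": 2,
                       "expected_exact": 1, "sections": ["disease", "function"]})
        expect.append({"id": "q5", "alt": "T", "expected_hits": 2,
                       "expected_exact": 0, "sections": ["disease", "function"]})

        # indel in intergenic flank (exercises the skipped-records report)
        del_ref = self.contigs["chrFIX1"][4:6]
        rec("q6", "chrFIX1", 5, del_ref, [del_ref[0]])
        expect.append({"id": "q6", "alt": None, "expected_hits": 0,
                       "expected_exact": 0, "sections": [], "skipped": True})

        # minus-strand split-codon query realizing the ClinVar substitution;
        # residue 17 also carries the NP_BIND functional anchor
        rev_row = next(
            r for r in self.annotation_rows
            if r["gene"] == "REV_FIX" and r["category"] == "disease"
        )
        record17 = rev.codon_record(17)
        change = next(
            c for c in non_synonymous_substitutions(record17)
            if c.alt_aa == rev_row["alt_aa"]
        )
        rec("q7", change.chrom, change.genomic_pos, change.genomic_ref,
            [change.genomic_alt])
        expect.append({"id": "q7", "alt": change.genomic_alt, "expected_hits": 2,
                       "expected_exact": 1, "sections": ["disease", "function"]})

        # intergenic query: zero hits
        fpos = 50
        fref = self.contigs["chrFIX2"][fpos - 1]
        falt = "T" if fref != "T" else "G"
        rec("q8", "chrFIX2", fpos, fref, [falt])
        expect.append({"id": "q8", "alt": falt, "expected_hits": 0,
                       "expected_exact": 0, "sections": []})

        # query on the unannotated family member at a conserved column: hits
        # come only from paralogue-transferred annotations (one per source)
        col = self.conserved_columns[0]
        change = non_synonymous_substitutions(blank.codon_record(col))[0]
        rec("q9", change.chrom, change.genomic_pos, change.genomic_ref,
            [change.genomic_alt])
        expect.append({"id": "q9", "alt": change.genomic_alt,
                       "expected_hits": len(self.family_members) - 1,
                       "expected_exact": None, "sections": ["paralogue"]})

        records.sort(key=lambda r: (r["chrom"], r["pos"], r["id"]))
        return records, expect

    # -- writing -------------------------------------------------------------

    def build(self, out_dir) -> FixtureSet:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self._plan_coding_genes()
        self._plan_family()
        self._assemble_genome()
        self._plan_annotations()

        fasta = out_dir / "reference.fa"
        with open(fasta, "w") as fh:
            for chrom, seq in self.contigs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        gff3 = out_dir / "genes.gff3"
        gff3.write_text("\n".join(self.gff_lines) + "\n")

        models = load_reference(fasta, gff3)
        expected_n = sum(len(p.transcripts) for p in self.plans.values())
        if len(models) != expected_n:
            raise ValueError(
                f"fixture self-check failed: {len(models)} of {expected_n} "
                "transcripts loaded"
            )
        for m in models:
            plan = self.plans[m.gene_symbol]
            if m.transcript_id == f"{m.gene_symbol}.t1" and m.cds_sequence != plan.cds_nt:
                raise ValueError(f"fixture self-check failed: {m.transcript_id} CDS mismatch")
        canonical = canonical_by_gene(models)

        annotations = out_dir / "annotations.tsv"
        header = ["gene", "residue_pos", "ref_aa", "alt_aa", "category",
                  "source", "source_id", "description", "sift", "polyphen"]
        with open(annotations, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in self.annotation_rows:
                fh.write("\t".join(str(row[c]) for c in header) + "\n")
        anchored, quarantine = ingest_annotations(annotations, canonical)
        if len(quarantine):
            raise ValueError(
                f"fixture self-check failed: {len(quarantine)} quarantined rows"
            )

        paralogues = out_dir / "paralogues.tsv"
        with open(paralogues, "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for i, a in enumerate(self.family_members):
                for b in self.family_members[i + 1 :]:
                    fh.write(f"{a}\t{b}\n")

        vcf_records, vcf_expect = self._plan_vcf(canonical)
        vcf = out_dir / "demo.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom, seq in self.contigs.items():
                fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in vcf_records:
                fh.write(
                    f"{r['chrom']}\t{r['pos']}\t{r['id']}\t{r['ref']}\t"
                    f"{','.join(r['alt'])}\t.\t.\t.\n"
                )

        n_annotated = len(self.family_members) - 1
        manifest = {
            "seed": self.spec.seed,
            "genes": {
                name: {
                    "chrom": plan.chrom,
                    "strand": plan.strand,
                    "protein": plan.protein,
                    "cds_sequence": plan.cds_nt,
                    "transcripts": [t["transcript_id"] for t in plan.transcripts],
                    "canonical": canonical[name].transcript_id,
                }
                for name, plan in self.plans.items()
            },
            "planted_codons": {"MYL2_FIX": {"18": "TTC", "22": "GAG"}},
            "family": {
                "members": self.family_members,
                "blank_member": self.family_members[-1],
                "annotated_members": self.family_members[:-1],
                "identity": self.spec.family_identity,
                "conserved_columns": self.conserved_columns,
                "expected_transfers_per_source": self.spec.family_conserved_sites,
                "expected_total_transfers_to_blank":
                    self.spec.family_conserved_sites * n_annotated,
            },
            "annotations": {
                "n_rows": len(self.annotation_rows),
                "n_disease": sum(
                    1 for r in self.annotation_rows if r["category"] == "disease"
                ),
                "functional_categories": sorted(
                    {r["category"] for r in self.annotation_rows
                     if r["category"] != "disease"}
                ),
            },
            "vcf": {
                "n_records": len(vcf_records),
                "expectations": vcf_expect,
            },
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

        return FixtureSet(
            out_dir=out_dir, fasta=fasta, gff3=gff3, annotations=annotations,
            paralogues=paralogues, vcf=vcf, manifest_path=manifest_path,
            manifest=manifest,
        )


def generate_fixture_set(out_dir, spec: FixtureSpec | None = None) -> FixtureSet:
    """Generate the complete fixture set under ``out_dir`` (see module docs)."""
    return FixtureBuilder(spec).build(out_dir)
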