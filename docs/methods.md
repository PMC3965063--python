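# Methods

## The codon-centric model

A missense annotation is anchored not to a genomic position but to a codon
of a protein, identified as (gene, canonical transcript, residue index).
For a sense codon there are exactly nine single-base substitutions (three
positions × three alternative bases); under the standard genetic code
(translation table 1) these partition into synonymous, missense and
nonsense changes. The package's core operation replaces the first, second
and third base of an anchored codon one by one, classifies each change, and
expresses it three ways: as a codon-level change, as HGVS c./p. names
(`c.52T>C` / `p.Phe18Leu`; CDS position of residue *i*, offset *k* is
3*i* − 3 + *k*), and as a forward-strand genomic allele (complemented
inside the mapping layer for minus-strand transcripts).

Three annotation classes result. A disease annotation (a known amino-acid
substitution) splits its codon's non-synonymous changes into **reported**
(alleles realizing the annotated substitution — possibly several, by
degeneracy) and **alternative-same-codon** (all others). A functional
residue (no target residue, just a position) yields **functional-site**
variants. Annotations projected from paralogues yield **para-disease** /
**para-function** the same way. Nonsense changes are retained in all
classes with an explicit consequence label rather than filtered: a stop
gained at an annotated residue is exactly the kind of allele a user wants
surfaced, and consumers can filter on the label.

Assumptions: nuclear human-style genes (no selenocysteine, no alternative
translation tables); curated canonical transcripts (CDS divisible by 3, no
internal stop — violations are skipped with a warning, never repaired);
annotation anchors are amino-acid residues, so a stop reference codon is a
contract violation, not a stop-loss case. Only single-base substitutions
are modelled; indels and multi-nucleotide variants are out of scope
throughout (they are routed to a skipped-records report at the VCF layer).

## Coordinate mapping

All genomic and CDS coordinates are 1-based inclusive (GFF3/HGVS/VCF
convention); no half-open coordinates appear in any public contract. Each
transcript keeps an explicit per-base table CDS position ↔ genomic
position, built from its CDS intervals (ascending genomic order, reversed
for minus strand). This makes reverse-strand transcripts and codons split
across exon junctions exact by construction, at a memory cost that is
trivial for coding sequences. The CDS may include its terminal stop codon
(the common GFF3 convention); the stop codon is excluded from the protein
and from codon enumeration.

Canonical transcript selection — needed because annotations are given per
gene — is deterministic: longest CDS, ties broken by lexicographically
smallest transcript id.

## Anchoring and quarantine

Annotation rows arrive in one flat TSV schema (gene, residue position,
reference and alternative residue, category, source, source id,
description, optional transcript and SIFT/PolyPhen pass-through columns).
A row is anchored only if its gene resolves to a canonical transcript, the
position is inside the protein, and the stated reference residue matches
the canonical protein. Failing rows are quarantined with a reason
(`residue mismatch`, `gene not found`, `non-canonical anchor`, `position
out of range`, `malformed row: ...`) rather than dropped: a silent drop
would hide systematic coordinate or versioning errors in the input, and
the accounting invariant (input rows = anchored + quarantined) is cheap to
test. Disease anchors whose alternative residue is not reachable from the
anchored codon by any single-base change are kept — their codon still
yields same-codon alternatives, and an empty reported set is visible in
the output. Two-residue categories (DISULFID, CROSSLNK) are represented as
two single-residue rows sharing a source id.

The category vocabulary is closed: `disease` plus the twelve UniProt
functional-residue categories (CA_BIND, ZN_FING, DNA_BIND, NP_BIND,
ACT_SITE, METAL, BINDING, MOD_RES, LIPID, CARBOHYD, DISULFID, CROSSLNK).

Rows from different sources are kept separate (per-source provenance in
every output row and per-source tallies in the summary); deduplication
happens only on (genomic variant, anchor). Because degeneracy makes
"number of substitutions" ambiguous, the summary always reports distinct
residue outcomes and distinct DNA alleles as separate columns.

## Paralogue transfer

Pairs are an input (two-column TSV, treated as undirected because paralogy
is symmetric); gene-tree construction is out of scope. Each accepted pair
is aligned once, globally (end-to-end Needleman–Wunsch — the declared
pairs are full-length homologues, and a local alignment would silently
truncate termini), with BLOSUM62 and affine gap penalties, open 10 /
extend 1. Residue symbols outside the BLOSUM62 alphabet are mapped to X
with a warning. Among co-optimal alignments the aligner's deterministic
enumeration order fixes the result, so alignments are reproducible for
fixed inputs. The alignment induces a residue map (strictly increasing in
both coordinates; a residue appears in at most one pair), and an identity
fraction over aligned columns.

A pair is accepted when its whole-alignment identity is at least 0.30
(configurable). The threshold exists to stop transfer across marginal
alignments where "equivalent position" is not meaningful; raising it can
only remove transfers. Annotations are projected to the aligned position
when one exists (gap columns do not transfer), re-anchored to the target's
actual residue, and labelled Para-disease / Para-function. Transfer does
**not** require the aligned residues to be identical: the conservation
flag (`aligned_column_identical`) and the pair identity are carried on
every transfer so users can filter as strictly as they like — forcing
identity here would silently discard the interesting near-conserved cases,
and the flag makes the choice reversible downstream.

## VCF annotation

Queries are read with standard VCF semantics: multi-allelic records split
per alternative allele; anything that is not an ACGT single-base
substitution goes to the skipped report with a reason. Because enrichment
already enumerated *every* non-synonymous single-base change of every
annotated codon, query intersection is an exact dictionary lookup on
(chrom, pos, ref, alt): synonymous, intronic, UTR and intergenic queries
simply miss the index, which is the correct zero-hit behaviour, not an
error path. One hit is emitted per (query, anchor) — a codon carrying
several anchors yields several rows, preserving per-source provenance.
`match_kind` is `exact-substitution` when the query's protein change
equals the anchor's reported substitution, else `same-codon`. Outputs are
a deterministic TSV (stable sort over query order and hit fields) and
optionally the input VCF with `NECTAR_CLASS`, `NECTAR_MATCH`,
`NECTAR_ANCHOR`, `NECTAR_HGVSP` INFO keys, comma-joined per hit.

## The synthetic input generator

The generator stands in for the genome/transcript/curation resources the
pipeline consumes in production, at a scale where every expectation can be
planted and counted. It emulates: multi-exon structure with UTRs, a
minus-strand gene, codons split across exon junctions, a gene with two
transcripts of different CDS length (exercising canonical selection), the
classic MYL2 example (codon 18 = TTC at c.52–54, codon 22 = GAG at
c.64–66, with Phe18Leu and Glu22Lys disease rows), one row per functional
category, and a four-member paralogue family. The family is built from a
base protein of length 100 by giving each member a distinct residue at a
fixed 15% of columns, so every pairwise identity is 0.85 by construction;
five annotated columns are held conserved across all members and one
member is left unannotated, making the expected transfer count exactly
five per annotated source. All planted truths are written to a JSON
manifest consumed by the tests.

What the generator does *not* emulate: real gene structure statistics
(intron lengths 40–80 bp here), sequence composition bias, alignment gaps
between paralogues (the family is gap-free by construction, so transfer
tests do not exercise gapped columns — the alignment module's gap handling
is tested separately on small sequences), conflicting or versioned source
databases, and genome-scale input sizes. Passing tests therefore
demonstrate correctness of the mapping, expansion, transfer and lookup
logic, not robustness to messy real-world annotation releases.

Default problem sizes (proteins of 30–100 residues, ~540 enriched
variants, a 9-record demo VCF) were chosen so the full build-and-annotate
cycle is a seconds-scale operation suitable for interactive use and CI;
all quantities scale linearly in annotation count. A single default seed
(17) is committed; every file is byte-identical for a fixed seed.

## Numerical and edge-case choices

* Enumeration order of substitutions is fixed (codon offset ascending,
  then alternative base A<C<G<T) so outputs are diff-stable.
* Enriched output and hit tables are fully sorted on explicit keys; two
  runs on identical inputs are byte-identical.
* Synonymous changes are named with the repeated residue (`p.Phe18Phe`);
  stops use `Ter`.
* Wrong-chromosome and off-CDS genomic lookups return "no mapping" rather
  than raising: they are legitimate queries with no coding interpretation.
  Out-of-range CDS/codon indices raise — they indicate a caller bug.
* An index directory is persisted as its normalized plain-text inputs plus
  derived tables; loading re-derives in-memory state, trading a few
  seconds of rebuild for a format that is inspectable and version-proof.

## Known limitations

* Single-base substitutions only; no indels, MNVs, splice or regulatory
  variants.
* One genetic code; no mitochondrial or selenocysteine handling.
* Canonical-transcript-only interpretation: a query in a codon of a
  non-canonical overlapping transcript is not annotated.
* Pairwise transfer only: no multiple-sequence alignment, no cross-species
  (orthologue) transfer, and transfer quality is bounded by the global
  alignment — for pairs near the identity threshold, equivalent positions
  should be treated as hypotheses.
* SIFT/PolyPhen columns are pass-through only; the package never computes
  pathogenicity scores.
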