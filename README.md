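# nectar

Codon-centric annotation of missense variants.

Most variant-annotation tools link a DNA variant to prior knowledge through
its *genomic position*. That misses two things clinical and research
sequencing groups care about when judging a novel missense variant:

1. **Codon degeneracy.** Because several codons encode one amino acid, the
   same substitution can arise from different DNA alleles. If codon 18 of
   the cardiac regulatory light chain MYL2 reads TTC (Phe), then c.52T>C,
   c.54C>A and c.54C>G — three alleles at two genomic positions — all
   produce p.Phe18Leu. A database keyed by position links only the reported
   allele; a database keyed by *codon* links all of them, plus the five
   other residues (Ile, Val, Tyr, Cys, Ser) reachable from that codon by a
   single base change.
2. **Paralogy.** Proteins of shared ancestry conserve the residues that
   matter, so a disease variant known in one paralogue is informative at
   the equivalent aligned position of an unannotated relative.

This package builds that codon-level index and queries it. Given a
reference genome (FASTA), transcript models (GFF3), a table of known
disease variants and functional residues (TSV), and optional paralogue
pairs (TSV), it:

* anchors every annotation to a codon of its gene's canonical transcript
  (longest CDS, ties by transcript id), verifying the stated residue and
  quarantining rows that do not match;
* expands each codon by substituting the first, second and third base one
  by one, classifying each of the nine changes as synonymous, missense or
  nonsense, and naming each as HGVS c./p. plus a forward-strand genomic
  allele — producing the classes **reported**, **alternative-same-codon**
  and **functional-site**;
* projects annotations across declared paralogue pairs via global protein
  alignment (Needleman–Wunsch, BLOSUM62, affine gaps), yielding
  **para-disease** / **para-function** annotations that expand the same way;
* annotates user VCFs on the fly, distinguishing a query that realizes a
  reported substitution (`exact-substitution`) from one that merely alters
  the same codon (`same-codon`).

Only single-base substitutions in coding regions are covered; indels,
splice-site and other variant classes are out of scope by design.

## Worked example

The package ships a deterministic generator for a complete toy input set
(a small genome with plus/minus-strand and split-codon transcripts, the
MYL2-style worked example planted at codons 18 and 22, a four-member
paralogue family, and a demo VCF):

```sh
nectar fixtures --out demo
nectar build --fasta demo/reference.fa --gff3 demo/genes.gff3 \
             --annotations demo/annotations.tsv --paralogues demo/paralogues.tsv \
             --out demo_index
nectar annotate --index demo_index --vcf demo/demo.vcf --out-tsv hits.tsv
```

which prints

```
indexed 31 annotations (0 quarantined), 45 paralogue transfers, 540 enriched variants -> demo_index
11 hits, 1 skipped allele(s) -> hits.tsv
```

31 annotation rows (3 disease variants, 13 functional residues across all
twelve categories, 15 family variants) expand to 540 concrete DNA variants;
45 annotations cross paralogue pairs, 15 of them landing on the family
member that carries no annotations of its own. Of the demo VCF's nine
records, the indel is skipped and the coding single-base queries receive 11
hits; the first rows of `hits.tsv`:

```
chrom    pos  ref alt vcf_id section class                   match_kind         gene     ... hgvs_c  hgvs_p
chrFIX1  223  T   C   q1     disease reported                exact-substitution MYL2_FIX ... c.52T>C p.Phe18Leu
chrFIX1  224  T   A   q2     disease alternative-same-codon  same-codon         MYL2_FIX ... c.53T>A p.Phe18Tyr
```

q1 is the reported Phe18Leu allele itself; q2 changes the same codon to a
*different* residue (Tyr), so it is annotated as a same-codon alternative —
the phenotype attached to the reported variant is relevant context for
interpreting it. Synonymous and intronic queries yield no hits.
`nectar summarize --index demo_index` prints per-source tallies, reporting
distinct residue outcomes and distinct DNA alleles separately (the two
differ precisely because of codon degeneracy), and `nectar expand` dumps
the full enrichment table.

The same functionality is available as a library: see
`nectar.NectarIndex.build(...)`, `nectar.enumerate_substitutions(...)`,
`nectar.align_proteins(...)` and friends.

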