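"""End-to-end orchestration: build, persist and query the annotation index.

Thin glue over the library modules, used by the command-line interface and
by scripts. An index directory is simply the normalized inputs (reference,
transcript models, annotation table, paralogue pairs) plus pre-computed
result tables for inspection; loading an index re-derives the in-memory
structures from the copied inputs, which keeps the on-disk format plain
text and version-proof.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation_store import (
    EnrichedVariant,
    SiteAnnotation,
    enrich,
    enriched_to_frame,
    ingest_annotations,
    summarize,
)
from .paralogue_transfer import (
    DEFAULT_MIN_IDENTITY,
    ParalogueAnnotation,
    transfer_annotations,
    transfers_to_frame,
)
from .transcript_model import TranscriptModel, canonical_by_gene, load_reference
from .vcf_annotator import AnnotationHit, annotate, read_vcf

__all__ = ["NectarIndex"]

_CONFIG = "config.json"


@dataclass
class NectarIndex:
    """The full in-memory annotation index."""

    models: list[TranscriptModel]
    canonical: dict[str, TranscriptModel]
    annotations: list[SiteAnnotation]
    quarantine: pd.DataFrame
    paralogue_annotations: list[ParalogueAnnotation]
    enriched: list[EnrichedVariant]
    min_identity: float = DEFAULT_MIN_IDENTITY
    source_paths: dict = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        fasta,
        gff3,
        annotations_tsv,
        paralogues_tsv=None,
        min_identity: float = DEFAULT_MIN_IDENTITY,
    ) -> "NectarIndex":
        """Load inputs, anchor annotations, transfer across paralogues, enrich."""
        models = load_reference(fasta, gff3)
        canonical = canonical_by_gene(models)
        anchored, quarantine = ingest_annotations(annotations_tsv, canonical)
        para: list[ParalogueAnnotation] = []
        if paralogues_tsv is not None:
            pairs_frame = pd.read_csv(paralogues_tsv, sep="\t", dtype=str)
            pairs = list(pairs_frame.itertuples(index=False, name=None))
            sequences = {g: m.protein_sequence for g, m in canonical.items()}
            para = transfer_annotations(
                anchored, pairs, sequences, min_identity=min_identity
            )
        enriched = enrich(list(anchored) + list(para), canonical)
        return cls(
            models=models,
            canonical=canonical,
            annotations=anchored,
            quarantine=quarantine,
            paralogue_annotations=para,
            enriched=enriched,
            min_identity=min_identity,
            source_paths={
                "fasta": str(fasta),
                "gff3": str(gff3),
                "annotations": str(annotations_tsv),
                "paralogues": str(paralogues_tsv) if paralogues_tsv else None,
            },
        )

    # -- persistence ---------------------------------------------------------

    def save(self, index_dir) -> Path:
        """Write the index directory: normalized inputs + result tables."""
        index_dir = Path(index_dir)
        index_dir.mkdir(parents=True, exist_ok=True)
        names = {"fasta": "reference.fa", "gff3": "genes.gff3",
                 "annotations": "annotations.tsv"}
        for key, name in names.items():
            shutil.copyfile(self.source_paths[key], index_dir / name)
        config = {"min_identity": self.min_identity, **names}
        if self.source_paths.get("paralogues"):
            shutil.copyfile(self.source_paths["paralogues"], index_dir / "paralogues.tsv")
            config["paralogues"] = "paralogues.tsv"
        (index_dir / _CONFIG).write_text(json.dumps(config, indent=2) + "\n")

        enriched_to_frame(self.enriched).to_csv(
            index_dir / "enriched.tsv", sep="\t", index=False
        )
        self.quarantine.to_csv(index_dir / "quarantine.tsv", sep="\t", index=False)
        transfers_to_frame(self.paralogue_annotations).to_csv(
            index_dir / "transfers.tsv", sep="\t", index=False
        )
        self.summary().to_csv(index_dir / "summary.tsv", sep="\t", index=False)
        return index_dir

    @classmethod
    def load(cls, index_dir) -> "NectarIndex":
        """Rebuild the in-memory index from a saved index directory."""
        index_dir = Path(index_dir)
        config = json.loads((index_dir / _CONFIG).read_text())
        return cls.build(
            fasta=index_dir / config["fasta"],
            gff3=index_dir / config["gff3"],
            annotations_tsv=index_dir / config["annotations"],
            paralogues_tsv=(
                index_dir / config["paralogues"] if "paralogues" in config else None
            ),
            min_identity=config.get("min_identity", DEFAULT_MIN_IDENTITY),
        )

    # -- queries -------------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        return summarize(self.enriched)

    def annotate_vcf(self, vcf_path) -> tuple[list[AnnotationHit], pd.DataFrame]:
        """Annotate a query VCF; returns (hits, skipped-records report)."""
        queries, skipped = read_vcf(vcf_path)
        return annotate(queries, self.enriched), skipped
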