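"""Two-stage genome annotation: PVP call, then functional category.

Stage 1 classifies every protein as virion (PVP) or not; stage 2 assigns
one of the seven functional categories to the predicted PVPs only. The
multi-class head always emits its argmax — proteins outside the seven
trained categories are surfaced with low confidence rather than suppressed,
and a confidence band ("high" above a configurable threshold, default
0.997, else "moderate_low") makes that legible downstream. Tail-fiber
extraction feeds phage-host prediction, which expects the receptor-binding
proteins as input.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .classifier import ModelState
from .core_io import (
    NON_PVP,
    PVP,
    FunctionalCategory,
    PredictionRecord,
    ProteinRecord,
    reverse_complement,
    translate_cds,
    write_predictions_tsv,
)
from .embeddings import EmbedderBackend, embed_proteins
from .train_eval import predict

HIGH_CONFIDENCE_THRESHOLD = 0.997

BINARY_CLASSES = (NON_PVP, PVP)
CATEGORY_CLASSES = tuple(cat.value for cat in FunctionalCategory)


@dataclass(frozen=True)
class AnnotationResult:
    """Per-protein verdicts of both stages."""

    id: str
    pvp_call: str
    pvp_confidence: float
    category: FunctionalCategory | None = None
    category_confidence: float | None = None
    confidence_band: str | None = None

    def __post_init__(self) -> None:
        if (self.category is not None) != (self.pvp_call == PVP):
            raise ValueError(
                f"{self.id}: category must be present exactly when pvp_call is {PVP}"
            )


@dataclass(frozen=True)
class ORF:
    """A called open reading frame: 1-based inclusive coordinates plus CDS."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"ORF {self.id}: strand must be '+' or '-'")
        if self.end < self.start or self.start < 1:
            raise ValueError(f"ORF {self.id}: bad coordinates {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"ORF {self.id}: sequence length {len(self.sequence)} does not match "
                f"coordinates {self.start}..{self.end}"
            )


def _check_compatible(binary_model: ModelState, multi_model: ModelState, dim: int) -> None:
    for name, model in (("binary", binary_model), ("multi-class", multi_model)):
        if model.config.input_dim != dim:
            raise ValueError(
                f"{name} model expects input dim {model.config.input_dim}, "
                f"but the embedder produces {dim}"
            )


def annotate_proteins(
    records: Sequence[ProteinRecord],
    binary_model: ModelState,
    multi_model: ModelState,
    backend: EmbedderBackend,
    high_confidence: float = HIGH_CONFIDENCE_THRESHOLD,
) -> list[AnnotationResult]:
    """Run the two-stage pipeline over protein records, order preserved."""
    _check_compatible(binary_model, multi_model, backend.dim)
    if not records:
        return []
    table = embed_proteins(records, backend)
    stage1 = predict(binary_model, table)
    pvp_index = (binary_model.classes or BINARY_CLASSES).index(PVP)

    pvp_ids = [p.id for p in stage1 if p.class_index == pvp_index]
    stage2_by_id = {}
    if pvp_ids:
        sub = table.subset(pvp_ids)
        for pred in predict(multi_model, sub):
            stage2_by_id[pred.id] = pred

    results = []
    for pred in stage1:
        pvp_conf = float(pred.confidence[pvp_index])
        if pred.class_index == pvp_index:
            cat_pred = stage2_by_id[pred.id]
            cat = FunctionalCategory.from_name(
                (multi_model.classes or CATEGORY_CLASSES)[cat_pred.class_index]
            )
            cat_conf = float(cat_pred.confidence[cat_pred.class_index])
            band = "high" if cat_conf > high_confidence else "moderate_low"
            results.append(
                AnnotationResult(pred.id, PVP, pvp_conf, cat, cat_conf, band)
            )
        else:
            results.append(AnnotationResult(pred.id, NON_PVP, pvp_conf))
    return results


def filter_by_category(
    results: Iterable[AnnotationResult], category: FunctionalCategory | str
) -> list[AnnotationResult]:
    """Subset of results annotated with the given category, order preserved."""
    if isinstance(category, str):
        category = FunctionalCategory.from_name(category)
    return [r for r in results if r.category == category]


def translate_orf(orf: ORF) -> ProteinRecord:
    cds = orf.sequence if orf.strand == "+" else reverse_complement(orf.sequence)
    protein = translate_cds(cds)
    if not protein:
        raise ValueError(f"ORF {orf.id}: translation is empty (leading stop codon?)")
    return ProteinRecord(id=orf.id, sequence=protein, description=f"ORF {orf.contig}:{orf.start}-{orf.end}({orf.strand})")


def _gff_escape(value: str) -> str:
    return urllib.parse.quote(str(value), safe="")


def write_gff3(
    orfs: Sequence[ORF],
    results: Sequence[AnnotationResult],
    path: str | Path,
    source: str = "pvpkit",
) -> None:
    """One GFF3 CDS feature per ORF carrying the annotation as attributes."""
    by_id = {r.id: r for r in results}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            r = by_id[orf.id]
            attrs = [f"ID={_gff_escape(orf.id)}", f"pvp_call={_gff_escape(r.pvp_call)}",
                     f"pvp_confidence={r.pvp_confidence:.4f}"]
            if r.category is not None:
                attrs.append(f"category={_gff_escape(r.category.value)}")
                attrs.append(f"category_confidence={r.category_confidence:.4f}")
                attrs.append(f"confidence_band={_gff_escape(r.confidence_band)}")
            fh.write(
                f"{orf.contig}\t{source}\tCDS\t{orf.start}\t{orf.end}\t"
                f"{r.pvp_confidence:.4f}\t{orf.strand}\t0\t{';'.join(attrs)}\n"
            )


def annotate_genome(
    orfs: Sequence[ORF],
    binary_model: ModelState,
    multi_model: ModelState,
    backend: EmbedderBackend,
    gff_path: str | Path | None = None,
    high_confidence: float = HIGH_CONFIDENCE_THRESHOLD,
) -> list[AnnotationResult]:
    """Translate called ORFs, annotate the proteins, optionally emit GFF3."""
    proteins = [translate_orf(orf) for orf in orfs]
    results = annotate_proteins(
        proteins, binary_model, multi_model, backend, high_confidence
    )
    if gff_path is not None:
        write_gff3(orfs, results, gff_path)
    return results


def read_orf_tsv(path: str | Path) -> list[ORF]:
    """ORF table: id, contig, start, end, strand, sequence (tab-separated)."""
    orfs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["id", "contig", "start", "end", "strand", "sequence"]
        if header != expected:
            raise ValueError(f"ORF TSV header must be {expected}, got {header}")
        for line in fh:
            pid, contig, start, end, strand, seq = line.rstrip("\n").split("\t")
            orfs.append(ORF(pid, contig, int(start), int(end), strand, seq))
    return orfs


def results_to_predictions(results: Iterable[AnnotationResult]) -> list[PredictionRecord]:
    return [
        PredictionRecord(
            id=r.id,
            pvp_call=r.pvp_call,
            pvp_confidence=r.pvp_confidence,
            category=r.category,
            category_confidence=r.category_confidence,
        )
        for r in results
    ]


def write_annotation_tsv(results: Sequence[AnnotationResult], path: str | Path) -> None:
    write_predictions_tsv(results_to_predictions(results), path)
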