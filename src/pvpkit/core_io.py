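"""Sequence records, FASTA/TSV I/O, CDS translation and keyword labeling.

Phage virion proteins (PVPs) are the structural components of the phage
particle — capsid, portal, tail machinery and host-binding appendages.
Reference databases annotate them in free text, so the binary (PVP vs
non-PVP) and seven-category datasets are built from the annotation line by
keyword matching: structural phrases define the PVP set, enzyme-style
annotations (words ending in "ase") and a short list of non-structural
keywords define the non-PVP set, and everything else stays unlabeled.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

PVP = "PVP"
NON_PVP = "nonPVP"
UNLABELED = "unlabeled"


class FunctionalCategory(str, Enum):
    """The seven virion-protein functional classes, in classifier index order."""

    PORTAL = "portal"
    MAJOR_CAPSID = "major capsid"
    MINOR_CAPSID = "minor capsid"
    MAJOR_TAIL = "major tail"
    MINOR_TAIL = "minor tail"
    BASEPLATE = "baseplate"
    TAIL_FIBER = "tail fiber"

    @classmethod
    def from_name(cls, name: str) -> "FunctionalCategory":
        name = name.strip().lower().replace("_", " ")
        for cat in cls:
            if cat.value == name:
                return cat
        valid = ", ".join(c.value for c in cls)
        raise ValueError(f"unknown functional category {name!r}; valid: {valid}")


CATEGORY_ORDER: tuple[FunctionalCategory, ...] = tuple(FunctionalCategory)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id, amino-acid sequence and its annotation metadata."""

    id: str
    sequence: str
    description: str = ""
    release_date: _dt.date | None = None
    binary_label: str = UNLABELED
    category: FunctionalCategory | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.binary_label not in (PVP, NON_PVP, UNLABELED):
            raise ValueError(f"invalid binary label {self.binary_label!r}")
        if self.category is not None and self.binary_label != PVP:
            raise ValueError(
                f"record {self.id!r}: category set but binary label is not {PVP}"
            )


@dataclass(frozen=True)
class LabelRuleSet:
    """Keyword rules mapping a description line to labels.

    ``structural_keywords`` mark the PVP set; ``category_keywords`` (matched
    longest phrase first) assign one of the seven categories;
    ``nonstructural_keywords`` plus any whitespace-delimited word ending in
    ``enzyme_suffix`` mark the non-PVP set. Matching is case-insensitive
    substring matching, and structural matches take precedence over the
    enzyme-suffix rule.
    """

    structural_keywords: tuple[str, ...] = (
        "portal",
        "capsid",
        "tail",
        "fiber",
        "tape measure",
        "baseplate",
        "structural",
    )
    nonstructural_keywords: tuple[str, ...] = (
        "transcription",
        "holin",
        "lysin",
        "regulator",
    )
    enzyme_suffix: str = "ase"
    category_keywords: Mapping[str, FunctionalCategory] = field(
        default_factory=lambda: {
            "major capsid": FunctionalCategory.MAJOR_CAPSID,
            "minor capsid": FunctionalCategory.MINOR_CAPSID,
            "major tail": FunctionalCategory.MAJOR_TAIL,
            "minor tail": FunctionalCategory.MINOR_TAIL,
            "tail fiber": FunctionalCategory.TAIL_FIBER,
            "baseplate": FunctionalCategory.BASEPLATE,
            "portal": FunctionalCategory.PORTAL,
        }
    )

    def __post_init__(self) -> None:
        structural = "\n".join(self.structural_keywords).lower()
        for phrase in self.category_keywords:
            # every category phrase must itself imply a structural match
            if not any(kw in phrase.lower() for kw in map(str.lower, self.structural_keywords)):
                raise ValueError(
                    f"category phrase {phrase!r} matches no structural keyword "
                    f"({structural!r})"
                )


DEFAULT_RULES = LabelRuleSet()


def _sanitize_sequence(seq: str) -> str:
    seq = seq.upper()
    return "".join(ch if ch in STANDARD_AA else "X" for ch in seq)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into records.

    Header token 1 becomes the id, the remainder the description. Sequences
    are uppercased and characters outside the 20 standard residues become X.
    Raises on an empty file or on duplicate ids.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=_sanitize_sequence(str(entry.seq)),
                description=desc,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


def translate_cds(nucleotides: str) -> str:
    """Frame-0 translation of a CDS under the standard genetic code.

    Stops at the first stop codon (not emitted); codons containing N (or any
    character outside ACGT) translate to X; a trailing partial codon is
    ignored. Raises if fewer than 3 nucleotides are supplied.
    """
    seq = nucleotides.upper()
    if len(seq) < 3:
        raise ValueError(f"CDS shorter than one codon ({len(seq)} nt)")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide characters {sorted(bad)!r}")
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in _STOP_CODONS:
            break
        protein.append(_CODON_TABLE.get(codon, "X"))
    return "".join(protein)


def reverse_complement(nucleotides: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return nucleotides.upper().translate(comp)[::-1]


_WORD_RE = re.compile(r"[A-Za-z]+")


def label_record(record: ProteinRecord, rules: LabelRuleSet = DEFAULT_RULES) -> ProteinRecord:
    """Assign binary label (and category for PVPs) from the description.

    Structural keyword => PVP, with the category taken from the first
    longest-phrase-first category match (absent for generic structural hits
    like bare "capsid" or "tape measure"). Otherwise a non-structural keyword
    or any word ending in the enzyme suffix => nonPVP. Otherwise unlabeled.
    """
    desc = record.description.lower()
    if any(kw.lower() in desc for kw in rules.structural_keywords):
        category = None
        for phrase in sorted(rules.category_keywords, key=len, reverse=True):
            if phrase.lower() in desc:
                category = rules.category_keywords[phrase]
                break
        return replace(record, binary_label=PVP, category=category)
    if any(kw.lower() in desc for kw in rules.nonstructural_keywords) or any(
        w.endswith(rules.enzyme_suffix.lower()) for w in _WORD_RE.findall(desc)
    ):
        return replace(record, binary_label=NON_PVP, category=None)
    return replace(record, binary_label=UNLABELED, category=None)


def label_records(
    records: Iterable[ProteinRecord], rules: LabelRuleSet = DEFAULT_RULES
) -> list[ProteinRecord]:
    return [label_record(r, rules) for r in records]


@dataclass(frozen=True)
class PredictionRecord:
    """Per-protein output of the two-stage annotation pipeline."""

    id: str
    pvp_call: str
    pvp_confidence: float
    category: FunctionalCategory | None = None
    category_confidence: float | None = None


def write_predictions_tsv(
    predictions: Sequence[PredictionRecord], path: str | Path
) -> None:
    """Write predictions as TSV (header + one row each, floats to 4 dp)."""
    with open(path, "w") as fh:
        fh.write("id\tpvp_call\tpvp_confidence\tcategory\tcategory_confidence\n")
        for p in predictions:
            cat = p.category.value if p.category is not None else "NA"
            cat_conf = f"{p.category_confidence:.4f}" if p.category_confidence is not None else "NA"
            fh.write(f"{p.id}\t{p.pvp_call}\t{p.pvp_confidence:.4f}\t{cat}\t{cat_conf}\n")
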