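"""Synthetic fixtures: every pipeline stage gets realistic offline inputs.

Three generators:

* ``gen_gaussian_embeddings`` — class-structured vectors standing in for
  pooled language-model embeddings. Each class is an isotropic unit-variance
  Gaussian; class means sit at pairwise distance ``separation`` (in units of
  the within-class standard deviation), one interpretable separability knob.
* ``gen_protein_families`` — toy homologous families: one random ancestor
  per family, members are per-site substitutions at a fixed rate, so
  within-family identity concentrates near 1 - rate and between-family
  identity stays at chance. Exercises the similarity splitter.
* ``gen_annotation_corpus`` — description lines assembled from the keyword
  vocabulary of the labeling rules plus distractors, with ground truth
  attached, for labeler round-trip tests.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import NON_PVP, PVP, UNLABELED, FunctionalCategory, ProteinRecord
from .embeddings import EmbeddingTable

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class GaussianSpec:
    n_per_class: tuple[int, ...] = (100, 100)
    dim: int = 1024
    separation: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("class counts must be positive")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")


@dataclass(frozen=True)
class FamilySpec:
    n_families: int = 3
    members_per_family: int = 5
    length: int = 100
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")
        if self.length < 10:
            raise ValueError("length must be >= 10")


def gen_gaussian_embeddings(
    spec: GaussianSpec, class_names: Sequence[str] | None = None
) -> tuple[EmbeddingTable, list[str]]:
    """Class-structured embeddings plus one label per row.

    Class means lie at ``separation / sqrt(2)`` along mutually orthogonal
    random unit directions, so every pair of class means is exactly
    ``separation`` apart while the signal is spread over all coordinates
    (as pooled language-model embeddings are, rather than concentrated in
    single features); within-class noise is standard normal everywhere.
    """
    k = len(spec.n_per_class)
    if k > spec.dim:
        raise ValueError("need dim >= number of classes for the orthogonal-mean construction")
    if class_names is None:
        class_names = [f"class{i}" for i in range(k)]
    rng = np.random.default_rng(spec.seed)
    directions, _ = np.linalg.qr(rng.standard_normal((spec.dim, k)))
    rows, ids, labels = [], [], []
    for c, n in enumerate(spec.n_per_class):
        mean = spec.separation / np.sqrt(2.0) * directions[:, c]
        rows.append(rng.standard_normal((n, spec.dim)) + mean)
        ids.extend(f"{class_names[c]}_{j}" for j in range(n))
        labels.extend([class_names[c]] * n)
    table = EmbeddingTable("synthetic_gaussian", ids, np.vstack(rows))
    return table, labels


def nearest_centroid_accuracy(table: EmbeddingTable, labels: Sequence[str]) -> float:
    """Training-set accuracy of a nearest-class-centroid rule (separability gauge)."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    centroids = np.vstack([table.values[labels == c].mean(axis=0) for c in classes])
    d2 = ((table.values[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    predicted = np.asarray(classes)[d2.argmin(axis=1)]
    return float((predicted == labels).mean())


def gen_protein_families(spec: FamilySpec) -> list[ProteinRecord]:
    """Toy homologous families with controllable within-family divergence."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for f in range(spec.n_families):
        ancestor = rng.choice(AMINO_ACIDS, size=spec.length)
        for m in range(spec.members_per_family):
            member = ancestor.copy()
            if spec.mutation_rate > 0:
                hit = rng.random(spec.length) < spec.mutation_rate
                for pos in np.flatnonzero(hit):
                    choices = AMINO_ACIDS[AMINO_ACIDS != member[pos]]
                    member[pos] = rng.choice(choices)
            records.append(
                ProteinRecord(
                    id=f"fam{f}_m{m}",
                    sequence="".join(member),
                    description=f"synthetic family {f} member {m}",
                )
            )
    return records


_CATEGORY_TEMPLATES = {
    FunctionalCategory.PORTAL: "portal protein",
    FunctionalCategory.MAJOR_CAPSID: "major capsid protein",
    FunctionalCategory.MINOR_CAPSID: "minor capsid protein",
    FunctionalCategory.MAJOR_TAIL: "major tail protein",
    FunctionalCategory.MINOR_TAIL: "minor tail protein",
    FunctionalCategory.BASEPLATE: "baseplate wedge protein",
    FunctionalCategory.TAIL_FIBER: "tail fiber protein",
}

_NON_PVP_TEMPLATES = (
    "DNA polymerase",
    "terminase large subunit",
    "holin",
    "endolysin",
    "transcription factor",
    "repressor regulator protein",
    "integrase",
)

_DISTRACTOR_TEMPLATES = ("hypothetical protein", "protein of unknown function")


def gen_annotation_corpus(
    n_per_category: int = 2,
    seed: int = 0,
    n_non_pvp: int | None = None,
    n_distractors: int = 2,
    length: int = 80,
) -> tuple[list[ProteinRecord], dict[str, tuple[str, FunctionalCategory | None]]]:
    """Labeled records built from the rule vocabulary, plus the ground truth.

    Returns (records, truth) where truth maps id -> (binary label, category).
    Records carry no labels; running the labeler over them should reproduce
    the truth exactly.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    if n_non_pvp is None:
        n_non_pvp = n_per_category * len(_NON_PVP_TEMPLATES) // len(_CATEGORY_TEMPLATES) + 1
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth: dict[str, tuple[str, FunctionalCategory | None]] = {}

    def _random_seq() -> str:
        return "".join(rng.choice(AMINO_ACIDS, size=length))

    i = 0
    for cat, template in _CATEGORY_TEMPLATES.items():
        for _ in range(n_per_category):
            pid = f"syn{i}"
            records.append(ProteinRecord(pid, _random_seq(), template))
            truth[pid] = (PVP, cat)
            i += 1
    for j in range(n_non_pvp):
        pid = f"syn{i}"
        records.append(
            ProteinRecord(pid, _random_seq(), _NON_PVP_TEMPLATES[j % len(_NON_PVP_TEMPLATES)])
        )
        truth[pid] = (NON_PVP, None)
        i += 1
    for j in range(n_distractors):
        pid = f"syn{i}"
        records.append(
            ProteinRecord(pid, _random_seq(), _DISTRACTOR_TEMPLATES[j % len(_DISTRACTOR_TEMPLATES)])
        )
        truth[pid] = (UNLABELED, None)
        i += 1
    return records, truth


def with_release_dates(
    records: Sequence[ProteinRecord],
    before: int,
    early_date: _dt.date = _dt.date(2019, 6, 1),
    late_date: _dt.date = _dt.date(2021, 6, 1),
) -> list[ProteinRecord]:
    """Give the first ``before`` records an early release date, the rest late."""
    from dataclasses import replace

    return [
        replace(r, release_date=early_date if i < before else late_date)
        for i, r in enumerate(records)
    ]
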