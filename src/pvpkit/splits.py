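"""Benchmark construction: similarity scoring and the three split protocols.

Three protocols mirror how new phage proteins are encountered in practice:

* split-by-time — train on proteins released before a cutoff date, test on
  later ones (temporal generalization).
* split-by-similarity — cap the identity x coverage similarity between any
  train/test pair at a threshold t, by single-linkage grouping of proteins
  whose pairwise score exceeds t and assigning whole groups to one side
  (homology-aware generalization).
* split-by-imbalance — subsample so the non-PVP : PVP ratio equals a chosen
  balance factor r in both partitions (robustness to class skew).

The pairwise score is identity x coverage from a local alignment: identity
is the fraction of identical alignment columns, coverage the alignment
length divided by the query length. The built-in scorer is Smith-Waterman
with BLOSUM62 and affine gaps (open -11, extend -1); precomputed scores
from an external aligner drop in as a replacement.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import NON_PVP, PVP, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityScore:
    """Identity x coverage for an (a as query, b as subject) alignment."""

    id_a: str
    id_b: str
    identity: float
    coverage: float

    @property
    def score(self) -> float:
        return self.identity * self.coverage


def default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_similarity(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
    id_a: str = "a",
    id_b: str = "b",
) -> SimilarityScore:
    """Local-alignment identity x coverage with ``seq_a`` as the query.

    Identity = identical columns / alignment columns (gaps included);
    coverage = alignment columns / len(query), capped at 1. If nothing
    aligns with positive score, identity and coverage are both 0.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    if aligner is None:
        aligner = default_aligner()
    try:
        alignments = aligner.align(seq_a, seq_b)
        if len(alignments) == 0 or alignments.score <= 0:
            return SimilarityScore(id_a, id_b, 0.0, 0.0)
        best = alignments[0]
    except (ValueError, OverflowError):  # no positive-scoring alignment
        return SimilarityScore(id_a, id_b, 0.0, 0.0)
    counts = best.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    if columns == 0:
        return SimilarityScore(id_a, id_b, 0.0, 0.0)
    identity = counts.identities / columns
    coverage = min(1.0, columns / len(seq_a))
    return SimilarityScore(id_a, id_b, identity, coverage)


def symmetric_score(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Max identity x coverage over both query orderings."""
    if aligner is None:
        aligner = default_aligner()
    return max(
        pairwise_similarity(seq_a, seq_b, aligner).score,
        pairwise_similarity(seq_b, seq_a, aligner).score,
    )


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test id sets plus the protocol that produced them."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    protocol: str
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("id\tpartition\n")
            for pid in self.train_ids:
                fh.write(f"{pid}\ttrain\n")
            for pid in self.test_ids:
                fh.write(f"{pid}\ttest\n")
        sidecar = {"protocol": self.protocol, "params": dict(self.params), "seed": self.seed}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "DatasetSplit":
        path = Path(path)
        train, test = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                pid, part = line.rstrip("\n").split("\t")
                (train if part == "train" else test).append(pid)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(tuple(train), tuple(test), meta["protocol"], meta["params"], meta["seed"])


def _binary_balance(
    records_by_id: Mapping[str, ProteinRecord], ids: Sequence[str], rng: np.random.Generator
) -> list[str]:
    """Down-sample the majority binary class among ``ids`` to the minority count."""
    pvp = [i for i in ids if records_by_id[i].binary_label == PVP]
    non = [i for i in ids if records_by_id[i].binary_label == NON_PVP]
    other = [i for i in ids if records_by_id[i].binary_label not in (PVP, NON_PVP)]
    if not pvp or not non:
        return list(ids)
    k = min(len(pvp), len(non))
    keep = {str(x) for x in rng.choice(pvp, size=k, replace=False)} | {
        str(x) for x in rng.choice(non, size=k, replace=False)
    }
    return [i for i in ids if i in keep] + other


def split_by_time(
    records: Sequence[ProteinRecord],
    cutoff_date: _dt.date | str,
    balance_binary: bool = False,
    seed: int = 0,
) -> DatasetSplit:
    """Train = released strictly before the cutoff; test = the rest."""
    if isinstance(cutoff_date, str):
        cutoff_date = _dt.date.fromisoformat(cutoff_date)
    by_id = {r.id: r for r in records}
    train, test = [], []
    for r in records:
        if r.release_date is None:
            raise ValueError(f"record {r.id!r} has no release date")
        (train if r.release_date < cutoff_date else test).append(r.id)
    if not test:
        logger.warning("split_by_time: empty test set (all dates before cutoff)")
    if balance_binary:
        rng = np.random.default_rng(seed)
        train = _binary_balance(by_id, train, rng)
        test = _binary_balance(by_id, test, rng)
    return DatasetSplit(
        tuple(train), tuple(test), "time",
        {"cutoff_date": cutoff_date.isoformat(), "balance_binary": balance_binary}, seed,
    )


def compute_pairwise_scores(
    records: Sequence[ProteinRecord], aligner: Align.PairwiseAligner | None = None
) -> dict[frozenset, float]:
    """All-against-all symmetrized identity x coverage (quadratic; toy scale)."""
    if aligner is None:
        aligner = default_aligner()
    scores: dict[frozenset, float] = {}
    for a, b in itertools.combinations(records, 2):
        scores[frozenset((a.id, b.id))] = symmetric_score(a.sequence, b.sequence, aligner)
    return scores


def _stratum(record: ProteinRecord) -> str:
    return record.binary_label


def split_by_similarity(
    records: Sequence[ProteinRecord],
    threshold: float,
    test_fraction: float = 0.2,
    seed: int = 0,
    scores: Mapping[frozenset, float] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> DatasetSplit:
    """Cap cross-split similarity at ``threshold``.

    Proteins with symmetrized score > threshold are linked; connected
    components move as blocks. Components are assigned to the test side
    (shuffled by seed, stratified by component majority class) until each
    class's test fraction is met or first exceeded; the rest train. The
    construction guarantees every (train, test) pair scores <= threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    by_id = {r.id: r for r in records}
    if scores is None:
        scores = compute_pairwise_scores(records, aligner)

    # union-find over ids linked at score > threshold
    parent = {r.id: r.id for r in records}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair, s in scores.items():
        if s > threshold:
            a, b = tuple(pair)
            if a in parent and b in parent:
                parent[find(a)] = find(b)

    components: dict[str, list[str]] = {}
    for r in records:
        components.setdefault(find(r.id), []).append(r.id)
    comps = sorted(components.values(), key=lambda c: c[0])

    class_totals: dict[str, int] = {}
    for r in records:
        class_totals[_stratum(r)] = class_totals.get(_stratum(r), 0) + 1
    targets = {c: math.ceil(test_fraction * n) for c, n in class_totals.items()}

    # a component monopolizing a class makes the threshold unattainable
    for comp in comps:
        for cls, total in class_totals.items():
            in_comp = sum(1 for pid in comp if _stratum(by_id[pid]) == cls)
            if in_comp > (1 - test_fraction) * total:
                raise ValueError(
                    f"one similarity component holds {in_comp}/{total} of class "
                    f"{cls!r}; raise the threshold above {threshold}"
                )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(comps))
    test_counts = {c: 0 for c in class_totals}
    test_ids: list[str] = []
    test_set: set[str] = set()
    for idx in order:
        comp = comps[idx]
        strata = [_stratum(by_id[pid]) for pid in comp]
        majority = max(set(strata), key=lambda c: (strata.count(c), c))
        if test_counts[majority] < targets[majority]:
            test_ids.extend(comp)
            test_set.update(comp)
            for s in strata:
                test_counts[s] += 1
    train_ids = [r.id for r in records if r.id not in test_set]
    return DatasetSplit(
        tuple(train_ids), tuple(test_ids), "similarity",
        {"threshold": threshold, "test_fraction": test_fraction}, seed,
    )


def max_cross_split_score(
    split: DatasetSplit,
    records: Sequence[ProteinRecord],
    scores: Mapping[frozenset, float] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Exhaustive post-check: max symmetrized score over all train/test pairs."""
    by_id = {r.id: r for r in records}
    if scores is None:
        scores = compute_pairwise_scores(records, aligner)
    best = 0.0
    for a in split.train_ids:
        for b in split.test_ids:
            best = max(best, scores.get(frozenset((a, b)), 0.0))
    return best


def split_by_imbalance(
    records: Sequence[ProteinRecord],
    balance_factor: int,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Retain all PVPs plus r x as many non-PVPs; stratified train/test split.

    Both partitions preserve the non-PVP : PVP ratio r within one record
    per class (rounding).
    """
    r = balance_factor
    if r < 1:
        raise ValueError("balance factor must be >= 1")
    pvp = [rec.id for rec in records if rec.binary_label == PVP]
    non = [rec.id for rec in records if rec.binary_label == NON_PVP]
    if not pvp:
        raise ValueError("no PVP records")
    if len(non) < r * len(pvp):
        max_r = len(non) // len(pvp)
        raise ValueError(
            f"insufficient non-PVP records for balance factor {r}; maximum feasible is {max_r}"
        )
    rng = np.random.default_rng(seed)
    non_kept = [str(x) for x in rng.choice(non, size=r * len(pvp), replace=False)]

    def _split(ids: list[str]) -> tuple[list[str], list[str]]:
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        k = round(train_fraction * len(ids))
        return shuffled[:k], shuffled[k:]

    pvp_train, pvp_test = _split(pvp)
    non_train, non_test = _split(non_kept)
    return DatasetSplit(
        tuple(pvp_train + non_train), tuple(pvp_test + non_test), "imbalance",
        {"balance_factor": r, "train_fraction": train_fraction}, seed,
    )
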