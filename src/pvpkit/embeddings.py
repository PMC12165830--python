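"""Per-protein embeddings: backend contract, mean pooling and a cache format.

A backend turns an amino-acid sequence into an L x dim matrix of per-residue
vectors (the last-layer residue embeddings of a protein language model, in
the reference configuration dim = 1024); the per-protein feature is the
arithmetic mean over residues. Two backends ship here: a deterministic
k-mer-hash backend that needs no model weights yet preserves sequence
locality (edit-similar proteins pool to nearby vectors), and an optional
adapter for a real transformer encoder loaded through ``transformers``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_io import ProteinRecord

logger = logging.getLogger(__name__)

_MAGIC = b"PVPKEMB1"


def mean_pool(residue_matrix: np.ndarray) -> np.ndarray:
    """Arithmetic mean over residue rows of an L x dim matrix."""
    m = np.asarray(residue_matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError(f"expected non-empty L x dim matrix, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("residue matrix contains non-finite entries")
    return m.mean(axis=0)


class EmbedderBackend:
    """Contract: a named, fixed-dimension, deterministic residue embedder."""

    name: str = "abstract"
    dim: int = 0

    def residue_embeddings(self, sequence: str) -> np.ndarray:  # (L, dim)
        raise NotImplementedError

    def embed(self, sequence: str) -> np.ndarray:
        return mean_pool(self.residue_embeddings(sequence))


class KmerHashBackend(EmbedderBackend):
    """Deterministic offline backend hashing k-mer windows to unit vectors.

    Each residue's row is a pseudo-random unit vector keyed by the k-mer
    window centred on it (clamped at the ends), so sequences within small
    edit distance share most windows and pool to nearby vectors. Purely a
    function of (sequence, dim, k, seed).
    """

    def __init__(self, dim: int = 1024, k: int = 3, seed: int = 0, max_len: int = 4000):
        if dim < 1 or k < 1:
            raise ValueError("dim and k must be >= 1")
        self.name = f"kmer_hash(k={k},seed={seed})"
        self.dim = dim
        self.k = k
        self.seed = seed
        self.max_len = max_len
        self._cache: dict[str, np.ndarray] = {}

    def _vector_for(self, kmer: str) -> np.ndarray:
        vec = self._cache.get(kmer)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}:{kmer}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(struct.unpack("<Q", digest)[0])
            vec = rng.standard_normal(self.dim)
            vec /= np.linalg.norm(vec)
            self._cache[kmer] = vec
        return vec

    def residue_embeddings(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("cannot embed an empty sequence")
        if len(sequence) > self.max_len:
            logger.warning(
                "sequence of length %d truncated to %d residues", len(sequence), self.max_len
            )
            sequence = sequence[: self.max_len]
        half = self.k // 2
        rows = np.empty((len(sequence), self.dim))
        for i in range(len(sequence)):
            window = sequence[max(0, i - half) : i + self.k - half]
            rows[i] = self._vector_for(window)
        return rows


class TransformerBackend(EmbedderBackend):
    """Adapter for a real protein language model via ``transformers``.

    Optional: requires the ``transformers`` package and downloaded weights;
    nothing in the toolkit depends on it. Pools over all residue positions
    by default (``skip_special_tokens`` drops the terminal special token
    emitted by T5-style encoders).
    """

    def __init__(self, model_name: str = "Rostlab/prot_t5_xl_half_uniref50-enc",
                 dim: int = 1024, max_len: int = 4000, skip_special_tokens: bool = False):
        try:
            from transformers import T5EncoderModel, T5Tokenizer  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "TransformerBackend requires the optional 'transformers' package"
            ) from exc
        import torch  # type: ignore # pragma: no cover

        self.name = f"plm({model_name})"
        self.dim = dim
        self.max_len = max_len
        self.skip_special_tokens = skip_special_tokens
        self._torch = torch
        self._tokenizer = T5Tokenizer.from_pretrained(model_name)
        self._model = T5EncoderModel.from_pretrained(model_name).eval()

    def residue_embeddings(self, sequence: str) -> np.ndarray:  # pragma: no cover
        seq = sequence[: self.max_len]
        tokens = self._tokenizer(" ".join(seq), return_tensors="pt")
        with self._torch.no_grad():
            out = self._model(**tokens).last_hidden_state[0]
        if self.skip_special_tokens:
            out = out[: len(seq)]
        return out.cpu().numpy().astype(np.float64)


def kmer_hash_backend(dim: int = 1024, k: int = 3, seed: int = 0) -> KmerHashBackend:
    return KmerHashBackend(dim=dim, k=k, seed=seed)


@dataclass
class EmbeddingTable:
    """Ordered per-protein vectors with their provenance."""

    backend: str
    ids: list[str]
    values: np.ndarray  # (n, dim) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.ids), -1)
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids and values length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in embedding table")

    @property
    def dim(self) -> int:
        return int(self.values.shape[1])

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "EmbeddingTable":
        index = {pid: i for i, pid in enumerate(self.ids)}
        rows = [index[pid] for pid in ids]
        return EmbeddingTable(self.backend, list(ids), self.values[rows])


def embed_proteins(
    records: Iterable[ProteinRecord], backend: EmbedderBackend
) -> EmbeddingTable:
    """Embed records in order; failures are re-raised naming the protein id."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in records:
        try:
            rows.append(backend.embed(rec.sequence))
        except Exception as exc:
            raise RuntimeError(f"embedding failed for record {rec.id!r}: {exc}") from exc
        ids.append(rec.id)
    values = np.vstack(rows) if rows else np.empty((0, backend.dim))
    return EmbeddingTable(backend.name, ids, values)


def save_table(table: EmbeddingTable, path: str | Path) -> None:
    """Write the cache container: magic, JSON header, float32 payload."""
    header = json.dumps(
        {"backend": table.backend, "dim": table.dim, "n": len(table), "ids": table.ids}
    ).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        fh.write(np.ascontiguousarray(table.values, dtype=np.float32).tobytes())


def load_table(path: str | Path, expect_dim: int | None = None) -> EmbeddingTable:
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"{path}: not an embedding cache file")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hlen).decode())
        n, dim = header["n"], header["dim"]
        if expect_dim is not None and dim != expect_dim:
            raise ValueError(f"{path}: dim {dim} != expected {expect_dim}")
        payload = fh.read()
    expected = n * dim * 4
    if len(payload) != expected:
        raise ValueError(
            f"{path}: truncated payload ({len(payload)} bytes, expected {expected})"
        )
    values = np.frombuffer(payload, dtype=np.float32).reshape(n, dim).astype(np.float64)
    return EmbeddingTable(header["backend"], list(header["ids"]), values)


def export_tsv(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"e{i}" for i in range(table.dim)) + "\n")
        for pid, row in zip(table.ids, table.values):
            fh.write(pid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
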