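"""Per-protein embeddings: the embedder contract, mean pooling, fusion.

Two protein language models stand behind the method: Ankh (per-residue
feature width 1536) and ESM-2 (width 1280).  Running them needs pretrained
weights and a GPU, so this package treats an *embedder* as a contract: any
object that maps a :class:`~plmppi.dataset.ProteinRecord` to a D x L matrix
with the contracted width for its source tag.  The packaged
:class:`SyntheticEmbedder` satisfies the contract deterministically from
(sequence, seed) alone, which lets the entire pipeline run at desk scale.

Downstream of the contract the arithmetic is fixed: each matrix row is
averaged over residues (mean pooling), and the pooled Ankh (1536) and ESM-2
(1280) vectors are concatenated, Ankh first, into one 2816-dim vector per
protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import h5py
import numpy as np

from .dataset import AMINO_ALPHABET, ProteinRecord

ANKH_DIM = 1536
ESM2_DIM = 1280
FUSED_DIM = ANKH_DIM + ESM2_DIM

SOURCE_DIMS = {
    "ankh": ANKH_DIM,
    "synthetic-a": ANKH_DIM,
    "esm2": ESM2_DIM,
    "synthetic-e": ESM2_DIM,
    "synthetic": None,  # free width, for desk-scale experiments
}

_POSITION_PERIOD = 8  # positional signal cycles mod 8
_ALPHABET = sorted(AMINO_ALPHABET)
_LETTER_INDEX = {c: i for i, c in enumerate(_ALPHABET)}

__all__ = [
    "ANKH_DIM", "ESM2_DIM", "FUSED_DIM", "SOURCE_DIMS",
    "EmbeddingMatrix", "PooledVector",
    "synthetic_embed", "SyntheticEmbedder",
    "mean_pool", "concat_pair_vector", "fused_vector", "embed_dataset",
]


@dataclass
class EmbeddingMatrix:
    """A D x L per-residue feature matrix for one protein."""

    protein_id: str
    values: np.ndarray
    source: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.source not in SOURCE_DIMS:
            raise ValueError(f"unknown embedding source {self.source!r}")
        if self.values.ndim != 2:
            raise ValueError("embedding values must be a 2-D (D, L) matrix")
        expected = SOURCE_DIMS[self.source]
        if expected is not None and self.values.shape[0] != expected:
            raise ValueError(
                f"{self.source} embeddings must have {expected} rows, "
                f"got {self.values.shape[0]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.protein_id}: non-finite embedding entries")


@dataclass
class PooledVector:
    """A length-D vector: the residue-wise mean of an embedding matrix."""

    protein_id: str
    values: np.ndarray
    source: str


@lru_cache(maxsize=8)
def _column_table(dim: int, seed: int) -> np.ndarray:
    """(letters, positions mod 8, dim) table of unit-variance pseudo-random columns.

    Each column is keyed by a stable integer triple through NumPy's
    SeedSequence, so the table is identical across platforms and runs.
    """
    table = np.empty((len(_ALPHABET), _POSITION_PERIOD, dim))
    for li in range(len(_ALPHABET)):
        for pm in range(_POSITION_PERIOD):
            ss = np.random.SeedSequence(entropy=(seed, dim, li, pm))
            table[li, pm] = np.random.default_rng(ss).standard_normal(dim)
    return table


def synthetic_embed(protein: ProteinRecord, dim: int, seed: int,
                    source: str = "synthetic") -> EmbeddingMatrix:
    """Deterministic stand-in embedder.

    Column ``j`` depends only on (residue letter at j, j mod 8, seed): a
    standard-normal vector keyed by that triple.  Entries therefore have
    zero mean and unit variance, identical sequences give bitwise-identical
    matrices, and a single-residue substitution changes exactly one column.
    """
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    table = _column_table(dim, seed)
    letters = [_LETTER_INDEX[c] for c in protein.sequence]
    positions = np.arange(len(letters)) % _POSITION_PERIOD
    values = table[letters, positions].T  # (dim, L)
    return EmbeddingMatrix(protein.protein_id, values, source)


class SyntheticEmbedder:
    """Contract-satisfying embedder emulating the Ankh/ESM-2 matrix shapes.

    The two sources use the same keyed construction but independent tables
    (the key includes the width), so their features are uncorrelated.
    """

    sources = ("synthetic-a", "synthetic-e")

    def __init__(self, seed: int = 42):
        self.seed = seed

    def embed(self, protein: ProteinRecord, source: str) -> EmbeddingMatrix:
        if source not in self.sources:
            raise ValueError(f"SyntheticEmbedder cannot produce {source!r}")
        return synthetic_embed(protein, SOURCE_DIMS[source], self.seed, source)

    def signature(self) -> str:
        return f"synthetic:seed={self.seed}"


def mean_pool(matrix: EmbeddingMatrix) -> PooledVector:
    """Average each feature row over the residue axis."""
    if matrix.values.shape[1] < 1:
        raise ValueError(f"{matrix.protein_id}: cannot pool an empty matrix")
    return PooledVector(matrix.protein_id, matrix.values.mean(axis=1),
                        matrix.source)


def concat_pair_vector(v_a: PooledVector, v_e: PooledVector) -> np.ndarray:
    """Concatenate pooled Ankh-type and ESM-type vectors, Ankh first."""
    if v_a.protein_id != v_e.protein_id:
        raise ValueError(
            f"pooled vectors belong to different proteins: "
            f"{v_a.protein_id} vs {v_e.protein_id}")
    if SOURCE_DIMS[v_a.source] != ANKH_DIM:
        raise ValueError(f"first argument must be Ankh-type, got {v_a.source}")
    if SOURCE_DIMS[v_e.source] != ESM2_DIM:
        raise ValueError(f"second argument must be ESM-type, got {v_e.source}")
    if v_a.values.shape != (ANKH_DIM,) or v_e.values.shape != (ESM2_DIM,):
        raise ValueError("pooled vector lengths do not match their sources")
    return np.concatenate([v_a.values, v_e.values])


def fused_vector(protein: ProteinRecord, embedder) -> np.ndarray:
    """Pool both sources of ``embedder`` and concatenate (length 2816)."""
    src_a, src_e = embedder.sources
    v_a = mean_pool(embedder.embed(protein, src_a))
    v_e = mean_pool(embedder.embed(protein, src_e))
    return concat_pair_vector(v_a, v_e)


def _compute_vectors(proteins, embedder, mode: str) -> dict[str, np.ndarray]:
    out = {}
    src_a, src_e = embedder.sources
    for prot in proteins:
        if mode == "fused":
            out[prot.protein_id] = fused_vector(prot, embedder)
        elif mode == "ankh":
            out[prot.protein_id] = mean_pool(embedder.embed(prot, src_a)).values
        elif mode == "esm2":
            out[prot.protein_id] = mean_pool(embedder.embed(prot, src_e)).values
        else:
            raise ValueError(f"unknown embedding mode {mode!r}")
    return out


def embed_dataset(proteins: list[ProteinRecord], embedder, cache_path,
                  mode: str = "fused") -> dict[str, np.ndarray]:
    """One pooled (fused or single-source) vector per protein, cached on disk.

    The HDF5 cache is keyed by protein id and stamped with the mode and the
    embedder signature.  A rerun with unchanged inputs loads bit-identically;
    a cache built under a different mode/embedder raises a stale-cache error;
    a changed protein set triggers a transparent rebuild.
    """
    mode_dims = {"fused": FUSED_DIM, "ankh": ANKH_DIM, "esm2": ESM2_DIM}
    if mode not in mode_dims:
        raise ValueError(f"unknown embedding mode {mode!r}")
    wanted = {p.protein_id for p in proteins}
    cache_path = str(cache_path)
    import os
    if os.path.exists(cache_path):
        with h5py.File(cache_path, "r") as f:
            dim = int(f.attrs.get("dim", -1))
            sig = str(f.attrs.get("signature", ""))
            cached_mode = str(f.attrs.get("mode", ""))
            if dim != mode_dims[mode] or cached_mode != mode or \
                    sig != embedder.signature():
                raise ValueError(
                    f"stale embedding cache {cache_path}: built for "
                    f"mode={cached_mode!r} dim={dim} signature={sig!r}; "
                    f"delete the file and rebuild")
            if set(f.keys()) == wanted:
                return {pid: f[pid][()] for pid in sorted(wanted)}
    vectors = _compute_vectors(proteins, embedder, mode)
    with h5py.File(cache_path, "w") as f:
        f.attrs["dim"] = mode_dims[mode]
        f.attrs["mode"] = mode
        f.attrs["signature"] = embedder.signature()
        for pid, vec in sorted(vectors.items()):
            f.create_dataset(pid, data=vec)
    return vectors
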