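"""Synthetic data generators for desk-scale exercise of the pipeline.

Two generators:

* :func:`make_toy_string` writes a miniature STRING-format links file and
  FASTA that deliberately span every filtering boundary (scores 0.39 / 0.40
  / 0.80 / 0.85, lengths 49 / 50 / 800 / 801, a duplicated sequence), plus a
  manifest of the exact record count expected to survive each pipeline
  stage, computed by the generator's own plain enumeration at write time.
* :func:`make_planted_embeddings` builds a pair dataset with a planted
  interaction rule: each protein carries a latent vector, a pair interacts
  iff the latent dot product exceeds the quantile giving the requested
  positive count, and observed features are a fixed random linear lift of
  the latents plus Gaussian noise.  The signal survives mean-style fusion,
  so a competent pair classifier must reach high AUC; at extreme noise the
  signal is destroyed and AUC collapses to chance.

Both generators are pure functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import LabeledPair, ProteinRecord, pairwise_identity
from .embedding import FUSED_DIM

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

__all__ = ["PlantedPairSpec", "make_toy_string", "make_planted_embeddings",
           "feature_views"]


# ---------------------------------------------------------------------------
# Toy STRING fixture
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, 20, size=length))


def make_toy_string(n_proteins: int = 12, seed: int = 42, out_dir=".",
                    ratio: int = 2):
    """Write a toy links file, FASTA and expected-counts manifest.

    Returns ``(links_path, fasta_path, manifest_path, manifest)``.  The
    manifest's stage counts come from the generator's own enumeration of the
    labeling / length / clustering / subsampling rules, so they serve as an
    oracle for the dataset pipeline.
    """
    if n_proteins < 10:
        raise ValueError(f"need n_proteins >= 10, got {n_proteins}")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ids = [f"prot{i:03d}" for i in range(n_proteins)]
    lengths = {ids[0]: 49, ids[1]: 50, ids[2]: 800, ids[3]: 801, ids[4]: 120,
               ids[5]: 120}
    for pid in ids[6:]:
        lengths[pid] = int(rng.integers(60, 301))
    seqs = {pid: _random_seq(rng, lengths[pid]) for pid in ids}
    seqs[ids[5]] = seqs[ids[4]]  # planted duplicate to trigger clustering

    # Planted pairs across every score regime and both length boundaries.
    interior = ids[6:]
    i0, i1, i2, i3 = interior[:4]
    planted = [
        (i0, i1, 390),              # negative: 0.39 < 0.40
        (i0, i2, 400),              # ambiguous band (endpoint)
        (i1, i2, 600),              # ambiguous band
        (i0, i3, 800),              # ambiguous band (endpoint)
        (i1, i3, 850),              # positive: 0.85 > 0.80
        (ids[0], i0, 850),          # positive lost to length 49
        (ids[3], i1, 850),          # positive lost to length 801
        (ids[1], ids[2], 850),      # positive with boundary lengths 50/800
        (ids[4], i2, 900),          # survives clustering (ids[4] is rep)
        (ids[5], i3, 900),          # lost: ids[5] duplicates ids[4]
    ]
    used = {(min(a, b), max(a, b)) for a, b, _ in planted}

    # Filler pairs drawn from the not-yet-used pool: mostly confident
    # negatives so subsampling has a surplus, plus a few extra positives and
    # ambiguous-band scores.
    pool = [ids[1], ids[2], ids[4]] + interior  # valid-length, representative
    candidates = [(a, b) for i, a in enumerate(pool) for b in pool[i + 1:]
                  if (min(a, b), max(a, b)) not in used]
    order = rng.permutation(len(candidates))
    n_pos_extra = min(3, len(candidates))
    n_band_extra = min(4, len(candidates) - n_pos_extra)
    extra: list[tuple[str, str, int]] = []
    for rank, ci in enumerate(order):
        a, b = candidates[ci]
        used.add((min(a, b), max(a, b)))
        if rank < n_pos_extra:
            raw = int(rng.integers(801, 1001))
        elif rank < n_pos_extra + n_band_extra:
            raw = int(rng.integers(401, 800))
        else:
            raw = int(rng.integers(0, 390))
        extra.append((a, b, raw))

    records = planted + extra
    links_path = out_dir / "links.txt"
    with open(links_path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b, raw in records:
            fh.write(f"{a} {b} {raw}\n")
        # duplicated reversed orderings exercise canonical dedup
        for a, b, raw in records[:3]:
            fh.write(f"{b} {a} {raw}\n")

    fasta_path = out_dir / "proteins.fasta"
    with open(fasta_path, "w") as fh:
        for pid in ids:
            fh.write(f">{pid}\n")
            seq = seqs[pid]
            for start in range(0, len(seq), 60):
                fh.write(seq[start:start + 60] + "\n")

    # --- generator-side enumeration of expected survivor counts ---------
    canonical = {(min(a, b), max(a, b)): raw for a, b, raw in records}
    labeled = {k: (0 if raw < 400 else 1)
               for k, raw in canonical.items() if raw < 400 or raw > 800}
    sized = {k: v for k, v in labeled.items()
             if all(50 <= lengths[p] <= 800 for p in k)}
    survivors = sorted({p for k in sized for p in k})
    order = sorted(survivors, key=lambda p: (-lengths[p], p))
    reps: list[str] = []
    for pid in order:
        if not any(pairwise_identity(seqs[pid], seqs[r]) >= 0.40 for r in reps):
            reps.append(pid)
    rep_set = set(reps)
    deduped = {k: v for k, v in sized.items()
               if k[0] in rep_set and k[1] in rep_set}
    n_pos = sum(deduped.values())
    n_neg = len(deduped) - n_pos
    if n_neg < ratio * n_pos:
        raise RuntimeError(
            f"toy fixture underfilled: {n_neg} negatives for {n_pos} positives "
            f"at 1:{ratio}; increase n_proteins")
    manifest = {
        "params": {"low": 0.4, "high": 0.8, "min_len": 50, "max_len": 800,
                   "identity": 0.40, "ratio": ratio, "seed": seed},
        "counts": {
            "parsed_pairs": len(canonical),
            "labeled_pairs": len(labeled),
            "length_filtered_pairs": len(sized),
            "cluster_deduped_pairs": len(deduped),
            "rebalanced_pairs": n_pos + ratio * n_pos,
            "positive_pairs": n_pos,
            "negative_pairs": ratio * n_pos,
        },
    }
    manifest_path = out_dir / "expected_counts.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return links_path, fasta_path, manifest_path, manifest


# ---------------------------------------------------------------------------
# Planted-structure embedding fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPairSpec:
    """Parameters of the planted-interaction pair generator."""

    n_proteins: int = 300
    latent_dim: int = 8
    n_pos: int = 200
    n_neg: int = 2000
    noise_sd: float = 0.1
    seed: int = 42
    dim: int = FUSED_DIM

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        total = self.n_proteins * (self.n_proteins - 1) // 2
        if self.n_pos + self.n_neg > total:
            raise ValueError(
                f"{self.n_pos} + {self.n_neg} pairs requested but only "
                f"{total} distinct pairs exist for {self.n_proteins} proteins")


def make_planted_embeddings(spec: PlantedPairSpec):
    """Generate (labeled pairs, per-protein feature dict) with planted signal.

    Labels: the ``n_pos`` pairs with the largest latent dot products are
    positives; ``n_neg`` negatives are drawn uniformly from the remainder.
    Features: ``lift(u) + noise_sd * N(0, I)`` with a fixed random lift of
    the latent space into ``spec.dim`` dimensions.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"prot{i:04d}" for i in range(spec.n_proteins)]
    U = rng.standard_normal((spec.n_proteins, spec.latent_dim))
    iu, ju = np.triu_indices(spec.n_proteins, k=1)
    dots = np.einsum("ij,ij->i", U[iu], U[ju])
    order = np.argsort(-dots, kind="stable")
    pos_idx = order[:spec.n_pos]
    neg_idx = rng.choice(order[spec.n_pos:], size=spec.n_neg, replace=False)

    lift = rng.standard_normal((spec.latent_dim, spec.dim)) / np.sqrt(spec.latent_dim)
    X = U @ lift + spec.noise_sd * rng.standard_normal((spec.n_proteins, spec.dim))
    features = {pid: X[i] for i, pid in enumerate(ids)}

    def pair(flat: int, label: int) -> LabeledPair:
        a, b = ids[iu[flat]], ids[ju[flat]]
        return LabeledPair(min(a, b), max(a, b), label)

    pairs = [pair(i, 1) for i in pos_idx] + [pair(i, 0) for i in neg_idx]
    return pairs, features


def feature_views(features: dict[str, np.ndarray]) -> dict[str, dict[str, np.ndarray]]:
    """Fused / Ankh-width / ESM-width views of fused feature vectors.

    The single-source views take the first 1536 and last 1280 coordinates,
    matching the Ankh-first concatenation order.
    """
    from .embedding import ANKH_DIM
    return {
        "fused": features,
        "ankh": {k: v[:ANKH_DIM] for k, v in features.items()},
        "esm2": {k: v[ANKH_DIM:] for k, v in features.items()},
    }
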