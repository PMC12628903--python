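"""STRING-based PPI dataset construction.

Turns a STRING ``protein.physical.links`` file plus a FASTA of sequences
into a labeled, redundancy-reduced, class-rebalanced pair dataset:

1. parse & canonicalize scored pairs (combined score / 1000);
2. label: score < ``low`` (default 0.4) -> non-interaction, score > ``high``
   (default 0.8) -> interaction, scores inside [low, high] discarded;
3. drop pairs where either protein is shorter than 50 or longer than 800
   residues;
4. redundancy removal: greedy length-ordered clustering at 40% pairwise
   identity (a CD-HIT-style surrogate) keeping representative-only pairs;
5. negative subsampling to a fixed interaction : non-interaction ratio
   (default 1:10);
6. reproducible train/validation and k-fold splits.

All randomness flows through explicit integer seeds; every stage is a pure
function of its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

logger = logging.getLogger(__name__)

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "ProteinRecord",
    "ScoredPair",
    "LabeledPair",
    "DatasetSplit",
    "read_fasta",
    "parse_links",
    "label_pairs",
    "filter_by_length",
    "pairwise_identity",
    "greedy_identity_cluster",
    "deduplicate_by_cluster",
    "subsample_negatives",
    "make_splits",
    "build_dataset",
    "write_pairs_tsv",
    "read_pairs_tsv",
    "write_split_manifest",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id}: characters outside the 21-letter "
                f"alphabet: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoredPair:
    """A canonical (lexicographically ordered) STRING edge with score in [0,1]."""

    protein_a: str
    protein_b: str
    score: float

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-pair {self.protein_a}")
        if self.protein_a > self.protein_b:
            raise ValueError("pair not in canonical (lexicographic) order")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class LabeledPair:
    protein_a: str
    protein_b: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class DatasetSplit:
    """Train/validation pair lists plus optional k-fold index sets.

    ``folds`` index into ``train`` (the training pool); they are pairwise
    disjoint, cover the pool, and differ in size by at most one.
    """

    train: list[LabeledPair]
    validation: list[LabeledPair]
    folds: list[np.ndarray] | None
    seed: int


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, ProteinRecord]:
    """Read sequences keyed by the first whitespace token of the header."""
    proteins: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteins:
            raise ValueError(f"duplicate protein id in FASTA: {rec.id}")
        proteins[rec.id] = ProteinRecord(rec.id, str(rec.seq).upper())
    return proteins


def parse_links(path, min_records: int = 0) -> list[ScoredPair]:
    """Parse a STRING physical-links file into deduplicated canonical pairs.

    Expects whitespace-delimited ``protein1 protein2 combined_score`` lines
    with the integer score in [0, 1000]; an optional header (first token
    ``protein1``) is skipped, and self-pairs are dropped.
    """
    best: dict[tuple[str, str], float] = {}
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if lineno == 1 and fields[0] == "protein1":
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 fields, got {len(fields)}")
            a, b, raw = fields[0], fields[1], fields[2]
            try:
                raw_score = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer score {raw!r}") from None
            if not 0 <= raw_score <= 1000:
                raise ValueError(
                    f"{path}: line {lineno}: score {raw_score} outside [0, 1000]")
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            score = raw_score / 1000.0
            if key in best and best[key] != score:
                raise ValueError(
                    f"{path}: line {lineno}: conflicting scores for pair {key}")
            best[key] = score
    if n_self:
        logger.info("dropped %d self-pairs while parsing %s", n_self, path)
    pairs = [ScoredPair(a, b, s) for (a, b), s in sorted(best.items())]
    if len(pairs) < min_records:
        raise ValueError(
            f"{path}: only {len(pairs)} pair records, expected >= {min_records}")
    return pairs


# ---------------------------------------------------------------------------
# Labeling and filtering
# ---------------------------------------------------------------------------

def label_pairs(pairs: list[ScoredPair], low: float = 0.4,
                high: float = 0.8) -> list[LabeledPair]:
    """Label scores strictly below ``low`` as 0 and strictly above ``high`` as 1.

    Scores inside the ambiguous band [low, high] — including the endpoints —
    match neither definition and are excluded.
    """
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"require 0 <= low < high <= 1, got low={low} high={high}")
    out = []
    for p in pairs:
        if p.score < low:
            out.append(LabeledPair(p.protein_a, p.protein_b, 0))
        elif p.score > high:
            out.append(LabeledPair(p.protein_a, p.protein_b, 1))
    return out


def filter_by_length(pairs: list[LabeledPair],
                     proteins: dict[str, ProteinRecord],
                     min_len: int = 50, max_len: int = 800) -> list[LabeledPair]:
    """Keep pairs where both members have min_len <= length <= max_len."""
    missing = sorted({pid for p in pairs for pid in (p.protein_a, p.protein_b)
                      if pid not in proteins})
    if missing:
        raise KeyError(f"pairs reference proteins absent from FASTA: {missing}")

    def ok(pid: str) -> bool:
        return min_len <= proteins[pid].length <= max_len

    return [p for p in pairs if ok(p.protein_a) and ok(p.protein_b)]


# ---------------------------------------------------------------------------
# Redundancy clustering (CD-HIT surrogate)
# ---------------------------------------------------------------------------

# Alignment scoring for the redundancy surrogate.  Affine gap costs are
# essential here: with linear gaps, globally aligning sequences of unequal
# length can scatter the mandatory gap columns to chase coincidental matches,
# pushing the "identity" of unrelated random sequences above any useful
# threshold.  Affine costs concentrate gaps into runs, so a short sequence
# aligns against one contiguous window of a long one and unrelated pairs
# score near-zero identity while duplicates and contained domains still
# reach 1.0.
MATCH_SCORE = 2
MISMATCH_SCORE = -1
GAP_OPEN = -16  # a reopened gap must be repaid by a >= 6-identity run
GAP_EXTEND = -1


def _aligner(big: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    # Combined objective: lexicographically maximize (alignment score,
    # identical positions).  Scaling every score component by `big` and
    # adding +1 per identical pair makes the single optimal value equal
    # big * score + identities, so both are recovered exactly and the
    # result is deterministic across platforms.
    aligner.match_score = big * MATCH_SCORE + 1
    aligner.mismatch_score = big * MISMATCH_SCORE
    aligner.open_gap_score = big * GAP_OPEN
    aligner.extend_gap_score = big * GAP_EXTEND
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identical aligned positions / shorter length.

    The alignment maximizes score under (match +2, mismatch -1, gap open -16,
    gap extend -1); among score-optimal alignments the identity count is
    itself maximized, making the value unique and platform-independent.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    big = min(len(seq_a), len(seq_b)) + 1
    combined = int(round(_aligner(big).score(seq_a, seq_b)))
    matches = combined % big
    return matches / min(len(seq_a), len(seq_b))


def greedy_identity_cluster(proteins: list[ProteinRecord],
                            threshold: float = 0.40) -> dict[str, str]:
    """Greedy incremental clustering in descending-length order.

    Each protein joins the first already-chosen representative it matches at
    pairwise identity >= ``threshold``, else becomes a representative itself.
    Length ties are broken by lexicographic id, so the outcome is a pure
    function of the input set.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    ordered = sorted(proteins, key=lambda p: (-p.length, p.protein_id))
    representatives: list[ProteinRecord] = []
    assignment: dict[str, str] = {}
    for prot in ordered:
        home = None
        for rep in representatives:
            if pairwise_identity(prot.sequence, rep.sequence) >= threshold:
                home = rep
                break
        if home is None:
            representatives.append(prot)
            assignment[prot.protein_id] = prot.protein_id
        else:
            assignment[prot.protein_id] = home.protein_id
    return assignment


def deduplicate_by_cluster(pairs: list[LabeledPair],
                           clusters: dict[str, str]) -> list[LabeledPair]:
    """Keep only pairs whose both members are cluster representatives."""
    missing = sorted({pid for p in pairs for pid in (p.protein_a, p.protein_b)
                      if pid not in clusters})
    if missing:
        raise KeyError(f"cluster map does not cover: {missing}")

    def is_rep(pid: str) -> bool:
        return clusters[pid] == pid

    return [p for p in pairs if is_rep(p.protein_a) and is_rep(p.protein_b)]


# ---------------------------------------------------------------------------
# Rebalancing and splits
# ---------------------------------------------------------------------------

def subsample_negatives(pairs: list[LabeledPair], ratio: int = 10,
                        seed: int = 42) -> list[LabeledPair]:
    """Keep all positives plus exactly ratio * n_positives negatives.

    Negatives are drawn uniformly without replacement; the output lists all
    positives first, then the sampled negatives, each group in input order.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    positives = [p for p in pairs if p.label == 1]
    negatives = [p for p in pairs if p.label == 0]
    needed = ratio * len(positives)
    if len(negatives) < needed:
        raise ValueError(
            f"insufficient negatives: {len(negatives)} available, "
            f"{needed} required for {len(positives)} positives at 1:{ratio}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(negatives), size=needed, replace=False))
    return positives + [negatives[i] for i in keep]


def make_splits(pairs: list[LabeledPair], val_fraction: float = 0.2,
                k: int = 5, seed: int = 42) -> DatasetSplit:
    """Shuffle pairs into train/validation and partition train into k folds."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError(f"val_fraction must lie in (0, 1), got {val_fraction}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(pairs) < k:
        raise ValueError(f"need at least k={k} pairs, got {len(pairs)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    n_val = int(round(val_fraction * len(pairs)))
    validation = [pairs[i] for i in perm[:n_val]]
    train = [pairs[i] for i in perm[n_val:]]
    folds = assign_folds(len(train), k, seed)
    return DatasetSplit(train=train, validation=validation, folds=folds, seed=seed)


def assign_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Partition range(n) into k shuffled folds with sizes differing by <= 1."""
    if k > n:
        raise ValueError(f"k={k} exceeds number of items {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def build_dataset(links_path, fasta_path, *, low: float = 0.4, high: float = 0.8,
                  min_len: int = 50, max_len: int = 800, identity: float = 0.40,
                  ratio: int = 10, val_fraction: float = 0.2, k: int = 5,
                  seed: int = 42):
    """Run the full construction pipeline.

    Returns ``(pairs, split, proteins, stage_counts)`` where ``stage_counts``
    records the number of records surviving each stage, in order.
    """
    counts: dict[str, int] = {}
    scored = parse_links(links_path)
    counts["parsed_pairs"] = len(scored)
    labeled = label_pairs(scored, low=low, high=high)
    counts["labeled_pairs"] = len(labeled)
    proteins = read_fasta(fasta_path)
    sized = filter_by_length(labeled, proteins, min_len=min_len, max_len=max_len)
    counts["length_filtered_pairs"] = len(sized)
    used_ids = sorted({pid for p in sized for pid in (p.protein_a, p.protein_b)})
    clusters = greedy_identity_cluster([proteins[i] for i in used_ids],
                                       threshold=identity)
    deduped = deduplicate_by_cluster(sized, clusters)
    counts["cluster_deduped_pairs"] = len(deduped)
    sampled = subsample_negatives(deduped, ratio=ratio, seed=seed)
    counts["rebalanced_pairs"] = len(sampled)
    counts["positive_pairs"] = sum(p.label for p in sampled)
    counts["negative_pairs"] = counts["rebalanced_pairs"] - counts["positive_pairs"]
    split = make_splits(sampled, val_fraction=val_fraction, k=k, seed=seed)
    for name, n in counts.items():
        logger.info("stage %s: %d records", name, n)
    return sampled, split, proteins, counts


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_pairs_tsv(pairs: list[LabeledPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tlabel\n")
        for p in pairs:
            fh.write(f"{p.protein_a}\t{p.protein_b}\t{p.label}\n")


def read_pairs_tsv(path) -> list[LabeledPair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_a"):
            raise ValueError(f"{path}: missing pairs TSV header")
        for line in fh:
            a, b, label = line.rstrip("\n").split("\t")
            pairs.append(LabeledPair(a, b, int(label)))
    return pairs


def write_split_manifest(split: DatasetSplit, path) -> None:
    """Plain-text key=value manifest of split membership (train-pool indices)."""
    with open(path, "w") as fh:
        fh.write(f"seed={split.seed}\n")
        fh.write(f"n_train={len(split.train)}\n")
        fh.write(f"n_validation={len(split.validation)}\n")
        if split.folds is not None:
            fh.write(f"n_folds={len(split.folds)}\n")
            for i, fold in enumerate(split.folds):
                fh.write(f"fold{i}={','.join(map(str, fold.tolist()))}\n")
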