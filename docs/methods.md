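# Methods

This note records the models, procedures, parameter choices and known
limitations of `plmppi`, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Dataset construction

Input is a STRING-style physical-links file (whitespace-delimited
`protein1 protein2 combined_score`, score an integer in [0, 1000]) and a
FASTA of sequences. Stages, in order:

1. **Parse & canonicalize.** Scores divide by 1000; pairs are stored with
   the lexicographically smaller id first so `(a,b)` and `(b,a)` dedupe;
   self-pairs are dropped; the same pair listed with two different scores is
   an error rather than a silent overwrite.
2. **Label.** Score < 0.4 → non-interaction (0); score > 0.8 → interaction
   (1). The band [0.4, 0.8] — including both endpoints, following the strict
   reading of "below"/"above" — matches neither definition and is discarded.
3. **Length filter.** A pair survives only if both members have
   50 ≤ L ≤ 800 residues. Boundaries are inclusive.
4. **Redundancy removal** (CD-HIT-style surrogate). Proteins are visited in
   descending length (ties broken by id); each joins the first existing
   representative it matches at pairwise identity ≥ 0.40, else becomes a
   representative. Only representative–representative pairs are kept;
   remapping member pairs onto representatives is deliberately avoided
   because it can fabricate duplicate or self pairs.
5. **Negative subsampling.** All positives are kept and exactly
   `ratio × n_pos` negatives are drawn uniformly without replacement
   (default ratio 10), so the output ratio is exact by construction.
6. **Splits.** A seeded shuffle produces the train/validation split
   (default 8:2) and k shuffled folds of the training pool with sizes
   differing by at most one.

All stages are pure functions of (input, seed); stage survivor counts are
logged for auditability.

### Pairwise identity

Identity is defined as identical aligned positions of an optimal global
alignment divided by the shorter sequence length, computed with Biopython's
`PairwiseAligner`. Scoring is match +2, mismatch −1, gap open −16, gap
extend −1. Two deliberate choices:

* **Affine, strongly-opened gaps.** Under linear gap costs, globally
  aligning sequences of unequal length must contain `|L1 − L2|` gap columns
  anyway, and scattering those free gaps lets unrelated random sequences
  chase coincidental matches — identity normalized by the shorter length
  then exceeds 0.4 for essentially any short-vs-long pair, collapsing every
  dataset into one cluster. With gap open −16, a reopened gap must be repaid
  by a run of at least six identities, so a short sequence aligns against
  one contiguous window: unrelated random pairs measure ≲ 0.15 identity
  while duplicates, point mutants and contained domains still measure ≈ 1.
* **Deterministic tie-break.** Among score-optimal alignments the identity
  count is itself maximized, implemented by scaling all score components by
  a constant `K` larger than any possible identity count and adding +1 per
  identical pair; the optimal combined score then decodes uniquely as
  `K·score + identities`. This makes the value a pure function of the two
  sequences, independent of aligner traceback order or platform.

The test suite checks this implementation against exhaustive enumeration of
all global alignments (with affine gap-state tracking) on short peptides.

## Embedding layer

The package fixes an **embedder contract**: an embedder maps a protein
record to a D×L per-residue matrix, with D = 1536 for Ankh-type sources and
D = 1280 for ESM-2-type sources. Downstream arithmetic is independent of
the embedder: each row is averaged over residues (mean pooling) and the
pooled vectors concatenate Ankh-first into a 2816-dim per-protein vector.
Single-embedding ablations use the single pooled vector (1536 or 1280)
directly, without zero-padding.

The packaged **synthetic embedder** makes the whole pipeline runnable
without pretrained weights: column `j` of the matrix is a standard-normal
vector keyed (via NumPy `SeedSequence`) by the triple (residue letter at
`j`, `j mod 8`, seed). Consequences, all tested: identical inputs give
bitwise-identical matrices across platforms; a single-residue substitution
changes exactly one column; entries have mean ≈ 0 and variance ≈ 1; the
positional signal cycles with period 8 so attention has exploitable
structure without an unbounded position vocabulary. What it does **not**
emulate: any dependence of features on sequence *context* (real PLM columns
depend on the whole sequence), long-range couplings, or biochemical
similarity between amino acids. Pipeline and learnability results on
synthetic embeddings therefore validate the machinery, not the biological
signal content of real PLMs.

Pooled vectors are cached in an HDF5 container keyed by protein id and
stamped with the embedder signature and mode; a mismatched cache raises a
stale-cache error instead of silently recomputing.

## The pair classifier

For pair vectors `(V1, V2)`:

* shared-weight extraction `f_i = Dropout(ReLU(W V_i + b))`, followed by
  LayerNorm (`use_layernorm`, default on);
* MDNN profile only: multi-head self-attention over the 2-token sequence
  `(f1, f2)` — per-head `d_k = E/n_heads`, heads concatenated and projected
  back to width `E` — added residually to the tokens. After mean pooling
  there is no residue axis left, so the two extracted pair tokens are the
  only coherent token axis for this block; a residue-level variant would
  require attention before pooling and is out of scope;
* fusion: `F1` flattens single self-attention over the token pair (the only
  reading under which concatenating `F1` with `F2` yields a fixed-length
  vector); `F2` is the element-wise token mean, invariant under swapping the
  pair (attention is permutation-equivariant, so this invariance survives
  the MDNN refinement); `F = cat(F1, F2)` has length `3E`;
* head: dense ReLU layers with dropout, ending in a single sigmoid neuron.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `extractor_dim E` | 128 | at the fixed optimization budget (batch 64, 10 epochs, Adam 1e-3) wider extractors (256–512) train slower per step *and* reach lower held-out AUC on the planted fixture |
| `head_layers` | (128, 64, 1) | matches the `3E = 384` fusion width; deeper heads overfit the desk-scale fixtures |
| `n_heads` | 4 | divides `E`; standard small-transformer choice |
| `dropout_rate` | 0.1 | 0.3 costs several AUC points inside a 10-epoch budget |
| `use_layernorm` | on | stabilizes the loss surface; the biggest single contributor to reliable convergence at the fixed budget |
| init | He-normal for ReLU layers; fusion `W_v ≈ I` with small `W_q, W_k` (near-uniform initial attention); multi-head output projection zero-initialized | the attention stack starts as a near-pass-through, so early gradients reach the extractor; zero-init of the residual branch is standard transformer practice |

The layer geometry, dropout rate, head count and initialization are not
fixed by the published protocol, so they are package design choices; all
are exposed in `ModelConfig`. The published values — batch size 64, 10
epochs, Adam with learning rate 1e-3, BCE loss — are the `TrainConfig`
defaults.

### Training

Minibatch Adam (β1 0.9, β2 0.999, ε 1e-8) on BCE computed from logits (a
numerically stable fused op; the public `bce_loss` on probabilities clips
to [1e-7, 1−1e-7]). Shuffling and dropout draw from one seeded generator.
Early stopping monitors validation AUC by default (`monitor="loss"`
switches to validation loss): the protocol specifies only "validation
performance", AUC is the headline metric, and AUC-based best-epoch
selection is markedly more stable on the planted fixture. Patience is 3
epochs (never published); the best epoch's weights are restored at the end.

Cross-validation trains k fresh models, each on k−1 folds with the held-out
fold as test set. Inside each fold the training portion is split 8:2 and
the 20% drives early stopping, so the test fold is never seen during
training. Per-fold seeds derive as `seed + fold_index`: folds are
independent yet reproducible.

Gradients come from a small reverse-mode autodiff engine over NumPy arrays
(`plmppi.autodiff`). The same forward code serves training (Tensor graph)
and inference (plain arrays), so train/eval skew is structurally excluded;
every primitive's backward pass is finite-difference-checked in the tests.

## Metrics

Sensitivity TP/(TP+FN), precision TP/(TP+FP), F1 = 2PR/(P+R), and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) from counts at a
configurable threshold (default 0.5, ties predicted positive). Zero
denominators yield 0 by convention — never NaN, so fold aggregation is
always defined — and each such event is logged. AUROC is the Mann–Whitney
probability computed via midranks (exact tie handling); AUPR is step-wise
average precision (descending score, stable tie-break), chosen over
trapezoidal interpolation because trapezoids overestimate PR area. Both
raise a typed error on degenerate inputs (single class / no positives)
rather than returning a silent 0. All six implementations are verified
against brute-force oracles and, on tie-free inputs, against scikit-learn.

## Synthetic data generators

**Toy STRING fixture.** Writes a links file and FASTA that plant every
boundary the pipeline must respect — raw scores 390/400/600/800/850,
lengths 49/50/800/801, a duplicated sequence for the clustering stage —
plus filler pairs, and a manifest of the exact expected survivor count at
every stage, computed by the generator's own flat enumeration of the rules
(independent of the pipeline implementation, sharing only the identity
primitive). Byte-identical regeneration from the same seed is tested.

**Planted-structure pairs.** Each of `n_proteins` gets a latent
`u ~ N(0, I_8)`; the `n_pos` pairs with the largest `u_i·u_j` are positives
and `n_neg` negatives are drawn from the rest; observed features are a
fixed random linear lift of `u` into 2816 dims plus `noise_sd`·N(0, 1)
(defaults: 300 proteins, 200 positives, 2000 negatives — the 1:10 regime —
noise 0.1). Dot-product thresholding was chosen because the downstream
fusion (element-wise mean plus attention) can represent it without encoding
the model's exact functional form. Two measured properties worth knowing:

* the rule is *not* linearly separable in concatenated pair features (a
  bilinear form has no linear representation), so a logistic probe performs
  poorly while nonlinear models succeed — the separability check in the
  tests uses a small MLP probe;
* because proteins recur across pairs, a model can memorize per-protein
  interaction propensity; even with the lift destroyed by extreme noise,
  held-out AUC stays well above chance. Extreme-noise tests therefore
  assert a large degradation relative to default conditions, not collapse
  to 0.5. The genuine chance-level check uses untrained models.

## Problem sizes

Desk-scale defaults keep every run cheap: the full test suite executes in
about two minutes on one CPU, dominated by the five-fold ablation on the
default planted fixture (2,200 pairs, three embedding views, ~20 s per
five-fold run); `scripts/acceptance.py` takes a similar time. These sizes
were chosen as the smallest at which five-fold AUC estimates are stable to
roughly ±0.03 across seeds.

## Known limitations

* The synthetic embedder validates plumbing and learnability machinery
  only; conclusions about real Ankh/ESM-2 feature quality require real
  embeddings through the adapter contract.
* The greedy identity surrogate is quadratic in the number of proteins and
  alignment-based; it is meant for desk-scale datasets, not proteome-scale
  clustering (no word-filter heuristics).
* The fusion attention branch is pair-order sensitive by construction;
  predictions are made canonical by lexicographic pair ordering, and
  `--symmetrize mean` averages both orders. The order-difference magnitude
  is logged as a symmetry audit.
* Probability outputs are not calibrated; thresholded metrics default to
  0.5.
* Negatives come only from low-scored pairs listed in the input links file;
  random non-edge sampling is deliberately out of scope.
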