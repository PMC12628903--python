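"""The pair-classifier network: shared-weight extraction, attention fusion,
and the sigmoid prediction head.

Architecture, for a protein pair represented by per-protein embedding vectors
``v1`` and ``v2`` (fused 2816-dim by default):

1. *Shared-weight extraction* — one dense layer applied to both proteins:
   ``f_i = Dropout(ReLU(W v_i + b))``.
2. *Optional multi-head refinement* (the MDNN profile) — shape-preserving
   multi-head self-attention over the two extracted feature tokens, with a
   residual connection.
3. *Pair fusion* — two branches concatenated:
   ``F1`` flattens the output of single self-attention over the 2-token
   stack ``[f1; f2]`` (order-sensitive), and ``F2 = (f1 + f2)/2`` is the
   element-wise mean (order-symmetric).  ``F = [F1; F2]``.
4. *Prediction head* — dense ReLU layers with dropout, ending in a single
   sigmoid neuron emitting the interaction probability.

Every operation is written against the dispatch helpers in
:mod:`plmppi.autodiff`, so the same code path runs on plain arrays for
inference and on :class:`~plmppi.autodiff.Tensor` graphs for training.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "AttentionParams",
    "AttentionResult",
    "FusionOutput",
    "ModelConfig",
    "feature_extract",
    "self_attention",
    "multi_head_attention",
    "fuse_pair",
    "predict_pair",
    "PairClassifier",
]


def _shape(a) -> tuple[int, ...]:
    return a.data.shape if isinstance(a, Tensor) else np.asarray(a).shape


@dataclass
class AttentionParams:
    """Projection matrices of one scaled dot-product attention block.

    Each matrix maps the model dimension to the key dimension ``d_k``;
    all three share the same input dimension.
    """

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray

    def __post_init__(self):
        dims = {_shape(w)[0] for w in (self.w_q, self.w_k, self.w_v)}
        if len(dims) != 1:
            raise ValueError(f"projection input dimensions differ: {dims}")
        if self.d_k < 1:
            raise ValueError("key dimension d_k must be >= 1")

    @property
    def d_k(self) -> int:
        return _shape(self.w_q)[1]


@dataclass
class AttentionResult:
    """Attention output rows plus the row-stochastic weight matrix."""

    output: np.ndarray   # (tokens, d_k)
    weights: np.ndarray  # (tokens, tokens); each row sums to 1


@dataclass
class FusionOutput:
    """Both fusion branches of a pair plus their concatenation."""

    f1_vec: np.ndarray
    f2_vec: np.ndarray
    F1: np.ndarray  # flattened self-attention branch
    F2: np.ndarray  # element-wise mean branch (pair-order symmetric)
    F: np.ndarray   # cat(F1, F2)


@dataclass
class ModelConfig:
    """Hyperparameters of the pair classifier.

    The source publication fixes the training protocol (batch size 64,
    10 epochs, Adam at 1e-3, BCE loss) but not the layer geometry; the
    defaults below are the package's own choices, all overridable.
    """

    input_dim: int = 2816
    extractor_dim: int = 128
    head_layers: tuple[int, ...] = (128, 64, 1)
    n_heads: int = 4
    dropout_rate: float = 0.1
    use_multihead: bool = True
    use_layernorm: bool = True
    seed: int = 42

    def __post_init__(self):
        if not self.head_layers or self.head_layers[-1] != 1:
            raise ValueError("head_layers must end in a single-logit layer (width 1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.use_multihead and self.extractor_dim % self.n_heads != 0:
            raise ValueError(
                f"n_heads={self.n_heads} must divide extractor_dim={self.extractor_dim}")

    def to_json(self) -> str:
        d = asdict(self)
        d["head_layers"] = list(self.head_layers)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["head_layers"] = tuple(d["head_layers"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Core operations (dispatch on ndarray / Tensor)
# ---------------------------------------------------------------------------

def _dropout(x, rate: float, rng: np.random.Generator | None):
    """Inverted dropout: active only when an RNG is supplied."""
    if rng is None or rate == 0.0:
        return x
    mask = (rng.random(_shape(x)) >= rate) / (1.0 - rate)
    return x * mask


def feature_extract(v, weight, bias, *, dropout_rate: float = 0.0,
                    rng: np.random.Generator | None = None):
    """Shared-weight dense extraction: ``Dropout(ReLU(W v + b))``.

    The same ``(weight, bias)`` serve both proteins of a pair, so extraction
    carries no pair-order information.  ``v`` may be a single vector or a
    batch ``(n, input_dim)``; ``weight`` has shape ``(input_dim, out_dim)``.
    """
    if _shape(v)[-1] != _shape(weight)[0]:
        raise ValueError(
            f"input width {_shape(v)[-1]} does not match extractor input "
            f"dimension {_shape(weight)[0]}")
    return _dropout(ad.relu(v @ weight + bias), dropout_rate, rng)


def _attend(x, w_q, w_k, w_v):
    """Scaled dot-product attention core; returns (output, weights)."""
    q = x @ w_q
    k = x @ w_k
    v = x @ w_v
    d_k = _shape(w_q)[1]
    scores = (q @ ad.swap_last(k)) * (1.0 / math.sqrt(d_k))
    weights = ad.softmax_last(scores)
    return weights @ v, weights


def self_attention(x: np.ndarray, params: AttentionParams) -> AttentionResult:
    """softmax(Q Kᵀ / √d_k) V over the token rows of ``x``.

    Output rows are convex combinations of the value projections; the
    returned weight matrix is row-stochastic.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("x must be a (tokens, dim) matrix with >= 1 token")
    if x.shape[1] != _shape(params.w_q)[0]:
        raise ValueError(
            f"token width {x.shape[1]} does not match projection input "
            f"dimension {_shape(params.w_q)[0]}")
    out, w = _attend(x, params.w_q, params.w_k, params.w_v)
    return AttentionResult(output=out, weights=w)


def multi_head_attention(x: np.ndarray, heads: list[AttentionParams],
                         w_out: np.ndarray) -> np.ndarray:
    """Parallel attention heads, concatenated and linearly projected.

    With per-head ``d_k = dim / n_heads`` the concatenation restores the
    model dimension and ``w_out`` keeps the output shape equal to the
    input shape.
    """
    x = np.asarray(x, dtype=np.float64)
    dim = x.shape[-1]
    if dim % len(heads) != 0:
        raise ValueError(f"{len(heads)} heads do not divide model dim {dim}")
    outputs = [_attend(x, h.w_q, h.w_k, h.w_v)[0] for h in heads]
    return ad.concat_last(outputs) @ w_out


def fuse_pair(f1: np.ndarray, f2: np.ndarray,
              params: AttentionParams) -> FusionOutput:
    """Fuse extracted pair features into ``F = cat(F1, F2)``.

    ``F1`` flattens the self-attention output over the 2-token stack
    ``[f1; f2]`` (sensitive to pair order); ``F2`` is the element-wise mean
    of ``f1`` and ``f2`` (invariant under swapping the pair).
    """
    f1 = np.asarray(f1, dtype=np.float64)
    f2 = np.asarray(f2, dtype=np.float64)
    if f1.shape != f2.shape:
        raise ValueError(f"pair feature lengths differ: {f1.shape} vs {f2.shape}")
    tokens = ad.stack_tokens(f1, f2)
    out, _ = _attend(tokens, params.w_q, params.w_k, params.w_v)
    F1 = ad.flatten_tokens(out)
    F2 = (f1 + f2) * 0.5
    F = ad.concat_last([F1, F2])
    return FusionOutput(f1_vec=f1, f2_vec=f2, F1=F1, F2=F2, F=F)


def predict_pair(F: np.ndarray, layers: list[tuple[np.ndarray, np.ndarray]],
                 *, dropout_rate: float = 0.0,
                 rng: np.random.Generator | None = None) -> float:
    """Run the deep head on a fused vector and return the probability.

    ``layers`` is a list of ``(weight, bias)`` pairs; every layer except the
    last is followed by ReLU and (when active) dropout, and the final single
    logit passes through the sigmoid, so the result lies strictly in (0, 1).
    """
    x = np.asarray(F, dtype=np.float64)
    for i, (w, b) in enumerate(layers):
        if x.shape[-1] != _shape(w)[0]:
            raise ValueError(
                f"head layer {i}: input width {x.shape[-1]} != {_shape(w)[0]}")
        x = x @ w + b
        if not np.all(np.isfinite(np.asarray(x.data if isinstance(x, Tensor) else x))):
            raise FloatingPointError(f"non-finite activation at head layer {i}")
        if i < len(layers) - 1:
            x = _dropout(ad.relu(x), dropout_rate, rng)
    prob = np.asarray(ad.sigmoid(x))
    return prob.item() if prob.size == 1 else prob


# ---------------------------------------------------------------------------
# The trainable model
# ---------------------------------------------------------------------------

class PairClassifier:
    """Trainable PPI pair classifier (DNN / MDNN profiles).

    Parameters are held as autodiff tensors; ``forward`` builds a graph in
    training mode and runs plain NumPy in evaluation mode, through the same
    arithmetic.  Initialization is uniform scaled by 1/sqrt(fan_in), driven
    by ``config.seed``.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        E = config.extractor_dim

        def he(shape):
            # He scaling for the ReLU-activated dense layers
            return Tensor(rng.standard_normal(shape) * math.sqrt(2.0 / shape[0]))

        def small(shape, scale=0.05):
            return Tensor(rng.standard_normal(shape) * scale)

        self.params: dict[str, Tensor] = {}
        p = self.params
        p["ext_w"] = he((config.input_dim, E))
        p["ext_b"] = Tensor(np.zeros(E))
        if config.use_multihead:
            dk = E // config.n_heads
            for h in range(config.n_heads):
                p[f"mha{h}_wq"] = small((E, dk))
                p[f"mha{h}_wk"] = small((E, dk))
                p[f"mha{h}_wv"] = small((E, dk))
            # zero output projection: the residual branch starts as identity
            p["mha_out"] = Tensor(np.zeros((E, E)))
        # fusion attention starts near a pass-through: V ~ identity, small Q/K
        # (near-uniform weights), so F1 begins as a smoothed copy of (f1, f2)
        p["fuse_wq"] = small((E, E))
        p["fuse_wk"] = small((E, E))
        p["fuse_wv"] = Tensor(np.eye(E) + 0.01 * rng.standard_normal((E, E)))
        widths = [3 * E, *config.head_layers]
        self.n_head_layers = len(config.head_layers)
        for i, (din, dout) in enumerate(zip(widths[:-1], widths[1:])):
            p[f"head{i}_w"] = he((din, dout))
            p[f"head{i}_b"] = Tensor(np.zeros(dout))

    # -- forward pass ---------------------------------------------------
    def _p(self, name: str, train: bool):
        t = self.params[name]
        return t if train else t.data

    def forward(self, x1: np.ndarray, x2: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None):
        """Compute pair logits for batches ``x1``, ``x2`` of shape (n, input_dim)."""
        cfg = self.config
        drop = cfg.dropout_rate if train else 0.0
        if not train:
            rng = None
        P = lambda n: self._p(n, train)

        f1 = feature_extract(x1, P("ext_w"), P("ext_b"), dropout_rate=drop, rng=rng)
        f2 = feature_extract(x2, P("ext_w"), P("ext_b"), dropout_rate=drop, rng=rng)
        if cfg.use_layernorm:
            f1 = ad.layer_norm(f1)
            f2 = ad.layer_norm(f2)
        tokens = ad.stack_tokens(f1, f2)

        if cfg.use_multihead:
            outs = [_attend(tokens, P(f"mha{h}_wq"), P(f"mha{h}_wk"),
                            P(f"mha{h}_wv"))[0] for h in range(cfg.n_heads)]
            refined = ad.concat_last(outs) @ P("mha_out")
            tokens = tokens + refined  # residual keeps the raw features in play

        att_out, _ = _attend(tokens, P("fuse_wq"), P("fuse_wk"), P("fuse_wv"))
        F1 = ad.flatten_tokens(att_out)
        tok1 = tokens[..., 0, :] if not isinstance(tokens, Tensor) else _token(tokens, 0)
        tok2 = tokens[..., 1, :] if not isinstance(tokens, Tensor) else _token(tokens, 1)
        F2 = (tok1 + tok2) * 0.5
        x = ad.concat_last([F1, F2])

        for i in range(self.n_head_layers):
            x = x @ P(f"head{i}_w") + P(f"head{i}_b")
            if i < self.n_head_layers - 1:
                x = _dropout(ad.relu(x), drop, rng)
        # final logit, squeeze trailing singleton
        if isinstance(x, Tensor):
            return x.reshape(x.data.shape[:-1])
        return x.reshape(x.shape[:-1])

    def predict_proba(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        """Interaction probabilities in evaluation mode (deterministic)."""
        return ad.sigmoid(self.forward(np.atleast_2d(x1), np.atleast_2d(x2)))

    # -- persistence -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data for k, v in self.params.items()}

    def save(self, path) -> None:
        arrays = {f"param_{k}": v.data for k, v in self.params.items()}
        np.savez(path, config_json=np.array(self.config.to_json()), **arrays)

    @classmethod
    def load(cls, path) -> "PairClassifier":
        with np.load(path, allow_pickle=False) as z:
            config = ModelConfig.from_json(str(z["config_json"]))
            model = cls(config)
            for k in model.params:
                model.params[k] = Tensor(z[f"param_{k}"])
        model.n_head_layers = len(config.head_layers)
        return model


def _token(x: Tensor, idx: int) -> Tensor:
    """Select one token row from a (..., 2, d) tensor."""
    out = Tensor(x.data[..., idx, :], (x,))

    def backward(g):
        full = np.zeros_like(x.data)
        full[..., idx, :] = g
        return (full,)

    out._backward = backward
    return out
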