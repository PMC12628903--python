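"""Training loop (Adam + binary cross-entropy) and k-fold cross-validation.

The published protocol: minibatches of 64, up to 10 epochs, Adam at
learning rate 1e-3, BCE loss, early stopping on validation performance,
five-fold cross-validation reported as mean +/- sd.  The patience value and
the early-stopping metric are not published; this package monitors
validation loss with a default patience of 3 epochs and returns the weights
of the best epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .dataset import LabeledPair, assign_folds
from .metrics import MetricsReport, UndefinedMetricError, auroc
from .network import ModelConfig, PairClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "bce_loss",
    "pairs_to_arrays",
    "train",
    "cross_validate",
    "summarize_reports",
]

EPS = 1e-7


@dataclass
class TrainConfig:
    """Optimization hyperparameters (published defaults)."""

    batch_size: int = 64
    epochs: int = 10
    learning_rate: float = 1e-3
    patience: int = 3
    monitor: str = "auc"  # early-stopping metric: "auc" or "loss"
    seed: int = 42
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.patience < 1:
            raise ValueError("batch_size, epochs and patience must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.monitor not in ("auc", "loss"):
            raise ValueError(f"monitor must be 'auc' or 'loss', got {self.monitor!r}")


@dataclass
class TrainHistory:
    """Per-epoch training record."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = 0          # 0-based index of the best monitored epoch
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def bce_loss(probs, labels) -> float:
    """Mean binary cross-entropy of probabilities against binary labels.

    Probabilities are clipped to [1e-7, 1 - 1e-7] before the logarithm.
    """
    probs = np.asarray(probs, dtype=np.float64).ravel()
    labels = np.asarray(labels, dtype=np.float64).ravel()
    if probs.shape != labels.shape:
        raise ValueError(
            f"probs and labels lengths differ: {probs.size} vs {labels.size}")
    p = np.clip(probs, EPS, 1.0 - EPS)
    return float(np.mean(-(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p))))


def pairs_to_arrays(pairs: list[LabeledPair],
                    features: dict[str, np.ndarray]):
    """Stack per-protein feature vectors into (X1, X2, y) arrays."""
    missing = sorted({pid for p in pairs for pid in (p.protein_a, p.protein_b)
                      if pid not in features})
    if missing:
        raise KeyError(f"no embedding for proteins: {missing}")
    x1 = np.stack([features[p.protein_a] for p in pairs])
    x2 = np.stack([features[p.protein_b] for p in pairs])
    y = np.array([p.label for p in pairs], dtype=np.float64)
    return x1, x2, y


class _Adam:
    """Adam update rule over the model's parameter dict."""

    def __init__(self, params, cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self):
        c = self.cfg
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g * g
            m_hat = self.m[k] / (1 - c.adam_beta1 ** self.t)
            v_hat = self.v[k] / (1 - c.adam_beta2 ** self.t)
            p.data -= c.learning_rate * m_hat / (np.sqrt(v_hat) + c.adam_eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def _eval_loss_auc(model, x1, x2, y):
    probs = model.predict_proba(x1, x2)
    loss = bce_loss(probs, y)
    try:
        auc = auroc(probs, y)
    except UndefinedMetricError:
        auc = float("nan")
    return loss, auc


def train(model: PairClassifier, train_pairs: list[LabeledPair],
          val_pairs: list[LabeledPair], features: dict[str, np.ndarray],
          cfg: TrainConfig) -> TrainHistory:
    """Minibatch Adam training with early stopping on validation performance.

    Shuffling and dropout are driven solely by ``cfg.seed``; the model is
    left holding the weights of the best epoch.  The monitored quantity is
    validation AUC by default (``cfg.monitor = "loss"`` switches to
    validation loss); an epoch counts as an improvement only if it strictly
    beats the best so far, and training stops once ``cfg.patience``
    consecutive epochs fail to improve, or at ``cfg.epochs``.
    """
    x1, x2, y = pairs_to_arrays(train_pairs, features)
    vx1, vx2, vy = pairs_to_arrays(val_pairs, features)
    for name, arr in (("train", x1), ("train", x2), ("val", vx1), ("val", vx2)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name} features")

    rng = np.random.default_rng(cfg.seed)
    optimizer = _Adam(model.params, cfg)
    history = TrainHistory()
    best_metric = -np.inf
    best_state = {k: v.data.copy() for k, v in model.params.items()}
    since_best = 0

    def monitored(val_loss: float, val_auc: float) -> float:
        # higher is better; fall back to loss when AUC is undefined
        if cfg.monitor == "auc" and np.isfinite(val_auc):
            return val_auc
        return -val_loss

    n = len(y)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            optimizer.zero_grad()
            logits = model.forward(x1[idx], x2[idx], train=True, rng=rng)
            loss = ad.bce_with_logits(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // cfg.batch_size}, "
                    f"lr {cfg.learning_rate}")
            loss.backward()
            optimizer.step()
            batch_losses.append(float(loss.data))
        val_loss, val_auc = _eval_loss_auc(model, vx1, vx2, vy)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(val_loss)
        history.val_auc.append(val_auc)
        logger.info("epoch %d: train %.4f  val %.4f  val AUC %.4f",
                    epoch, history.train_loss[-1], val_loss, val_auc)
        if monitored(val_loss, val_auc) > best_metric:
            best_metric = monitored(val_loss, val_auc)
            history.best_epoch = epoch
            best_state = {k: v.data.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                history.stopped_early = True
                break
    for k, v in model.params.items():
        v.data = best_state[k]
    return history


def cross_validate(pairs: list[LabeledPair], features: dict[str, np.ndarray],
                   model_config: ModelConfig, cfg: TrainConfig, k: int = 5,
                   threshold: float = 0.5, inner_val_fraction: float = 0.2):
    """k-fold cross-validation: k fresh models, each tested on its held-out fold.

    Within each fold the training portion is split (1 - inner_val_fraction) :
    inner_val_fraction to drive early stopping; the test fold is never seen
    during training.  Per-fold seeds are derived as base seed + fold index so
    folds are independent yet reproducible.  Returns (reports, summary) with
    the summary holding mean and sd per metric.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    folds = assign_folds(len(pairs), k, cfg.seed)
    reports: list[MetricsReport] = []
    for i, test_idx in enumerate(folds):
        test_mask = np.zeros(len(pairs), dtype=bool)
        test_mask[test_idx] = True
        pool = [pairs[j] for j in range(len(pairs)) if not test_mask[j]]
        fold_rng = np.random.default_rng(cfg.seed + i)
        perm = fold_rng.permutation(len(pool))
        n_val = max(1, int(round(inner_val_fraction * len(pool))))
        val_pairs = [pool[j] for j in perm[:n_val]]
        tr_pairs = [pool[j] for j in perm[n_val:]]

        fold_model_cfg = ModelConfig(**{**model_config.__dict__,
                                        "seed": model_config.seed + i})
        fold_train_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + i})
        model = PairClassifier(fold_model_cfg)
        train(model, tr_pairs, val_pairs, features, fold_train_cfg)

        tx1, tx2, ty = pairs_to_arrays([pairs[j] for j in test_idx], features)
        probs = model.predict_proba(tx1, tx2)
        reports.append(MetricsReport.from_scores(probs, ty, threshold))
    return reports, summarize_reports(reports)


def summarize_reports(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Mean and sample standard deviation of each metric across folds."""
    summary = {}
    for key in ("sensitivity", "precision", "f1", "mcc", "aupr", "auc"):
        vals = np.array([getattr(r, key) for r in reports], dtype=np.float64)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        summary[key] = {"mean": float(vals.mean()), "sd": sd}
    return summary
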