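"""Training loop, class-weighted loss, cosine schedule and metrics.

Training follows the recipe of the phenotyping task: Adam (default
moments, no weight decay), cosine annealing of the learning rate from
``lr_max`` to ``lr_min`` over the epoch budget, and a cross-entropy loss
with inverse-frequency class weights (mean-normalized to 1) to counter
the imbalanced level distribution.  The best-validation-accuracy weights
are retained.

Metrics are one-vs-rest per class: precision TP/(TP+FP), recall
TP/(TP+FN), specificity TN/(TN+FP), F1 2TP/(2TP+FP+FN), with macro
averages; zero denominators yield 0 with a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from . import autodiff as ad
from .autodiff import Tensor
from .errors import DataError


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 200
    lr_max: float = 1e-4
    lr_min: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr_min < self.lr_max:
            raise ValueError(f"need lr_min < lr_max, got {self.lr_min} >= {self.lr_max}")


@dataclass
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_specificity: float
    macro_f1: float
    zero_division_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "specificity": self.specificity.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_specificity": self.macro_specificity,
            "macro_f1": self.macro_f1,
            "zero_division_flags": self.zero_division_flags,
        }


# ------------------------------------------------------------------ pieces

def class_weights(counts) -> np.ndarray:
    """Inverse-frequency weights normalized to mean 1."""
    counts = np.asarray(counts, dtype=float)
    if (counts <= 0).any():
        raise ValueError(f"all class counts must be positive, got {counts}")
    w = 1.0 / counts
    return w * len(counts) / w.sum()


def weighted_cross_entropy(logits: Tensor, labels, weights=None) -> Tensor:
    """Weight-renormalized batch cross-entropy.

    ``labels`` are 1-based class levels.  The batch loss is
    ``sum(w_i * nll_i) / sum(w_i)`` so it reduces to the plain mean when
    all weights are 1.
    """
    logits = ad.as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    n, k = logits.shape
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    if weights is None:
        weights = np.ones(k)
    weights = np.asarray(weights, dtype=float)
    ls = ad.log_softmax(logits, axis=-1)
    picked = ls[np.arange(n), labels - 1]          # (n,)
    w = weights[labels - 1]
    return -ad.sum_(ad.mul(picked, w)) * (1.0 / w.sum())


def cosine_lr(t: float, config: TrainConfig) -> float:
    """lr(t) = lr_min + (lr_max - lr_min) (1 + cos(pi t / epochs)) / 2."""
    if t < 0 or t > config.epochs:
        raise ValueError(f"epoch {t} outside [0, {config.epochs}]")
    span = config.lr_max - config.lr_min
    return config.lr_min + span * (1.0 + math.cos(math.pi * t / config.epochs)) / 2.0


class Adam:
    """Adam with default moments (0.9, 0.999), no weight decay."""

    def __init__(self, params: dict[str, Tensor], betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


# ------------------------------------------------------------------- train

def _predict_logits(model, images, text, batch_size=64) -> np.ndarray:
    out = []
    for i in range(0, len(images), batch_size):
        out.append(model.forward(images[i:i + batch_size], text[i:i + batch_size]).data)
    return np.concatenate(out, axis=0)


def train(model, train_data, val_data=None, config: TrainConfig | None = None,
          weights=None, verbose: bool = False):
    """Seeded training loop with per-epoch logging.

    ``train_data``/``val_data`` are ``(images, text, levels)`` triples with
    1-based levels.  Returns ``(best_state, log)`` where ``best_state`` is
    the parameter snapshot with the highest validation accuracy (training
    accuracy if no validation data) and ``log`` is a DataFrame with one row
    per epoch: epoch, lr, train_loss, val_loss, train_acc, val_acc.
    """
    config = config or TrainConfig()
    images, text, levels = train_data
    levels = np.asarray(levels, dtype=int)
    n = len(levels)
    params = model.named_parameters()
    opt = Adam(params)
    rng = np.random.default_rng(config.seed)
    rows = []
    best_state = {k: p.data.copy() for k, p in params.items()}
    best_metric = -np.inf

    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config)
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward(images[idx], text[idx])
            loss = weighted_cross_entropy(logits, levels[idx], weights)
            if not np.isfinite(loss.data):
                raise DataError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            ad.backward(loss)
            opt.step(lr)
            epoch_loss += float(loss.data) * len(idx)
            correct += int((logits.data.argmax(axis=1) + 1 == levels[idx]).sum())
        train_loss = epoch_loss / n
        train_acc = correct / n

        val_loss, val_acc = float("nan"), float("nan")
        if val_data is not None:
            v_img, v_txt, v_lvl = val_data
            v_logits = _predict_logits(model, v_img, v_txt)
            val_loss = float(weighted_cross_entropy(
                ad.Tensor(v_logits), v_lvl, weights).data)
            val_acc = float((v_logits.argmax(axis=1) + 1 == np.asarray(v_lvl)).mean())
            metric = val_acc
        else:
            metric = train_acc
        if metric > best_metric:
            best_metric = metric
            best_state = {k: p.data.copy() for k, p in params.items()}
        rows.append({"epoch": epoch, "lr": lr, "train_loss": train_loss,
                     "val_loss": val_loss, "train_acc": train_acc,
                     "val_acc": val_acc})
        if verbose:
            print(f"epoch {epoch:3d} lr {lr:.2e} loss {train_loss:.4f} "
                  f"acc {train_acc:.3f} val_acc {val_acc:.3f}")

    return best_state, pd.DataFrame(rows)


def load_state(model, state: dict[str, np.ndarray]) -> None:
    params = model.named_parameters()
    for k, p in params.items():
        p.data = state[k].copy()


# ---------------------------------------------------------------- evaluate

def confusion_counts(y_true, y_pred, n_classes: int):
    """Per-class one-vs-rest counts + the full confusion matrix.

    Levels are 1-based; matrix rows are true levels, columns predictions.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0:
        raise DataError("cannot evaluate an empty split")
    mat = confusion_matrix(y_true, y_pred, labels=np.arange(1, n_classes + 1))
    n = mat.sum()
    counts = []
    for c in range(n_classes):
        tp = int(mat[c, c])
        fn = int(mat[c].sum() - tp)
        fp = int(mat[:, c].sum() - tp)
        tn = int(n - tp - fn - fp)
        counts.append(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
    return counts, mat


def metrics_from_counts(counts: list[ConfusionCounts]) -> MetricsReport:
    flags = []

    def safe(num, den, what, c):
        if den == 0:
            flags.append(f"class {c + 1}: {what} denominator zero")
            return 0.0
        return num / den

    k = len(counts)
    precision = np.array([safe(cc.tp, cc.tp + cc.fp, "precision", c)
                          for c, cc in enumerate(counts)])
    recall = np.array([safe(cc.tp, cc.tp + cc.fn, "recall", c)
                       for c, cc in enumerate(counts)])
    specificity = np.array([safe(cc.tn, cc.tn + cc.fp, "specificity", c)
                            for c, cc in enumerate(counts)])
    f1 = np.array([safe(2 * cc.tp, 2 * cc.tp + cc.fp + cc.fn, "F1", c)
                   for c, cc in enumerate(counts)])
    total = counts[0].n
    correct = sum(cc.tp for cc in counts)
    return MetricsReport(
        accuracy=correct / total,
        precision=precision, recall=recall, specificity=specificity, f1=f1,
        macro_precision=float(precision.mean()), macro_recall=float(recall.mean()),
        macro_specificity=float(specificity.mean()), macro_f1=float(f1.mean()),
        zero_division_flags=flags)


def evaluate(y_true, y_pred, n_classes: int = 5):
    """MetricsReport + per-class counts + confusion matrix from predictions."""
    counts, mat = confusion_counts(y_true, y_pred, n_classes)
    return metrics_from_counts(counts), counts, mat
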