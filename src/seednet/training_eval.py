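"""Training protocol, cross-validation, metrics and Grad-CAM.

Training is plain SGD with momentum and weight decay on a softmax
cross-entropy loss (mean reduction); defaults follow the study protocol
(150 epochs, batch 32, lr 1e-3, momentum 0.9, weight decay 5e-4, 5 folds).
Evaluation reports a confusion matrix (rows = true class), overall accuracy
and per-class precision / recall / F1:

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2 P R / (P + R).

Grad-CAM heatmaps weight a chosen stage's feature maps by the spatially
averaged gradient of the target-class score, rectify the weighted sum,
min-max normalize and bilinearly upsample to the input size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .network_builder import SeedNet, softmax

__all__ = ["TrainConfig", "EvalReport", "kfold_splits", "train", "evaluate",
           "cross_validate", "grad_cam", "f1_score", "preprocess_images"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0005
    optimizer: str = "sgd"
    folds: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.optimizer != "sgd":
            raise ValueError("only the sgd optimizer is supported")


@dataclass
class EvalReport:
    confusion: np.ndarray                      # (K, K), rows = true
    accuracy: float
    per_class: List[Tuple[float, float, float]]  # (precision, recall, f1)
    n: int

    def as_dict(self) -> dict:
        return {"confusion": self.confusion.tolist(),
                "accuracy": self.accuracy,
                "per_class": [{"precision": p, "recall": r, "f1": f}
                              for p, r, f in self.per_class],
                "n": self.n}


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def preprocess_images(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 (N, 3, H, W) in roughly [-1, 1]."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError("expected (N, H, W, 3) images")
    return ((x / 255.0) - 0.5).transpose(0, 3, 1, 2) * 2.0


def kfold_splits(labels: Sequence[int], k: int = 5, rng_seed: int = 0
                 ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions; every index validates exactly once."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least {k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]


class SGD:
    """SGD with classical momentum; weight decay added to the gradient."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


def _cross_entropy(logits: np.ndarray, labels: np.ndarray
                   ) -> Tuple[float, np.ndarray]:
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -float(logp[np.arange(n), labels].mean())
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def train(model: SeedNet, images: np.ndarray, labels: np.ndarray,
          cfg: TrainConfig = TrainConfig(),
          val_images: Optional[np.ndarray] = None,
          val_labels: Optional[np.ndarray] = None,
          callback: Optional[Callable[[int, dict], None]] = None
          ) -> List[Dict[str, float]]:
    """Fit in place; returns per-epoch history of loss and accuracy."""
    if len(images) == 0:
        raise ValueError("empty dataset")
    x = preprocess_images(images) if images.ndim == 4 and \
        images.shape[-1] == 3 else np.asarray(images, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(cfg.rng_seed)
    opt = SGD(model.parameters(), lr=cfg.learning_rate,
              momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    history: List[Dict[str, float]] = []
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            logits = model(x[idx])
            loss, dlogits = _cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        entry = {"epoch": epoch + 1,
                 "loss": float(np.mean(losses)),
                 "accuracy": correct / len(x)}
        if val_images is not None:
            report = evaluate(model, val_images, val_labels)
            entry["val_accuracy"] = report.accuracy
            model.train()
        history.append(entry)
        if callback is not None:
            callback(epoch, entry)
    model.eval()
    return history


def predict_logits(model: SeedNet, images: np.ndarray,
                   batch_size: int = 32) -> np.ndarray:
    x = preprocess_images(images) if images.ndim == 4 and \
        images.shape[-1] == 3 else np.asarray(images, dtype=np.float32)
    model.eval()
    outs = [model(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def evaluate(model: SeedNet, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 32) -> EvalReport:
    """Argmax predictions -> confusion matrix and per-class P/R/F1."""
    y = np.asarray(labels, dtype=np.int64)
    pred = predict_logits(model, images, batch_size).argmax(axis=1)
    k = model.cfg.num_classes
    confusion = _sk_confusion(y, pred, labels=np.arange(k))
    return report_from_confusion(confusion)


def report_from_confusion(confusion: np.ndarray) -> EvalReport:
    confusion = np.asarray(confusion)
    n = int(confusion.sum())
    accuracy = float(np.trace(confusion) / n) if n else 0.0
    per_class = []
    for c in range(confusion.shape[0]):
        tp = confusion[c, c]
        fp = confusion[:, c].sum() - tp
        fn = confusion[c, :].sum() - tp
        if tp + fp == 0:
            warnings.warn(f"class {c} has no predicted positives; "
                          "precision reported as 0", stacklevel=2)
            precision = 0.0
        else:
            precision = float(tp / (tp + fp))
        recall = float(tp / (tp + fn)) if tp + fn else 0.0
        per_class.append((precision, recall, f1_score(precision, recall)))
    return EvalReport(confusion=confusion, accuracy=accuracy,
                      per_class=per_class, n=n)


def cross_validate(build_fn: Callable[[], SeedNet], images: np.ndarray,
                   labels: np.ndarray, cfg: TrainConfig = TrainConfig()
                   ) -> Dict[str, object]:
    """k-fold training; the validation fold doubles as the test set.

    Final metrics are the mean over folds of the last-epoch validation
    values.
    """
    folds = kfold_splits(labels, k=cfg.folds, rng_seed=cfg.rng_seed)
    reports, histories = [], []
    for fi, (tr, va) in enumerate(folds):
        model = build_fn()
        fold_cfg = replace(cfg, rng_seed=cfg.rng_seed + fi)
        histories.append(train(model, images[tr], labels[tr], fold_cfg))
        reports.append(evaluate(model, images[va], labels[va]))
    return {
        "fold_reports": reports,
        "histories": histories,
        "mean_accuracy": float(np.mean([r.accuracy for r in reports])),
        "mean_loss": float(np.mean([h[-1]["loss"] for h in histories])),
    }


def grad_cam(model: SeedNet, image: np.ndarray, target_class: int,
             stage_index: int = -1) -> np.ndarray:
    """Class-discriminative heatmap in [0, 1] at the input's spatial size.

    ``stage_index`` selects which stage's output feature maps are explained;
    the default is the last stage (the last conv's output after its block).
    """
    if not 0 <= target_class < model.cfg.num_classes:
        raise ValueError("target_class out of range")
    n_stages = len(model.stages)
    if stage_index < 0:
        stage_index += n_stages
    if not 0 <= stage_index < n_stages:
        raise ValueError(f"stage_index must be in [-{n_stages}, {n_stages})")
    if image.ndim == 3 and image.shape[-1] == 3:
        x = preprocess_images(image[None])
    elif image.ndim == 3:
        x = np.asarray(image, dtype=np.float32)[None]
    else:
        raise ValueError("expected one (H, W, 3) image")
    model.eval()
    logits = model(x)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    grad = model.backward_to_stage(dlogits, stage_index)
    feat = model._stage_maps[stage_index]
    weights = grad.mean(axis=(2, 3))          # (1, C)
    cam = np.maximum((weights[:, :, None, None] * feat).sum(axis=1), 0.0)[0]
    cam = resize(cam, x.shape[2:], order=1, mode="edge", anti_aliasing=False)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        return (cam - lo) / (hi - lo)
    return np.zeros_like(cam)
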