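"""Branch training (momentum SGD), patch voting, hybrid fusion and bagging.

A branch is trained with cross-entropy on minibatches; at inference the local
branch votes over per-patch predictions, the two branches are merged by a
convex weight, and several hybrid models trained on different fold
compositions vote for the final label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .nn import softmax
from .tiling import TilingSpec, downsample_global, tile

__all__ = [
    "TrainConfig",
    "TrainingDivergedError",
    "train_branch",
    "vote",
    "predict_local",
    "predict_hybrid",
    "HybridClassifier",
    "ensemble_predict",
    "image_to_tensor",
]

DEFAULT_LAMBDA = 0.6


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    """Momentum-SGD hyperparameters.

    Defaults follow the reference training protocol: batch 10, initial
    learning rate 4e-4 decaying exponentially every 10000 iterations,
    momentum 0.9, weight decay 0.009, 40000 iterations.  The decay factor is
    not stated in the protocol; 0.1 per step is the documented default.
    """

    batch_size: int = 10
    initial_lr: float = 0.0004
    momentum: float = 0.9
    weight_decay: float = 0.009
    iterations: int = 40000
    lr_decay_every: int = 10000
    lr_decay_factor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.iterations < 0 or self.lr_decay_every < 1:
            raise ValueError("batch size / iterations / decay period must be positive")
        if self.initial_lr < 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("hyperparameters must be non-negative")

    @classmethod
    def desk(cls, iterations: int = 1000, initial_lr: float = 0.02, seed: int = 0,
             **kwargs) -> "TrainConfig":
        """Desk-scale profile for toy-width models in tests."""
        return cls(iterations=iterations, initial_lr=initial_lr, seed=seed,
                   weight_decay=1e-4, **kwargs)


def train_branch(model, x: np.ndarray, y: np.ndarray, cfg: TrainConfig
                 ) -> list[float]:
    """Cross-entropy training of one branch; returns the per-iteration loss trace."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.ndim != 4 or x.shape[0] == 0 or x.shape[0] != y.shape[0]:
        raise ValueError("expected non-empty (N, C, H, W) inputs with matching labels")
    rng = np.random.default_rng(cfg.seed)
    params = list(model.parameters())
    velocity = [np.zeros_like(p.value) for p in params]
    n = x.shape[0]
    order = rng.permutation(n)
    cursor = 0
    trace: list[float] = []
    for it in range(cfg.iterations):
        if cursor + cfg.batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + cfg.batch_size]
        cursor += cfg.batch_size
        logits = model.forward(x[idx], train=True, return_logits=True)
        probs = softmax(logits)
        b = idx.shape[0]
        loss = float(-np.mean(np.log(probs[np.arange(b), y[idx]] + 1e-12)))
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss at iteration {it}: {loss}"
            )
        trace.append(loss)
        grad = probs.copy()
        grad[np.arange(b), y[idx]] -= 1.0
        grad /= b
        for p in params:
            p.zero_grad()
        model.backward(grad)
        lr = cfg.initial_lr * cfg.lr_decay_factor ** (it // cfg.lr_decay_every)
        for p, v in zip(params, velocity):
            g = p.grad + (cfg.weight_decay * p.value if p.weight_decay else 0.0)
            v *= cfg.momentum
            v -= lr * g
            p.value += v
    return trace


# ---------------------------------------------------------------------------
# Prediction fusion
# ---------------------------------------------------------------------------

def vote(probs: Sequence[np.ndarray], rule: str = "sum") -> np.ndarray:
    """Combine probability vectors by mean (sum rule) or majority vote (max).

    Under the max rule the winner is the majority argmax label and the
    returned vector is the mean over the voters of that label; label ties
    fall back to the sum rule.
    """
    mat = np.asarray([np.asarray(p, dtype=float).ravel() for p in probs])
    if mat.shape[0] == 0:
        raise ValueError("need at least one prediction to vote")
    if rule == "sum":
        return mat.mean(axis=0)
    if rule == "max":
        labels = mat.argmax(axis=1)
        counts = np.bincount(labels, minlength=mat.shape[1])
        winners = np.flatnonzero(counts == counts.max())
        if winners.size != 1:
            return mat.mean(axis=0)
        return mat[labels == winners[0]].mean(axis=0)
    raise ValueError(f"unknown voting rule {rule!r}")


def predict_local(model, patches, rule: str = "sum") -> np.ndarray:
    """Local-branch prediction: forward every patch and vote."""
    if isinstance(patches, np.ndarray) and patches.ndim == 4:
        batch = patches.astype(float)
    else:
        patches = list(patches)
        if not patches:
            raise ValueError("empty patch list")
        batch = np.stack([np.asarray(p, dtype=float) for p in patches])
    if batch.shape[0] == 0:
        raise ValueError("empty patch list")
    probs = model.forward(batch, train=False)
    return vote(list(probs), rule)


def predict_hybrid(p_local: np.ndarray, p_global: np.ndarray,
                   lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Convex combination lam * P_L + (1 - lam) * P_G."""
    if not 0 <= lam <= 1:
        raise ValueError("fusion weight must lie in [0, 1]")
    p_local = np.asarray(p_local, dtype=float).ravel()
    p_global = np.asarray(p_global, dtype=float).ravel()
    if p_local.shape != p_global.shape:
        raise ValueError("branch predictions must have the same length")
    for v in (p_local, p_global):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("branch predictions must be probability vectors")
    return lam * p_local + (1.0 - lam) * p_global


def image_to_tensor(image: np.ndarray) -> np.ndarray:
    """(H, W, 3) raster in [0, 255] -> centred (3, H, W) float tensor."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    return arr.transpose(2, 0, 1) / 255.0 - 0.5


@dataclass
class HybridClassifier:
    """Two independently trained branches fused at inference."""

    global_model: object
    local_model: object
    tiling: TilingSpec = field(default_factory=TilingSpec)
    lam: float = DEFAULT_LAMBDA
    local_rule: str = "sum"

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        g_in = image_to_tensor(downsample_global(image, self.tiling))[None]
        p_global = self.global_model.forward(g_in, train=False)[0]
        patches = tile(image, self.tiling)
        batch = np.stack([image_to_tensor(p) for p in patches])
        p_local = predict_local(self.local_model, batch, self.local_rule)
        return predict_hybrid(p_local, p_global, self.lam)

    def predict(self, image: np.ndarray) -> int:
        return int(np.argmax(self.predict_proba(image)))


def ensemble_predict(models: Sequence, image: np.ndarray, rule: str = "sum"
                     ) -> tuple[np.ndarray, int]:
    """Multi-model voting over per-model hybrid predictions."""
    if len(models) == 0:
        raise ValueError("empty model list")
    probs = [m.predict_proba(image) for m in models]
    fused = vote(probs, rule)
    return fused, int(np.argmax(fused))


def load_branch_arrays(records, class_names: Sequence[str], input_side: int,
                       patches: bool = False, patch_side: int | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Load manifest records into (x, y) branch training tensors.

    Global branch: each image downsampled to ``input_side``.  Local branch
    (``patches=True``): non-overlapping tiles of ``patch_side``, each
    inheriting the image label.
    """
    from PIL import Image

    spec = TilingSpec(resize_to=None, patch_side=patch_side or input_side,
                      global_input_side=input_side)
    xs, ys = [], []
    for rec in records:
        img = np.asarray(Image.open(rec.path).convert("RGB"))
        label_idx = class_names.index(rec.label)
        if patches:
            for p in tile(img, spec):
                xs.append(image_to_tensor(p))
                ys.append(label_idx)
        else:
            xs.append(image_to_tensor(downsample_global(img, spec)))
            ys.append(label_idx)
    return np.stack(xs), np.asarray(ys, dtype=int)


def predictions_frame(records, probs, class_names: Sequence[str]) -> pd.DataFrame:
    """Assemble a prediction table (one row per image) for evaluation/export."""
    rows = []
    for rec, p in zip(records, probs):
        p = np.asarray(p, dtype=float).ravel()
        row = {"path": rec.path, "patient_id": rec.patient_id,
               "true_label": rec.label}
        for cls, v in zip(class_names, p):
            row[f"P_{cls}"] = v
        row["pred_label"] = class_names[int(np.argmax(p))]
        rows.append(row)
    return pd.DataFrame(rows)
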