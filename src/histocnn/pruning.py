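"""Channel pruning driven by squeeze/excite gate statistics.

Channel importance is the mean activation factor of each channel over a
sample stream.  A geometric multi-loop schedule chooses an equal per-loop
proportion X such that R loops remove an overall fraction O of channels, and
each loop removes the X lowest-importance channels of every prunable layer,
physically rebuilding the network afterwards.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ChannelImportance",
    "PruneSchedule",
    "ThresholdRule",
    "PruneMask",
    "per_loop_proportion",
    "accumulate_importance",
    "select_prune_set",
    "select_by_threshold",
    "apply_pruning",
    "plan_masks",
    "prune_retrain_loop",
]


@dataclass
class ChannelImportance:
    """Per-layer mean activation factors accumulated over n_samples inputs."""

    layer_id: str
    w: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.w.size < 1 or np.any(self.w < 0) or np.any(self.w > 1):
            raise ValueError("importance components must lie in [0, 1]")

    @property
    def channels(self) -> int:
        return self.w.size


def per_loop_proportion(overall_ratio: float, n_loops: int) -> float:
    """Equal per-loop pruning proportion X = 1 - (1 - O)^(1/R)."""
    if not 0 <= overall_ratio < 1:
        raise ValueError("overall ratio O must satisfy 0 <= O < 1")
    if int(n_loops) != n_loops or n_loops < 1:
        raise ValueError("loop count R must be a positive integer")
    return 1.0 - (1.0 - overall_ratio) ** (1.0 / n_loops)


@dataclass
class PruneSchedule:
    """Target overall ratio O removed over R loops of equal proportion X."""

    overall_ratio: float
    n_loops: int = 1

    def __post_init__(self):
        # Raises on invalid (O, R).
        per_loop_proportion(self.overall_ratio, self.n_loops)

    @property
    def per_loop(self) -> float:
        return per_loop_proportion(self.overall_ratio, self.n_loops)


@dataclass
class ThresholdRule:
    """Comparison pruning rule: prune channels with w below mu + sigma + k."""

    k: float

    def __post_init__(self):
        if not 0.1 <= self.k <= 0.5:
            raise ValueError("k must lie in [0.1, 0.5]")

    def threshold(self, w: np.ndarray) -> float:
        return float(np.mean(w) + np.std(w) + self.k)


@dataclass
class PruneMask:
    """Strictly increasing kept-channel indices for one layer."""

    layer_id: str
    kept_indices: np.ndarray

    def __post_init__(self):
        self.kept_indices = np.asarray(self.kept_indices, dtype=int).ravel()
        if self.kept_indices.size < 1:
            raise ValueError("at least one channel must be kept")
        if np.any(np.diff(self.kept_indices) <= 0) or self.kept_indices.min() < 0:
            raise ValueError("kept indices must be strictly increasing and non-negative")

    @property
    def n_kept(self) -> int:
        return self.kept_indices.size


def _iter_batches(samples, batch_size: int):
    if isinstance(samples, np.ndarray):
        if samples.ndim == 3:
            samples = samples[None]
        for i in range(0, samples.shape[0], batch_size):
            yield samples[i : i + batch_size]
        return
    buf: list[np.ndarray] = []
    for s in samples:
        s = np.asarray(s, dtype=float)
        if s.ndim == 4:
            if buf:
                yield np.stack(buf)
                buf = []
            yield s
            continue
        buf.append(s)
        if len(buf) == batch_size:
            yield np.stack(buf)
            buf = []
    if buf:
        yield np.stack(buf)


def accumulate_importance(model, samples, batch_size: int = 16
                          ) -> dict[str, ChannelImportance]:
    """Mean SE activation factors per layer over a stream of inputs.

    The model runs in inference mode; the streaming accumulation equals the
    stacked-batch mean.  ``samples`` may be an (N, C, H, W) array, or an
    iterable of (C, H, W) samples / (N, C, H, W) batches.
    """
    se = model.se_layers()
    sums: dict[str, np.ndarray | None] = {k: None for k in se}
    n = 0
    for blk in se.values():
        blk.record = True
    try:
        for batch in _iter_batches(samples, batch_size):
            model.forward(batch, train=False)
            for name, blk in se.items():
                s = blk.last_s.sum(axis=0)
                sums[name] = s if sums[name] is None else sums[name] + s
            n += batch.shape[0]
    finally:
        for blk in se.values():
            blk.record = False
            blk.last_s = None
    if n == 0:
        raise ValueError("sample stream is empty")
    return {name: ChannelImportance(name, sums[name] / n, n) for name in se}


def select_prune_set(imp: ChannelImportance, proportion: float) -> PruneMask:
    """Prune the round(X*C) lowest-importance channels, keeping at least one.

    Ties are broken by pruning the lower channel index first.
    """
    if not 0 <= proportion < 1:
        raise ValueError("proportion X must satisfy 0 <= X < 1")
    c = imp.channels
    n_prune = min(c - 1, int(np.floor(proportion * c + 0.5)))
    order = np.argsort(imp.w, kind="stable")  # ascending w, ties by index
    kept = np.sort(order[n_prune:])
    return PruneMask(imp.layer_id, kept)


def select_by_threshold(imp: ChannelImportance, rule: ThresholdRule) -> PruneMask:
    """Prune channels with importance below mu + sigma + k; keep >= 1."""
    th = rule.threshold(imp.w)
    kept = np.flatnonzero(imp.w >= th)
    if kept.size == 0:
        kept = np.array([int(np.argmax(imp.w))])
    return PruneMask(imp.layer_id, kept)


def apply_pruning(model, masks: Mapping[str, PruneMask] | Iterable[PruneMask]):
    """Physically remove pruned channels; returns the (mutated) model."""
    if not isinstance(masks, Mapping):
        masks = {m.layer_id: m for m in masks}
    for name, mask in masks.items():
        if mask.layer_id != name:
            raise ValueError(f"mask for {mask.layer_id!r} keyed as {name!r}")
    model.prune({name: mask.kept_indices for name, mask in masks.items()})
    return model


def plan_masks(model, importance: Mapping[str, ChannelImportance],
               proportion: float) -> dict[str, PruneMask]:
    """Per-layer masks at proportion X; residual-coupled pairs share a mask
    computed from the mean of their importance vectors."""
    masks = {name: select_prune_set(imp, proportion)
             for name, imp in importance.items()}
    for a, b in model.residual_coupled_pairs():
        if a in importance and b in importance:
            mean_w = (importance[a].w + importance[b].w) / 2.0
            shared = select_prune_set(
                ChannelImportance(a, mean_w, importance[a].n_samples), proportion
            )
            masks[a] = PruneMask(a, shared.kept_indices)
            masks[b] = PruneMask(b, shared.kept_indices.copy())
    return masks


@dataclass
class LoopReport:
    """Per-loop record of the prune-retrain cycle."""

    loop: int
    proportion: float
    channels_before: dict[str, int]
    channels_after: dict[str, int]
    final_loss: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def prune_retrain_loop(model, train_x: np.ndarray, train_y: np.ndarray,
                       schedule: PruneSchedule, train_cfg,
                       ) -> tuple[object, list[LoopReport]]:
    """Iterate {accumulate importance, prune X per layer, retrain} R times.

    Retraining reuses ``train_cfg`` with the learning rate reduced to a tenth
    of the initial run (fine-tuning convention).  Returns the compact model
    and one report per loop.
    """
    from .training import train_branch  # local import: avoid a cycle

    x = schedule.per_loop
    reports: list[LoopReport] = []
    retrain_cfg = dataclasses.replace(train_cfg, initial_lr=train_cfg.initial_lr * 0.1)
    for loop in range(1, schedule.n_loops + 1):
        before = model.layer_channels()
        if x > 0:
            importance = accumulate_importance(model, train_x)
            masks = plan_masks(model, importance, x)
            apply_pruning(model, masks)
        after = model.layer_channels()
        final_loss = None
        if retrain_cfg.iterations > 0:
            trace = train_branch(model, train_x, train_y, retrain_cfg)
            final_loss = float(trace[-1])
        reports.append(LoopReport(loop, x, before, after, final_loss))
    return model, reports
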