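"""Training loop: warmup/step-decay schedule, Adam, checkpoint averaging,
and slide-level max-voting inference.

The backbone is frozen, so each tissue slice is reduced once to its per-scale
(m, native) feature matrices and the optimizer only ever sees the transformer
head. One optimization step = one tissue slice (all scales). Validation after
every epoch scores *slides*: slice predictions are combined by max-voting
(the most severe predicted category wins, matching clinical practice), and
the best epochs' parameter snapshots are element-wise averaged at the end.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .model import ModelConfig, ScaleAwareModel, lift_parameters
from .soft_labeling import LabelVector


@dataclass
class SliceExample:
    """One tissue slice ready for the model: cached features plus its label."""

    slide_id: str
    slice_id: str
    embeddings: dict[str, np.ndarray]  # scale tag -> (m, native) float
    label: LabelVector
    slide_class: int  # 1-based severity category of the parent slide


@dataclass
class TrainConfig:
    epochs: int = 200
    warmup_steps: int = 500
    lr_start: float = 1e-6
    lr_peak: float = 5e-4
    decay_epochs: tuple[int, ...] = (100, 150)
    decay_factor: float = 0.5
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    checkpoint_capacity: int = 5
    average_ks: tuple[int, ...] = (3, 5)


def lr_at(step: int, epoch: int, cfg: TrainConfig = TrainConfig()) -> float:
    """Learning rate at a global step / epoch.

    Linear warmup ``lr_start -> lr_peak`` over the first ``warmup_steps``
    steps, then a constant ``lr_peak`` halved at each epoch in
    ``decay_epochs``.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if step < cfg.warmup_steps:
        frac = step / cfg.warmup_steps
        return cfg.lr_start + (cfg.lr_peak - cfg.lr_start) * frac
    lr = cfg.lr_peak
    for boundary in sorted(cfg.decay_epochs):
        if epoch >= boundary:
            lr *= cfg.decay_factor
    return lr


def soft_target_loss(scores: np.ndarray, target: LabelVector | np.ndarray) -> float:
    """Cross-entropy of the score softmax against a (soft) target vector."""
    t = target.probs if isinstance(target, LabelVector) else np.asarray(target, float)
    s = np.asarray(scores, float)
    log_probs = s - s.max()
    log_probs = log_probs - np.log(np.exp(log_probs).sum())
    return float(-(t * log_probs).sum())


def _loss_t(scores: Tensor, target: np.ndarray) -> Tensor:
    return (Tensor(-target) * scores.log_softmax(axis=-1)).sum()


def max_vote(slice_predictions: list[int]) -> int:
    """Slide label = most severe category predicted among its slices."""
    if not slice_predictions:
        raise ValueError("cannot max-vote an empty prediction list")
    return max(slice_predictions)


class CheckpointSet:
    """Top-``capacity`` parameter snapshots ranked by validation score.

    Ties are broken in favor of the earlier epoch.
    """

    def __init__(self, capacity: int = 5):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._entries: list[tuple[float, int, dict[str, np.ndarray]]] = []

    def add(self, score: float, epoch: int, params: dict[str, np.ndarray]) -> None:
        self._entries.append((score, epoch, {k: v.copy() for k, v in params.items()}))
        self._entries.sort(key=lambda t: (-t[0], t[1]))
        del self._entries[self.capacity :]

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def scores(self) -> list[float]:
        return [s for s, _, _ in self._entries]

    @property
    def epochs(self) -> list[int]:
        return [e for _, e, _ in self._entries]

    def snapshot(self, rank: int) -> dict[str, np.ndarray]:
        return self._entries[rank][2]


def average_checkpoints(cks: CheckpointSet, k: int) -> dict[str, np.ndarray]:
    """Element-wise mean of the top-``k`` snapshots' parameters."""
    if k < 1 or k > len(cks):
        raise ValueError(f"k={k} but only {len(cks)} checkpoints available")
    keys = cks.snapshot(0).keys()
    return {
        key: np.mean([cks.snapshot(i)[key] for i in range(k)], axis=0) for key in keys
    }


def group_by_slide(slices: list[SliceExample]) -> dict[str, list[SliceExample]]:
    out: dict[str, list[SliceExample]] = {}
    for sl in slices:
        out.setdefault(sl.slide_id, []).append(sl)
    return out


def predict_slides(
    model: ScaleAwareModel, slices: list[SliceExample]
) -> dict[str, tuple[int, np.ndarray]]:
    """Per-slide (max-voted class, mean slice probability vector)."""
    results = {}
    for slide_id, group in group_by_slide(slices).items():
        probs = np.stack([model.predict(sl.embeddings) for sl in group])
        votes = [int(np.argmax(p)) + 1 for p in probs]
        results[slide_id] = (max_vote(votes), probs.mean(axis=0))
    return results


def slide_accuracy(model: ScaleAwareModel, slices: list[SliceExample]) -> float:
    groups = group_by_slide(slices)
    preds = predict_slides(model, slices)
    correct = sum(
        preds[sid][0] == groups[sid][0].slide_class for sid in groups
    )
    return correct / len(groups)


@dataclass
class TrainResult:
    model: ScaleAwareModel
    checkpoints: CheckpointSet
    log: pd.DataFrame
    loss_trace: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)
    chosen_k: int = 1
    final_val_accuracy: float = 0.0


def train(
    train_slices: list[SliceExample],
    val_slices: list[SliceExample],
    model: ScaleAwareModel,
    cfg: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Adam training of the transformer head on cached slice features.

    After every epoch the slide-level validation accuracy is recorded and the
    parameters snapshotted into a :class:`CheckpointSet`. At the end, the
    element-wise averages of the best-3 and best-5 snapshots (where
    available) are compared on the validation split and the better one is
    kept.
    """
    if not train_slices:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    cks = CheckpointSet(cfg.checkpoint_capacity)
    log_rows = []
    loss_trace: list[float] = []
    val_history: list[float] = []
    step = 0
    adam_t = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_slices))
        epoch_loss = 0.0
        for idx in order:
            example = train_slices[idx]
            lr = lr_at(step, epoch, cfg)
            params_t = lift_parameters(model.params, trainable=True)
            scores = model.forward(example.embeddings, params_t)
            loss = _loss_t(scores, example.label.probs)
            loss.backward()
            adam_t += 1
            for key, tensor in params_t.items():
                g = tensor.grad
                if g is None:
                    continue
                adam_m[key] = cfg.beta1 * adam_m[key] + (1 - cfg.beta1) * g
                adam_v[key] = cfg.beta2 * adam_v[key] + (1 - cfg.beta2) * g * g
                m_hat = adam_m[key] / (1 - cfg.beta1**adam_t)
                v_hat = adam_v[key] / (1 - cfg.beta2**adam_t)
                model.params[key] = model.params[key] - lr * m_hat / (
                    np.sqrt(v_hat) + cfg.adam_eps
                )
            loss_value = float(loss.data)
            epoch_loss += loss_value
            loss_trace.append(loss_value)
            log_rows.append(
                {"epoch": epoch, "step": step, "lr": lr, "loss": loss_value}
            )
            step += 1
        val_acc = slide_accuracy(model, val_slices) if val_slices else float("nan")
        val_history.append(val_acc)
        if val_slices:
            cks.add(val_acc, epoch, model.params)
        log_rows[-1]["val_acc"] = val_acc

    chosen_k = 1
    if len(cks):
        candidates = sorted({k for k in cfg.average_ks if k <= len(cks)}) or [len(cks)]
        best = None
        for k in candidates:
            averaged = average_checkpoints(cks, k)
            acc = slide_accuracy(
                ScaleAwareModel(cfg=model.cfg, params=averaged), val_slices
            )
            if best is None or acc > best[0]:
                best = (acc, k, averaged)
        _, chosen_k, model.params = best
        final_val = best[0]
    else:
        final_val = float("nan")

    return TrainResult(
        model=model,
        checkpoints=cks,
        log=pd.DataFrame(log_rows),
        loss_trace=loss_trace,
        val_history=val_history,
        chosen_k=chosen_k,
        final_val_accuracy=final_val,
    )
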