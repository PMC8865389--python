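"""End-to-end experiment plumbing: slides -> slices -> features -> model.

These helpers wire the stages together for the common case (synthetic or
manifest-loaded slides, frozen backbone, cached features) so the examples,
the CLI and the test harness all run the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import RandomConvBackbone
from .evaluation import confusion_matrix, macro_auc, overall_metrics, per_class_metrics
from .model import ModelConfig, ScaleAwareModel
from .slide_prep import DEFAULT_M_PER_SCALE, SlideRecord, TissueSlice, prepare_slide, tile_patches
from .soft_labeling import assign_slice_labels
from .synthetic import SynthDataset
from .training import (
    SliceExample,
    TrainConfig,
    TrainResult,
    predict_slides,
    train,
)


def prepare_slices(slides: list[SlideRecord]) -> dict[str, list[TissueSlice]]:
    """Segment every slide into ROI-marked, per-scale-cropped tissue slices."""
    return {record.slide_id: prepare_slide(record) for record in slides}


def compute_slice_features(
    slices_by_slide: dict[str, list[TissueSlice]],
    backbone: RandomConvBackbone,
    m_per_scale: dict[str, int] | None = None,
) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Cache the frozen (m, native) feature matrix per slice and scale."""
    m_per_scale = m_per_scale or dict(DEFAULT_M_PER_SCALE)
    features = {}
    for slide_id, slices in slices_by_slide.items():
        for sl in slices:
            per_scale = {}
            for tag, m in m_per_scale.items():
                grid = tile_patches(sl.crops[tag], m, scale_tag=tag)
                per_scale[tag] = backbone(grid.patches)
            features[(slide_id, sl.slice_id)] = per_scale
    return features


def build_examples(
    slices_by_slide: dict[str, list[TissueSlice]],
    features: dict[tuple[str, str], dict[str, np.ndarray]],
    slide_classes: dict[str, int],
) -> list[SliceExample]:
    return [
        SliceExample(
            slide_id=slide_id,
            slice_id=sl.slice_id,
            embeddings=features[(slide_id, sl.slice_id)],
            label=sl.label,
            slide_class=slide_classes[slide_id],
        )
        for slide_id, slices in slices_by_slide.items()
        for sl in slices
    ]


@dataclass
class ExperimentResult:
    scheme: str
    train_result: TrainResult
    test_accuracy: float
    majority_baseline: float
    metrics: dict[str, float]
    per_class: list[dict] = field(default_factory=list)
    confusion: np.ndarray | None = None
    predictions: dict[str, tuple[int, np.ndarray]] = field(default_factory=dict)


def run_experiment(
    dataset: SynthDataset,
    scheme: str = "constrained_soft",
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    backbone: RandomConvBackbone | None = None,
    slices_by_slide: dict[str, list[TissueSlice]] | None = None,
    features: dict[tuple[str, str], dict[str, np.ndarray]] | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Train on the dataset's train split with a labeling scheme; score test.

    Slice segmentation and frozen features can be passed in to reuse across
    labeling schemes (they do not depend on the labels).
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig(seed=seed)
    backbone = backbone or RandomConvBackbone(feature_dim=model_cfg.native_dim, seed=0)
    slide_classes = dataset.slide_classes()

    if slices_by_slide is None:
        slices_by_slide = prepare_slices(dataset.slides)
    if features is None:
        features = compute_slice_features(slices_by_slide, backbone, model_cfg.m_per_scale)

    train_ids = set(dataset.slide_ids("train"))
    val_ids = set(dataset.slide_ids("val"))
    test_ids = set(dataset.slide_ids("test"))
    if not train_ids or not test_ids:
        raise ValueError("dataset must provide non-empty train and test splits")

    # soft-label prototypes come from training ROI slices only
    train_slices = {sid: slices_by_slide[sid] for sid in train_ids}
    assign_slice_labels(train_slices, slide_classes, scheme=scheme)
    # val/test slices get hard labels (only used as ground truth, not for loss)
    for sid in val_ids | test_ids:
        assign_slice_labels(
            {sid: slices_by_slide[sid]}, slide_classes, scheme="hard"
        )

    examples = {
        split: build_examples(
            {sid: slices_by_slide[sid] for sid in ids}, features, slide_classes
        )
        for split, ids in (("train", train_ids), ("val", val_ids), ("test", test_ids))
    }

    model = ScaleAwareModel(cfg=model_cfg, seed=seed)
    result = train(examples["train"], examples["val"], model, train_cfg)

    preds = predict_slides(result.model, examples["test"])
    y_true = np.array([slide_classes[sid] for sid in sorted(preds)])
    y_pred = np.array([preds[sid][0] for sid in sorted(preds)])
    scores = np.stack([preds[sid][1] for sid in sorted(preds)])
    cm = confusion_matrix(y_true, y_pred, model_cfg.n_classes)
    metrics = overall_metrics(cm, y_true=y_true, scores=scores)
    counts = np.bincount(y_true, minlength=model_cfg.n_classes + 1)
    return ExperimentResult(
        scheme=scheme,
        train_result=result,
        test_accuracy=float(metrics["accuracy"]),
        majority_baseline=float(counts.max() / counts.sum()),
        metrics=metrics,
        per_class=per_class_metrics(cm),
        confusion=cm,
        predictions=preds,
    )


def match_slices_to_blobs(
    slices: list[TissueSlice], blobs
) -> dict[str, int]:
    """Map each extracted slice to the nearest registry blob's true category."""
    out = {}
    for sl in slices:
        cx = (sl.bbox.x0 + sl.bbox.x1) / 2
        cy = (sl.bbox.y0 + sl.bbox.y1) / 2
        nearest = min(
            blobs,
            key=lambda b: (b.centroid[0] - cx) ** 2 + (b.centroid[1] - cy) ** 2,
        )
        out[sl.slice_id] = nearest.class_index
    return out
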