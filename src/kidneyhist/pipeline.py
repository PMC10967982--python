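"""End-to-end orchestration: discovery, split, features, training, evaluation.

The train/test split follows the published protocol for the imbalanced
kidney dataset: a fixed number of samples per class (1000 in the original
study — roughly 70% of the smallest class, the stones) is drawn uniformly
without replacement for training and everything else is held out for
testing. Bin-edge optimisation, when requested, sees training images only,
so no test-set information leaks into the feature definition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, rnn_classifier
from .bin_optimizer import GAConfig, ga_optimize
from .image_prep import CLASS_NAMES, crop_black_border, discover_dataset, load_gray_image
from .local_histogram import (
    GRADIENT_EDGES,
    INTENSITY_EDGES,
    SYMMETRIC_EDGES,
    BinEdges,
    extract_features,
    gradient_magnitude,
    local_histograms,
)
from .rnn_classifier import LSTMClassifier, TrainConfig

__all__ = [
    "FEATURE_MODES",
    "SplitSpec",
    "RunConfig",
    "PipelineReport",
    "split_dataset",
    "compute_features",
    "features_to_frame",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: The four feature configurations of the ablation study.
FEATURE_MODES = ("intensity", "gradient", "combined", "symmetric")


@dataclass(frozen=True)
class SplitSpec:
    """Per-class training quota; the remainder of each class is test data."""

    n_train_per_class: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train_per_class < 1:
            raise ValueError("n_train_per_class must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    dataset_root: str | Path | None = None
    intensity_edges: BinEdges = field(default_factory=lambda: BinEdges(INTENSITY_EDGES))
    gradient_edges: BinEdges = field(default_factory=lambda: BinEdges(GRADIENT_EDGES))
    crop_threshold: int = 10
    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    feature_mode: str = "combined"
    #: re-optimise bin edges on the training split before feature extraction
    optimize_bins: bool = False
    ga: GAConfig = field(default_factory=GAConfig)
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")


@dataclass
class PipelineReport:
    confusion: np.ndarray
    accuracy: float
    metrics: pd.DataFrame
    predictions: pd.DataFrame
    model: LSTMClassifier
    intensity_edges: BinEdges
    gradient_edges: BinEdges
    train_indices: np.ndarray
    test_indices: np.ndarray


def split_dataset(
    class_counts: dict[str, int], spec: SplitSpec
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class (train_indices, test_indices) under the fixed-quota rule.

    Indices are within-class positions 0..count-1, sampled uniformly without
    replacement (seeded). A class whose quota equals its size gets an empty
    test set with a warning; a smaller class is an error.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rng = np.random.default_rng(spec.seed)
    for cls in sorted(class_counts):
        n = int(class_counts[cls])
        if n < spec.n_train_per_class:
            raise ValueError(
                f"class {cls!r} has {n} samples, fewer than the "
                f"training quota {spec.n_train_per_class}")
        perm = rng.permutation(n)
        train = np.sort(perm[: spec.n_train_per_class])
        test = np.sort(perm[spec.n_train_per_class:])
        if test.size == 0:
            logger.warning("class %r: every sample assigned to training; empty test set", cls)
        out[cls] = (train, test)
    return out


def compute_features(
    img: np.ndarray,
    mode: str,
    intensity_edges: BinEdges,
    gradient_edges: BinEdges,
) -> np.ndarray:
    """Feature vector of one cropped image under one of the four modes.

    ``intensity`` and ``gradient`` yield the single-channel 1x800 vectors,
    ``combined`` the merged 1x1600 vector, and ``symmetric`` the merged
    vector computed with conventional equal-width edges for both channels.
    """
    if mode == "intensity":
        return local_histograms(img, intensity_edges).ravel()
    if mode == "gradient":
        return local_histograms(gradient_magnitude(img), gradient_edges).ravel()
    if mode == "combined":
        return extract_features(img, intensity_edges, gradient_edges)
    if mode == "symmetric":
        sym = BinEdges(SYMMETRIC_EDGES)
        return extract_features(img, sym, sym)
    raise ValueError(f"unknown feature mode: {mode}")


def features_to_frame(features: np.ndarray, labels: list[str]) -> pd.DataFrame:
    """Feature matrix + label column as a DataFrame (CSV-exportable)."""
    df = pd.DataFrame(features,
                      columns=[f"f{k:04d}" for k in range(features.shape[1])])
    df["label"] = labels
    return df


def _load_images(cfg: RunConfig,
                 images: list[tuple[str, np.ndarray]] | None):
    if images is not None:
        return list(images)
    if cfg.dataset_root is None:
        raise ValueError("either images or cfg.dataset_root must be provided")
    pairs = discover_dataset(cfg.dataset_root)
    return [(lab, load_gray_image(p)) for lab, p in pairs]


def run_pipeline(
    cfg: RunConfig,
    images: list[tuple[str, np.ndarray]] | None = None,
) -> PipelineReport:
    """Crop -> split -> (optional GA) -> features -> train -> test -> metrics.

    ``images`` may supply an in-memory (label, image) list instead of a
    dataset root. When ``cfg.output_dir`` is set, features, the model,
    predictions, the metrics report and a run log of all effective settings
    are written there.
    """
    data = _load_images(cfg, images)
    labels = [lab for lab, _ in data]
    present = sorted(set(labels))
    if len(present) < 2:
        raise ValueError("pipeline requires at least 2 classes in the dataset")

    logger.info("pipeline: %d images, classes %s, feature mode %s, "
                "split seed %d, train seed %d",
                len(data), present, cfg.feature_mode,
                cfg.split.seed, cfg.train.seed)

    cropped = [(lab, crop_black_border(img, cfg.crop_threshold)) for lab, img in data]

    # fixed-quota split on within-class positions, mapped to global indices
    class_counts = {c: labels.count(c) for c in present}
    split = split_dataset(class_counts, cfg.split)
    by_class: dict[str, list[int]] = {c: [] for c in present}
    for k, lab in enumerate(labels):
        by_class[lab].append(k)
    train_idx = np.sort(np.concatenate(
        [np.asarray(by_class[c])[split[c][0]] for c in present]))
    test_idx = np.sort(np.concatenate(
        [np.asarray(by_class[c])[split[c][1]] for c in present])) \
        if any(split[c][1].size for c in present) else np.array([], dtype=int)

    intensity_edges, gradient_edges = cfg.intensity_edges, cfg.gradient_edges
    if cfg.optimize_bins:
        train_images = [cropped[k] for k in train_idx]
        if cfg.feature_mode in ("intensity", "combined"):
            res = ga_optimize(train_images, mode="intensity", cfg=cfg.ga)
            intensity_edges = res.best_edges
            logger.info("optimised intensity edges: %s (score %.4f)",
                        intensity_edges.edges, res.best_score)
        if cfg.feature_mode in ("gradient", "combined"):
            res = ga_optimize(train_images, mode="gradient", cfg=cfg.ga)
            gradient_edges = res.best_edges
            logger.info("optimised gradient edges: %s (score %.4f)",
                        gradient_edges.edges, res.best_score)

    feats = np.stack([
        compute_features(img, cfg.feature_mode, intensity_edges, gradient_edges)
        for _, img in cropped
    ])

    model = rnn_classifier.train(
        [(feats[k], labels[k]) for k in train_idx], cfg.train)

    if test_idx.size == 0:
        raise ValueError("empty test set: reduce n_train_per_class")
    pred_labels, probs = rnn_classifier.predict_batch(model, feats[test_idx])
    true_labels = [labels[k] for k in test_idx]
    cm = evaluation.confusion_matrix(true_labels, pred_labels)
    acc = evaluation.overall_accuracy(cm)
    metrics = evaluation.metrics_report(cm)

    predictions = pd.DataFrame({
        "index": test_idx,
        "true_label": true_labels,
        "predicted_label": pred_labels,
        **{f"p_{c}": probs[:, k] for k, c in enumerate(CLASS_NAMES)},
    })

    report = PipelineReport(cm, acc, metrics, predictions, model,
                            intensity_edges, gradient_edges, train_idx, test_idx)

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        features_to_frame(feats, labels).to_csv(out / "features.csv", index=False)
        model.save(out / "model.npz")
        predictions.to_csv(out / "predictions.csv", index=False)
        evaluation.write_report(cm, out)
        (out / "run_log.json").write_text(json.dumps({
            "n_images": len(data),
            "classes": present,
            "feature_mode": cfg.feature_mode,
            "crop_threshold": cfg.crop_threshold,
            "intensity_edges": list(intensity_edges.edges),
            "gradient_edges": list(gradient_edges.edges),
            "split": {"n_train_per_class": cfg.split.n_train_per_class,
                      "seed": cfg.split.seed},
            "train_config": cfg.train.__dict__,
            "optimize_bins": cfg.optimize_bins,
            "overall_accuracy": acc,
        }, indent=2))
        logger.info("pipeline outputs written to %s", out)

    return report


def run_ablation(
    cfg: RunConfig,
    images: list[tuple[str, np.ndarray]] | None = None,
) -> dict[str, PipelineReport]:
    """Run all four feature modes with otherwise identical settings."""
    data = _load_images(cfg, images)
    return {mode: run_pipeline(replace(cfg, feature_mode=mode), images=data)
            for mode in FEATURE_MODES}
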