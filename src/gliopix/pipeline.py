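"""End-to-end orchestration: training both models and segmenting slices.

Segmentation of one slice runs the full chain
align -> TAR/TC -> predict K -> SLIC0 -> background removal -> features
-> SVM -> mask. Training labels the best K per training slice (grid
search against ground truth), fits the K regressor, annotates superpixels
at the labelled K, and fits the SVM on the pooled feature table. Every
stage can log a JSON-lines record of its parameters and outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import adaptive_k, classify, features
from .config import PipelineConfig
from .evaluate import EvalMetrics, dice, hausdorff_distance, sensitivity_specificity
from .superpixel import run_slic0

__all__ = ["PipelineLog", "SegmentationResult", "segment_slice", "train_all", "evaluate_pair"]


class PipelineLog:
    """JSON-lines stage log; one record per pipeline stage."""

    def __init__(self, path: str | None = None):
        self.path = path
        self.records: list[dict] = []

    def log(self, stage: str, **info) -> None:
        rec = {"stage": stage, **info}
        self.records.append(rec)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


@dataclass
class SegmentationResult:
    mask: np.ndarray
    k_predicted: int
    descriptor: adaptive_k.TumorDescriptor | None
    n_superpixels: int
    metrics: EvalMetrics | None = None
    log: PipelineLog | None = field(default=None, repr=False)


def segment_slice(
    image: np.ndarray,
    k_model: adaptive_k.KModel,
    svm_model: classify.SvmModel,
    config: PipelineConfig | None = None,
    gt: np.ndarray | None = None,
    log: PipelineLog | None = None,
) -> SegmentationResult:
    """Segment one slice with trained K and SVM models."""
    cfg = config or PipelineConfig()
    log = log or PipelineLog()
    img = np.asarray(image, dtype=np.float64)
    if not np.any(img >= cfg.background_threshold):
        log.log("segment", warning="all-background image; empty mask returned")
        empty = np.zeros(img.shape, dtype=bool)
        metrics = evaluate_pair(empty, gt) if gt is not None else None
        return SegmentationResult(mask=empty, k_predicted=0, descriptor=None, n_superpixels=0, metrics=metrics, log=log)

    descriptor = adaptive_k.compute_descriptor(img, threshold=cfg.similarity_threshold)
    log.log("describe", tar=descriptor.tar, tc=descriptor.tc, n_blocks=descriptor.n_blocks)

    k = adaptive_k.predict_k(k_model, descriptor)
    log.log("predict_k", k=k)

    sp = run_slic0(img, k, iterations=cfg.iterations)
    log.log("superpixels", requested=k, count=sp.count)

    retained = features.remove_background_superpixels(img, sp, threshold=cfg.background_threshold)
    background_ids = np.setdiff1d(np.arange(sp.count), retained)
    log.log("background_removal", retained=len(retained), removed=len(background_ids))

    table = features.extract_feature_table(
        img, sp, retained_ids=retained, levels_set=cfg.quant_levels, directions=cfg.directions
    )
    predictions = classify.predict_superpixels(svm_model, table)
    mask = classify.assemble_segmentation(sp, predictions, background_ids)
    log.log("classify", tumor_superpixels=int(sum(predictions.values())), mask_pixels=int(mask.sum()))

    metrics = evaluate_pair(mask, gt) if gt is not None else None
    return SegmentationResult(
        mask=mask, k_predicted=k, descriptor=descriptor, n_superpixels=sp.count, metrics=metrics, log=log
    )


def evaluate_pair(pred: np.ndarray, gt: np.ndarray) -> EvalMetrics:
    sens, spec = sensitivity_specificity(pred, gt)
    return EvalMetrics(
        dice=dice(pred, gt), hd=hausdorff_distance(pred, gt), sensitivity=sens, specificity=spec
    )


def train_all(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    config: PipelineConfig | None = None,
    strata: list | None = None,
    log: PipelineLog | None = None,
) -> tuple[adaptive_k.KModel, classify.SvmModel, dict]:
    """Train the K regressor and the SVM from (slice, ground-truth) pairs.

    Splits the pairs 80/20 (stratified when ``strata`` labels are given),
    uses the training portion for both models, and returns the models plus
    a manifest with the split, the labelled K values and the descriptors.
    """
    cfg = config or PipelineConfig()
    log = log or PipelineLog()
    if len(pairs) < 10:
        raise ValueError("need at least 10 (slice, mask) pairs")
    train_idx, test_idx = classify.train_test_split_ids(
        len(pairs), cfg.train_fraction, cfg.seed, strata=strata
    )
    log.log("split", train=train_idx.tolist(), test=test_idx.tolist())

    samples = []
    svm_tables = []
    svm_labels = []
    for i in train_idx:
        image, gt = pairs[i]
        descriptor = adaptive_k.compute_descriptor(image, threshold=cfg.similarity_threshold)
        k_best = adaptive_k.label_best_k(
            image,
            gt,
            k_grid=cfg.k_grid,
            merge_ratio=cfg.merge_ratio,
            plateau_epsilon=cfg.plateau_epsilon,
            iterations=cfg.iterations,
        )
        samples.append(adaptive_k.KTrainingSample(descriptor=descriptor, k_best=k_best))
        log.log("label_k", sample=int(i), k_best=k_best, tar=descriptor.tar, tc=descriptor.tc)

        sp = run_slic0(np.asarray(image, dtype=np.float64), k_best, iterations=cfg.iterations)
        retained = features.remove_background_superpixels(image, sp, threshold=cfg.background_threshold)
        table = features.extract_feature_table(
            image, sp, retained_ids=retained, levels_set=cfg.quant_levels, directions=cfg.directions
        )
        ann = classify.annotate_superpixels(sp, gt, threshold=cfg.annotation_threshold)
        labels = np.array([1 if ann[sid].label == "tumor" else 0 for sid in retained])
        svm_tables.append(table)
        svm_labels.append(labels)

    k_model = adaptive_k.train_k_model(samples, seed=cfg.seed, n_trees=cfg.rf_trees)
    log.log("train_k", n_samples=len(samples))

    import pandas as pd

    all_features = pd.concat(svm_tables, ignore_index=True)
    all_labels = np.concatenate(svm_labels)
    svm_model = classify.train_svm(all_features, all_labels, seed=cfg.seed, cv_folds=cfg.cv_folds)
    log.log(
        "train_svm",
        n_samples=len(all_labels),
        n_tumor=int(all_labels.sum()),
        C=svm_model.C,
        gamma=svm_model.gamma,
    )

    manifest = {
        "train_indices": train_idx.tolist(),
        "test_indices": test_idx.tolist(),
        "k_best": [s.k_best for s in samples],
        "descriptors": [
            {"tar": s.descriptor.tar, "tc": s.descriptor.tc, "n_blocks": s.descriptor.n_blocks}
            for s in samples
        ],
        "svm_cv_score": svm_model.training_meta["cv_score"],
        "config": cfg.to_dict(),
    }
    return k_model, svm_model, manifest
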