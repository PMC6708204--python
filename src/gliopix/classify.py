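"""Superpixel annotation, RBF-SVM training/prediction and mask assembly.

Training slices come with an expert ground-truth mask; a superpixel is
annotated tumor when the fraction of its own pixels inside the ground
truth reaches the annotation threshold (default 0.5). Features are
z-scored with training statistics; (C, gamma) are selected on a
deterministic 7x7 logarithmic grid by mean 5-fold cross-validated
balanced accuracy, and the winning model is refit on all training data.
Tumor superpixels are a small minority, so classes are weighted inversely
to their frequency.

The fitted model is stored as portable arrays (scaler statistics, kernel
parameters, support vectors, dual coefficients, bias), so prediction is a
plain RBF kernel expansion and the model round-trips through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SuperpixelLabel",
    "SvmModel",
    "annotate_superpixels",
    "train_svm",
    "predict_superpixels",
    "assemble_segmentation",
    "train_test_split_ids",
    "C_GRID",
    "GAMMA_GRID",
]

ANNOTATION_THRESHOLD = 0.5
C_GRID = tuple(np.logspace(-3, 3, 7))
GAMMA_GRID = tuple(np.logspace(-4, 1, 7))
CV_FOLDS = 5


@dataclass(frozen=True)
class SuperpixelLabel:
    id: int
    overlap: float  # fraction of the superpixel's pixels inside ground truth
    label: str  # "tumor" | "non-tumor"


def annotate_superpixels(sp, gt: np.ndarray, threshold: float = ANNOTATION_THRESHOLD) -> list[SuperpixelLabel]:
    """Label each superpixel from its overlap fraction with the ground truth.

    overlap = |superpixel ∩ gt| / |superpixel|; tumor iff overlap >= threshold.
    """
    gt_mask = np.asarray(gt, dtype=bool)
    if gt_mask.shape != sp.labels.shape:
        raise ValueError("ground truth and superpixel map dimensions differ")
    inter = np.bincount(sp.labels.ravel(), weights=gt_mask.ravel(), minlength=sp.count)
    sizes = sp.sizes()
    out = []
    for sid in range(sp.count):
        ov = inter[sid] / sizes[sid]
        out.append(SuperpixelLabel(id=sid, overlap=float(ov), label="tumor" if ov >= threshold else "non-tumor"))
    return out


@dataclass
class SvmModel:
    """A fitted RBF-SVM plus the standardization it was trained with."""

    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray
    C: float
    gamma: float
    support_vectors: np.ndarray  # standardized coordinates
    dual_coef: np.ndarray
    intercept: float
    training_meta: dict = field(default_factory=dict)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """RBF kernel expansion: sum_i alpha_i exp(-gamma ||sv_i - x||^2) + b."""
        Z = self.standardize(np.asarray(X, dtype=np.float64))
        d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.gamma * d2)
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean tumor predictions (positive decision value = tumor)."""
        return self.decision_function(X) > 0

    def save(self, path: str) -> None:
        obj = {
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "C": self.C,
            "gamma": self.gamma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path: str) -> "SvmModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            feature_names=obj["feature_names"],
            mean=np.asarray(obj["mean"]),
            std=np.asarray(obj["std"]),
            C=obj["C"],
            gamma=obj["gamma"],
            support_vectors=np.asarray(obj["support_vectors"]),
            dual_coef=np.asarray(obj["dual_coef"]),
            intercept=obj["intercept"],
            training_meta=obj.get("training_meta", {}),
        )


def _as_binary_labels(labels) -> np.ndarray:
    if not isinstance(labels, np.ndarray):
        labels = list(labels)
        if labels and isinstance(labels[0], SuperpixelLabel):
            return np.array([1 if l.label == "tumor" else 0 for l in labels])
    return np.asarray(labels).astype(int)


def train_svm(
    features: pd.DataFrame,
    labels,
    seed: int,
    cv_folds: int = CV_FOLDS,
    c_grid: tuple[float, ...] = C_GRID,
    gamma_grid: tuple[float, ...] = GAMMA_GRID,
) -> SvmModel:
    """Train the tumor/non-tumor superpixel classifier.

    ``labels`` may be SuperpixelLabel objects (aligned with the feature
    table's index) or a plain 0/1 array. Deterministic for a fixed seed.
    """
    from sklearn.metrics import balanced_accuracy_score
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    X = features.to_numpy(dtype=np.float64)
    y = _as_binary_labels(labels)
    if len(X) != len(y):
        raise ValueError("features and labels length mismatch")
    if len(X) < 20:
        raise ValueError("need at least 20 samples")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")

    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std == 0, 1.0, std)
    Z = (X - mean) / std

    n_splits = min(cv_folds, int(np.bincount(y).min()))
    n_splits = max(2, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(Z, y))

    trace = []
    best = (-np.inf, None, None)
    for C in c_grid:
        for gamma in gamma_grid:
            scores = []
            for tr, te in folds:
                clf = SVC(kernel="rbf", C=C, gamma=gamma, class_weight="balanced")
                clf.fit(Z[tr], y[tr])
                scores.append(balanced_accuracy_score(y[te], clf.predict(Z[te])))
            mean_score = float(np.mean(scores))
            trace.append({"C": C, "gamma": gamma, "cv_balanced_accuracy": mean_score})
            if mean_score > best[0] + 1e-12:
                best = (mean_score, C, gamma)
    _, C, gamma = best
    final = SVC(kernel="rbf", C=C, gamma=gamma, class_weight="balanced")
    final.fit(Z, y)
    return SvmModel(
        feature_names=list(features.columns),
        mean=mean,
        std=std,
        C=float(C),
        gamma=float(gamma),
        support_vectors=final.support_vectors_.copy(),
        dual_coef=final.dual_coef_[0].copy(),
        intercept=float(final.intercept_[0]),
        training_meta={
            "seed": seed,
            "cv_folds": n_splits,
            "cv_score": best[0],
            "n_samples": len(y),
            "n_tumor": int(y.sum()),
            "optimizer": "deterministic 7x7 log-grid",
            "trace": trace,
        },
    )


def predict_superpixels(model: SvmModel, features: pd.DataFrame) -> dict[int, bool]:
    """Tumor/non-tumor prediction per superpixel id."""
    if list(features.columns) != model.feature_names:
        raise ValueError("feature columns do not match the trained model")
    pred = model.predict(features.to_numpy(dtype=np.float64))
    return {int(sid): bool(p) for sid, p in zip(features.index, pred)}


def assemble_segmentation(sp, predictions: dict[int, bool], background_ids) -> np.ndarray:
    """Union of tumor-predicted superpixels; background ids are forced 0."""
    bg = set(int(b) for b in background_ids)
    tumor = np.zeros(sp.count, dtype=bool)
    for sid in range(sp.count):
        if sid in bg:
            continue
        if sid not in predictions:
            raise ValueError(f"missing prediction for retained superpixel {sid}")
        tumor[sid] = predictions[sid]
    return tumor[sp.labels]


def train_test_split_ids(
    n: int, train_fraction: float, seed: int, strata: list | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Seed-reproducible train/test split, stratified when strata are given."""
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    if strata is None:
        strata = ["all"] * n
    strata = np.asarray(strata)
    train, test = [], []
    for s in np.unique(strata):
        members = idx[strata == s]
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1) if len(members) > 1 else len(members)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))
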