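"""Adaptive selection of the superpixel count K (the ASLIC0 step).

A healthy brain is close to bilaterally symmetric; a glioma breaks that
symmetry. Two scalar descriptors computed from hemispheric asymmetry drive
the choice of K:

* **TAR** (tumor area ratio): the slice is aligned to its own midline,
  divided into a 16x16 grid of 15x15-pixel cells, and each left-hemisphere
  cell is correlated (Pearson) with its mirrored right-hemisphere
  counterpart. Cells with r below a threshold (default 0.81) are flagged
  as suspected tumor; TAR = n_flagged_left / 256.
* **TC** (tumor boundary complexity): boundary-pixel count divided by the
  area-pixel count of the suspected region (a discrete perimeter/area
  ratio).

For training slices with ground truth the best K is labelled by a grid
search over K in {10, 20, ..., 450}: for each K, superpixels overlapping
the ground truth by more than 90% are merged into a candidate region, its
Dice against the ground truth is computed, and the middle of the widest
near-optimal plateau of the Dice-vs-K curve is taken. A 5-tree random
forest regressor then maps (TAR, TC) to K for unseen slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .evaluate import dice
from .superpixel import run_slic0

__all__ = [
    "SymmetryAlignment",
    "GridSimilarityMap",
    "TumorDescriptor",
    "KTrainingSample",
    "KModel",
    "align_midline",
    "grid_similarity",
    "flag_suspected_blocks",
    "compute_tar",
    "compute_tc",
    "compute_descriptor",
    "label_best_k",
    "train_k_model",
    "predict_k",
    "r_square",
]

GRID_CELLS = 16
CELL_SIZE = 15
GRID_IMAGE_SIZE = GRID_CELLS * CELL_SIZE  # 240
SIMILARITY_THRESHOLD = 0.81
K_GRID = tuple(range(10, 451, 10))
SHIFT_RANGE = 20
ROTATION_RANGE = 10
PLATEAU_EPSILON = 0.01
MERGE_RATIO = 0.9
FOREGROUND_THRESHOLD = 5.0


@dataclass
class SymmetryAlignment:
    """Result of the midline search: the correction applied and its score."""

    shift: int  # horizontal pixels applied to correct the image
    rotation: float  # degrees applied to correct the image
    corrected: np.ndarray
    score: float = np.nan


@dataclass
class GridSimilarityMap:
    """16x16 grid of left/right mirror correlations (NaN = zero variance)."""

    r_values: np.ndarray
    cell_size: int = CELL_SIZE

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=np.float64)
        if self.r_values.shape != (GRID_CELLS, GRID_CELLS):
            raise ValueError("r_values must be 16x16")

    def effective(self) -> np.ndarray:
        """Correlations with zero-variance cells treated as symmetric (r=1)."""
        return np.where(np.isnan(self.r_values), 1.0, self.r_values)


@dataclass(frozen=True)
class TumorDescriptor:
    """(TAR, TC) pair summarising suspected-tumor size and boundary complexity."""

    tar: float
    tc: float
    n_blocks: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tar <= 1.0):
            raise ValueError("TAR must lie in [0, 1]")
        if self.tc < 0:
            raise ValueError("TC must be non-negative")


@dataclass(frozen=True)
class KTrainingSample:
    descriptor: TumorDescriptor
    k_best: int

    def __post_init__(self) -> None:
        if not (10 <= self.k_best <= 450) or self.k_best % 10:
            raise ValueError("k_best must be in [10, 450] and divisible by 10")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equally sized pixel blocks; NaN if either
    block has zero variance."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0:
        return np.nan
    return float((da * db).sum() / denom)


def _shift_horizontal(image: np.ndarray, shift: int) -> np.ndarray:
    """Translate columns by ``shift`` pixels (positive = rightward), zero fill."""
    out = np.zeros_like(image)
    if shift >= 0:
        if shift < image.shape[1]:
            out[:, shift:] = image[:, : image.shape[1] - shift]
    else:
        out[:, :shift] = image[:, -shift:]
    return out


def _symmetry_score(image: np.ndarray) -> float:
    W = image.shape[1]
    half = W // 2
    left = image[:, :half]
    right_mirrored = image[:, W - half :][:, ::-1]
    r = _pearson(left, right_mirrored)
    return 0.0 if np.isnan(r) else r


def align_midline(
    image: np.ndarray,
    shift_range: int = SHIFT_RANGE,
    rotation_range: int = ROTATION_RANGE,
) -> SymmetryAlignment:
    """Find the shift/rotation making the slice most mirror-symmetric.

    Exhaustive search over integer shifts in [-shift_range, shift_range]
    and integer rotations (degrees) in [-rotation_range, rotation_range],
    maximizing the Pearson correlation between the left half and the
    mirrored right half of the corrected image. Ties prefer the smallest
    correction.
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.any(img >= FOREGROUND_THRESHOLD):
        raise ValueError("image is all background; cannot align")
    best = (-np.inf, np.inf, 0, 0.0, img)  # score, |corr| penalty, shift, rot, corrected
    for rot in range(-rotation_range, rotation_range + 1):
        rotated = (
            img
            if rot == 0
            else ndi.rotate(img, rot, reshape=False, order=1, mode="constant", cval=0.0)
        )
        for s in range(-shift_range, shift_range + 1):
            candidate = _shift_horizontal(rotated, s) if s else rotated
            score = _symmetry_score(candidate)
            penalty = abs(s) + abs(rot)
            if score > best[0] + 1e-12 or (abs(score - best[0]) <= 1e-12 and penalty < best[1]):
                best = (score, penalty, s, float(rot), candidate)
    return SymmetryAlignment(shift=best[2], rotation=best[3], corrected=best[4], score=best[0])


def grid_similarity(corrected: np.ndarray) -> GridSimilarityMap:
    """Mirror-correlation of each grid cell with its opposite-hemisphere twin.

    The slice is resampled to 240x240 if needed and divided into 16x16
    cells of 15x15 pixels. Cell (i, j) on the left is compared with the
    horizontally flipped cell (i, 15-j) on the right; both cells of a pair
    receive the same r.
    """
    img = np.asarray(corrected, dtype=np.float64)
    if img.shape != (GRID_IMAGE_SIZE, GRID_IMAGE_SIZE):
        from skimage.transform import resize

        img = resize(
            img, (GRID_IMAGE_SIZE, GRID_IMAGE_SIZE), preserve_range=True, anti_aliasing=True
        )
    r = np.full((GRID_CELLS, GRID_CELLS), np.nan)
    for i in range(GRID_CELLS):
        for j in range(GRID_CELLS // 2):
            jm = GRID_CELLS - 1 - j
            a = img[i * CELL_SIZE : (i + 1) * CELL_SIZE, j * CELL_SIZE : (j + 1) * CELL_SIZE]
            b = img[i * CELL_SIZE : (i + 1) * CELL_SIZE, jm * CELL_SIZE : (jm + 1) * CELL_SIZE]
            val = _pearson(a, b[:, ::-1])
            if np.isnan(val) and (a.std() > 0) != (b.std() > 0):
                # one side flat, the other structured: evidence of asymmetry
                # (e.g. a homogeneous tumor interior facing textured tissue),
                # not of symmetry. Both-flat pairs stay NaN => symmetric.
                val = 0.0
            r[i, j] = val
            r[i, jm] = val
    return GridSimilarityMap(r_values=r)


def flag_suspected_blocks(
    sim: GridSimilarityMap, threshold: float = SIMILARITY_THRESHOLD
) -> tuple[np.ndarray, int]:
    """Cells whose mirror correlation falls below the threshold.

    Returns the union of flagged *left-hemisphere* cell footprints as a
    240x240 boolean mask, plus the count n of flagged left cells (the
    numerator of TAR). Zero-variance cells count as symmetric.
    """
    eff = sim.effective()
    flagged = eff < threshold
    mask = np.zeros((GRID_IMAGE_SIZE, GRID_IMAGE_SIZE), dtype=bool)
    n = 0
    for i in range(GRID_CELLS):
        for j in range(GRID_CELLS // 2):
            if flagged[i, j]:
                n += 1
                mask[
                    i * CELL_SIZE : (i + 1) * CELL_SIZE, j * CELL_SIZE : (j + 1) * CELL_SIZE
                ] = True
    return mask, n


def compute_tar(n_blocks: int) -> float:
    """TAR = n / 256."""
    if not (0 <= n_blocks <= GRID_CELLS * GRID_CELLS):
        raise ValueError("n_blocks out of range")
    return n_blocks / float(GRID_CELLS * GRID_CELLS)


def compute_tc(suspected: np.ndarray) -> float:
    """Boundary complexity: boundary-pixel count / area-pixel count.

    A mask pixel is boundary if at least one 4-neighbour is outside the
    mask; the image border counts as outside. Empty mask gives 0.
    """
    mask = np.asarray(suspected, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        return 0.0
    inside = np.zeros_like(mask)
    inside[1:-1, 1:-1] = (
        mask[:-2, 1:-1] & mask[2:, 1:-1] & mask[1:-1, :-2] & mask[1:-1, 2:]
    )
    edge = mask & ~inside
    return float(edge.sum()) / area


def compute_descriptor(
    image: np.ndarray, threshold: float = SIMILARITY_THRESHOLD
) -> TumorDescriptor:
    """Full TAR/TC computation: align, grid-correlate, flag, measure."""
    alignment = align_midline(image)
    sim = grid_similarity(alignment.corrected)
    mask, n = flag_suspected_blocks(sim, threshold=threshold)
    return TumorDescriptor(tar=compute_tar(n), tc=compute_tc(mask), n_blocks=n)


def label_best_k(
    image: np.ndarray,
    gt: np.ndarray,
    k_grid: tuple[int, ...] = K_GRID,
    merge_ratio: float = MERGE_RATIO,
    plateau_epsilon: float = PLATEAU_EPSILON,
    iterations: int = 10,
    return_curve: bool = False,
):
    """Label the best superpixel count for a slice with known ground truth.

    For each K on the grid, SLIC0 superpixels overlapping the ground truth
    by more than ``merge_ratio`` are merged into a candidate region and its
    Dice against the ground truth recorded. The longest contiguous run of K
    with Dice within ``plateau_epsilon`` of the maximum is the plateau; the
    middle of the plateau is returned (a robust choice: anywhere on the
    plateau performs almost equally).
    """
    gt_mask = np.asarray(gt, dtype=bool)
    if not gt_mask.any():
        raise ValueError("ground truth is empty")
    img = np.asarray(image, dtype=np.float64)
    dices = np.empty(len(k_grid))
    for idx, K in enumerate(k_grid):
        sp = run_slic0(img, K, iterations=iterations)
        inter = np.bincount(sp.labels.ravel(), weights=gt_mask.ravel(), minlength=sp.count)
        sizes = sp.sizes()
        merged_ids = inter / sizes > merge_ratio
        candidate = merged_ids[sp.labels]
        dices[idx] = dice(candidate, gt_mask)
    dmax = dices.max()
    ok = dices >= dmax - plateau_epsilon
    # longest contiguous run of near-optimal K (first such run on ties)
    best_start, best_len, start = 0, 0, None
    for i, flag in enumerate(list(ok) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    k_best = int(k_grid[best_start + (best_len - 1) // 2])
    if return_curve:
        return k_best, np.asarray(k_grid), dices
    return k_best


# ---------------------------------------------------------------------------
# Random-forest regression of K from (TAR, TC)


@dataclass
class KModel:
    """A 5-tree random-forest regressor of K, stored as portable arrays.

    Each tree is a dict of parallel lists (children_left, children_right,
    feature, threshold, value) so the model round-trips through JSON and
    predicts without scikit-learn at hand.
    """

    trees: list[dict]
    training_meta: dict = field(default_factory=dict)

    def predict_raw(self, tar: float, tc: float) -> float:
        if not self.trees:
            raise ValueError("model has no trees (untrained)")
        x = (float(tar), float(tc))
        preds = []
        for t in self.trees:
            node = 0
            while t["children_left"][node] != -1:
                if x[t["feature"][node]] <= t["threshold"][node]:
                    node = t["children_left"][node]
                else:
                    node = t["children_right"][node]
            preds.append(t["value"][node])
        return float(np.mean(preds))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"trees": self.trees, "training_meta": self.training_meta}, fh)

    @classmethod
    def load(cls, path: str) -> "KModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(trees=obj["trees"], training_meta=obj.get("training_meta", {}))


def train_k_model(
    samples: list[KTrainingSample], seed: int, n_trees: int = 5, min_samples_split: int = 5
) -> KModel:
    """Fit the (TAR, TC) -> K regressor.

    5 bootstrap-seeded trees, unlimited depth, nodes with fewer than
    ``min_samples_split`` samples are not split.
    """
    from sklearn.ensemble import RandomForestRegressor

    if len(samples) < 10:
        raise ValueError("need at least 10 training samples")
    X = np.array([[s.descriptor.tar, s.descriptor.tc] for s in samples])
    y = np.array([s.k_best for s in samples], dtype=np.float64)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_depth=None,
        min_samples_split=min_samples_split,
        bootstrap=True,
        random_state=seed,
    )
    forest.fit(X, y)
    trees = []
    for est in forest.estimators_:
        t = est.tree_
        trees.append(
            {
                "children_left": t.children_left.tolist(),
                "children_right": t.children_right.tolist(),
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "value": t.value[:, 0, 0].tolist(),
            }
        )
    meta = {
        "seed": seed,
        "n_trees": n_trees,
        "stopping": f"no split below {min_samples_split} samples",
        "n_samples": len(samples),
        "k_range": [float(y.min()), float(y.max())],
    }
    return KModel(trees=trees, training_meta=meta)


def predict_k(model: KModel, descriptor: TumorDescriptor) -> int:
    """Forest prediction rounded to the nearest multiple of 10, clipped to [10, 450]."""
    raw = model.predict_raw(descriptor.tar, descriptor.tc)
    k = int(np.floor(raw / 10.0 + 0.5) * 10)
    return int(np.clip(k, 10, 450))


def r_square(k_best, k_predict) -> float:
    """Coefficient of determination between labelled and predicted K."""
    yb = np.asarray(k_best, dtype=np.float64)
    yp = np.asarray(k_predict, dtype=np.float64)
    if yb.shape != yp.shape or yb.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    ss_tot = float(((yb - yb.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("k_best values are all identical; R^2 undefined")
    ss_res = float(((yb - yp) ** 2).sum())
    return 1.0 - ss_res / ss_tot
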