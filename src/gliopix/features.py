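"""Per-superpixel feature descriptor: 69 named scalars.

The descriptor quantifies the intensity distribution, texture, shape and
self-similarity of each superpixel:

* 17 first-order intensity statistics of the raw pixel values;
* 13 Haralick texture measures from gray-level co-occurrence matrices of
  the original image (GLCM), of its Roberts gradient map (GLGCM) and of
  its Prewitt curvature map (GLCCM) — each averaged over the four
  directions {0°, 45°, 90°, 135°} at step 1 and over the four gray
  quantizations {8, 16, 32, 64};
* 1 mean curvature of the intensity surface;
* 12 fractal measures: area, mean brightness and box-counting dimension of
  the superpixel's intersection with 4 multi-Otsu intensity channels.

17 + 3*13 + 1 + 12 = 69.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

__all__ = [
    "FEATURE_NAMES",
    "INTENSITY_NAMES",
    "HARALICK_NAMES",
    "CooccurrenceMatrix",
    "FractalChannelSet",
    "intensity_statistics",
    "quantize_gray",
    "cooccurrence_matrix",
    "roberts_gradient_map",
    "prewitt_curvature_map",
    "haralick_features",
    "curvature_map",
    "curvature_feature",
    "otsu_channels",
    "box_counting_dimension",
    "fractal_features",
    "remove_background_superpixels",
    "extract_feature_table",
]

BACKGROUND_THRESHOLD = 5.0
QUANT_LEVELS = (8, 16, 32, 64)
DIRECTIONS = (0, 45, 90, 135)
N_FRACTAL_CHANNELS = 4
BOX_SIZES = (1, 2, 4, 8, 16, 32)
_EPS = 1e-12

INTENSITY_NAMES = (
    "energy",
    "entropy",
    "minimum",
    "maximum",
    "mean",
    "median",
    "range",
    "std",
    "variance",
    "mad",
    "rms",
    "skewness",
    "kurtosis",
    "uniformity",
    "p10",
    "p90",
    "iqr",
)

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"int_{n}" for n in INTENSITY_NAMES)
    + tuple(f"glcm_{n}" for n in HARALICK_NAMES)
    + tuple(f"glgcm_{n}" for n in HARALICK_NAMES)
    + tuple(f"glccm_{n}" for n in HARALICK_NAMES)
    + ("curvature",)
    + tuple(
        f"fractal_ch{k}_{m}" for k in range(N_FRACTAL_CHANNELS) for m in ("area", "brightness", "boxdim")
    )
)
assert len(FEATURE_NAMES) == 69

# offsets as (drow, dcol) for each co-occurrence direction
_DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


# ---------------------------------------------------------------------------
# first-order statistics


def intensity_statistics(pixels: np.ndarray) -> np.ndarray:
    """The 17 first-order statistics, in the canonical order.

    Entropy (bits) and uniformity use a 64-bin histogram over the value
    range. Kurtosis is the non-excess (Pearson) form, 3 for a normal
    distribution; skewness and kurtosis of a constant input are defined 0.
    """
    x = np.asarray(pixels, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty pixel set")
    mn, mx = float(x.min()), float(x.max())
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    hist, _ = np.histogram(x, bins=64, range=(mn, mx) if mx > mn else (mn - 0.5, mn + 0.5))
    p = hist / x.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p * p).sum())
    if sd > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skew = kurt = 0.0
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    return np.array(
        [
            float((x * x).sum()),  # energy
            entropy,
            mn,
            mx,
            mean,
            float(np.median(x)),
            mx - mn,
            sd,
            sd * sd,
            float(np.abs(x - mean).mean()),  # mean absolute deviation
            float(np.sqrt((x * x).mean())),  # root mean square
            skew,
            kurt,
            uniformity,
            float(p10),
            float(p90),
            float(p75 - p25),
        ]
    )


# ---------------------------------------------------------------------------
# co-occurrence texture


def quantize_gray(image: np.ndarray, levels: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Linear binning of region intensities into {0..levels-1}.

    Returns an integer grid with -1 outside the region. A constant region
    maps entirely to level 0.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(image, dtype=np.float64)
    m = np.ones(img.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty region")
    vals = img[m]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full(img.shape, -1, dtype=np.int64)
    if hi == lo:
        out[m] = 0
        return out
    q = np.floor((img[m] - lo) * levels / (hi - lo)).astype(np.int64)
    out[m] = np.clip(q, 0, levels - 1)
    return out


@dataclass
class CooccurrenceMatrix:
    """Symmetric L x L joint-occurrence counts at 1-pixel offset."""

    counts: np.ndarray
    levels: int
    direction: int
    offset: int = 1

    @property
    def empty(self) -> bool:
        return self.counts.sum() == 0

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return self.counts / total


def cooccurrence_matrix(quantized: np.ndarray, direction: int, levels: int) -> CooccurrenceMatrix:
    """Count symmetric gray-level pairs at the direction's 1-pixel offset.

    ``quantized`` uses -1 for pixels outside the region; both ends of a
    pair must lie inside it.
    """
    if direction not in _DIRECTION_OFFSETS:
        raise ValueError(f"direction must be one of {tuple(_DIRECTION_OFFSETS)}")
    q = np.asarray(quantized)
    dr, dc = _DIRECTION_OFFSETS[direction]
    H, W = q.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (a >= 0) & (b >= 0)
    counts = np.zeros((levels, levels), dtype=np.float64)
    if valid.any():
        np.add.at(counts, (a[valid], b[valid]), 1.0)
        np.add.at(counts, (b[valid], a[valid]), 1.0)
    return CooccurrenceMatrix(counts=counts, levels=levels, direction=direction)


def haralick_features(matrix: CooccurrenceMatrix | np.ndarray) -> np.ndarray:
    """The 13 classic Haralick measures of a normalized co-occurrence matrix.

    Logarithms are base 2 with an epsilon guard, so entropies are in bits
    and always finite. An empty matrix yields 13 zeros. The unstable 14th
    measure (maximal correlation coefficient) is omitted.
    """
    if isinstance(matrix, CooccurrenceMatrix):
        p = matrix.normalized()
    else:
        p = np.asarray(matrix, dtype=np.float64)
    if p.sum() == 0:
        return np.zeros(13)
    L = p.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    asm = float((p * p).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    sum_of_squares = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    p_sum = np.bincount((ii + jj).astype(np.int64).ravel(), weights=p.ravel(), minlength=2 * L - 1)
    k_sum = np.arange(len(p_sum), dtype=np.float64)
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = float(-(p_sum * np.log2(p_sum + _EPS)).sum())

    entropy = float(-(p * np.log2(p + _EPS)).sum())

    p_diff = np.bincount(np.abs(ii - jj).astype(np.int64).ravel(), weights=p.ravel(), minlength=L)
    k_diff = np.arange(len(p_diff), dtype=np.float64)
    diff_avg = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    difference_entropy = float(-(p_diff * np.log2(p_diff + _EPS)).sum())

    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())
    pxy = np.outer(px, py)
    hxy1 = float(-(p * np.log2(pxy + _EPS)).sum())
    hxy2 = float(-(pxy * np.log2(pxy + _EPS)).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            sum_of_squares,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
        ]
    )


def roberts_gradient_map(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude from the two 2x2 Roberts cross kernels.

    Borders are handled by edge replication so the map keeps the image
    shape. This map feeds the GLGCM texture matrices.
    """
    img = np.asarray(image, dtype=np.float64)
    pad = np.pad(img, ((0, 1), (0, 1)), mode="edge")
    g1 = pad[:-1, :-1] - pad[1:, 1:]
    g2 = pad[:-1, 1:] - pad[1:, :-1]
    return np.hypot(g1, g2)


_PREWITT_X = np.array([[-1.0, 0.0, 1.0]] * 3)
_PREWITT_Y = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -1.0, -1.0]])


def prewitt_curvature_map(image: np.ndarray) -> np.ndarray:
    """Magnitude of the two 3x3 Prewitt kernel responses (feeds GLCCM).

    Distinct from :func:`curvature_map`, which is the differential-geometry
    curvature used for the scalar curvature feature.
    """
    img = np.asarray(image, dtype=np.float64)
    gx = ndi.convolve(img, _PREWITT_X, mode="nearest")
    gy = ndi.convolve(img, _PREWITT_Y, mode="nearest")
    return np.hypot(gx, gy)


# ---------------------------------------------------------------------------
# curvature of the intensity surface


def curvature_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel curvature of the intensity surface.

    Curv = (f_xx f_y^2 + f_yy f_x^2 - 2 f_xx f_x f_y) / (f_x^2 + f_y^2)^(3/2)

    with central-difference derivatives (x = columns, y = rows). Pixels
    with a degenerate gradient (f_x^2 + f_y^2 < 1e-8) get curvature 0.
    """
    img = np.asarray(image, dtype=np.float64)
    f_y, f_x = np.gradient(img)
    f_xx = np.gradient(f_x, axis=1)
    f_yy = np.gradient(f_y, axis=0)
    g2 = f_x * f_x + f_y * f_y
    num = f_xx * f_y * f_y + f_yy * f_x * f_x - 2.0 * f_xx * f_x * f_y
    degenerate = g2 < 1e-8
    den = np.power(np.where(degenerate, 1.0, g2), 1.5)
    return np.where(degenerate, 0.0, num / den)


def curvature_feature(image: np.ndarray, region: np.ndarray) -> float:
    """Mean per-pixel curvature over a superpixel."""
    m = np.asarray(region, dtype=bool)
    if not m.any():
        raise ValueError("empty region")
    return float(curvature_map(image)[m].mean())


# ---------------------------------------------------------------------------
# fractal features


@dataclass
class FractalChannelSet:
    """Four binary intensity channels from multi-level Otsu thresholding.

    The channel masks partition the slice foreground into 4 threshold
    intervals; each carries a 4-neighbour edge image. ``degenerate`` marks
    slices with too few distinct intensities to threshold.
    """

    masks: list = field(default_factory=list)
    edges: list = field(default_factory=list)
    thresholds: tuple = ()
    degenerate: bool = False


def _edge_of(mask: np.ndarray) -> np.ndarray:
    inside = np.zeros_like(mask)
    inside[1:-1, 1:-1] = mask[:-2, 1:-1] & mask[2:, 1:-1] & mask[1:-1, :-2] & mask[1:-1, 2:]
    return mask & ~inside


def otsu_channels(
    image: np.ndarray,
    n_channels: int = N_FRACTAL_CHANNELS,
    foreground_threshold: float = BACKGROUND_THRESHOLD,
) -> FractalChannelSet:
    """Split the slice foreground into intensity channels by multi-Otsu.

    n_channels - 1 thresholds maximize the between-class variance of the
    foreground histogram; channel k is the binary mask of the k-th
    intensity interval. Slices with fewer distinct foreground values than
    channels are flagged degenerate (all fractal features become 0).
    """
    from skimage.filters import threshold_multiotsu

    img = np.asarray(image, dtype=np.float64)
    fg = img >= foreground_threshold
    vals = img[fg]
    uniq, counts = np.unique(vals, return_counts=True)
    if len(uniq) < n_channels:
        return FractalChannelSet(degenerate=True)
    # exact-value histogram when the intensity alphabet is small (plateau
    # images), otherwise 256 equal bins; thresholds are attained bin
    # centers, so the class rule is value <= threshold (right=True)
    if len(uniq) <= 1024:
        hist = (counts.astype(np.float64), uniq)
    else:
        h, edges = np.histogram(vals, bins=256)
        hist = (h.astype(np.float64), (edges[:-1] + edges[1:]) / 2.0)
    try:
        thresholds = threshold_multiotsu(classes=n_channels, hist=hist)
    except ValueError:
        return FractalChannelSet(degenerate=True)
    idx = np.digitize(img, thresholds, right=True)
    masks = [fg & (idx == k) for k in range(n_channels)]
    edges = [_edge_of(m) for m in masks]
    return FractalChannelSet(masks=masks, edges=edges, thresholds=tuple(float(t) for t in thresholds))


def box_counting_dimension(binary: np.ndarray, sizes: tuple[int, ...] = BOX_SIZES) -> float:
    """Box-counting (Minkowski) dimension of a binary image.

    Occupied-box counts at box sizes {1, 2, 4, 8, 16, 32}; the dimension is
    the least-squares slope of log(count) against log(1/size). Empty input
    gives 0.
    """
    m = np.asarray(binary, dtype=bool)
    if not m.any():
        return 0.0
    counts = []
    for s in sizes:
        H, W = m.shape
        ph = (-H) % s
        pw = (-W) % s
        padded = np.pad(m, ((0, ph), (0, pw)))
        blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    x = np.log(1.0 / np.asarray(sizes, dtype=np.float64))
    y = np.log(np.asarray(counts, dtype=np.float64))
    slope = float(np.polyfit(x, y, 1)[0])
    return slope


def fractal_features(
    image: np.ndarray, region: np.ndarray, channels: FractalChannelSet
) -> np.ndarray:
    """Area, mean brightness and edge box-dimension per channel (12 values).

    Everything is restricted to the superpixel: area = |channel ∩ region|,
    brightness = mean original intensity there (0 if empty), box dimension
    of the channel's edge image inside the region.
    """
    m = np.asarray(region, dtype=bool)
    out = np.zeros(3 * N_FRACTAL_CHANNELS)
    if channels.degenerate:
        return out
    img = np.asarray(image, dtype=np.float64)
    for k in range(N_FRACTAL_CHANNELS):
        inter = channels.masks[k] & m
        area = int(inter.sum())
        out[3 * k] = area
        out[3 * k + 1] = float(img[inter].mean()) if area else 0.0
        out[3 * k + 2] = box_counting_dimension(channels.edges[k] & m)
    return out


# ---------------------------------------------------------------------------
# assembly


def remove_background_superpixels(
    image: np.ndarray, sp, threshold: float = BACKGROUND_THRESHOLD
) -> np.ndarray:
    """Ids of superpixels whose mean brightness clears the background cut.

    Superpixels with mean intensity strictly below the threshold are
    background (black surround): they are dropped from the feature table
    and forced non-tumor in the final mask.
    """
    img = np.asarray(image, dtype=np.float64)
    sums = np.bincount(sp.labels.ravel(), weights=img.ravel(), minlength=sp.count)
    means = sums / sp.sizes()
    return np.nonzero(means >= threshold)[0]


def _haralick_block(source: np.ndarray, bbox_mask: np.ndarray, levels_set, directions) -> np.ndarray:
    """13 Haralick values averaged over quantization levels and directions."""
    acc = np.zeros(13)
    n = 0
    for levels in levels_set:
        q = quantize_gray(source, levels, bbox_mask)
        for d in directions:
            acc += haralick_features(cooccurrence_matrix(q, d, levels))
            n += 1
    return acc / n


def extract_feature_table(
    image: np.ndarray,
    sp,
    retained_ids: np.ndarray | None = None,
    levels_set: tuple[int, ...] = QUANT_LEVELS,
    directions: tuple[int, ...] = DIRECTIONS,
) -> pd.DataFrame:
    """The 69-column feature table, one row per retained superpixel.

    Texture sources (Roberts/Prewitt maps), the curvature map and the Otsu
    channels are computed once for the whole slice; per superpixel the
    co-occurrence statistics are then evaluated on the bounding box of its
    mask so both ends of every counted pair lie inside the superpixel.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape != sp.labels.shape:
        raise ValueError("image and superpixel map dimensions differ")
    ids = np.arange(sp.count) if retained_ids is None else np.asarray(retained_ids)
    roberts = roberts_gradient_map(img)
    prewitt = prewitt_curvature_map(img)
    curv = curvature_map(img)
    channels = otsu_channels(img)
    slices = ndi.find_objects(sp.labels + 1)

    rows = np.empty((len(ids), 69))
    for row_i, sid in enumerate(ids):
        sl = slices[sid]
        local_mask = sp.labels[sl] == sid
        pix = img[sl][local_mask]
        vec = np.empty(69)
        vec[0:17] = intensity_statistics(pix)
        vec[17:30] = _haralick_block(img[sl], local_mask, levels_set, directions)
        vec[30:43] = _haralick_block(roberts[sl], local_mask, levels_set, directions)
        vec[43:56] = _haralick_block(prewitt[sl], local_mask, levels_set, directions)
        vec[56] = float(curv[sl][local_mask].mean())
        # crop the channel set to the bounding box; intersections are unchanged
        local_channels = (
            channels
            if channels.degenerate
            else FractalChannelSet(
                masks=[m[sl] for m in channels.masks],
                edges=[e[sl] for e in channels.edges],
                thresholds=channels.thresholds,
            )
        )
        vec[57:69] = fractal_features(img[sl], local_mask, local_channels)
        rows[row_i] = vec
    return pd.DataFrame(rows, index=pd.Index(ids, name="superpixel_id"), columns=list(FEATURE_NAMES))
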