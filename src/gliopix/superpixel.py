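"""SLIC and SLIC0 superpixel generation on single-channel intensity images.

The clustering distance between a pixel i and a cluster center j is

    D = sqrt(d_c^2 + (d_s / S)^2 * C^2)

with d_c = |I_i - I_j| the gray distance, d_s the Euclidean pixel distance,
S = sqrt(N/K) the grid interval and C the compactness. Larger C weighs the
spatial term more and yields smoother, more regular superpixels.

SLIC uses one fixed C. SLIC0 removes the choice: each center's C becomes
the running maximum gray distance observed among its members (floored at 1
intensity unit), starting from the second iteration, so flat regions get
compact cells while high-variance regions let boundaries follow the image.

Assignment is restricted to pixels within the center's search window:
|row - center_row| <= S and |col - center_col| <= S. Ties go to the
lowest-index center; a pixel covered by no window (possible after centers
drift) falls back to the nearest center by the same distance over all
centers. Both rules are part of the documented behaviour so results are
exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterCenter",
    "SuperpixelMap",
    "slic_distance",
    "initialize_centers",
    "run_slic",
    "run_slic0",
    "enforce_connectivity",
]

#: compactness used for the first SLIC0 iteration, before any gray
#: distances have been observed (classic SLIC default).
SLIC0_INITIAL_COMPACTNESS = 10.0
#: floor for the adaptive per-center compactness, in intensity units.
SLIC0_COMPACTNESS_FLOOR = 1.0
DEFAULT_ITERATIONS = 10


@dataclass
class ClusterCenter:
    """A k-means cluster center in (gray, row, col) space."""

    gray: float
    position: tuple[float, float]  # (row, col)
    compactness: float = SLIC0_INITIAL_COMPACTNESS

    def __post_init__(self) -> None:
        if self.compactness <= 0:
            raise ValueError("compactness must be positive")


@dataclass
class SuperpixelMap:
    """A partition of a slice into ``count`` connected superpixels.

    ``labels`` holds one integer per pixel, taking exactly the values
    0..count-1; after connectivity enforcement every label is a single
    4-connected component.
    """

    labels: np.ndarray
    count: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        if self.count != len(present) or present[0] != 0 or present[-1] != self.count - 1:
            raise ValueError("labels must be exactly {0..count-1}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.count)

    def save(self, path: str) -> None:
        """Persist as a 16-bit PNG label image plus a JSON sidecar."""
        import imageio.v3 as iio

        iio.imwrite(path, self.labels.astype(np.uint16))
        with open(str(path) + ".json", "w") as fh:
            json.dump({"count": self.count, **self.meta}, fh)

    @classmethod
    def load(cls, path: str) -> "SuperpixelMap":
        import imageio.v3 as iio

        labels = np.asarray(iio.imread(path)).astype(np.int64)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        count = meta.pop("count")
        return cls(labels=labels, count=count, meta=meta)


def slic_distance(
    pixel_gray: float,
    pixel_pos: tuple[float, float],
    center: ClusterCenter,
    S: float,
    C: float | None = None,
) -> float:
    """Clustering distance D between one pixel and one center.

    ``C`` overrides the center's own compactness when given (plain SLIC);
    SLIC0 passes None to use the per-center adaptive value.
    """
    if S <= 0:
        raise ValueError("S must be positive")
    c = center.compactness if C is None else C
    if c <= 0:
        raise ValueError("C must be positive")
    dc = abs(float(pixel_gray) - center.gray)
    dr = pixel_pos[0] - center.position[0]
    dcol = pixel_pos[1] - center.position[1]
    ds2 = dr * dr + dcol * dcol
    return float(np.sqrt(dc * dc + ds2 / (S * S) * c * c))


def _gradient_magnitude(image: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(image.astype(np.float64))
    return np.hypot(gy, gx)


def initialize_centers(image: np.ndarray, K: int) -> list[ClusterCenter]:
    """Seed centers on a regular grid, perturbed to the local gradient minimum.

    The grid has spacing ~S = sqrt(N/K) in each direction; each seed is moved
    to the lowest-gradient pixel of its 3x3 neighbourhood so seeds avoid
    edges. The actual number of centers can differ from K by grid rounding
    (within ±10% for images much larger than S).
    """
    img = np.asarray(image, dtype=np.float64)
    H, W = img.shape
    N = H * W
    if K < 1 or K > N:
        raise ValueError(f"K must be in [1, {N}], got {K}")
    # grid shaped to approximate K while following the image aspect ratio
    n_rows = max(1, int(round(np.sqrt(K * H / W))))
    n_cols = max(1, int(round(K / n_rows)))
    grad = _gradient_magnitude(img)
    centers: list[ClusterCenter] = []
    for i in range(n_rows):
        for j in range(n_cols):
            r = int((i + 0.5) * H / n_rows)
            c = int((j + 0.5) * W / n_cols)
            r0, r1 = max(0, r - 1), min(H, r + 2)
            c0, c1 = max(0, c - 1), min(W, c + 2)
            win = grad[r0:r1, c0:c1]
            if grad[r, c] > win.min():  # ties keep the grid seed
                dr, dc = np.unravel_index(np.argmin(win), win.shape)
                r, c = r0 + int(dr), c0 + int(dc)
            centers.append(ClusterCenter(gray=float(img[r, c]), position=(float(r), float(c))))
    return centers


def _assign(
    img: np.ndarray,
    gray: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    comp: np.ndarray,
    S: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One assignment sweep; returns (labels, per-center max gray distance).

    Centers are visited in index order and a pixel is re-assigned only on a
    strictly smaller distance, so ties resolve to the lowest center index —
    the same rule as an argmin over centers.
    """
    H, W = img.shape
    K = len(gray)
    dist = np.full((H, W), np.inf)
    labels = np.full((H, W), -1, dtype=np.int64)
    for k in range(K):
        r0 = max(0, int(np.ceil(rows[k] - S)))
        r1 = min(H - 1, int(np.floor(rows[k] + S)))
        c0 = max(0, int(np.ceil(cols[k] - S)))
        c1 = min(W - 1, int(np.floor(cols[k] + S)))
        if r1 < r0 or c1 < c0:
            continue
        sub = img[r0 : r1 + 1, c0 : c1 + 1]
        dc = np.abs(sub - gray[k])
        rr = np.arange(r0, r1 + 1, dtype=np.float64)[:, None] - rows[k]
        cc = np.arange(c0, c1 + 1, dtype=np.float64)[None, :] - cols[k]
        D = np.sqrt(dc * dc + (rr * rr + cc * cc) / (S * S) * (comp[k] * comp[k]))
        view = dist[r0 : r1 + 1, c0 : c1 + 1]
        upd = D < view
        view[upd] = D[upd]
        lab_view = labels[r0 : r1 + 1, c0 : c1 + 1]
        lab_view[upd] = k
    # fallback for pixels outside every search window
    orphan = labels < 0
    if np.any(orphan):
        orows, ocols = np.nonzero(orphan)
        for r, c in zip(orows, ocols):
            dc = np.abs(img[r, c] - gray)
            ds2 = (r - rows) ** 2 + (c - cols) ** 2
            D = np.sqrt(dc * dc + ds2 / (S * S) * comp * comp)
            labels[r, c] = int(np.argmin(D))
    # per-center max gray distance actually observed (for SLIC0)
    maxdc = np.zeros(K)
    np.maximum.at(maxdc, labels.ravel(), np.abs(img.ravel() - gray[labels.ravel()]))
    return labels, maxdc


def _slic_core(
    image: np.ndarray,
    K: int,
    iterations: int,
    compactness: float | None,
    history: list[np.ndarray] | None = None,
) -> SuperpixelMap:
    img = np.asarray(image, dtype=np.float64)
    H, W = img.shape
    N = H * W
    S = float(np.sqrt(N / K))
    centers = initialize_centers(img, K)
    gray = np.array([c.gray for c in centers])
    rows = np.array([c.position[0] for c in centers])
    cols = np.array([c.position[1] for c in centers])
    adaptive = compactness is None
    comp = np.full(len(centers), SLIC0_INITIAL_COMPACTNESS if adaptive else compactness)

    labels = np.zeros((H, W), dtype=np.int64)
    rr_idx, cc_idx = np.indices((H, W))
    for it in range(iterations):
        labels, maxdc = _assign(img, gray, rows, cols, comp, S)
        if history is not None:
            history.append(labels.copy())
        # center update: mean gray/position of members; empty clusters keep
        # their previous center
        counts = np.bincount(labels.ravel(), minlength=len(gray)).astype(np.float64)
        nz = counts > 0
        sums_g = np.bincount(labels.ravel(), weights=img.ravel(), minlength=len(gray))
        sums_r = np.bincount(labels.ravel(), weights=rr_idx.ravel(), minlength=len(gray))
        sums_c = np.bincount(labels.ravel(), weights=cc_idx.ravel(), minlength=len(gray))
        gray[nz] = sums_g[nz] / counts[nz]
        rows[nz] = sums_r[nz] / counts[nz]
        cols[nz] = sums_c[nz] / counts[nz]
        if adaptive:
            if it == 0:
                comp = np.maximum(SLIC0_COMPACTNESS_FLOOR, maxdc)
            else:
                comp = np.maximum(comp, maxdc)
    sp = enforce_connectivity(labels, K_requested=K)
    sp.meta.update(
        {
            "K_requested": K,
            "compactness": "slic0" if adaptive else float(compactness),
            "iterations": iterations,
        }
    )
    return sp


def run_slic(
    image: np.ndarray,
    K: int,
    C: float,
    iterations: int = DEFAULT_ITERATIONS,
    history: list[np.ndarray] | None = None,
) -> SuperpixelMap:
    """Plain SLIC with a fixed compactness C.

    ``history``, when given, collects the raw label grid after every
    assignment sweep (before connectivity enforcement).
    """
    if C <= 0:
        raise ValueError("C must be positive")
    return _slic_core(image, K, iterations, float(C), history)


def run_slic0(
    image: np.ndarray,
    K: int,
    iterations: int = DEFAULT_ITERATIONS,
    history: list[np.ndarray] | None = None,
) -> SuperpixelMap:
    """SLIC0: per-center compactness adapted to the observed gray range."""
    return _slic_core(image, K, iterations, None, history)


def enforce_connectivity(labels: np.ndarray, K_requested: int | None = None) -> SuperpixelMap:
    """Merge stray fragments so every superpixel is one 4-connected component.

    Connected components smaller than (N/K)/4 pixels are absorbed into
    their largest 4-adjacent neighbour; final labels are renumbered
    0..count-1 in raster order of first appearance.
    """
    from skimage.measure import label as cc_label

    labels = np.asarray(labels)
    H, W = labels.shape
    N = H * W
    # split into 4-connected components of equal original label
    comp = cc_label(labels, connectivity=1, background=int(labels.min()) - 1) - 1
    n_comp = int(comp.max()) + 1
    K = K_requested if K_requested is not None else len(np.unique(labels))
    min_size = (N / K) / 4.0

    sizes = np.bincount(comp.ravel(), minlength=n_comp)
    # adjacency from horizontal/vertical neighbour pairs (unique pairs only)
    adj: dict[int, set[int]] = {i: set() for i in range(n_comp)}
    pairs = []
    for a, b in ((comp[:, :-1], comp[:, 1:]), (comp[:-1, :], comp[1:, :])):
        diff = a != b
        pairs.append(np.stack([a[diff], b[diff]], axis=1))
    if pairs:
        allp = np.concatenate(pairs)
        if len(allp):
            allp = np.unique(np.sort(allp, axis=1), axis=0)
            for u, v in allp:
                adj[int(u)].add(int(v))
                adj[int(v)].add(int(u))

    # merge small components (ascending size) into their largest neighbour
    target = np.arange(n_comp)

    def resolve(i: int) -> int:
        while target[i] != i:
            target[i] = target[target[i]]
            i = target[i]
        return i

    for i in sorted(range(n_comp), key=lambda i: (sizes[i], i)):
        if sizes[i] >= min_size:
            continue
        neighbours = {resolve(j) for j in adj[i]} - {i}
        if not neighbours:
            continue
        best = max(neighbours, key=lambda j: (sizes[j], -j))
        sizes[best] += sizes[i]
        sizes[i] = 0
        target[i] = best
        adj[best] |= adj[i]

    final = np.array([resolve(i) for i in range(n_comp)])
    merged = final[comp]
    # renumber in raster order of first appearance
    _, first_pos = np.unique(merged.ravel(), return_index=True)
    order = np.argsort(first_pos)
    remap = np.empty(merged.max() + 1, dtype=np.int64)
    remap[np.unique(merged.ravel())[order]] = np.arange(len(order))
    out = remap[merged]
    return SuperpixelMap(labels=out, count=int(out.max()) + 1)
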