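"""Synthetic head phantoms and training sets.

The generator emulates what the segmentation pipeline assumes about a
T2-weighted axial slice: a bilaterally symmetric head on a near-black
background (background intensity < 5), tissue on a 12-bit scale with
mirror-symmetric internal structure, and — for tumor phantoms — a single
bright irregular blob confined to one hemisphere, as edema/tumor appears
bright on T2.

Tissue carries a mirrored smooth random texture field so that healthy
15x15 grid cells stay strongly correlated with their mirror twins even
under independent pixel noise; without internal structure a flat noisy
cell would decorrelate and inflate TAR, which real brain texture does not
do. The tumor blob is a disk whose radius is modulated by a low-order
random harmonic series; the ``irregularity`` amplitude therefore controls
the boundary complexity (TC) monotonically by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .adaptive_k import KTrainingSample, TumorDescriptor

__all__ = [
    "PhantomSpec",
    "generate_symmetric_phantom",
    "generate_tumor_phantom",
    "generate_k_dataset",
]

MAX_INTENSITY = 4095.0  # 12-bit scale
BACKGROUND_VALUE = 2.0
TISSUE_VALUE = 600.0
TEXTURE_SD = 80.0
VENTRICLE_VALUE = 300.0
BAND_VALUE = 900.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom slice.

    Defaults give a high-contrast T2-like tumor: radius 25 px, +800
    intensity units over tissue, moderate boundary irregularity, pixel
    noise sd 10.
    """

    seed: int = 0
    size: int = 240
    tumor_radius: float = 25.0
    tumor_contrast: float = 800.0
    irregularity: float = 0.3
    noise_sd: float = 10.0
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.size % 16:
            raise ValueError("size must be divisible by 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.irregularity <= 1.0):
            raise ValueError("irregularity must lie in [0, 1]")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")


def _ellipse(size: int, center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.indices((size, size))
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _base_phantom(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free symmetric head; returns (image, head mask)."""
    n = spec.size
    mid = n / 2.0 - 0.5  # mirror axis of the pixel lattice
    head = _ellipse(n, (mid, mid), (0.44 * n, 0.36 * n))
    img = np.full((n, n), BACKGROUND_VALUE)
    img[head] = TISSUE_VALUE
    # mirrored smooth texture field: structure dominates pixel noise
    field = ndi.gaussian_filter(rng.standard_normal((n, n)), sigma=3.0)
    field = 0.5 * (field + field[:, ::-1])
    field *= TEXTURE_SD / field[head].std()
    img[head] += field[head]
    # symmetric internal anatomy: ventricle pair and a bright tissue band
    for side in (-1, 1):
        vent = _ellipse(n, (mid - 0.05 * n, mid + side * 0.10 * n), (0.12 * n, 0.05 * n))
        img[vent & head] = VENTRICLE_VALUE
    band = _ellipse(n, (mid + 0.18 * n, mid), (0.10 * n, 0.22 * n)) & ~_ellipse(
        n, (mid + 0.18 * n, mid), (0.06 * n, 0.16 * n)
    )
    img[band & head] = BAND_VALUE
    return img, head


def _apply_noise(img: np.ndarray, head: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sd > 0:
        noisy = img.copy()
        noisy[head] += rng.normal(0.0, spec.noise_sd, int(head.sum()))
        img = noisy
    return np.clip(img, 0.0, MAX_INTENSITY)


def generate_symmetric_phantom(spec: PhantomSpec) -> np.ndarray:
    """A tumor-free head slice, exactly mirror-symmetric when noise_sd = 0."""
    rng = np.random.default_rng(spec.seed)
    img, head = _base_phantom(spec, rng)
    return _apply_noise(img, head, spec, rng)


def _tumor_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.size
    mid_col = n / 2.0
    max_r = spec.tumor_radius * (1.0 + 0.45 * spec.irregularity)
    row_c = float(rng.uniform(0.40 * n, 0.60 * n))
    lo, hi = max_r + 0.08 * n, mid_col - max_r - 2.0
    if lo >= hi:
        raise ValueError("tumor does not fit inside one hemisphere")
    col_c = float(rng.uniform(max(lo, 0.22 * n), min(hi, 0.38 * n)))
    if spec.hemisphere == "right":
        col_c = n - 1 - col_c
    rr, cc = np.indices((n, n))
    dr = rr - row_c
    dc = cc - col_c
    theta = np.arctan2(dr, dc)
    radius = np.full_like(theta, spec.tumor_radius)
    if spec.irregularity > 0:
        for k in range(2, 6):
            amp = rng.uniform(-1.0, 1.0) * 0.45 * spec.irregularity / 4.0
            phase = rng.uniform(0, 2 * np.pi)
            radius = radius + spec.tumor_radius * amp * np.cos(k * theta + phase)
    mask = np.hypot(dr, dc) <= radius
    half = slice(0, n // 2) if spec.hemisphere == "left" else slice(n // 2, n)
    other = np.ones((n, n), dtype=bool)
    other[:, half] = False
    if (mask & other).any():
        raise ValueError("tumor crosses the midline")
    return mask


def generate_tumor_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric phantom plus a bright irregular blob; returns (image, mask).

    The blob sits strictly inside the chosen hemisphere at intensity
    tissue + tumor_contrast; the returned mask is the exact ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    img, head = _base_phantom(spec, rng)
    mask = _tumor_mask(spec, rng)
    img[mask] = TISSUE_VALUE + spec.tumor_contrast
    img = _apply_noise(img, head | mask, spec, rng)
    return img, mask


def generate_k_dataset(n: int, seed: int) -> list[KTrainingSample]:
    """Synthetic (TAR, TC) -> best-K samples for regressor recovery tests.

    TAR ~ U(0.01, 0.3), TC ~ U(0.1, 1.0),
    k = clip(round10(600 TAR + 120 TC + eps), 10, 450), eps ~ N(0, 10^2).
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    tar = rng.uniform(0.01, 0.3, n)
    tc = rng.uniform(0.1, 1.0, n)
    eps = rng.normal(0.0, 10.0, n)
    k_raw = 600.0 * tar + 120.0 * tc + eps
    k = np.clip(np.floor(k_raw / 10.0 + 0.5) * 10.0, 10, 450).astype(int)
    return [
        KTrainingSample(
            descriptor=TumorDescriptor(tar=float(t), tc=float(c), n_blocks=int(round(t * 256))),
            k_best=int(kb),
        )
        for t, c, kb in zip(tar, tc, k)
    ]
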