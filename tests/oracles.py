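"""Independent brute-force oracles shared by the unit and acceptance suites."""

import numpy as np

from gliopix.superpixel import (
    SLIC0_COMPACTNESS_FLOOR,
    SLIC0_INITIAL_COMPACTNESS,
    initialize_centers,
)


def oracle_iterations(image, K, iterations, fixed_C=None):
    """Per-pixel/per-center loop re-implementation of the clustering.

    Returns the label grid after each assignment sweep. ``fixed_C=None``
    runs the adaptive (SLIC0) compactness rule.
    """
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    S = np.sqrt(H * W / K)
    centers = initialize_centers(img, K)
    gray = [c.gray for c in centers]
    pos = [list(c.position) for c in centers]
    comp = [SLIC0_INITIAL_COMPACTNESS if fixed_C is None else fixed_C] * len(centers)
    history = []
    for it in range(iterations):
        labels = np.full((H, W), -1, dtype=int)
        for r in range(H):
            for c in range(W):
                best_d, best_k = np.inf, -1
                in_window = False
                for k in range(len(gray)):
                    dr, dc = r - pos[k][0], c - pos[k][1]
                    if abs(dr) <= S and abs(dc) <= S:
                        in_window = True
                        dcol = abs(img[r, c] - gray[k])
                        d = np.sqrt(dcol**2 + (dr**2 + dc**2) / S**2 * comp[k] ** 2)
                        if d < best_d:
                            best_d, best_k = d, k
                if not in_window:  # fallback: nearest center over all
                    for k in range(len(gray)):
                        dr, dc = r - pos[k][0], c - pos[k][1]
                        dcol = abs(img[r, c] - gray[k])
                        d = np.sqrt(dcol**2 + (dr**2 + dc**2) / S**2 * comp[k] ** 2)
                        if d < best_d:
                            best_d, best_k = d, k
                labels[r, c] = best_k
        history.append(labels.copy())
        maxdc = [0.0] * len(gray)
        sums = [[0.0, 0.0, 0.0, 0] for _ in gray]
        for r in range(H):
            for c in range(W):
                k = labels[r, c]
                maxdc[k] = max(maxdc[k], abs(img[r, c] - gray[k]))
                sums[k][0] += img[r, c]
                sums[k][1] += r
                sums[k][2] += c
                sums[k][3] += 1
        for k in range(len(gray)):
            if sums[k][3]:
                gray[k] = sums[k][0] / sums[k][3]
                pos[k] = [sums[k][1] / sums[k][3], sums[k][2] / sums[k][3]]
        if fixed_C is None:
            for k in range(len(gray)):
                comp[k] = (
                    max(SLIC0_COMPACTNESS_FLOOR, maxdc[k])
                    if it == 0
                    else max(comp[k], maxdc[k])
                )
    return history

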