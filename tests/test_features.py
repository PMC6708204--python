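"""The 69-dimensional superpixel descriptor: statistics, co-occurrence
textures, curvature and fractal measures."""

import numpy as np
import pytest
from scipy import ndimage

from gliopix.features import (
    BOX_SIZES,
    FEATURE_NAMES,
    HARALICK_NAMES,
    INTENSITY_NAMES,
    box_counting_dimension,
    cooccurrence_matrix,
    curvature_feature,
    curvature_map,
    extract_feature_table,
    fractal_features,
    haralick_features,
    intensity_statistics,
    otsu_channels,
    prewitt_curvature_map,
    quantize_gray,
    remove_background_superpixels,
    roberts_gradient_map,
)
from gliopix.superpixel import SuperpixelMap


def _stat(vec, name):
    return vec[INTENSITY_NAMES.index(name)]


# ---------------------------------------------------------------------------
# intensity statistics


def test_feature_name_bookkeeping():
    assert len(FEATURE_NAMES) == 69
    assert len(set(FEATURE_NAMES)) == 69
    assert len(INTENSITY_NAMES) == 17
    assert len(HARALICK_NAMES) == 13


def test_intensity_constant_input():
    v = intensity_statistics(np.array([5.0, 5.0, 5.0]))
    assert _stat(v, "std") == 0.0
    assert _stat(v, "entropy") == 0.0
    assert _stat(v, "uniformity") == 1.0
    assert _stat(v, "skewness") == 0.0
    assert _stat(v, "kurtosis") == 0.0
    assert _stat(v, "range") == 0.0


def test_intensity_hand_arithmetic():
    v = intensity_statistics(np.array([1.0, 2.0, 3.0, 4.0]))
    assert _stat(v, "mean") == pytest.approx(2.5)
    assert _stat(v, "median") == pytest.approx(2.5)
    assert _stat(v, "range") == pytest.approx(3.0)
    assert _stat(v, "minimum") == 1.0
    assert _stat(v, "maximum") == 4.0
    assert _stat(v, "energy") == pytest.approx(1 + 4 + 9 + 16)
    assert _stat(v, "rms") == pytest.approx(np.sqrt(30 / 4))
    assert _stat(v, "variance") == pytest.approx(_stat(v, "std") ** 2)


def test_intensity_normal_moments(rng):
    x = rng.normal(50.0, 10.0, 1000)
    v = intensity_statistics(x)
    assert abs(_stat(v, "skewness")) < 0.25
    assert abs(_stat(v, "kurtosis") - 3.0) < 0.5
    assert _stat(v, "mean") == pytest.approx(50.0, abs=1.5)


def test_intensity_rejects_empty():
    with pytest.raises(ValueError):
        intensity_statistics(np.array([]))


# ---------------------------------------------------------------------------
# quantization and co-occurrence


def test_quantize_identity_binning():
    img = np.arange(64, dtype=float).reshape(8, 8)
    q = quantize_gray(img, 64)
    np.testing.assert_array_equal(q, np.arange(64).reshape(8, 8))


def test_quantize_constant_region():
    q = quantize_gray(np.full((4, 4), 7.0), 8)
    assert np.all(q == 0)


def test_quantize_binning_oracle(rng):
    img = rng.uniform(10, 500, (12, 12))
    mask = rng.random((12, 12)) < 0.7
    levels = 16
    q = quantize_gray(img, levels, mask)
    lo, hi = img[mask].min(), img[mask].max()
    width = (hi - lo) / levels
    for r, c in np.argwhere(mask):
        expected = min(int((img[r, c] - lo) / width), levels - 1)
        assert q[r, c] == expected
    assert np.all(q[~mask] == -1)


def test_cooccurrence_single_pair():
    q = np.full((3, 4), -1, dtype=int)
    q[1, 1], q[1, 2] = 0, 1
    m = cooccurrence_matrix(q, direction=0, levels=2)
    p = m.normalized()
    assert p[0, 1] == pytest.approx(0.5)
    assert p[1, 0] == pytest.approx(0.5)
    assert p.sum() == pytest.approx(1.0)


def test_cooccurrence_constant_region():
    q = np.zeros((5, 5), dtype=int)
    m = cooccurrence_matrix(q, direction=90, levels=4)
    p = m.normalized()
    assert p[0, 0] == pytest.approx(1.0)


def test_cooccurrence_empty_region_flagged():
    q = np.full((5, 5), -1, dtype=int)
    q[2, 2] = 1  # no neighbour inside the region in any direction
    m = cooccurrence_matrix(q, direction=0, levels=4)
    assert m.empty
    assert np.all(haralick_features(m) == 0.0)


@pytest.mark.parametrize("direction,offset", [(0, (0, 1)), (45, (-1, 1)), (90, (-1, 0)), (135, (-1, -1))])
def test_cooccurrence_matches_brute_force(rng, direction, offset):
    levels = 8
    q = rng.integers(0, levels, (8, 8))
    hole = rng.random((8, 8)) < 0.2
    q[hole] = -1
    expected = np.zeros((levels, levels))
    dr, dc = offset
    for r in range(8):
        for c in range(8):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < 8 and 0 <= c2 < 8 and q[r, c] >= 0 and q[r2, c2] >= 0:
                expected[q[r, c], q[r2, c2]] += 1
                expected[q[r2, c2], q[r, c]] += 1
    m = cooccurrence_matrix(q, direction=direction, levels=levels)
    np.testing.assert_array_equal(m.counts, expected)


# ---------------------------------------------------------------------------
# Haralick


def test_haralick_deterministic_texture():
    p = np.zeros((4, 4))
    p[0, 0] = 1.0
    v = haralick_features(p)
    named = dict(zip(HARALICK_NAMES, v))
    assert named["asm"] == pytest.approx(1.0)
    assert named["entropy"] == pytest.approx(0.0, abs=1e-9)
    assert named["contrast"] == pytest.approx(0.0)


def test_haralick_uniform_2x2_hand_values():
    p = np.full((2, 2), 0.25)
    named = dict(zip(HARALICK_NAMES, haralick_features(p)))
    assert named["asm"] == pytest.approx(0.25)
    assert named["entropy"] == pytest.approx(2.0, abs=1e-6)  # bits
    assert named["correlation"] == pytest.approx(0.0)
    assert named["idm"] == pytest.approx(0.25 + 0.25 + 0.5 / 2)


@pytest.mark.parametrize("L", [2, 4])
def test_haralick_entropy_maximal_for_uniform(rng, L):
    uniform = np.full((L, L), 1.0 / L**2)
    h_uniform = dict(zip(HARALICK_NAMES, haralick_features(uniform)))["entropy"]
    for _ in range(10):
        m = rng.random((L, L))
        m = (m + m.T) / 2
        m /= m.sum()
        h = dict(zip(HARALICK_NAMES, haralick_features(m)))["entropy"]
        assert h <= h_uniform + 1e-9


def test_haralick_bounds(rng):
    m = rng.random((8, 8))
    m = (m + m.T) / 2
    m /= m.sum()
    named = dict(zip(HARALICK_NAMES, haralick_features(m)))
    assert named["contrast"] >= 0
    assert 0 < named["asm"] <= 1


# ---------------------------------------------------------------------------
# gradient / curvature maps


def test_roberts_constant_zero():
    assert np.all(roberts_gradient_map(np.full((6, 6), 9.0)) == 0.0)


def test_roberts_matches_kernel_convolution(rng):
    img = rng.uniform(0, 50, (5, 5))
    got = roberts_gradient_map(img)
    pad = np.pad(img, ((0, 1), (0, 1)), mode="edge")
    for r in range(5):
        for c in range(5):
            g1 = pad[r, c] - pad[r + 1, c + 1]
            g2 = pad[r, c + 1] - pad[r + 1, c]
            assert got[r, c] == pytest.approx(np.hypot(g1, g2))


def test_roberts_step_edge_local():
    img = np.zeros((8, 8))
    img[:, 4:] = 10.0
    g = roberts_gradient_map(img)
    assert np.all(g[:, [0, 1, 2]] == 0)
    assert np.all(g[:, 3] > 0)


def test_prewitt_constant_zero():
    assert np.all(prewitt_curvature_map(np.full((6, 6), 3.0)) == 0.0)


def test_prewitt_vertical_ramp_interior():
    rr = np.tile(np.arange(10.0)[:, None], (1, 10))
    g = prewitt_curvature_map(rr)
    assert np.allclose(g[1:-1, 1:-1], 6.0)


def test_prewitt_matches_kernel_convolution(rng):
    img = rng.uniform(0, 50, (5, 5))
    kx = np.array([[-1.0, 0.0, 1.0]] * 3)
    ky = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -1.0, -1.0]])
    gx = ndimage.convolve(img, kx, mode="nearest")
    gy = ndimage.convolve(img, ky, mode="nearest")
    np.testing.assert_allclose(prewitt_curvature_map(img), np.hypot(gx, gy))


def test_curvature_zero_on_ramp_and_constant():
    rr, cc = np.indices((10, 10)).astype(float)
    assert curvature_feature(3 * rr + 2 * cc, np.ones((10, 10), dtype=bool)) == pytest.approx(0.0)
    assert curvature_feature(np.full((10, 10), 4.0), np.ones((10, 10), dtype=bool)) == 0.0


def test_curvature_matches_finite_difference_oracle():
    rr, cc = np.indices((20, 20)).astype(float)
    img = (rr - 10.0) ** 2 + (cc - 10.0) ** 2
    got = curvature_map(img)
    f_y, f_x = np.gradient(img)
    f_xx = np.gradient(f_x, axis=1)
    f_yy = np.gradient(f_y, axis=0)
    for r in range(3, 17):
        for c in range(3, 17):
            g2 = f_x[r, c] ** 2 + f_y[r, c] ** 2
            if g2 < 1e-8:
                assert got[r, c] == 0.0
                continue
            num = (
                f_xx[r, c] * f_y[r, c] ** 2
                + f_yy[r, c] * f_x[r, c] ** 2
                - 2 * f_xx[r, c] * f_x[r, c] * f_y[r, c]
            )
            assert got[r, c] == pytest.approx(num / g2**1.5)


# ---------------------------------------------------------------------------
# fractal channels


def test_otsu_recovers_four_plateaus():
    vals = np.repeat([10.0, 100.0, 1000.0, 3000.0], 256)
    img = vals.reshape(32, 32)
    ch = otsu_channels(img)
    assert not ch.degenerate
    for k, v in enumerate([10.0, 100.0, 1000.0, 3000.0]):
        np.testing.assert_array_equal(ch.masks[k], img == v)


def test_otsu_constant_image_degenerate():
    ch = otsu_channels(np.full((32, 32), 500.0))
    assert ch.degenerate
    out = fractal_features(np.full((32, 32), 500.0), np.ones((32, 32), dtype=bool), ch)
    assert np.all(out == 0.0)


def test_otsu_channels_partition_foreground(rng):
    img = rng.uniform(0, 4000, (64, 64))
    img[:8] = 0.0  # background strip
    ch = otsu_channels(img)
    fg = img >= 5.0
    union = np.zeros_like(fg)
    for k in range(4):
        for k2 in range(k + 1, 4):
            assert not (ch.masks[k] & ch.masks[k2]).any()
        union |= ch.masks[k]
    np.testing.assert_array_equal(union, fg)


def test_box_counting_dimension_cases():
    assert box_counting_dimension(np.zeros((64, 64), dtype=bool)) == 0.0
    line = np.zeros((64, 64), dtype=bool)
    line[32, :] = True
    assert box_counting_dimension(line) == pytest.approx(1.0, abs=0.15)
    assert box_counting_dimension(np.ones((64, 64), dtype=bool)) == pytest.approx(2.0, abs=0.15)


def test_box_counts_match_direct_enumeration(rng):
    m = rng.random((40, 40)) < 0.1
    if not m.any():
        pytest.skip("empty draw")
    # recompute counts per size by explicit box enumeration, refit slope
    counts = []
    for s in BOX_SIZES:
        n = 0
        for r0 in range(0, 40, s):
            for c0 in range(0, 40, s):
                if m[r0 : r0 + s, c0 : c0 + s].any():
                    n += 1
        counts.append(n)
    slope = np.polyfit(np.log(1.0 / np.array(BOX_SIZES)), np.log(counts), 1)[0]
    assert box_counting_dimension(m) == pytest.approx(slope)


def test_fractal_features_disjoint_region():
    img = np.repeat([10.0, 100.0, 1000.0, 3000.0], 256).reshape(32, 32)
    ch = otsu_channels(img)
    region = np.zeros((32, 32), dtype=bool)
    region[0:4, 0:4] = True  # inside the 10.0 plateau
    out = fractal_features(img, region, ch)
    assert out[0] == 16  # channel 0 area
    assert out[1] == pytest.approx(10.0)  # channel 0 brightness
    assert np.all(out[3::3] == 0.0)  # other channels empty
    assert np.all(out[4::3] == 0.0)


def test_fractal_areas_partition_region(rng):
    img = rng.uniform(100, 4000, (64, 64))
    ch = otsu_channels(img)
    region = rng.random((64, 64)) < 0.5
    out = fractal_features(img, region, ch)
    assert out[0::3].sum() == region.sum()  # everything is foreground here


# ---------------------------------------------------------------------------
# table assembly


def _quadrant_map():
    labels = np.zeros((32, 32), dtype=int)
    labels[:16, 16:] = 1
    labels[16:, :16] = 2
    labels[16:, 16:] = 3
    return SuperpixelMap(labels=labels, count=4)


def test_feature_table_shape_and_names(rng):
    img = rng.uniform(0, 4000, (32, 32))
    table = extract_feature_table(img, _quadrant_map())
    assert table.shape == (4, 69)
    assert list(table.columns) == list(FEATURE_NAMES)
    assert np.isfinite(table.to_numpy()).all()


def test_constant_superpixel_degenerate_features():
    img = np.full((32, 32), 100.0)
    img[:16, :16] = 600.0  # one non-constant superpixel boundary region
    table = extract_feature_table(img, _quadrant_map())
    row = table.loc[3]  # fully constant quadrant
    assert row["int_std"] == 0.0
    assert row["glcm_entropy"] == pytest.approx(0.0, abs=1e-6)
    assert row["curvature"] == 0.0


def test_identical_superpixels_identical_vectors(rng):
    """Two superpixels with equal pixel content, shape and local context
    give equal feature rows (the texture maps see a border of neighbouring
    pixels, so the surroundings must match too)."""
    block = rng.uniform(100, 2000, (16, 16))
    img = np.full((44, 44), 50.0)
    img[4:20, 4:20] = block
    img[24:40, 24:40] = block
    labels = np.zeros((44, 44), dtype=int)
    labels[4:20, 4:20] = 1
    labels[24:40, 24:40] = 2
    labels[22:, :22] = 3
    sp = SuperpixelMap(labels=labels, count=4)
    table = extract_feature_table(img, sp)
    np.testing.assert_allclose(table.loc[1].to_numpy(), table.loc[2].to_numpy())


def test_features_invariant_to_relabeling(rng):
    img = rng.uniform(0, 4000, (32, 32))
    sp = _quadrant_map()
    perm = np.array([2, 0, 3, 1])
    sp2 = SuperpixelMap(labels=perm[sp.labels], count=4)
    t1 = extract_feature_table(img, sp)
    t2 = extract_feature_table(img, sp2)
    for sid in range(4):
        np.testing.assert_allclose(t1.loc[sid].to_numpy(), t2.loc[perm[sid]].to_numpy())


def test_remove_background_boundary_rule():
    labels = np.zeros((32, 32), dtype=int)
    labels[:, 16:] = 1
    sp = SuperpixelMap(labels=labels, count=2)
    img = np.zeros((32, 32))
    img[:, :16] = 4.9
    img[:, 16:] = 5.0
    retained = remove_background_superpixels(img, sp)
    assert list(retained) == [1]


def test_remove_background_phantom_head(tumor_phantom):
    from gliopix.superpixel import run_slic0

    img, _ = tumor_phantom
    sp = run_slic0(img, 100)
    retained = remove_background_superpixels(img, sp)
    head = img >= 5.0
    frac_inside = [
        head[sp.labels == sid].mean() for sid in range(sp.count)
    ]
    for sid in range(sp.count):
        if frac_inside[sid] > 0.9:
            assert sid in retained
        if frac_inside[sid] < 0.05:
            assert sid not in retained
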