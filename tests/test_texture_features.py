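"""GLCM construction and statistics against two independent oracles: a
brute-force pair-enumeration implementation written here, and
scikit-image's co-occurrence routines."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vegtexture.spectral_layers import build_layers
from vegtexture.texture_features import (ALL_STATS, DIRECTION_OFFSETS,
                                         DIRECTIONS, FEATURE_COLUMNS,
                                         GLCM_STATS, MaskedWindowError,
                                         extract_features, first_order, glcm,
                                         glcm_stats, quantize,
                                         window_features)

windows = arrays(np.int64, (7, 7), elements=st.integers(0, 63))


def brute_glcm(window, direction, levels=64):
    """Independent oracle: enumerate every pixel pair at the offset."""
    dr, dc = DIRECTION_OFFSETS[direction]
    h, w = window.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[window[r, c], window[r2, c2]] += 1
                counts[window[r2, c2], window[r, c]] += 1
    return counts / counts.sum()


def brute_stats(p):
    """Independent oracle: direct double-loop over matrix cells."""
    L = p.shape[0]
    mu = sum(i * p[i, j] for i in range(L) for j in range(L))
    var = sum((i - mu) ** 2 * p[i, j] for i in range(L) for j in range(L))
    out = {
        "MEAN": mu, "VAR": var,
        "CONT": sum(p[i, j] * (i - j) ** 2 for i in range(L) for j in range(L)),
        "DISS": sum(p[i, j] * abs(i - j) for i in range(L) for j in range(L)),
        "HOM": sum(p[i, j] / (1 + (i - j) ** 2)
                   for i in range(L) for j in range(L)),
        "ASM": sum(p[i, j] ** 2 for i in range(L) for j in range(L)),
        "ENT": -sum(p[i, j] * np.log(p[i, j])
                    for i in range(L) for j in range(L) if p[i, j] > 0),
    }
    out["CORR"] = (sum(p[i, j] * (i - mu) * (j - mu)
                       for i in range(L) for j in range(L)) / var
                   if var > 0 else np.nan)
    return out


# --- quantization -----------------------------------------------------------


def test_quantize_constant_layer_maps_to_zero():
    assert (quantize(np.full((4, 4), 0.7)) == 0).all()


def test_quantize_endpoints(rng):
    layer = rng.uniform(0, 1, (10, 10))
    q = quantize(layer)
    assert q[np.unravel_index(layer.argmin(), layer.shape)] == 0
    assert q[np.unravel_index(layer.argmax(), layer.shape)] == 63
    assert q.min() >= 0 and q.max() <= 63


def test_quantize_ramp_of_64_values_hits_each_level_once():
    ramp = np.linspace(0.2, 0.8, 64).reshape(8, 8)
    q = quantize(ramp)
    np.testing.assert_array_equal(np.sort(q.ravel()), np.arange(64))
    assert (np.diff(q.ravel()) > 0).all()  # order preserved


def test_quantize_all_masked_raises():
    with pytest.raises(ValueError):
        quantize(np.full((3, 3), np.nan))


# --- first order ------------------------------------------------------------


def test_first_order_degenerate_and_symmetric():
    assert first_order(np.full((5, 5), 2.0)) == (0.0, 0.0)
    dr, sk = first_order(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]))
    assert dr == 4.0 and sk == pytest.approx(0.0, abs=1e-12)


def test_first_order_moment_oracle():
    v = np.array([1.0, 2.0, 10.0])
    d = v - v.mean()
    expected = (d ** 3).mean() / (d ** 2).mean() ** 1.5
    dr, sk = first_order(v.reshape(1, 3))
    assert dr == 9.0
    assert sk == pytest.approx(expected, rel=1e-12)


def test_first_order_rejects_masked_window():
    with pytest.raises(MaskedWindowError):
        first_order(np.array([[1.0, np.nan]]))


# --- GLCM construction ------------------------------------------------------


def test_constant_window_glcm_is_single_cell():
    p = glcm(np.full((5, 5), 7, dtype=int), 0)
    assert p[7, 7] == 1.0 and p.sum() == 1.0


def test_two_pixel_window_symmetric_counts():
    p = glcm(np.array([[0, 1]]), 0)
    assert p[0, 1] == 0.5 and p[1, 0] == 0.5


def test_window_too_small_for_direction_raises():
    with pytest.raises(ValueError):
        glcm(np.array([[0, 1]]), 90)  # vertical pairs need 2 rows


@given(windows)
def test_glcm_normalized_and_symmetric(win):
    for d in DIRECTIONS:
        p = glcm(win, d)
        assert abs(p.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(p, p.T, atol=0)
        assert (p >= 0).all()


@given(windows)
def test_glcm_matches_brute_force_enumeration(win):
    for d in DIRECTIONS:
        np.testing.assert_allclose(glcm(win, d), brute_glcm(win, d), atol=1e-14)


# --- GLCM statistics --------------------------------------------------------


def test_constant_window_statistics():
    s = glcm_stats(glcm(np.full((5, 5), 3, dtype=int), 0))
    assert s["CONT"] == 0 and s["DISS"] == 0
    assert s["HOM"] == 1.0 and s["ASM"] == 1.0 and s["ENT"] == 0.0
    assert np.isnan(s["CORR"])


def test_checkerboard_contrast_dissimilarity_homogeneity():
    i, j = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
    board = np.where((i + j) % 2 == 0, 0, 63)
    s = glcm_stats(glcm(board, 0))
    assert s["CONT"] == pytest.approx(63 ** 2)
    assert s["DISS"] == pytest.approx(63)
    assert s["HOM"] == pytest.approx(1 / (1 + 63 ** 2))


def test_uniform_glcm_entropy_and_asm():
    for k in (2, 5, 8):
        p = np.full((k, k), 1.0 / k ** 2)
        s = glcm_stats(p)
        assert s["ENT"] == pytest.approx(np.log(k ** 2), rel=1e-12)
        assert s["ASM"] == pytest.approx(1.0 / k ** 2, rel=1e-12)


@given(windows)
def test_statistics_match_brute_force(win):
    p = glcm(win, 45)
    s = glcm_stats(p)
    expected = brute_stats(p)
    for name in GLCM_STATS:
        if np.isnan(expected[name]):
            assert np.isnan(s[name])
        else:
            assert s[name] == pytest.approx(expected[name], abs=1e-10)


@given(windows)
def test_entropy_asm_extremes_coincide(win):
    s = glcm_stats(glcm(win, 0))
    single_cell = (glcm(win, 0) > 0).sum() == 1
    assert (s["ENT"] == 0) == (s["ASM"] == 1.0) == single_cell


@given(windows)
def test_dissimilarity_cauchy_schwarz_bound(win):
    s = glcm_stats(glcm(win, 135))
    assert s["DISS"] <= np.sqrt(s["CONT"]) + 1e-12


def test_reference_implementation_equivalence(rng):
    """All statistics agree with scikit-image's GLCM on random windows."""
    graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
    from skimage.feature import graycoprops

    # scikit-image measures angles with the row offset pointing down;
    # under symmetric accumulation its pi/4 equals our 135-degree offset
    angle = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
    prop = {"CONT": "contrast", "DISS": "dissimilarity", "HOM": "homogeneity",
            "ASM": "ASM", "CORR": "correlation", "MEAN": "mean",
            "VAR": "variance", "ENT": "entropy"}
    for _ in range(10):
        win = rng.integers(0, 64, (15, 15))
        for d in DIRECTIONS:
            ref = graycomatrix(win.astype(np.uint8), [1], [angle[d]],
                               levels=64, symmetric=True, normed=True)
            ours = glcm(win, d)
            np.testing.assert_allclose(ours, ref[:, :, 0, 0], atol=1e-12)
            s = glcm_stats(ours)
            for name, sk_name in prop.items():
                expected = float(graycoprops(ref, sk_name)[0, 0])
                assert s[name] == pytest.approx(expected, abs=1e-8), name


# --- window/plot extraction -------------------------------------------------


def test_extract_produces_forty_named_features(scene, features):
    assert len(FEATURE_COLUMNS) == 40
    assert list(features.columns) == ["plot_id", *FEATURE_COLUMNS]
    assert len(features) == len(scene.plot_registry)
    assert features[FEATURE_COLUMNS].notna().all().all()


def test_feature_ranges(features):
    for layer in ("RED", "IR", "NDVI", "EVI"):
        assert (features[f"{layer}_ENT"] >= 0).all()
        assert features[f"{layer}_ASM"].between(0, 1, inclusive="right").all()
        assert features[f"{layer}_HOM"].between(0, 1, inclusive="right").all()
        for stat in ("CONT", "DISS", "VAR"):
            assert (features[f"{layer}_{stat}"] >= 0).all()


def test_direction_averaged_features_invariant_to_180_rotation(rng):
    raw = rng.uniform(0, 1, (15, 15))
    q = quantize(raw)
    a = window_features(raw, q)
    b = window_features(raw[::-1, ::-1].copy(), q[::-1, ::-1].copy())
    for name in ALL_STATS:
        if name == "SKEW":
            assert b[name] == pytest.approx(a[name], rel=1e-9)
        else:
            assert b[name] == pytest.approx(a[name], abs=1e-10)


def test_glcm_features_invariant_to_positive_scaling(scene):
    """Global min-max quantization absorbs any positive gain, so the EVI
    gain convention cannot affect GLCM features."""
    stack = build_layers(scene.bands)
    plots = scene.plot_registry
    base = extract_features(stack, plots)
    scaled_bands = dict(scene.bands)
    stack2 = build_layers(scaled_bands)
    stack2.layers["EVI"] = stack2.layers["EVI"] * 3.7
    scaled = extract_features(stack2, plots)
    for stat in GLCM_STATS:
        np.testing.assert_allclose(scaled[f"EVI_{stat}"], base[f"EVI_{stat}"],
                                   atol=1e-10)


def test_edge_plots_are_skipped_with_warning(scene):
    import pandas as pd

    stack = build_layers(scene.bands)
    plots = pd.DataFrame([{"plot_id": "EDGE", "row": 2, "col": 2, "age": 5}])
    with pytest.warns(UserWarning, match="edge"):
        out = extract_features(stack, plots)
    assert len(out) == 0
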