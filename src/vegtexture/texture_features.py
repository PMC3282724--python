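"""First-order and GLCM texture features over moving windows.

Ten statistics per layer: the first-order data range (DR) and skewness
(SKEW) on the raw layer values, and eight gray-level co-occurrence matrix
(GLCM) statistics (MEAN, VAR, CORR, CONT, DISS, HOM, ASM, ENT) computed on
the 64-level quantized layer at pixel distance 1 and averaged over the four
directions 0/45/90/135 degrees.  Over the four layers this yields the 40
texture variables the regression stage consumes.

Conventions (the literature varies): quantization stretches the *global*
per-layer min-max to the gray levels, so features are comparable across
plot windows; GLCMs are accumulated symmetrically (each pixel pair counted
in both orders); entropy is in nats.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .spectral_layers import LAYER_NAMES, LayerStack

GLCM_STATS = ("MEAN", "VAR", "CORR", "CONT", "DISS", "HOM", "ASM", "ENT")
FIRST_ORDER_STATS = ("DR", "SKEW")
ALL_STATS = FIRST_ORDER_STATS + GLCM_STATS

#: row/col offset per direction (row axis increases downward)
DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
DIRECTIONS = tuple(DIRECTION_OFFSETS)

FEATURE_COLUMNS = [f"{layer}_{stat}" for layer in LAYER_NAMES for stat in ALL_STATS]


class MaskedWindowError(ValueError):
    """A plot window touches masked pixels or the image edge."""


def quantize(layer, levels: int = 64) -> np.ndarray:
    """Map a layer's global min-max linearly onto gray levels 0..levels-1.

    The maximum maps to levels-1 (not levels); a constant layer maps to
    level 0 everywhere.  Masked pixels keep a sentinel of -1.
    """
    a = np.ma.masked_invalid(layer)
    if np.ma.getmaskarray(a).all():
        raise ValueError("cannot quantize: all pixels are masked")
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        q = np.zeros(a.shape, dtype=np.int64)
    else:
        q = np.floor((a - lo) / (hi - lo) * levels).astype(np.int64)
        q = np.minimum(q, levels - 1)
    return np.ma.filled(q, -1)


def first_order(window) -> tuple[float, float]:
    """(data range, Fisher-Pearson skewness g1) of the raw window values.

    g1 = m3 / m2^(3/2) with population moments; defined as 0 when the
    window is constant (m2 = 0).
    """
    w = np.ma.masked_invalid(window)
    if np.ma.getmaskarray(w).any():
        raise MaskedWindowError("window contains masked pixels")
    v = np.asarray(w, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty window")
    dr = float(v.max() - v.min())
    d = v - v.mean()
    m2 = float((d ** 2).mean())
    skew = 0.0 if m2 == 0 else float((d ** 3).mean() / m2 ** 1.5)
    return dr, skew


def glcm(window: np.ndarray, direction: int, distance: int = 1,
         levels: int = 64) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix of a quantized window."""
    q = np.asarray(window, dtype=np.int64)
    if (q < 0).any() or (q >= levels).any():
        raise ValueError(f"window values must lie in 0..{levels - 1}")
    dr, dc = DIRECTION_OFFSETS[direction]
    dr, dc = dr * distance, dc * distance
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("window too small for any pixel pair in this direction")
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.zeros((levels, levels))
    np.add.at(counts, (a, b), 1.0)
    np.add.at(counts, (b, a), 1.0)  # symmetric accumulation
    return counts / counts.sum()


def glcm_stats(p: np.ndarray) -> dict[str, float]:
    """The eight Haralick-style statistics of a normalized symmetric GLCM.

    CORR is undefined (NaN) for a zero-variance matrix, e.g. from a
    constant window.
    """
    levels = p.shape[0]
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)  # row marginal (= column marginal by symmetry)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    diff = ii - jj
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = float((p * (ii - mu) * (jj - mu)).sum() / var) if var > 0 else np.nan
    pos = p > 0
    return {
        "MEAN": mu,
        "VAR": var,
        "CORR": corr,
        "CONT": float((p * diff ** 2).sum()),
        "DISS": float((p * np.abs(diff)).sum()),
        "HOM": float((p / (1.0 + diff ** 2)).sum()),
        "ASM": float((p ** 2).sum()),
        "ENT": float(-(p[pos] * np.log(p[pos])).sum()),
    }


def window_features(raw_window, quantized_window, distance: int = 1,
                    levels: int = 64) -> dict[str, float]:
    """All ten statistics for one window: first-order on raw values, GLCM
    statistics averaged over the four directions."""
    dr, skew = first_order(raw_window)
    feats = {"DR": dr, "SKEW": skew}
    per_dir = [glcm_stats(glcm(quantized_window, d, distance, levels))
               for d in DIRECTIONS]
    for stat in GLCM_STATS:
        feats[stat] = float(np.mean([s[stat] for s in per_dir]))
    return feats


def extract_features(stack: LayerStack, plots: pd.DataFrame, window: int = 15,
                     levels: int = 64, distance: int = 1) -> pd.DataFrame:
    """Texture feature table: one row per plot, 40 named feature columns.

    Windows are ``window x window`` squares centered on each plot's
    (row, col).  Plots whose window crosses the image edge or touches a
    masked pixel are skipped with a warning.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be odd and >= 3")
    half = window // 2
    h, w = stack.shape
    quantized = {name: quantize(stack[name], levels) for name in LAYER_NAMES}

    rows = []
    for rec in plots.itertuples(index=False):
        r, c = int(rec.row), int(rec.col)
        if not (half <= r < h - half and half <= c < w - half):
            warnings.warn(f"plot {rec.plot_id}: window crosses the image edge; "
                          "skipped")
            continue
        sl = np.s_[r - half:r + half + 1, c - half:c + half + 1]
        try:
            feats = {"plot_id": rec.plot_id}
            for name in LAYER_NAMES:
                qwin = quantized[name][sl]
                if (qwin < 0).any():
                    raise MaskedWindowError(
                        f"plot {rec.plot_id}: masked pixels in {name} window")
                for stat, val in window_features(
                        stack[name][sl], qwin, distance, levels).items():
                    feats[f"{name}_{stat}"] = val
            rows.append(feats)
        except MaskedWindowError as err:
            warnings.warn(str(err) + "; plot skipped")
    return pd.DataFrame(rows, columns=["plot_id", *FEATURE_COLUMNS])
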