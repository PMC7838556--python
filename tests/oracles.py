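"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths they check: morphology is the
set-theoretic shift definition, the stopping rule is a direct transcription
of its statement, multi-level Otsu is an exhaustive search, the chi-square
statistic is the textbook O/E formula, and the odds ratio of a 2x2 table is
the cross-product ratio.
"""

from __future__ import annotations

import itertools

import numpy as np


def shift_dilate(mask: np.ndarray, footprint: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    """Dilation as a union of shifted masks (exhaustive over SE cells)."""
    h, w = mask.shape
    out = np.zeros((h, w), dtype=bool)
    oy, ox = origin
    for i in range(footprint.shape[0]):
        for j in range(footprint.shape[1]):
            if not footprint[i, j]:
                continue
            dy, dx = i - oy, j - ox
            src = mask[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)]
            out[max(0, dy) : h - max(0, -dy), max(0, dx) : w - max(0, -dx)] |= src
    return out


def shift_erode(mask: np.ndarray, footprint: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    """Erosion as an intersection of shifted masks, outside-image = false."""
    h, w = mask.shape
    out = np.ones((h, w), dtype=bool)
    oy, ox = origin
    for i in range(footprint.shape[0]):
        for j in range(footprint.shape[1]):
            if not footprint[i, j]:
                continue
            dy, dx = i - oy, j - ox
            shifted = np.zeros((h, w), dtype=bool)
            src = mask[max(0, dy) : h + min(0, dy), max(0, dx) : w + min(0, dx)]
            shifted[max(0, -dy) : h + min(0, -dy), max(0, -dx) : w + min(0, -dx)] = src
            out &= shifted
    return out


def pixelwise_dilate(mask: np.ndarray, footprint: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    """Fully scalar double-loop dilation (slow; tiny inputs only)."""
    h, w = mask.shape
    oy, ox = origin
    out = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            for i in range(footprint.shape[0]):
                for j in range(footprint.shape[1]):
                    yy, xx = y - (i - oy), x - (j - ox)
                    if footprint[i, j] and 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                        out[y, x] = True
    return out


def pixelwise_erode(mask: np.ndarray, footprint: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    """Fully scalar double-loop erosion (slow; tiny inputs only)."""
    h, w = mask.shape
    oy, ox = origin
    out = np.ones((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            for i in range(footprint.shape[0]):
                for j in range(footprint.shape[1]):
                    if not footprint[i, j]:
                        continue
                    yy, xx = y + (i - oy), x + (j - ox)
                    if not (0 <= yy < h and 0 <= xx < w and mask[yy, xx]):
                        out[y, x] = False
    return out


def reference_stop_epoch(values: list[float], patience: int, min_gain: float) -> int:
    """The stopping rule, transcribed directly from its statement."""
    best, best_e = -1.0, 0
    for e, v in enumerate(values, start=1):
        if v > best and (best <= 0 or (v - best) / best >= min_gain):
            best, best_e = v, e
        if e - best_e >= patience:
            return e
    return len(values)


def exhaustive_multiotsu_thresholds(gray: np.ndarray, classes: int = 3) -> tuple[int, ...]:
    """Maximize between-class variance over all threshold tuples (256 bins)."""
    hist, _ = np.histogram(gray.ravel(), bins=256, range=(0, 256))
    p = hist / hist.sum()
    levels = np.arange(256)
    best, best_t = -1.0, None
    for cuts in itertools.combinations(range(1, 256), classes - 1):
        bounds = (0,) + cuts + (256,)
        var = 0.0
        ok = True
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            w = p[lo:hi].sum()
            if w == 0:
                ok = False
                break
            mu = (p[lo:hi] * levels[lo:hi]).sum() / w
            var += w * mu * mu
        if ok and var > best:
            best, best_t = var, cuts
    return best_t


def chi_square_statistic(table: np.ndarray) -> float:
    """Pearson chi-square, sum (O - E)^2 / E, no continuity correction."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def cross_product_or(a: int, b: int, c: int, d: int) -> float:
    """Odds ratio of the 2x2 table [[a, b], [c, d]] = (a*d)/(b*c)."""
    return (a * d) / (b * c)


def trapezoid_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by trapezoidal integration of the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    thresholds = np.unique(scores)[::-1]
    m, n = labels.sum(), (~labels).sum()
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = scores >= t
        tpr.append((pred & labels).sum() / m)
        fpr.append((pred & ~labels).sum() / n)
    return float(np.trapezoid(tpr, fpr))
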