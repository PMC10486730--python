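"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit Python loops, textbook
formulas) and shares no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def brute_glcm(quantized, mask, levels, direction, distance=1, symmetric=True, normalize=True):
    """Exhaustive pair enumeration over all pixel positions."""
    q = np.asarray(quantized)
    mask = np.asarray(mask, dtype=bool)
    rows, cols = q.shape
    counts = np.zeros((levels, levels), dtype=float)
    for r in range(rows):
        for c in range(cols):
            if direction == "H":
                r2, c2 = r, c + distance
            else:
                r2, c2 = r + distance, c
            if r2 >= rows or c2 >= cols:
                continue
            if mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1.0
                if symmetric:
                    counts[q[r2, c2], q[r, c]] += 1.0
    total = counts.sum()
    if normalize and total > 0:
        counts = counts / total
    return counts


def brute_glcm_stats(p):
    """Double-loop evaluation of the five co-occurrence statistics."""
    p = np.asarray(p, dtype=float)
    levels = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(levels) for j in range(levels))
    mu_j = sum(j * p[i, j] for i in range(levels) for j in range(levels))
    sig_i = math.sqrt(
        sum((i - mu_i) ** 2 * p[i, j] for i in range(levels) for j in range(levels))
    )
    sig_j = math.sqrt(
        sum((j - mu_j) ** 2 * p[i, j] for i in range(levels) for j in range(levels))
    )
    contrast = sum(
        p[i, j] * (i - j) ** 2 for i in range(levels) for j in range(levels)
    )
    if sig_i * sig_j == 0:
        correlation = 0.0
    else:
        correlation = sum(
            p[i, j] * (i - mu_i) * (j - mu_j)
            for i in range(levels)
            for j in range(levels)
        ) / (sig_i * sig_j)
    energy = sum(p[i, j] ** 2 for i in range(levels) for j in range(levels))
    homogeneity = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(levels) for j in range(levels)
    )
    variance = sum(
        p[i, j] * (i - mu_i) ** 2 for i in range(levels) for j in range(levels)
    )
    return contrast, correlation, energy, homogeneity, variance


def brute_quantize(values, levels):
    """Per-pixel min-max binning formula, evaluated one value at a time."""
    vals = np.asarray(values, dtype=float)
    lo, hi = vals.min(), vals.max()
    out = []
    for v in vals.ravel():
        if hi == lo:
            out.append(0)
        else:
            out.append(min(int(math.floor((v - lo) / (hi - lo) * levels)), levels - 1))
    return np.array(out).reshape(vals.shape)


def pearson_hand(x, y):
    """Textbook Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def single_feature_t_test(x, y):
    """Closed-form slope t-test for y = a + b x, returning (b, se, t, p)."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xm = x - x.mean()
    b = float((xm * (y - y.mean())).sum() / (xm**2).sum())
    a = float(y.mean() - b * x.mean())
    resid = y - a - b * x
    s2 = float((resid**2).sum()) / (n - 2)
    se = math.sqrt(s2 / (xm**2).sum())
    t = b / se
    p = 2 * t_dist.sf(abs(t), n - 2)
    return b, se, t, float(p)
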