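"""Independent brute-force reference implementations used as test oracles.

Every function here recomputes a quantity with explicit loops and textbook
definitions, deliberately sharing no code with the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def std_scores_loops(values: np.ndarray) -> np.ndarray:
    """Two-pass per-band population standard deviation with explicit loops."""
    y, x, n = values.shape
    out = np.empty(n)
    for l in range(n):
        total = 0.0
        for i in range(y):
            for j in range(x):
                total += values[i, j, l]
        mean = total / (y * x)
        ssq = 0.0
        for i in range(y):
            for j in range(x):
                ssq += (values[i, j, l] - mean) ** 2
        out[l] = math.sqrt(ssq / (y * x))
    return out


def bin_index(v: float, lo: float, hi: float, n_bins: int) -> int:
    if hi == lo:
        return 0
    b = int((v - lo) / (hi - lo) * n_bins)
    return min(b, n_bins - 1)


def entropy_loops(pixels: np.ndarray, n_bins: int) -> float:
    """Shannon entropy in bits via dict counting over equal-width bins."""
    lo, hi = float(pixels.min()), float(pixels.max())
    counts: dict[int, int] = {}
    for v in pixels.ravel():
        b = bin_index(float(v), lo, hi, n_bins)
        counts[b] = counts.get(b, 0) + 1
    n = pixels.size
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def mi_loops(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Mutual information in bits via explicit joint/marginal counting."""
    xlo, xhi = float(x.min()), float(x.max())
    ylo, yhi = float(y.min()), float(y.max())
    joint: dict[tuple[int, int], int] = {}
    px: dict[int, int] = {}
    py: dict[int, int] = {}
    n = x.size
    for xv, yv in zip(x.ravel(), y.ravel()):
        bx = bin_index(float(xv), xlo, xhi, n_bins)
        by = bin_index(float(yv), ylo, yhi, n_bins)
        joint[(bx, by)] = joint.get((bx, by), 0) + 1
        px[bx] = px.get(bx, 0) + 1
        py[by] = py.get(by, 0) + 1
    mi = 0.0
    for (bx, by), c in joint.items():
        p_xy = c / n
        mi += p_xy * math.log2(p_xy / ((px[bx] / n) * (py[by] / n)))
    return mi


def window_scores_loops(scores: np.ndarray, w: int) -> np.ndarray:
    """Cumulative window scores by direct summation of each window."""
    n = scores.size
    return np.array([sum(scores[k + t] for t in range(w)) for k in range(n - w + 1)])


def best_window_loops(scores: np.ndarray, w: int) -> tuple[int, float]:
    """Exhaustive argmax over all window starts; first maximum wins."""
    ws = window_scores_loops(scores, w)
    best_s, best = 0, ws[0]
    for k in range(1, ws.size):
        if ws[k] > best:
            best_s, best = k, ws[k]
    return best_s, float(best)
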