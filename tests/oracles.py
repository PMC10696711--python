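"""Independent brute-force oracles for the texture-feature families.

Deliberately naive per-pixel/per-line enumerations, kept free of any
code shared with the package implementation so they can serve as
ground truth.
"""

from __future__ import annotations

import numpy as np


def glcm_oracle(levels: np.ndarray, L: int, offset: tuple[int, int]) -> np.ndarray:
    """Pair counting by explicit double loop."""
    dr, dc = offset
    h, w = levels.shape
    counts = np.zeros((L, L), dtype=int)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    return counts


def _lines(levels: np.ndarray, direction: int) -> list[list[int]]:
    h, w = levels.shape
    if direction == 0:
        return [list(levels[r]) for r in range(h)]
    if direction == 90:
        return [list(levels[:, c]) for c in range(w)]
    if direction == 135:        # main diagonals (down-right)
        return [list(np.diagonal(levels, offset=k))
                for k in range(-(h - 1), w)]
    if direction == 45:         # anti-diagonals (up-right)
        flipped = levels[::-1]
        return [list(np.diagonal(flipped, offset=k))
                for k in range(-(h - 1), w)]
    raise ValueError(direction)


def glrlm_oracle(levels: np.ndarray, L: int, direction: int,
                 jmax: int) -> np.ndarray:
    """Maximal-run counting by explicit scan of each line."""
    runs = np.zeros((L, jmax), dtype=int)
    for line in _lines(levels, direction):
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            runs[line[i] - 1, j - i - 1] += 1
            i = j
    return runs


def lbp_oracle(roi: np.ndarray) -> np.ndarray:
    """Per-pixel rotation-invariant uniform LBP via string rotation."""
    offsets = ((0, 1), (-1, 1), (-1, 0), (-1, -1),
               (0, -1), (1, -1), (1, 0), (1, 1))
    h, w = roi.shape
    hist = np.zeros(10)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            bits = [int(roi[r + dr, c + dc] >= roi[r, c])
                    for dr, dc in offsets]
            transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
            hist[sum(bits) if transitions <= 2 else 9] += 1
    return hist / hist.sum()


def stats_oracle(roi: np.ndarray) -> tuple[float, float, float, float, float]:
    """Moments via scipy, entropy via direct formula."""
    from scipy import stats

    x = np.asarray(roi, dtype=float).ravel()
    mean = x.mean()
    sd = x.std()                        # population SD
    skew = stats.skew(x, bias=True)
    kurt = stats.kurtosis(x, bias=True, fisher=True)
    p = x / x.sum()
    ent = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    return float(mean), float(sd), float(skew), float(kurt), ent
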