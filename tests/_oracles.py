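"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: flood fill instead of
scipy labeling, exact rational hypergeometric enumeration instead of
scipy's Fisher test, the literal step-up definition instead of statsmodels,
and a dense sliding-window mean instead of uniform filters.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from math import comb

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components by BFS flood fill; returns sets of (r, c)."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    y, x = q.popleft()
                    comp.add((y, x))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
                comps.append(comp)
    return comps


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration over all tables with
    the observed margins: sum P(table) over tables with P <= P(observed)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Literal BH step-up definition: sort, scale by m/i, cumulative min from
    the largest rank down, clip at 1, restore input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def sliding_window_mean(img: np.ndarray, radius: int) -> np.ndarray:
    """Dense local mean with the window clipped at image borders."""
    h, w = img.shape
    out = np.empty((h, w), dtype=float)
    for r in range(h):
        r0, r1 = max(0, r - radius), min(h, r + radius + 1)
        for c in range(w):
            c0, c1 = max(0, c - radius), min(w, c + radius + 1)
            out[r, c] = img[r0:r1, c0:c1].mean()
    return out
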