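"""Brute-force reference implementations used only by the tests.

Each oracle is an independent, simple-as-possible computation of a
quantity the package computes by a faster route: flood-fill component
labeling, exhaustive Euclidean dilation, exhaustive Otsu, hand-rolled BH,
and combinatorial hypergeometric tails.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb

import numpy as np


def flood_fill_count(mask: np.ndarray, connectivity: str) -> int:
    """Connected-component count by BFS flood fill (2D or 3D).

    ``connectivity``: "face" (4/6-neighborhood) or "full" (8/26).
    """
    mask = np.asarray(mask, dtype=bool)
    ndim = mask.ndim
    if connectivity == "face":
        offsets = [
            o
            for o in itertools.product((-1, 0, 1), repeat=ndim)
            if sum(abs(v) for v in o) == 1
        ]
    else:
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=ndim) if any(o)]
    seen = np.zeros_like(mask)
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            node = queue.popleft()
            for off in offsets:
                nb = tuple(n + o for n, o in zip(node, off))
                if all(0 <= nb[i] < mask.shape[i] for i in range(ndim)):
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
    return count


def flood_fill_sizes(mask: np.ndarray, connectivity: str) -> list[int]:
    """Component pixel counts by flood fill, sorted ascending."""
    mask = np.asarray(mask, dtype=bool)
    ndim = mask.ndim
    if connectivity == "face":
        offsets = [
            o
            for o in itertools.product((-1, 0, 1), repeat=ndim)
            if sum(abs(v) for v in o) == 1
        ]
    else:
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=ndim) if any(o)]
    seen = np.zeros_like(mask)
    sizes = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        size = 0
        queue = deque([start])
        seen[start] = True
        while queue:
            node = queue.popleft()
            size += 1
            for off in offsets:
                nb = tuple(n + o for n, o in zip(node, off))
                if all(0 <= nb[i] < mask.shape[i] for i in range(ndim)):
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
        sizes.append(size)
    return sorted(sizes)


def exhaustive_dilate(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean dilation by checking every pixel against every positive pixel."""
    mask = np.asarray(mask, dtype=bool)
    pos = np.argwhere(mask)
    out = np.zeros_like(mask)
    if pos.size == 0:
        return out
    for idx in np.ndindex(mask.shape):
        d2 = ((pos - np.asarray(idx)) ** 2).sum(axis=1)
        if (d2 <= radius_px**2 + 1e-9).any():
            out[idx] = True
    return out


def exhaustive_otsu(img: np.ndarray) -> float:
    """Otsu threshold by scanning all candidate thresholds (unique values)."""
    vals = np.sort(np.unique(np.asarray(img, dtype=float)))
    best_thr, best_var = vals[0], -np.inf
    for thr in vals[:-1]:
        lo, hi = img[img <= thr], img[img > thr]
        w0, w1 = lo.size, hi.size
        if w0 == 0 or w1 == 0:
            continue
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_thr = var, thr
    return float(best_thr)


def hand_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the definition q_(i) = min_{j>=i} p_(j) n / j."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = np.inf
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def hypergeom_tail_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for the overlap of a size-n draw with a size-K set, by
    summing the pmf computed from binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total
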