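"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid scikit-image and scipy.stats: morphological
reconstruction is computed by fixpoint iteration over explicit neighbor
shifts, regional maxima by exhaustive plateau flood search, and Fisher's
exact p by full hypergeometric enumeration with integer combinatorics.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    """3D neighbor offsets for the 6/18/26 voxel neighborhoods."""
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                steps = abs(dz) + abs(dy) + abs(dx)
                if 0 < steps <= rank:
                    out.append((dz, dy, dx))
    return out


def bf_reconstruct_dilation(
    marker: np.ndarray, mask: np.ndarray, connectivity: int
) -> np.ndarray:
    """Grayscale reconstruction by dilation via parallel fixpoint iteration."""
    marker = np.asarray(marker, dtype=float)
    mask = np.asarray(mask, dtype=float)
    assert (marker <= mask).all()
    rec = marker.copy()
    offsets = neighbor_offsets(connectivity)
    pad_value = -np.inf
    while True:
        best = rec.copy()
        for dz, dy, dx in offsets:
            shifted = np.full_like(rec, pad_value)
            src = tuple(
                slice(max(-d, 0), rec.shape[i] - max(d, 0))
                for i, d in enumerate((dz, dy, dx))
            )
            dst = tuple(
                slice(max(d, 0), rec.shape[i] + min(d, 0))
                for i, d in enumerate((dz, dy, dx))
            )
            shifted[dst] = rec[src]
            best = np.maximum(best, shifted)
        new = np.minimum(mask, best)
        if np.array_equal(new, rec):
            return rec
        rec = new


def bf_regional_maxima(img: np.ndarray, connectivity: int) -> list[frozenset]:
    """Regional maxima by exhaustive plateau flood.

    A maxima region is a connected plateau of equal value all of whose
    external neighbors are strictly lower; a plateau covering the whole
    image (no external neighbors) is not counted, matching the behavior of
    regional-maxima extractors on constant images.
    """
    img = np.asarray(img)
    offsets = neighbor_offsets(connectivity)
    visited = np.zeros(img.shape, dtype=bool)
    maxima = []
    for start in zip(*np.nonzero(~visited)):
        if visited[start]:
            continue
        value = img[start]
        plateau = []
        is_max = True
        has_external = False
        queue = deque([start])
        visited[start] = True
        while queue:
            p = queue.popleft()
            plateau.append(p)
            for off in offsets:
                q = tuple(p[i] + off[i] for i in range(3))
                if any(q[i] < 0 or q[i] >= img.shape[i] for i in range(3)):
                    continue
                if img[q] == value:
                    if not visited[q]:
                        visited[q] = True
                        queue.append(q)
                else:
                    has_external = True
                    if img[q] > value:
                        is_max = False
        if is_max and has_external:
            maxima.append(frozenset(plateau))
    return maxima


def bf_extended_maxima(img: np.ndarray, h: float, connectivity: int) -> set[frozenset]:
    """Extended maxima (h-maxima then regional maxima), brute force."""
    img = np.asarray(img, dtype=float)
    rec = bf_reconstruct_dilation(img - h, img, connectivity)
    return set(bf_regional_maxima(rec, connectivity))


def labels_to_components(labels: np.ndarray) -> set[frozenset]:
    """Convert a label volume to a set of voxel-coordinate frozensets."""
    out = set()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out.add(frozenset(zip(*np.nonzero(labels == lab))))
    return out


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by full enumeration of the margin family.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is at most (1 + 1e-7) times the observed
    table's probability.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def weight(a_: int) -> int:
        return math.comb(r1, a_) * math.comb(r2, c1 - a_)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    w_obs = weight(a)
    total = sum(
        weight(k) for k in range(lo, hi + 1) if weight(k) <= w_obs * (1 + 1e-7)
    )
    return total / denom
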