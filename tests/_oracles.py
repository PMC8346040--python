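"""Naive reference implementations used as independent oracles.

Everything here evaluates the underlying set definitions literally —
per-pixel window loops, breadth-first flood fill, exhaustive neighbour
scans, iteration until stabilisation — with no shared code paths with the
package implementation.
"""

from __future__ import annotations

import numpy as np

NEIGHBOURS_8 = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def naive_local_mean(image: np.ndarray, block_size: int) -> np.ndarray:
    """O(N * block_size^2) windowed mean with edge replication, summing in
    exact Python integers for integer input."""
    img = np.asarray(image)
    h, w = img.shape
    r = block_size // 2
    out = np.empty((h, w), dtype=np.float64)
    denom = block_size * block_size
    for y in range(h):
        for x in range(w):
            total = 0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    total += int(img[yy, xx])
            out[y, x] = total / denom
    return out


def naive_threshold(image: np.ndarray, block_size: int, offset: float,
                    dark_foreground: bool = True) -> np.ndarray:
    img = np.asarray(image)
    bound = naive_local_mean(img, block_size) - offset
    return img <= bound if dark_foreground else img > bound


def flood_components(mask: np.ndarray) -> list[frozenset[tuple[int, int]]]:
    """8-connected components by explicit breadth-first flood fill, in
    raster-scan order of each component's first pixel."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    components = []
    for y0 in range(h):
        for x0 in range(w):
            if not mask[y0, x0] or seen[y0, x0]:
                continue
            queue = [(y0, x0)]
            seen[y0, x0] = True
            pixels = set()
            while queue:
                y, x = queue.pop()
                pixels.add((y, x))
                for dy, dx in NEIGHBOURS_8:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                        seen[yy, xx] = True
                        queue.append((yy, xx))
            components.append(frozenset(pixels))
    return components


def touches_cell(pixels: frozenset[tuple[int, int]], cell_slice: np.ndarray) -> bool:
    """Exhaustive scan: some pixel q lies in the 8-neighbourhood of some
    cell pixel r (q itself excluded)."""
    h, w = cell_slice.shape
    for y, x in pixels:
        for dy, dx in NEIGHBOURS_8:
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and cell_slice[yy, xx]:
                return True
    return False


def oracle_select(
    collagen: np.ndarray,
    cell: np.ndarray,
    min_size: int = 5,
    enrich: bool = True,
) -> set[tuple[int, frozenset[tuple[int, int]]]]:
    """Literal evaluation of the whole selection algebra on boolean
    (z, y, x) stacks; returns {(slice_index, pixel_set), ...}."""
    n_slices = collagen.shape[0]
    cleaned = collagen & ~cell
    per_slice = [flood_components(cleaned[i]) for i in range(n_slices)]
    universe = {
        (i, comp)
        for i in range(n_slices)
        for comp in per_slice[i]
        if len(comp) > min_size
    }
    selected = {
        (i, comp) for (i, comp) in universe if touches_cell(comp, cell[i])
    }
    if not enrich:
        return selected
    while True:
        added = set()
        for (i, comp) in universe - selected:
            for (j, other) in selected:
                if abs(i - j) == 1 and comp & other:
                    added.add((i, comp))
                    break
        if not added:
            return selected
        selected |= added


def oracle_chain(
    collagen: np.ndarray, cell: np.ndarray, min_size: int = 5
) -> list[set[tuple[int, frozenset[tuple[int, int]]]]]:
    """The enrichment chain S'1, S'2, ... by naive iteration, for the
    monotonicity checks."""
    n_slices = collagen.shape[0]
    cleaned = collagen & ~cell
    universe = {
        (i, comp)
        for i in range(n_slices)
        for comp in flood_components(cleaned[i])
        if len(comp) > min_size
    }
    selected = {(i, c) for (i, c) in universe if touches_cell(c, cell[i])}
    chain = [set(selected)]
    while True:
        added = {
            (i, comp)
            for (i, comp) in universe - selected
            if any(abs(i - j) == 1 and comp & other for (j, other) in selected)
        }
        if not added:
            return chain
        selected |= added
        chain.append(set(selected))
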