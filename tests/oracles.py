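"""Brute-force oracle twins of the spatial primitives.

Each oracle enumerates all cell pairs directly (vectorised over the inner
loop only), independent of the convolution / distance-transform code paths it
checks.
"""

from __future__ import annotations

import numpy as np

NODATA = -1


def _pair_distances(shape, cell_size):
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    return rr, cc


def oracle_neighborhood_fraction(codes, target_classes, radius, cell_size):
    """Per-cell target fraction by enumerating every other cell."""
    codes = np.asarray(codes)
    rows, cols = codes.shape
    valid = codes != NODATA
    target = np.isin(codes, list(target_classes)) & valid
    rr, cc = np.mgrid[0:rows, 0:cols]
    out = np.zeros(codes.shape)
    for i in range(rows):
        for j in range(cols):
            if not valid[i, j]:
                continue
            inside = np.hypot(rr - i, cc - j) * cell_size <= radius
            den = int((inside & valid).sum())
            num = int((inside & target).sum())
            out[i, j] = num / den
    return out


def oracle_distance_to_nearest(codes, target_classes, cell_size):
    """Per-cell minimum centre distance to any target cell."""
    codes = np.asarray(codes)
    rows, cols = codes.shape
    target = np.isin(codes, list(target_classes)) & (codes != NODATA)
    ti, tj = np.nonzero(target)
    out = np.full(codes.shape, np.inf)
    if ti.size == 0:
        return out
    for i in range(rows):
        for j in range(cols):
            out[i, j] = np.hypot(ti - i, tj - j).min() * cell_size
    return out


def oracle_rewilding(fs_values, fs_nodata, suitable, valid, home_range_radius, cell_size):
    """Per-cell distance-weighted function aggregate by double loop.

    Sums FS(k) * w(d) over in-bounds non-NoData cells with d < R, divided by
    the sum of weights over those cells.
    """
    rows, cols = fs_values.shape
    fs = np.where(fs_nodata, 0.0, fs_values)
    rr, cc = np.mgrid[0:rows, 0:cols]
    out = np.zeros(fs_values.shape)
    for i in range(rows):
        for j in range(cols):
            if not suitable[i, j]:
                continue
            d = np.hypot(rr - i, cc - j) * cell_size
            w = np.where((d < home_range_radius) & valid, 1.0 - d / home_range_radius, 0.0)
            wsum = w.sum()
            out[i, j] = (fs * w).sum() / wsum if wsum > 0 else 0.0
    return out


def oracle_point_in_polygon(x, y, vertices):
    """Even-odd ray casting for a simple polygon given as a vertex list."""
    inside = False
    n = len(vertices)
    for k in range(n):
        x1, y1 = vertices[k]
        x2, y2 = vertices[(k + 1) % n]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


def oracle_flood_fill(mask, connectivity=8):
    """Connected components of a boolean mask by iterative flood fill."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros(mask.shape, dtype=bool)
    components = []
    for i in range(rows):
        for j in range(cols):
            if not mask[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            seen[i, j] = True
            comp = set()
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            components.append(frozenset(comp))
    return components
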