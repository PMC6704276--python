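"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately takes the most literal route (explicit loops,
normal equations, flood fill) so it shares no code path with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def affine_normal_equations(src: np.ndarray, dst: np.ndarray) -> tuple:
    """Least-squares affine fit by explicitly inverting the normal equations."""
    n = len(src)
    A = np.column_stack([src[:, 0], src[:, 1], np.ones(n)])
    AtA_inv = np.linalg.inv(A.T @ A)
    sol_x = AtA_inv @ A.T @ dst[:, 0]
    sol_y = AtA_inv @ A.T @ dst[:, 1]
    return (sol_x[0], sol_x[1], sol_x[2], sol_y[0], sol_y[1], sol_y[2])


def silhouette_brute(X: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) per-point silhouette with explicit loops."""
    n = len(X)
    s_values = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            s_values.append(0.0)
            continue
        a = sum(math.dist(X[i], X[j]) for j in same) / len(same)
        b = math.inf
        for other in set(labels.tolist()) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            b = min(b, sum(math.dist(X[i], X[j]) for j in members) / len(members))
        denom = max(a, b)
        s_values.append((b - a) / denom if denom > 0 else 0.0)
    return float(np.mean(s_values))


def point_in_polygon_scalar(x: float, y: float, poly: np.ndarray) -> bool:
    """Even-odd rule for a single point, classic scalar crossing loop."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def flood_fill_from_border(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Background pixels reachable from the image border (BFS flood fill)."""
    h, w = mask.shape
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    reach = np.zeros_like(mask, dtype=bool)
    queue: deque = deque()
    for y in range(h):
        for x in range(w):
            if (y in (0, h - 1) or x in (0, w - 1)) and not mask[y, x]:
                reach[y, x] = True
                queue.append((y, x))
    while queue:
        y, x = queue.popleft()
        for dy, dx in offsets:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and not reach[ny, nx]:
                reach[ny, nx] = True
                queue.append((ny, nx))
    return reach


def count_components(mask: np.ndarray, connectivity: int = 8) -> int:
    """Connected-component count by BFS labeling."""
    h, w = mask.shape
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                count += 1
                queue = deque([(y, x)])
                seen[y, x] = True
                while queue:
                    cy, cx = queue.popleft()
                    for dy, dx in offsets:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            queue.append((ny, nx))
    return count


def nearest_neighbor_warp_brute(mask: np.ndarray, t_matrix: np.ndarray,
                                target_shape: tuple) -> np.ndarray:
    """Pixel-by-pixel inverse-mapping warp with floor(v + 0.5) rounding."""
    inv = np.linalg.inv(t_matrix)
    out = np.zeros(target_shape, dtype=bool)
    for y in range(target_shape[0]):
        for x in range(target_shape[1]):
            sx, sy, _ = inv @ np.array([x, y, 1.0])
            ix = math.floor(sx + 0.5)
            iy = math.floor(sy + 0.5)
            if 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]:
                out[y, x] = mask[iy, ix]
    return out


def complete_linkage_brute(X: np.ndarray) -> list:
    """Naive O(n^3) agglomeration with complete linkage; returns merge heights."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = (math.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    math.dist(X[a], X[b]) for a in clusters[i] for b in clusters[j]
                )
                if d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    return heights
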