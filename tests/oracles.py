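"""Independent reference implementations used as test oracles.

Deliberately naive (per-pixel loops, exhaustive searches, direct textbook
formulas) and kept separate from the package so each check compares two
independent routes to the same quantity.
"""

from __future__ import annotations

import math

import numpy as np


def zhang_suen_reference(grid: np.ndarray) -> np.ndarray:
    """Loop-based Zhang-Suen thinning, straight from the published rules.

    Parallel scheme: each sub-iteration marks deletions on the image state
    at its start, then applies them; repeats until a full pass changes
    nothing.
    """
    img = np.asarray(grid, dtype=bool).copy()

    def p(im, r, c):
        if 0 <= r < im.shape[0] and 0 <= c < im.shape[1]:
            return int(im[r, c])
        return 0

    def neighbors(im, r, c):
        # P2..P9 clockwise starting north
        return [
            p(im, r - 1, c), p(im, r - 1, c + 1), p(im, r, c + 1),
            p(im, r + 1, c + 1), p(im, r + 1, c), p(im, r + 1, c - 1),
            p(im, r, c - 1), p(im, r - 1, c - 1),
        ]

    while True:
        changed = False
        for step in (0, 1):
            to_delete = []
            for r in range(img.shape[0]):
                for c in range(img.shape[1]):
                    if not img[r, c]:
                        continue
                    nb = neighbors(img, r, c)
                    b = sum(nb)
                    if not 2 <= b <= 6:
                        continue
                    a = sum(
                        1 for i in range(8) if nb[i] == 0 and nb[(i + 1) % 8] == 1
                    )
                    if a != 1:
                        continue
                    p2, p4, p6, p8 = nb[0], nb[2], nb[4], nb[6]
                    if step == 0:
                        if p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0:
                            to_delete.append((r, c))
                    else:
                        if p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0:
                            to_delete.append((r, c))
            for r, c in to_delete:
                img[r, c] = False
            changed = changed or bool(to_delete)
        if not changed:
            return img


def brute_force_distance_transform(grid: np.ndarray) -> np.ndarray:
    """O(n^2) exact Euclidean distance to the nearest background pixel.

    The grid is conceptually padded by one background pixel on all sides,
    matching the measurement convention for tightly cropped masks.
    """
    padded = np.pad(np.asarray(grid, dtype=bool), 1)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape, dtype=float)
    for r, c in np.argwhere(padded):
        d2 = ((bg[:, 0] - r) ** 2 + (bg[:, 1] - c) ** 2).min()
        out[r, c] = math.sqrt(d2)
    return out[1:-1, 1:-1]


def all_pairs_longest_path_length(grid: np.ndarray) -> int:
    """Exhaustive all-pairs BFS; returns the diameter in *pixels on path*.

    Exact for any 8-connected skeleton graph (restricted to the largest
    component), cycles included.
    """
    pix = [tuple(p) for p in np.argwhere(np.asarray(grid, dtype=bool))]
    pset = set(pix)
    if not pix:
        raise ValueError("empty skeleton")

    def bfs(start):
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for (r, c) in frontier:
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        q = (r + dr, c + dc)
                        if q == (r, c) or q not in pset or q in dist:
                            continue
                        dist[q] = dist[(r, c)] + 1
                        nxt.append(q)
            frontier = nxt
        return dist

    # largest connected component
    seen: set = set()
    best_comp: list = []
    for s in pix:
        if s in seen:
            continue
        comp = list(bfs(s))
        seen.update(comp)
        if len(comp) > len(best_comp):
            best_comp = comp
    diameter = 0
    for s in best_comp:
        dist = bfs(s)
        diameter = max(diameter, max(d for q, d in dist.items() if q in best_comp))
    return diameter + 1  # path pixel count


def point_in_polygon_evenodd(x: float, y: float, verts: np.ndarray,
                             tol: float = 1e-9) -> bool:
    """Scalar even-odd test, boundary-inclusive."""
    n = len(verts)
    # boundary check
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        seg = math.hypot(dx, dy)
        if seg < tol:
            if abs(x - x1) < tol and abs(y - y1) < tol:
                return True
            continue
        cross = (x - x1) * dy - (y - y1) * dx
        t = ((x - x1) * dx + (y - y1) * dy) / (seg * seg)
        if abs(cross) <= tol * seg and -tol <= t <= 1 + tol:
            return True
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


def brute_force_rasterize_count(verts: np.ndarray, height: int, width: int) -> int:
    """Foreground pixel count by looping the even-odd test over all centers."""
    verts = np.asarray(verts, dtype=float)
    return sum(
        point_in_polygon_evenodd(float(c), float(r), verts)
        for r in range(height)
        for c in range(width)
    )


def student_t_two_sided_p(t_stat: float, df: float) -> float:
    """Two-sided p-value by numerical integration of the t density."""
    from scipy.integrate import quad

    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = quad(pdf, abs(t_stat), np.inf)
    return min(1.0, 2 * tail)


def greedy_match_reference(pred_items, gt_items, iou_matrix, threshold):
    """Exhaustive greedy matching oracle.

    ``pred_items``: list of (instance_id, confidence, class); ``gt_items``:
    list of classes; ``iou_matrix[i][j]``: IoU of pred i and gt j.  Returns
    the list of matched gt indices (or None) in original pred order.
    """
    order = sorted(
        range(len(pred_items)),
        key=lambda i: (-pred_items[i][1], pred_items[i][0]),
    )
    taken = set()
    result = [None] * len(pred_items)
    for i in order:
        best, best_iou = None, 0.0
        for j in range(len(gt_items)):
            if j in taken or gt_items[j] != pred_items[i][2]:
                continue
            if iou_matrix[i][j] >= threshold and iou_matrix[i][j] > best_iou:
                best, best_iou = j, iou_matrix[i][j]
        if best is not None:
            taken.add(best)
            result[i] = best
    return result
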