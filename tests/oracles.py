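"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions, in a deliberately naive
style (explicit loops, bisection root finding instead of closed forms),
so agreement with the package is a genuine cross-check rather than a
shared code path.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull


def moving_average_brute(values, window):
    half = window // 2
    out = []
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return np.array(out)


def linear_interp_brute(x, mask, max_gap):
    """Fill interior NaN runs of length <= max_gap by hand."""
    x = np.array(x, dtype=float)
    idx = [i for i, m in enumerate(mask) if m]
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            for j in range(a + 1, b):
                frac = (j - a) / (b - a)
                x[j] = x[a] + frac * (x[b] - x[a])
    return x


def total_distance_brute(points):
    return sum(math.dist(points[i], points[i + 1])
               for i in range(len(points) - 1))


def msd_brute(points, m):
    """All-pairs-at-lag average of squared displacement, lag m samples."""
    vals = []
    for i in range(len(points) - m):
        dx = points[i + m][0] - points[i][0]
        dy = points[i + m][1] - points[i][1]
        vals.append(dx * dx + dy * dy)
    return sum(vals) / len(vals)


def hull_area_shoelace(points):
    """Convex-hull area via scipy vertices and the shoelace formula."""
    hull = ConvexHull(points)
    verts = np.asarray(points)[hull.vertices]
    s = 0.0
    for i in range(len(verts)):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % len(verts)]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


def chord_walk_brute(points, q):
    """First-crossing divider walk found by scanning + bisection.

    Same definition as the package's rediscretizer but a different root
    finder, so coincidence of the resampled vertices is meaningful.
    """
    pts = np.asarray(points, dtype=float)
    out = [pts[0]]
    anchor = pts[0]
    seg, t0 = 0, 0.0

    def dist_at(s, u):
        p = pts[s] + u * (pts[s + 1] - pts[s])
        return math.dist(p, anchor)

    while True:
        hit = None
        s, lo = seg, t0
        while s < len(pts) - 1:
            # scan the segment finely for the first sign change of dist - q
            grid = np.linspace(lo, 1.0, 65)
            prev = grid[0]
            found = None
            for u in grid[1:]:
                if dist_at(s, prev) < q <= dist_at(s, u):
                    found = (prev, u)
                    break
                prev = u
            if found is not None:
                a, b = found
                for _ in range(100):
                    mid = 0.5 * (a + b)
                    if dist_at(s, mid) < q:
                        a = mid
                    else:
                        b = mid
                hit = (s, b, pts[s] + b * (pts[s + 1] - pts[s]))
                break
            s, lo = s + 1, 0.0
        if hit is None:
            break
        seg, t0, anchor = hit
        out.append(anchor)
    remainder = math.dist(pts[-1], anchor)
    return np.asarray(out), remainder


def sinuosity_brute(points, q):
    """Sinuosity from the definition on brute-force rediscretized points."""
    pts, _ = chord_walk_brute(points, q)
    if len(pts) < 3:
        return float("nan")
    steps = [math.dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]
    headings = [math.atan2(pts[i + 1][1] - pts[i][1], pts[i + 1][0] - pts[i][0])
                for i in range(len(pts) - 1)]
    cosines = [math.cos(headings[i + 1] - headings[i])
               for i in range(len(headings) - 1)]
    p = sum(steps) / len(steps)
    c = sum(cosines) / len(cosines)
    mean_sq = sum(s * s for s in steps) / len(steps)
    b = math.sqrt(max(mean_sq - p * p, 0.0)) / p
    if c >= 1.0 - 1e-12:
        return 0.0
    return 2.0 / math.sqrt(p * ((1.0 + c) / (1.0 - c) + b * b))


def fractal_d_brute(points, eps_grid):
    """Divider-walk fractal dimension with an explicit least-squares fit."""
    xs, ys = [], []
    for eps in eps_grid:
        pts, rem = chord_walk_brute(points, eps)
        n_steps = len(pts) - 1
        if n_steps < 1:
            continue
        xs.append(math.log(eps))
        ys.append(math.log(n_steps * eps + rem))
    if len(xs) < 3:
        return float("nan")
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    slope = (sum((x - mx) * (y - my) for x, y in zip(xs, ys))
             / sum((x - mx) ** 2 for x in xs))
    return min(2.0, max(1.0, 1.0 - slope))


def mwu_brute(a, b):
    """Min-orientation Mann–Whitney U by explicit pair counting."""
    u1 = 0.0
    for x in a:
        for y in b:
            if x > y:
                u1 += 1.0
            elif x == y:
                u1 += 0.5
    return min(u1, len(a) * len(b) - u1)


def auc_brute(labels, scores):
    """ROC AUC as the fraction of correctly ranked (pos, neg) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
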