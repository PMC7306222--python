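"""Independent oracles used only by the test suite.

Deliberately naive implementations (dense quadrature, O(n^3) hulls,
pairwise segment scans) kept separate from the package so the code paths
they validate share nothing with them.
"""
from __future__ import annotations

import numpy as np


def quadrature_efd(points: np.ndarray, n_harmonics: int, samples: int = 100_000) -> np.ndarray:
    """EFD coefficients by dense per-segment trapezoid quadrature.

    Integrates x(t)cos/sin and y(t)cos/sin over the arc-length parameterized
    piecewise-linear closed curve, sampling each segment separately so the
    integrand's kinks coincide with sample nodes.
    """
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    dt = np.hypot(seg[:, 0], seg[:, 1])
    T = dt.sum()
    t0 = np.concatenate(([0.0], np.cumsum(dt)))
    out = np.zeros((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        acc = np.zeros(4)
        for i in range(len(pts)):
            if dt[i] == 0:
                continue
            m = max(20, int(samples * dt[i] / T))
            u = np.linspace(0.0, 1.0, m)
            tt = t0[i] + u * dt[i]
            x = closed[i, 0] + u * seg[i, 0]
            y = closed[i, 1] + u * seg[i, 1]
            w = 2.0 * np.pi * n * tt / T
            acc[0] += np.trapezoid(x * np.cos(w), tt)
            acc[1] += np.trapezoid(x * np.sin(w), tt)
            acc[2] += np.trapezoid(y * np.cos(w), tt)
            acc[3] += np.trapezoid(y * np.sin(w), tt)
        out[n - 1] = acc * 2.0 / T
    return out


def brute_force_hull_area(points: np.ndarray) -> float:
    """Convex-hull area via the O(n^3) edge test + shoelace.

    A directed pair (i, j) is a hull edge iff every other point lies on or
    to the left of the line i->j.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        return 0.0
    edges = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            cross = d[0] * (pts[:, 1] - pts[i, 1]) - d[1] * (pts[:, 0] - pts[i, 0])
            if np.all(cross >= -1e-12):
                edges.append((i, j))
    if not edges:
        return 0.0
    nxt = dict(edges)
    start = edges[0][0]
    order = [start]
    while True:
        nx = nxt[order[-1]]
        if nx == start:
            break
        order.append(nx)
        if len(order) > n:
            break
    hull = pts[order]
    x, y = hull[:, 0], hull[:, 1]
    return float(abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4


def is_simple_polygon(points: np.ndarray) -> bool:
    """Pairwise segment-intersection scan (non-adjacent edges only)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    for i in range(n):
        a1, a2 = pts[i], pts[(i + 1) % n]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if _segments_intersect(a1, a2, pts[j], pts[(j + 1) % n]):
                return False
    return True


def random_star_polygon(rng: np.random.Generator, n_vertices: int = 12) -> np.ndarray:
    """A random simple (star-shaped) polygon around the origin."""
    ang = np.sort(rng.uniform(0.0, 2.0 * np.pi, n_vertices))
    # enforce distinct angles so no zero-length edges
    ang += np.linspace(0.0, 1e-6, n_vertices)
    rad = rng.uniform(0.5, 1.5, n_vertices)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
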