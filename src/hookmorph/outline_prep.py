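"""Canonicalization of hook outlines before Fourier analysis.

Mirrors the preparation applied to the redrawn dactylus illustrations:
orientation and start-vertex canonicalization, equal-arc-length resampling,
mirroring of left-side appendages for consistency, optional smoothing, and
closure of the concave proximal base with a convex circular cap (the
articulation end of the dactylus is open/concave in most drawings and would
otherwise dominate the outline harmonics).
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .efd_core import EFDCoefficients, NormalizedEFD, normalize_efd
from .shapes import Outline

__all__ = [
    "BaseSpec",
    "CapKind",
    "canonicalize",
    "resample_equal_arclength",
    "mirror",
    "mirror_efd",
    "cap_base",
    "smooth",
]


class CapKind(str, enum.Enum):
    SEMICIRCLE = "semicircle"
    ARC = "arc"


@dataclass(frozen=True)
class BaseSpec:
    """How to close the open proximal base of a hook curve.

    ``base_endpoints`` are indices of the two articulation points (they must
    be the first and last vertex of the open curve). ``arc_bulge`` is the
    cap sagitta as a fraction of the base chord; a semicircle corresponds to
    0.5.
    """

    base_endpoints: tuple[int, int] = (0, -1)
    cap_kind: CapKind = CapKind.SEMICIRCLE
    arc_bulge: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.arc_bulge <= 1.0:
            raise ValueError("arc_bulge must be in (0, 1]")
        if self.base_endpoints[0] == self.base_endpoints[1]:
            raise ValueError("base endpoints must be distinct")


def _merge_duplicates(pts: np.ndarray, rel_tol: float = 1e-12) -> np.ndarray:
    scale = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1.0)
    d = np.roll(pts, -1, axis=0) - pts
    keep = np.hypot(d[:, 0], d[:, 1]) > rel_tol * scale
    # keep[i] False means pts[i+1] duplicates pts[i]; drop the later one
    mask = np.ones(len(pts), dtype=bool)
    mask[(np.nonzero(~keep)[0] + 1) % len(pts)] = False
    return pts[mask] if mask.sum() >= 3 else pts


def canonicalize(outline: Outline) -> Outline:
    """Deterministic canonical form: ccw, start at min-(y, x) vertex.

    Consecutive duplicate vertices are merged; a zero-area outline is an
    error. Idempotent.
    """
    pts = _merge_duplicates(outline.points)
    o = Outline(pts)
    scale = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1e-300)
    if abs(o.signed_area) < 1e-12 * scale**2:
        raise ValueError("degenerate outline: zero signed area")
    if not o.is_ccw:
        pts = pts[::-1]
    start = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    return Outline(np.roll(pts, -start, axis=0))


def resample_equal_arclength(outline: Outline, n_points: int) -> Outline:
    """Resample to ``n_points`` vertices at equal arc-length spacing."""
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    pts = outline.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    t = np.concatenate(([0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))))
    T = t[-1]
    if T == 0:
        raise ValueError("outline has zero perimeter")
    ts = np.linspace(0.0, T, n_points, endpoint=False)
    x = np.interp(ts, t, closed[:, 0])
    y = np.interp(ts, t, closed[:, 1])
    return Outline(np.column_stack([x, y]))


def mirror(outline: Outline) -> Outline:
    """Reflect across the vertical axis through the centroid.

    The vertex order is reversed after reflection so traversal orientation
    (ccw/cw) is preserved; applying :func:`mirror` twice is the identity.
    """
    cx = outline.centroid[0]
    pts = outline.points.copy()
    pts[:, 0] = 2.0 * cx - pts[:, 0]
    return Outline(pts[::-1])


def mirror_efd(efd: EFDCoefficients) -> EFDCoefficients:
    """EFD of the mirrored outline: (a, b, c, d) -> (-a, b, c, -d).

    The transform combines reflection of x with reversal of the traversal
    direction, so orientation is preserved. A :class:`NormalizedEFD` input
    is re-normalized afterwards (mirroring moves the first-harmonic axis
    start to the opposite end).
    """
    out = efd.coeffs * np.array([-1.0, 1.0, 1.0, -1.0])
    if isinstance(efd, NormalizedEFD):
        return normalize_efd(EFDCoefficients(out, A0=efd.A0, C0=efd.C0))
    return EFDCoefficients(out, A0=efd.A0, C0=efd.C0)


def cap_base(open_curve: np.ndarray, spec: BaseSpec = BaseSpec()) -> Outline:
    """Close an open hook curve with a convex circular arc over its base.

    ``open_curve`` runs from one articulation point to the other; the cap is
    appended from the last point back to the first, bulging away from the
    curve's interior so the closed outline stays simple and the cap is
    convex. Raises if the capped outline self-intersects (try a smaller
    ``arc_bulge``).
    """
    pts = np.asarray(open_curve, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("open_curve must be an (n, 2) array with n >= 3")
    i0, i1 = spec.base_endpoints
    n = len(pts)
    if (i0 % n, i1 % n) not in {(0, n - 1), (n - 1, 0)}:
        raise ValueError("base endpoints must be the first and last vertex of the open curve")

    p_end, p_start = pts[-1], pts[0]
    chord = p_start - p_end
    c_len = float(np.hypot(*chord))
    if c_len == 0:
        raise ValueError("base endpoints coincide; nothing to cap")
    # interior side: sign of the signed area of the curve closed by the chord
    closed = Outline(pts)
    interior_ccw = closed.signed_area > 0
    u = chord / c_len
    # outward normal of the chord (away from interior)
    nrm = np.array([-u[1], u[0]]) if not interior_ccw else np.array([u[1], -u[0]])

    bulge = 0.5 if spec.cap_kind is CapKind.SEMICIRCLE else spec.arc_bulge
    s = bulge * c_len  # sagitta
    R = (c_len**2 / 4.0 + s**2) / (2.0 * s)
    mid = 0.5 * (p_end + p_start)
    center = mid - (R - s) * nrm
    ang0 = math.atan2(*(p_end - center)[::-1])
    ang1 = math.atan2(*(p_start - center)[::-1])
    # sweep from p_end to p_start on the outward side, matching traversal
    # orientation of the curve
    if interior_ccw:
        while ang1 <= ang0:
            ang1 += 2.0 * math.pi
    else:
        while ang1 >= ang0:
            ang1 -= 2.0 * math.pi
    mean_step = closed.perimeter / len(pts)
    arc_len = abs(ang1 - ang0) * R
    n_cap = max(8, int(round(arc_len / mean_step)))
    angs = np.linspace(ang0, ang1, n_cap + 2)[1:-1]  # endpoints already present
    cap_pts = center + R * np.column_stack([np.cos(angs), np.sin(angs)])
    out = Outline(np.vstack([pts, cap_pts]))
    if not out.is_simple():
        raise ValueError("capped outline self-intersects; try a smaller arc_bulge")
    return out


def smooth(outline: Outline, iterations: int = 1) -> Outline:
    """Closed-curve (1/4, 1/2, 1/4) vertex smoothing, ``iterations`` times."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    pts = outline.points
    for _ in range(iterations):
        pts = 0.25 * np.roll(pts, 1, axis=0) + 0.5 * pts + 0.25 * np.roll(pts, -1, axis=0)
    return Outline(pts)
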