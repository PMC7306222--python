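"""Elliptic Fourier descriptors (EFD) of closed outlines.

A closed outline parameterized by arc length t in [0, T] has truncated
Fourier series

    x(t) = A0 + sum_n a_n cos(2*pi*n*t/T) + b_n sin(2*pi*n*t/T)
    y(t) = C0 + sum_n c_n cos(2*pi*n*t/T) + d_n sin(2*pi*n*t/T)

For a polygon the coefficients have a closed form (per-segment sums), which
is what :func:`compute_efd` evaluates. :func:`normalize_efd` removes size,
rotation, translation and digitization start point using the first-harmonic
ellipse, making coefficient sets comparable across specimens — the
representation fed to the morphospace PCA.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .shapes import Outline

__all__ = [
    "EFDCoefficients",
    "NormalizedEFD",
    "compute_efd",
    "normalize_efd",
    "reconstruct",
    "harmonic_power",
]


@dataclass(frozen=True)
class EFDCoefficients:
    """Raw EFD: centroid offsets A0/C0 plus an (N, 4) array of harmonics.

    Column order per harmonic n is (a_n, b_n, c_n, d_n).
    """

    coeffs: np.ndarray
    A0: float = 0.0
    C0: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4 or c.shape[0] < 1:
            raise ValueError("coeffs must be an (N, 4) array with N >= 1")
        if not np.isfinite(c).all():
            raise ValueError("EFD coefficients must be finite")
        object.__setattr__(self, "coeffs", c)

    @property
    def n_harmonics(self) -> int:
        return int(self.coeffs.shape[0])

    def harmonic(self, n: int) -> np.ndarray:
        """Quadruple (a_n, b_n, c_n, d_n) for harmonic ``n`` (1-based)."""
        return self.coeffs[n - 1]


@dataclass(frozen=True)
class NormalizedEFD(EFDCoefficients):
    """Size/rotation/start-point normalized EFD.

    After normalization a1 == 1, b1 == c1 == 0 and A0 == C0 == 0. The
    removed quantities are kept as metadata: ``scale`` (semi-major axis of
    the first-harmonic ellipse), ``rotation`` (psi, radians) and
    ``start_shift`` (theta, radians of parameter phase).
    """

    scale: float = float("nan")
    rotation: float = float("nan")
    start_shift: float = float("nan")

    def __post_init__(self) -> None:
        super().__post_init__()

    def check(self, atol: float = 1e-6) -> None:
        a1, b1, c1, _ = self.coeffs[0]
        if abs(a1 - 1.0) > atol or abs(b1) > atol or abs(c1) > atol:
            raise ValueError(
                "coefficients are not normalized: expected a1=1, b1=c1=0, "
                f"got a1={a1:.6g}, b1={b1:.3g}, c1={c1:.3g}"
            )


def compute_efd(outline: Outline, n_harmonics: int) -> EFDCoefficients:
    """Closed-form EFD of a polygonal outline (arc-length parameterization).

    Parameters
    ----------
    outline
        Closed polygon; consecutive duplicate vertices are tolerated (zero-
        length segments are dropped).
    n_harmonics
        Number of harmonics N >= 1.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = outline.points
    d = np.roll(pts, -1, axis=0) - pts
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    if not keep.all():
        d, dt = d[keep], dt[keep]
        pts = pts[keep]
    T = dt.sum()
    if T == 0:
        raise ValueError("outline has zero perimeter")
    t = np.concatenate(([0.0], np.cumsum(dt)))
    phi = (2.0 * np.pi / T) * t
    n = np.arange(1, n_harmonics + 1)[:, None]
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    fac = T / (2.0 * (n.ravel() * np.pi) ** 2)
    a = fac * (dcos @ vx)
    b = fac * (dsin @ vx)
    c = fac * (dcos @ vy)
    dd = fac * (dsin @ vy)
    # offsets = arc-length centroid (exact for a polyline)
    mid = 0.5 * (pts + np.roll(pts, -1, axis=0))
    A0 = float((mid[:, 0] * dt).sum() / T)
    C0 = float((mid[:, 1] * dt).sum() / T)
    return EFDCoefficients(np.column_stack([a, b, c, dd]), A0=A0, C0=C0)


def _phase_shift(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the curve parameter start by theta radians of phase."""
    n = np.arange(1, coeffs.shape[0] + 1)
    cn, sn = np.cos(n * theta), np.sin(n * theta)
    a, b, c, d = coeffs.T
    return np.column_stack(
        [a * cn + b * sn, -a * sn + b * cn, c * cn + d * sn, -c * sn + d * cn]
    )


def _rotate(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the shape by ``psi`` radians (about the origin)."""
    cp, sp = math.cos(psi), math.sin(psi)
    a, b, c, d = coeffs.T
    return np.column_stack([cp * a - sp * c, cp * b - sp * d, sp * a + cp * c, sp * b + cp * d])


def normalize_efd(efd: EFDCoefficients, atol: float = 1e-12) -> NormalizedEFD:
    """Normalize for size, rotation, translation and start point.

    Uses the first-harmonic ellipse: its phase fixes the start point, its
    orientation the rotation, its semi-major axis the scale. The residual
    180-degree ambiguity is resolved by requiring a1 > 0 (semi-major axis
    pointing along +x); for counterclockwise outlines d1 then comes out
    positive. Raises ``ValueError`` on a degenerate first harmonic.
    """
    a1, b1, c1, d1 = efd.coeffs[0]
    theta1 = 0.5 * math.atan2(2.0 * (a1 * b1 + c1 * d1), a1 * a1 + c1 * c1 - b1 * b1 - d1 * d1)
    candidates = []
    for k in range(4):
        th = theta1 + k * (np.pi / 2.0)
        shifted = _phase_shift(efd.coeffs, th)
        psi = math.atan2(shifted[0, 2], shifted[0, 0])
        rotated = _rotate(shifted, -psi)
        candidates.append((rotated[0, 0], rotated, psi, th))
    # Candidates k and k+2 share the semi-axis length; keep the semi-major pair.
    pair = [candidates[0], candidates[2]] if candidates[0][0] >= candidates[1][0] else [candidates[1], candidates[3]]
    lam = pair[0][0]
    if lam <= atol:
        raise ValueError("degenerate first harmonic: cannot normalize")
    # The two remaining candidates differ only in the signs of the even
    # harmonics (the "which end of the major axis is the start" ambiguity).
    # Resolve it with an input-invariant rule: the first significant entry
    # among the even harmonics — probed in order c_n, d_n, a_n, b_n, n = 2,
    # 4, ... — must be positive. For bent (hook-like) shapes c2, the
    # dominant bending coefficient, decides, so the rule is also continuous
    # across a family of hooks of varying curvature and thickness.
    chosen = pair[0]
    if efd.n_harmonics >= 2:
        even_rows = np.arange(1, efd.n_harmonics, 2)  # harmonics 2, 4, ...
        probe = (pair[0][1][even_rows][:, [2, 3, 0, 1]] / lam).ravel()
        sig = np.nonzero(np.abs(probe) > 1e-6)[0]
        if sig.size and probe[sig[0]] < 0:
            chosen = pair[1]
    lam, rotated, psi, th = chosen
    out = rotated / lam
    if abs(out[0, 1]) > 1e-9 or abs(out[0, 2]) > 1e-9:  # pragma: no cover
        raise AssertionError("normalization failed to zero b1/c1")
    out[0, 0] = 1.0
    out[0, 1] = 0.0
    out[0, 2] = 0.0
    return NormalizedEFD(
        out,
        A0=0.0,
        C0=0.0,
        scale=float(lam),
        rotation=float(psi % (2.0 * np.pi)),
        start_shift=float(th % (2.0 * np.pi)),
    )


def reconstruct(efd: EFDCoefficients, n_points: int = 256) -> Outline:
    """Truncated Fourier synthesis of the outline, ``n_points`` vertices."""
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, efd.n_harmonics + 1)[:, None]
    cos_nt = np.cos(n * t)
    sin_nt = np.sin(n * t)
    a, b, c, d = efd.coeffs.T
    x = efd.A0 + a @ cos_nt + b @ sin_nt
    y = efd.C0 + c @ cos_nt + d @ sin_nt
    return Outline(np.column_stack([x, y]))


def harmonic_power(efd: EFDCoefficients) -> tuple[np.ndarray, np.ndarray]:
    """Per-harmonic power (a^2+b^2+c^2+d^2)/2 and its cumulative fraction."""
    power = 0.5 * (efd.coeffs**2).sum(axis=1)
    total = power.sum()
    if total == 0:
        return power, np.zeros_like(power)
    return power, np.cumsum(power) / total


def min_harmonics_for_power(efd: EFDCoefficients, fraction: float = 0.9999) -> int:
    """Smallest N whose cumulative harmonic power reaches ``fraction``."""
    _, cum = harmonic_power(efd)
    idx = np.searchsorted(cum, fraction)
    return int(min(idx + 1, efd.n_harmonics))
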