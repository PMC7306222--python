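"""Core value types: Freeman chain codes, closed outlines, specimen labels.

All in-memory geometry uses mathematical (y-up) coordinates; chain codes as
stored on disk use raster (y-down) coordinates and are converted on load.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class Stage(str, enum.Enum):
    """Ontogenetic stage of a specimen."""

    IMMATURE = "immature"
    ADULT = "adult"


class Site(str, enum.Enum):
    """Host-attachment site of the parasite."""

    MOUTH = "mouth"
    GILL = "gill"
    EXTERNAL = "external"


class Appendage(str, enum.Enum):
    """Pereopod whose dactylus (hook) was outlined."""

    P1 = "P1"
    P6 = "P6"


# Freeman 8-direction steps in image coordinates (x right, y down).
# Code 0 is +x; codes increase counterclockwise in the mathematical sense,
# so code 2 points up the image (-y).
FREEMAN_DX = np.array([1, 1, 0, -1, -1, -1, 0, 1], dtype=int)
FREEMAN_DY_IMAGE = np.array([0, -1, -1, -1, 0, 1, 1, 1], dtype=int)


@dataclass(frozen=True)
class ChainCode:
    """A digitized closed boundary: start pixel plus Freeman 8-direction codes.

    ``start`` is an (x, y) pixel coordinate in image convention (y down,
    0-based). The code sequence must trace back to the start pixel.
    """

    name: str
    start: tuple[int, int]
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "start", (int(self.start[0]), int(self.start[1])))
        if codes.ndim != 1 or codes.size < 4:
            raise ValueError(f"chain '{self.name}': need at least 4 codes")
        if codes.min() < 0 or codes.max() > 7:
            raise ValueError(f"chain '{self.name}': codes must be in 0..7")
        if FREEMAN_DX[codes].sum() != 0 or FREEMAN_DY_IMAGE[codes].sum() != 0:
            raise ValueError(f"chain '{self.name}': chain not closed")

    def __len__(self) -> int:
        return int(self.codes.size)


@dataclass(frozen=True)
class Outline:
    """An implicitly closed polygon (last vertex connects back to the first).

    Vertices are (x, y) in y-up mathematical convention; counterclockwise
    traversal has positive signed area.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("outline needs an (n, 2) array with n >= 3")
        if not np.isfinite(pts).all():
            raise ValueError("outline coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @property
    def segment_vectors(self) -> np.ndarray:
        """Edge vectors including the closing edge, shape (n, 2)."""
        return np.roll(self.points, -1, axis=0) - self.points

    @property
    def segment_lengths(self) -> np.ndarray:
        d = self.segment_vectors
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def perimeter(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        return float(0.5 * np.sum(x * yn - xn * y))

    @property
    def is_ccw(self) -> bool:
        return self.signed_area > 0

    @property
    def centroid(self) -> np.ndarray:
        """Arc-length (perimeter) centroid; matches the EFD offset terms."""
        mid = 0.5 * (self.points + np.roll(self.points, -1, axis=0))
        w = self.segment_lengths
        total = w.sum()
        if total == 0:
            return self.points.mean(axis=0)
        return (mid * w[:, None]).sum(axis=0) / total

    def is_simple(self) -> bool:
        """True if the closed boundary has no self-intersections."""
        from shapely.geometry import LinearRing

        try:
            return bool(LinearRing(self.points).is_simple)
        except Exception:
            return False


@dataclass
class SpecimenRecord:
    """One hook outline (or its EFD) with its biological labels."""

    specimen_id: str
    species: str
    stage: Stage
    site: Site
    appendage: Appendage
    shape: Optional[object] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        self.site = Site(self.site)
        self.appendage = Appendage(self.appendage)
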