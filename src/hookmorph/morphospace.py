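"""PCA morphospace of normalized EFD coefficients.

Each specimen's normalized coefficient set becomes one row of a matrix
(columns a2..aN, b2..bN, c2..cN, d1..dN — a1, b1, c1 are constants after
normalization and are dropped). A covariance PCA of that matrix gives the
morphospace: eigenvalues/variance fractions, specimen scores, loadings and
the mean shape vector. On top of it sit eigen-shape reconstruction (what a
PC axis "looks like"), per-group convex-hull occupation of the score plane,
hull overlaps, and adult-minus-immature displacement vectors whose angular
concentration quantifies whether a shared ontogenetic trajectory exists.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .efd_core import NormalizedEFD, reconstruct
from .shapes import Outline, SpecimenRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CoefficientMatrix",
    "MorphospaceResult",
    "GroupSummary",
    "OntogeneticVector",
    "assemble_matrix",
    "run_pca",
    "eigen_shape",
    "group_hulls",
    "hull_overlap",
    "ontogenetic_vectors",
]

LABEL_COLUMNS = ["species", "stage", "site", "appendage"]


def coefficient_columns(n_harmonics: int) -> list[str]:
    """Fixed column order: a2..aN, b2..bN, c2..cN, d1..dN (4N-3 columns)."""
    cols = [f"a{n}" for n in range(2, n_harmonics + 1)]
    cols += [f"b{n}" for n in range(2, n_harmonics + 1)]
    cols += [f"c{n}" for n in range(2, n_harmonics + 1)]
    cols += [f"d{n}" for n in range(1, n_harmonics + 1)]
    return cols


@dataclass
class CoefficientMatrix:
    """Specimens x coefficients matrix with aligned labels."""

    data: pd.DataFrame
    labels: pd.DataFrame
    n_harmonics: int

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("coefficient matrix contains missing values")
        if not self.data.index.is_unique:
            raise ValueError("specimen ids must be unique")


@dataclass
class MorphospaceResult:
    """PCA of a coefficient matrix: eigenvalues, scores, loadings, mean."""

    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame
    mean_vector: pd.Series
    labels: pd.DataFrame
    n_harmonics: int


@dataclass
class GroupSummary:
    """Convex-hull occupation of one group in a PC plane."""

    key: tuple
    n: int
    hull_area: float
    hull_vertices: np.ndarray
    pc_pair: tuple[int, int] = (1, 2)


@dataclass
class OntogeneticVector:
    """Adult-minus-immature displacement of one species in a PC plane."""

    species: str
    appendage: str
    displacement: np.ndarray
    magnitude: float = field(init=False)
    angle: float = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        self.displacement = d
        self.magnitude = float(np.hypot(*d))
        self.angle = float(np.arctan2(d[1], d[0]))


def assemble_matrix(records: Sequence[SpecimenRecord], n_harmonics: int) -> CoefficientMatrix:
    """Stack normalized EFDs into the fixed-column coefficient matrix.

    Records carrying more harmonics are truncated to ``n_harmonics``; records
    with fewer are an error (named in the message).
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    short = [r.specimen_id for r in records if not isinstance(r.shape, NormalizedEFD)]
    if short:
        raise ValueError(f"records without normalized EFDs: {short}")
    too_few = [r.specimen_id for r in records if r.shape.n_harmonics < n_harmonics]
    if too_few:
        raise ValueError(
            f"records with fewer than {n_harmonics} harmonics: {too_few}"
        )
    cols = coefficient_columns(n_harmonics)
    rows, labels = [], []
    for r in records:
        c = r.shape.coeffs[:n_harmonics]
        rows.append(np.concatenate([c[1:, 0], c[1:, 1], c[1:, 2], c[:, 3]]))
        labels.append(
            {
                "species": r.species,
                "stage": r.stage.value,
                "site": r.site.value,
                "appendage": r.appendage.value,
            }
        )
    index = pd.Index([r.specimen_id for r in records], name="specimen_id")
    data = pd.DataFrame(rows, index=index, columns=cols)
    return CoefficientMatrix(data=data, labels=pd.DataFrame(labels, index=index), n_harmonics=n_harmonics)


def run_pca(matrix: CoefficientMatrix) -> MorphospaceResult:
    """Covariance PCA (full rank) with a deterministic sign convention.

    Each loading is oriented so its largest-magnitude entry is positive.
    A rank-0 (constant) matrix yields all-zero eigenvalues, not an error.
    """
    X = matrix.data.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("PCA needs at least 3 specimens and 2 coefficients")
    from sklearn.decomposition import PCA

    k = min(n, p)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # p x k
    eigenvalues = pca.explained_variance_.copy()
    total = eigenvalues.sum()
    if total <= 1e-30:
        eigenvalues = np.zeros(k)
        frac = np.zeros(k)
        scores = np.zeros_like(scores)
    else:
        frac = eigenvalues / total
    # sign convention: largest-|loading| entry positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    pc_names = [f"PC{j + 1}" for j in range(k)]
    return MorphospaceResult(
        eigenvalues=eigenvalues,
        variance_fraction=frac,
        scores=pd.DataFrame(scores, index=matrix.data.index, columns=pc_names),
        loadings=pd.DataFrame(loadings, index=matrix.data.columns, columns=pc_names),
        mean_vector=pd.Series(pca.mean_, index=matrix.data.columns),
        labels=matrix.labels,
        n_harmonics=matrix.n_harmonics,
    )


def _vector_to_efd(vec: np.ndarray, n_harmonics: int) -> NormalizedEFD:
    """Rebuild an (N, 4) coefficient array from a matrix-row vector."""
    m = n_harmonics - 1
    coeffs = np.zeros((n_harmonics, 4))
    coeffs[0, 0] = 1.0  # a1=1, b1=c1=0 reinserted
    coeffs[1:, 0] = vec[:m]
    coeffs[1:, 1] = vec[m : 2 * m]
    coeffs[1:, 2] = vec[2 * m : 3 * m]
    coeffs[:, 3] = vec[3 * m :]
    return NormalizedEFD(coeffs)


def eigen_shape(
    result: MorphospaceResult,
    component: int,
    k_sd: float,
    n_points: int = 256,
) -> Outline:
    """Mean shape displaced ``k_sd`` score standard deviations along one PC.

    ``component`` is 1-based. ``k_sd = 0`` returns the mean shape.
    """
    if abs(k_sd) > 5:
        raise ValueError("|k_sd| must be <= 5")
    k = result.loadings.shape[1]
    if not 1 <= component <= k:
        raise ValueError(f"component must be in 1..{k}")
    vec = (
        result.mean_vector.to_numpy()
        + k_sd * np.sqrt(result.eigenvalues[component - 1]) * result.loadings.iloc[:, component - 1].to_numpy()
    )
    return reconstruct(_vector_to_efd(vec, result.n_harmonics), n_points=n_points)


def _hull(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Convex hull area and ccw-ordered hull vertices (degenerate -> area 0)."""
    from scipy.spatial import ConvexHull, QhullError

    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return 0.0, pts.copy()
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear / duplicate points
        return 0.0, pts.copy()
    return float(hull.volume), pts[hull.vertices]


def group_hulls(
    result: MorphospaceResult,
    group_by: Sequence[str] | pd.Series = ("site", "stage"),
    pc_pair: tuple[int, int] = (1, 2),
) -> list[GroupSummary]:
    """Convex-hull occupation of each group in the ``pc_pair`` score plane.

    ``group_by`` is either label column names (from species/stage/site/
    appendage) or an explicit per-specimen Series aligned with the scores.
    """
    cols = [f"PC{pc_pair[0]}", f"PC{pc_pair[1]}"]
    pts = result.scores[cols]
    if isinstance(group_by, pd.Series):
        keys = group_by.reindex(pts.index)
        grouped = pts.groupby(keys)
    else:
        keys = result.labels[list(group_by)]
        grouped = pts.groupby([keys[c] for c in keys.columns])
    out = []
    for key, sub in grouped:
        area, verts = _hull(sub.to_numpy())
        out.append(
            GroupSummary(
                key=key if isinstance(key, tuple) else (key,),
                n=len(sub),
                hull_area=area,
                hull_vertices=verts,
                pc_pair=pc_pair,
            )
        )
    return out


def hull_overlap(a: GroupSummary, b: GroupSummary) -> float:
    """Area of intersection of two convex hulls (same PC plane)."""
    if a.pc_pair != b.pc_pair:
        raise ValueError("hulls were computed in different PC planes")
    if a.hull_area == 0.0 or b.hull_area == 0.0:
        return 0.0
    from shapely.geometry import Polygon

    return float(Polygon(a.hull_vertices).intersection(Polygon(b.hull_vertices)).area)


def ontogenetic_vectors(
    result: MorphospaceResult,
    pc_pair: tuple[int, int] = (1, 2),
) -> tuple[list[OntogeneticVector], dict]:
    """Adult-minus-immature displacement per species/appendage pair.

    Returns the vectors and a summary dict with ``n``, ``mean_magnitude``
    and ``rbar`` — the circular concentration of displacement directions,
    |mean unit vector| in [0, 1]. R-bar near 1 means a shared ontogenetic
    trajectory; near 0, none. Species lacking one of the two stages are
    skipped with a logged warning.
    """
    cols = [f"PC{pc_pair[0]}", f"PC{pc_pair[1]}"]
    df = result.scores[cols].join(result.labels)
    vectors: list[OntogeneticVector] = []
    for (species, appendage), sub in df.groupby(["species", "appendage"]):
        stages = sub.groupby("stage")[cols].mean()
        if not {"adult", "immature"}.issubset(stages.index):
            logger.warning(
                "species %s appendage %s: missing a stage, skipped", species, appendage
            )
            continue
        disp = stages.loc["adult"].to_numpy() - stages.loc["immature"].to_numpy()
        vectors.append(OntogeneticVector(species=species, appendage=appendage, displacement=disp))
    if not vectors:
        return vectors, {"n": 0, "mean_magnitude": float("nan"), "rbar": float("nan")}
    mags = np.array([v.magnitude for v in vectors])
    units = np.array(
        [v.displacement / v.magnitude for v in vectors if v.magnitude > 0]
    )
    rbar = float(np.hypot(*units.mean(axis=0))) if len(units) else float("nan")
    return vectors, {"n": len(vectors), "mean_magnitude": float(mags.mean()), "rbar": rbar}
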