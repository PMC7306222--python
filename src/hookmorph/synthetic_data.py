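"""Synthetic hook outlines with controlled curvature and thickness.

A hook is built from a circular-arc centerline of curvature ``kappa`` and
arc length ``L``, a width profile tapering from the base toward the tip,
offset curves on both sides joined by a rounded tip, and a convex cap over
the open proximal base. The two free shape parameters — centerline
curvature and relative thickness — are exactly the features the morphospace
axes are read as (more/less curved, thinner/thicker), which is what makes
parameter-recovery tests of the PC axes meaningful.

:func:`generate_dataset` emulates the comparative design of the study this
package reproduces: 15 species (5 per host-attachment site), both
ontogenetic stages and both pereopod hooks per species, 60 outlines in all,
with site and stage shifting the mean parameters and species adding a
shared random deviation.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import outline_prep
from .outline_prep import BaseSpec, CapKind, canonicalize, resample_equal_arclength
from .shapes import Appendage, Outline, Site, SpecimenRecord, Stage

__all__ = [
    "HookShapeParams",
    "DesignSpec",
    "SyntheticDataset",
    "generate_hook",
    "estimate_curvature_thickness",
    "generate_dataset",
    "rasterize_outline",
    "write_chc",
]

_W_MIN_FRAC = 0.04  # tip width floor, fraction of centerline length


@dataclass(frozen=True)
class HookShapeParams:
    """Generative parameters of one hook outline.

    kappa : centerline curvature (1/length units; 0 = straight blade)
    length : centerline arc length L
    tau : relative thickness, max width / L, in (0.02, 0.6)
    taper : exponent >= 1; width decays toward the tip as (1 - s/L)^taper
    cap_bulge : sagitta/chord of the convex base cap (0.5 = semicircle)
    noise_sd : low-frequency radial noise SD as a fraction of L
    seed : RNG seed for the noise
    """

    kappa: float = 1.5
    length: float = 1.0
    tau: float = 0.28
    taper: float = 1.5
    cap_bulge: float = 0.5
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.kappa * self.length >= 2 * np.pi:
            raise ValueError("kappa * length must be < 2*pi (hook would self-overlap)")
        if not _W_MIN_FRAC < self.tau < 0.6:
            raise ValueError(f"tau must be in ({_W_MIN_FRAC}, 0.6)")
        if self.taper < 1:
            raise ValueError("taper must be >= 1")
        if not 0 <= self.noise_sd < 0.05:
            raise ValueError("noise_sd must be in [0, 0.05)")
        if self.kappa > 0 and self.tau * self.length / 2.0 >= 0.95 / self.kappa:
            raise ValueError("width exceeds curvature radius: offset would self-intersect")


def _centerline(params: HookShapeParams, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Centerline points and unit normals at m arc-length stations."""
    L, k = params.length, params.kappa
    s = np.linspace(0.0, L, m)
    if k < 1e-9:
        pts = np.column_stack([s, np.zeros(m)])
        nrm = np.tile([0.0, 1.0], (m, 1))
    else:
        R = 1.0 / k
        phi = s / R
        pts = np.column_stack([R * np.sin(phi), R * (1.0 - np.cos(phi))])
        nrm = np.column_stack([-np.sin(phi), np.cos(phi)])
    return pts, nrm


def _smooth_radial_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Correlated (low-frequency) noise emulating redrawing error."""
    raw = rng.standard_normal(n)
    half = 24  # correlation length ~8 vertices: smooth redrawing wobble
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / 8.0) ** 2)
    k /= k.sum()
    sm = np.convolve(np.concatenate([raw[-half:], raw, raw[:half]]), k, mode="same")[half:-half]
    std = sm.std()
    return sm * (sd / std) if std > 0 else sm


def generate_hook(params: HookShapeParams, n_points: int = 256) -> Outline:
    """Build one canonical hook outline with ``n_points`` vertices.

    Deterministic for a given (params, n_points); raises if the parameter
    combination produces a self-intersecting outline.
    """
    L = params.length
    m = 160
    center, nrm = _centerline(params, m)
    s = np.linspace(0.0, L, m)
    w_min = _W_MIN_FRAC * L
    w = (params.tau * L - w_min) * (1.0 - s / L) ** params.taper + w_min
    right = center - 0.5 * w[:, None] * nrm
    left = center + 0.5 * w[:, None] * nrm

    # rounded tip: semicircle of radius w(L)/2 from the right to the left side
    tip_c = center[-1]
    if params.kappa < 1e-9:
        tang = np.array([1.0, 0.0])
    else:
        phi_tip = params.kappa * L
        tang = np.array([np.cos(phi_tip), np.sin(phi_tip)])
    tip_n = nrm[-1]
    alphas = np.linspace(-np.pi / 2, np.pi / 2, 17)[1:-1]
    r_tip = 0.5 * w[-1]
    tip = tip_c + r_tip * (np.outer(np.cos(alphas), tang) + np.outer(np.sin(alphas), tip_n))

    open_curve = np.vstack([right, tip, left[::-1]])
    capped = outline_prep.cap_base(
        open_curve, BaseSpec(cap_kind=CapKind.ARC, arc_bulge=params.cap_bulge)
    )
    pts = capped.points
    if params.noise_sd > 0:
        # displace along the local normal (radial w.r.t. the curve): varying
        # tangential displacement would fold the polyline where the line to
        # the centroid grazes the outline
        rng = np.random.default_rng(params.seed)
        tangent = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
        tlen = np.hypot(tangent[:, 0], tangent[:, 1])
        tangent /= np.where(tlen > 0, tlen, 1.0)[:, None]
        normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
        pts = pts + normal * _smooth_radial_noise(len(pts), params.noise_sd * L, rng)[:, None]
    out = canonicalize(resample_equal_arclength(Outline(pts), n_points))
    if not out.is_simple():
        raise ValueError("generated outline self-intersects; reduce noise_sd or tau")
    return out


# ---------------------------------------------------------------------------
# Independent curvature / thickness estimator (medial-axis based)
# ---------------------------------------------------------------------------

def rasterize_outline(outline: Outline, height_px: int = 256, margin: int = 4) -> tuple[np.ndarray, float]:
    """Binary mask of the filled outline and the px-per-unit scale used."""
    from skimage.draw import polygon as draw_polygon

    pts = outline.points
    span_x = np.ptp(pts[:, 0])
    span_y = np.ptp(pts[:, 1])
    span = max(span_x, span_y)
    if span == 0:
        raise ValueError("degenerate outline")
    ppu = (height_px - 2 * margin) / span
    cols = (pts[:, 0] - pts[:, 0].min()) * ppu + margin
    rows = (pts[:, 1].max() - pts[:, 1]) * ppu + margin
    h = int(np.ceil(rows.max())) + margin + 1
    w = int(np.ceil(cols.max())) + margin + 1
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True
    return mask, ppu


def _skeleton_longest_path(skel: np.ndarray) -> list[tuple[int, int]]:
    """Ordered pixel path between the two most distant skeleton endpoints."""
    pix = set(zip(*np.nonzero(skel)))
    if not pix:
        raise ValueError("empty skeleton: not a hook-like outline")

    def neighbors(p):
        r, c = p
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in pix:
                    yield q

    def bfs(src):
        dist = {src: 0.0}
        parent = {src: None}
        queue = deque([src])
        far = src
        while queue:
            p = queue.popleft()
            if dist[p] > dist[far]:
                far = p
            for q in neighbors(p):
                if q not in dist:
                    dist[q] = dist[p] + 1.0
                    parent[q] = p
                    queue.append(q)
        return far, parent

    start = next(iter(pix))
    e1, _ = bfs(start)
    e2, parent = bfs(e1)
    path = []
    p = e2
    while p is not None:
        path.append(p)
        p = parent[p]
    return path


def _circumcircle_curvature(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Curvature 1/R of the circle through three points (0 if collinear)."""
    a = np.hypot(*(p2 - p1))
    b = np.hypot(*(p3 - p2))
    c = np.hypot(*(p3 - p1))
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    area2 = abs(cross)
    if area2 < 1e-12 * max(a * b * c, 1e-300):
        return 0.0
    return 2.0 * area2 / (a * b * c)


def estimate_curvature_thickness(
    outline: Outline, height_px: int = 400
) -> tuple[float, float]:
    """Estimate (kappa_hat, tau_hat) of a hook-like outline.

    Independent of both the generator's construction and the Fourier
    pipeline: the outline is rasterized, its medial axis extracted, and the
    longest skeleton path taken as the centerline. ``kappa_hat`` is the
    curvature of the circle through three points at 15/50/85% of that path;
    ``tau_hat`` is the maximum inscribed width divided by the estimated
    centerline length (path length extended by the inscribed radius at each
    end, since the skeleton retracts from tip and base).
    """
    from skimage.morphology import medial_axis

    mask, ppu = rasterize_outline(outline, height_px=height_px)
    skel, dist = medial_axis(mask, return_distance=True)
    path = _skeleton_longest_path(skel)
    if len(path) < 10:
        raise ValueError("skeleton too short: not a hook-like outline")
    coords = np.asarray(path, dtype=float)
    steps = np.hypot(*(np.diff(coords, axis=0).T))
    cum = np.concatenate(([0.0], np.cumsum(steps)))
    plen = cum[-1]
    idx = [int(np.searchsorted(cum, f * plen)) for f in (0.15, 0.5, 0.85)]
    p1, p2, p3 = (coords[min(i, len(coords) - 1)] for i in idx)
    kappa_px = _circumcircle_curvature(p1, p2, p3)
    kappa_hat = kappa_px * ppu
    r_end1 = dist[path[0]]
    r_end2 = dist[path[-1]]
    L_px = plen + r_end1 + r_end2
    width_px = 2.0 * max(dist[p] for p in path)
    tau_hat = float(width_px / L_px)
    return float(kappa_hat), tau_hat


# ---------------------------------------------------------------------------
# Full study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """The comparative design: sites x species x stages x appendages.

    Defaults emulate the study layout (5 species per attachment site, both
    stages, both pereopod hooks: 60 outlines). ``site_effects`` and
    ``stage_effects`` shift the mean (kappa, tau); species draw one shared
    random deviation (SD ``species_sd``) reused for all four of their
    outlines. ``stage_effect_mode='per_species_random'`` replaces the shared
    stage effect by a per-species random direction of the same magnitude —
    the "no shared ontogenetic trajectory" scenario.
    """

    n_species_per_site: int = 5
    sites: tuple[Site, ...] = (Site.MOUTH, Site.GILL, Site.EXTERNAL)
    stages: tuple[Stage, ...] = (Stage.IMMATURE, Stage.ADULT)
    appendages: tuple[Appendage, ...] = (Appendage.P1, Appendage.P6)
    base_params: HookShapeParams = HookShapeParams(kappa=1.5, tau=0.28, noise_sd=0.005)
    site_effects: dict = field(
        default_factory=lambda: {
            Site.MOUTH: (0.5, 0.05),
            Site.GILL: (0.0, 0.0),
            Site.EXTERNAL: (-0.5, -0.05),
        }
    )
    stage_effects: dict = field(
        default_factory=lambda: {
            Stage.IMMATURE: (-0.25, -0.03),
            Stage.ADULT: (0.25, 0.03),
        }
    )
    species_sd: tuple[float, float] = (0.15, 0.045)
    stage_effect_mode: Literal["shared", "per_species_random"] = "shared"
    n_points: int = 256
    seed: int = 0

    @property
    def n_records(self) -> int:
        return len(self.sites) * self.n_species_per_site * len(self.stages) * len(self.appendages)


@dataclass
class SyntheticDataset:
    """Generated records plus the ground-truth parameter table."""

    records: list[SpecimenRecord]
    truth: pd.DataFrame

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _cell_seed(design_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=design_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(design: DesignSpec = DesignSpec()) -> SyntheticDataset:
    """Generate the full labeled dataset (fully reproducible from the seed)."""
    records: list[SpecimenRecord] = []
    rows = []
    base = design.base_params
    mag = tuple(
        0.5 * abs(design.stage_effects[Stage.ADULT][i] - design.stage_effects[Stage.IMMATURE][i])
        for i in range(2)
    )
    for si, site in enumerate(design.sites):
        for sp in range(design.n_species_per_site):
            sp_rng = np.random.default_rng(_cell_seed(design.seed, 0, si, sp))
            # truncated-normal species effects (+-2.5 SD) keep every cell of
            # the design inside the generator's valid parameter ranges
            dev = np.clip(sp_rng.standard_normal(2), -2.5, 2.5) * np.asarray(design.species_sd)
            phi = sp_rng.uniform(0.0, 2.0 * np.pi)
            species = f"{site.value}_sp{sp + 1}"
            for sti, stage in enumerate(design.stages):
                if design.stage_effect_mode == "shared":
                    eff = design.stage_effects[stage]
                else:
                    sign = 1.0 if stage is Stage.ADULT else -1.0
                    eff = (sign * mag[0] * np.cos(phi), sign * mag[1] * np.sin(phi))
                for ai, appendage in enumerate(design.appendages):
                    kappa = base.kappa + design.site_effects[site][0] + eff[0] + dev[0]
                    tau = base.tau + design.site_effects[site][1] + eff[1] + dev[1]
                    cell = f"{species}/{stage.value}/{appendage.value}"
                    try:
                        params = replace(
                            base,
                            kappa=kappa,
                            tau=tau,
                            seed=_cell_seed(design.seed, 1, si, sp, sti, ai),
                        )
                    except ValueError as exc:
                        raise ValueError(f"cell {cell}: {exc}") from exc
                    outline = generate_hook(params, n_points=design.n_points)
                    rec = SpecimenRecord(
                        specimen_id=f"{species}_{stage.value}_{appendage.value}",
                        species=species,
                        stage=stage,
                        site=site,
                        appendage=appendage,
                        shape=outline,
                        extra={"params": params},
                    )
                    records.append(rec)
                    rows.append(
                        {
                            "specimen_id": rec.specimen_id,
                            "species": species,
                            "stage": stage.value,
                            "site": site.value,
                            "appendage": appendage.value,
                            "kappa": kappa,
                            "tau": tau,
                            "length": base.length,
                        }
                    )
    truth = pd.DataFrame(rows).set_index("specimen_id")
    return SyntheticDataset(records=records, truth=truth)


def write_chc(records: Sequence[SpecimenRecord], target, px_height: int = 200) -> None:
    """Digitize record outlines to pixel chains and write a ``.chc`` file."""
    from .io_formats import outline_to_chain, trace_boundary, write_chain_codes

    chains = []
    for rec in records:
        mask, _ = rasterize_outline(rec.shape, height_px=px_height)
        boundary = trace_boundary(mask)
        chains.append(outline_to_chain(boundary, name=rec.specimen_id))
    write_chain_codes(chains, target)
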