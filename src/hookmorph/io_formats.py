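"""Readers and writers for every on-disk form the pipeline touches.

Formats (all plain text, record oriented):

``.chc`` chain-code files
    Per record: a name line; a start-pixel line ``x y`` (image coordinates,
    y down, 0-based); whitespace-separated Freeman codes (0..7) terminated
    by the sentinel ``-1``, possibly spanning several lines. Lines starting
    with ``#`` are comments when ``allow_comments`` is set (the default).

``.nef`` normalized-EFD files
    Per record: a name line; a line with the harmonic count N; N lines of
    four reals ``a_n b_n c_n d_n``.

Outlines travel as 2-column CSV (``x,y`` header), specimen metadata as
CSV/TSV with columns specimen_id, species, stage, site, appendage, and
binary masks as PNG/TIFF rasters or plain 0/1 text grids.
"""
from __future__ import annotations

import io
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .efd_core import NormalizedEFD
from .shapes import (
    FREEMAN_DX,
    FREEMAN_DY_IMAGE,
    Appendage,
    ChainCode,
    Outline,
    Site,
    SpecimenRecord,
    Stage,
)

PathOrStream = Union[str, Path, IO[str]]


def _open_text(source: PathOrStream, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def _logical_lines(stream: IO[str], allow_comments: bool) -> list[tuple[int, str]]:
    out = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if allow_comments and line.startswith("#"):
            continue
        out.append((lineno, line))
    return out


# ---------------------------------------------------------------------------
# Freeman chain codes
# ---------------------------------------------------------------------------

def read_chain_codes(source: PathOrStream, allow_comments: bool = True) -> list[ChainCode]:
    """Parse a ``.chc`` stream into :class:`ChainCode` records (file order)."""
    stream, close = _open_text(source)
    try:
        lines = _logical_lines(stream, allow_comments)
    finally:
        if close:
            stream.close()
    records: list[ChainCode] = []
    i = 0
    while i < len(lines):
        _, name = lines[i]
        if i + 1 >= len(lines):
            raise ValueError(f"record '{name}': missing start-coordinate line")
        lineno, start_line = lines[i + 1]
        parts = start_line.split()
        if len(parts) != 2:
            raise ValueError(f"record '{name}' line {lineno}: expected 'x y' start coordinates")
        try:
            start = (int(parts[0]), int(parts[1]))
        except ValueError as exc:
            raise ValueError(f"record '{name}' line {lineno}: non-integer start coordinates") from exc
        codes: list[int] = []
        i += 2
        terminated = False
        while i < len(lines):
            lineno, line = lines[i]
            for tok in line.split():
                try:
                    val = int(tok)
                except ValueError as exc:
                    raise ValueError(f"record '{name}' line {lineno}: bad code token {tok!r}") from exc
                if val == -1:
                    terminated = True
                    break
                if not 0 <= val <= 7:
                    raise ValueError(f"record '{name}' line {lineno}: code {val} outside 0..7")
                codes.append(val)
            i += 1
            if terminated:
                break
        if not terminated:
            raise ValueError(f"record '{name}': missing -1 sentinel")
        records.append(ChainCode(name=name, start=start, codes=np.asarray(codes)))
    return records


def write_chain_codes(records: Iterable[ChainCode], target: PathOrStream, codes_per_line: int = 30) -> None:
    """Write records in the ``.chc`` dialect read by :func:`read_chain_codes`."""
    stream, close = _open_text(target, "w")
    try:
        for rec in records:
            stream.write(f"{rec.name}\n{rec.start[0]} {rec.start[1]}\n")
            codes = list(map(str, rec.codes)) + ["-1"]
            for j in range(0, len(codes), codes_per_line):
                stream.write(" ".join(codes[j : j + codes_per_line]) + "\n")
    finally:
        if close:
            stream.close()


def chain_to_outline(chain: ChainCode) -> Outline:
    """Trace a chain into a y-up outline (duplicate terminal vertex dropped)."""
    dx = FREEMAN_DX[chain.codes]
    dy = -FREEMAN_DY_IMAGE[chain.codes]  # image y-down -> math y-up
    x = chain.start[0] + np.concatenate(([0], np.cumsum(dx)))[:-1]
    y = -chain.start[1] + np.concatenate(([0], np.cumsum(dy)))[:-1]
    return Outline(np.column_stack([x, y]).astype(float))


def outline_to_chain(outline: Outline, name: str = "outline") -> ChainCode:
    """Encode a pixel-grid outline (unit/diagonal steps) as a chain code."""
    pts = outline.points
    ipts = np.rint(pts).astype(int)
    if not np.allclose(pts, ipts, atol=1e-9):
        raise ValueError("outline vertices must lie on the integer pixel grid")
    steps = np.roll(ipts, -1, axis=0) - ipts
    codes = np.empty(len(steps), dtype=int)
    lut = {(1, 0): 0, (1, 1): 1, (0, 1): 2, (-1, 1): 3, (-1, 0): 4, (-1, -1): 5, (0, -1): 6, (1, -1): 7}
    for i, (sx, sy) in enumerate(steps):
        key = (int(sx), int(sy))
        if key not in lut:
            raise ValueError(f"step {i} of {key} is not a Freeman unit step")
        codes[i] = lut[key]
    return ChainCode(name=name, start=(int(ipts[0, 0]), int(-ipts[0, 1])), codes=codes)


# ---------------------------------------------------------------------------
# Boundary tracing of binary masks
# ---------------------------------------------------------------------------

# Moore neighborhood in clockwise order (image coordinates, row down),
# starting from west.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> Outline:
    """Outer boundary of the single foreground component of a binary mask.

    Moore-neighbor tracing with Jacob's stopping criterion; the result is a
    closed, counterclockwise outline through pixel centers in y-up
    coordinates (x = column, y = -row).
    """
    from skimage.measure import label

    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
        raise ValueError("mask border pixels must be background")
    lab, n_comp = label(m, connectivity=2, return_num=True)
    if n_comp == 0:
        raise ValueError("no foreground component")
    if n_comp > 1:
        raise ValueError(f"expected one foreground component, found {n_comp}")

    # start: first foreground pixel in row-major scan; its west neighbor is
    # background by construction
    rows, cols = np.nonzero(m)
    order = np.lexsort((cols, rows))
    s = (int(rows[order[0]]), int(cols[order[0]]))
    b = (s[0], s[1] - 1)

    contour = [s]
    p, backtrack = s, b
    first_entry = b
    max_steps = 4 * m.size
    while len(contour) <= max_steps:
        # index of backtrack in the Moore neighborhood of p
        off = (backtrack[0] - p[0], backtrack[1] - p[1])
        start_idx = _MOORE.index(off)
        nxt = None
        for j in range(1, 9):
            cand_off = _MOORE[(start_idx + j) % 8]
            cand = (p[0] + cand_off[0], p[1] + cand_off[1])
            if m[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel
            break
        if nxt == s and backtrack == first_entry:
            break  # Jacob's criterion: re-entered the start the same way
        contour.append(nxt)
        p = nxt

    pts = np.array([(c, -r) for r, c in contour], dtype=float)
    # drop consecutive duplicates (single-pixel spurs revisit pixels; keep them)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    if len(pts) >= 2 and np.all(pts[0] == pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("foreground component too small to trace")
    outline = Outline(pts)
    if not outline.is_ccw:
        outline = Outline(pts[::-1])
    return outline


def read_mask(source: Union[str, Path]) -> np.ndarray:
    """Load a binary mask from a PNG/TIFF raster or a 0/1 text grid."""
    path = Path(source)
    if path.suffix.lower() in {".txt", ".dat", ".grid"}:
        return np.loadtxt(path, dtype=int).astype(bool)
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img > (img.max() / 2 if img.max() > 1 else 0)


# ---------------------------------------------------------------------------
# Normalized-EFD (.nef) files
# ---------------------------------------------------------------------------

def read_nef(
    source: PathOrStream, allow_comments: bool = True, check_normalized: bool = True
) -> list[tuple[str, NormalizedEFD]]:
    """Parse a ``.nef`` stream into (name, :class:`NormalizedEFD`) pairs."""
    stream, close = _open_text(source)
    try:
        lines = _logical_lines(stream, allow_comments)
    finally:
        if close:
            stream.close()
    records: list[tuple[str, NormalizedEFD]] = []
    i = 0
    while i < len(lines):
        _, name = lines[i]
        if i + 1 >= len(lines):
            raise ValueError(f"record '{name}': missing harmonic-count line")
        lineno, count_line = lines[i + 1]
        try:
            n_harm = int(count_line.split()[0])
        except ValueError as exc:
            raise ValueError(f"record '{name}' line {lineno}: bad harmonic count") from exc
        rows = []
        for j in range(n_harm):
            if i + 2 + j >= len(lines):
                raise ValueError(f"record '{name}': expected {n_harm} coefficient rows")
            lineno, row_line = lines[i + 2 + j]
            parts = row_line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"record '{name}' line {lineno}: expected 4 coefficients, got {len(parts)}"
                )
            rows.append([float(p) for p in parts])
        efd = NormalizedEFD(np.asarray(rows))
        if check_normalized:
            try:
                efd.check(atol=1e-4)
            except ValueError as exc:
                raise ValueError(f"record '{name}': {exc}") from exc
        records.append((name, efd))
        i += 2 + n_harm
    return records


def write_nef(records: Iterable[tuple[str, NormalizedEFD]], target: PathOrStream) -> None:
    """Write (name, EFD) pairs in the ``.nef`` dialect (10 significant digits)."""
    stream, close = _open_text(target, "w")
    try:
        for name, efd in records:
            stream.write(f"{name}\n{efd.n_harmonics}\n")
            for row in efd.coeffs:
                stream.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Outline CSV and specimen metadata
# ---------------------------------------------------------------------------

def read_outline_csv(source: PathOrStream) -> Outline:
    """Read an outline from a 2-column CSV with an ``x,y`` header."""
    df = pd.read_csv(source)
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError("outline CSV must have columns 'x' and 'y'")
    return Outline(df[[cols["x"], cols["y"]]].to_numpy(dtype=float))


def write_outline_csv(outline: Outline, target: PathOrStream) -> None:
    pd.DataFrame(outline.points, columns=["x", "y"]).to_csv(target, index=False)


_REQUIRED_META = ["specimen_id", "species", "stage", "site", "appendage"]


def read_metadata(source: PathOrStream) -> list[SpecimenRecord]:
    """Read a specimen table into :class:`SpecimenRecord` stubs (shape=None).

    Accepts CSV or TSV; headers are matched case-insensitively; stage, site
    and appendage values are validated against their permitted vocabularies.
    """
    df = pd.read_csv(source, sep=None, engine="python")
    rename = {}
    lower = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in _REQUIRED_META if c not in lower]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    for want in _REQUIRED_META:
        rename[lower[want]] = want
    df = df.rename(columns=rename)
    ids = df["specimen_id"].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate specimen_id values: {list(dup)}")
    records = []
    for _, row in df.iterrows():
        try:
            stage = Stage(str(row["stage"]).strip().lower())
        except ValueError:
            raise ValueError(
                f"specimen {row['specimen_id']}: unknown stage {row['stage']!r}; "
                f"permitted: {[s.value for s in Stage]}"
            ) from None
        try:
            site = Site(str(row["site"]).strip().lower())
        except ValueError:
            raise ValueError(
                f"specimen {row['specimen_id']}: unknown site {row['site']!r}; "
                f"permitted: {[s.value for s in Site]}"
            ) from None
        try:
            appendage = Appendage(str(row["appendage"]).strip().upper())
        except ValueError:
            raise ValueError(
                f"specimen {row['specimen_id']}: unknown appendage {row['appendage']!r}; "
                f"permitted: {[a.value for a in Appendage]}"
            ) from None
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                species=str(row["species"]),
                stage=stage,
                site=site,
                appendage=appendage,
            )
        )
    return records


def write_metadata(records: Iterable[SpecimenRecord], target: PathOrStream) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "species": r.species,
            "stage": r.stage.value,
            "site": r.site.value,
            "appendage": r.appendage.value,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(target, index=False)
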