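"""Closed artifact outlines: I/O, raster extraction, resampling, orientation.

The canonical object is a :class:`Contour` — an ordered, closed polygon of
2-D vertices in millimetres, counterclockwise in y-up coordinates, with
vertex 1 (``tip_index``) at the sharpest point after :func:`orient_contour`.
Downstream modules (symmetry, Fourier shape space) assume contours have been
resampled to an even number of equally arc-length-spaced vertices.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .exceptions import (
    DegenerateContourError,
    DuplicateRecordError,
    ExtractionError,
    ParameterError,
    ParseError,
)

VIEWS = ("top", "lateral", "frontal")

XY_HEADER = ["artifact_id", "view", "x", "y"]


# ---------------------------------------------------------------------------
# Core data types


@dataclass
class Contour:
    """An ordered closed 2-D vertex sequence for one artifact view.

    Parameters
    ----------
    artifact_id : str
        Identifier of the artifact the outline belongs to.
    view : str
        One of ``top``, ``lateral``, ``frontal``.
    vertices : (N, 2) ndarray
        Vertex coordinates in mm, y-up. The polygon is implicitly closed:
        the last vertex connects back to the first.
    closed : bool
        Always true for valid contours; kept explicit for I/O round trips.
    tip_index : int
        1-based ordinal of the sharpest vertex. ``orient_contour`` rotates
        the sequence so this becomes 1.
    """

    artifact_id: str
    view: str
    vertices: np.ndarray
    closed: bool = True
    tip_index: int = 1

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ParameterError("vertices must be an (N, 2) array")

    @property
    def n(self) -> int:
        return len(self.vertices)

    def copy(self) -> "Contour":
        return replace(self, vertices=self.vertices.copy())

    def with_vertices(self, vertices: np.ndarray) -> "Contour":
        return replace(self, vertices=np.asarray(vertices, dtype=float))


@dataclass
class RasterMask:
    """Binary (or grayscale) silhouette image with physical scale.

    ``origin`` is the (x, y) mm coordinate of the lower-left pixel corner,
    so contours extracted from a mask produced by
    :func:`lithosym.synthetic_data.rasterize_outline` land in the source
    coordinate frame.
    """

    pixels: np.ndarray
    scale: float = 1.0  # mm per pixel
    origin: tuple = (0.0, 0.0)


@dataclass
class OutlineSet:
    """A list of contours plus a metadata table keyed by (artifact_id, view)."""

    contours: list = field(default_factory=list)
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        keys = [(c.artifact_id, c.view) for c in self.contours]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise DuplicateRecordError(f"duplicate (artifact_id, view) records: {sorted(dupes)}")
        for c in self.contours:
            if c.view not in VIEWS:
                raise ParameterError(f"unknown view {c.view!r} for {c.artifact_id!r}")

    def __iter__(self):
        return iter(self.contours)

    def __len__(self):
        return len(self.contours)

    def get(self, artifact_id: str, view: str) -> Contour:
        for c in self.contours:
            if c.artifact_id == artifact_id and c.view == view:
                return c
        raise KeyError((artifact_id, view))

    def views_of(self, artifact_id: str) -> dict:
        return {c.view: c for c in self.contours if c.artifact_id == artifact_id}

    @property
    def artifact_ids(self) -> list:
        seen = dict.fromkeys(c.artifact_id for c in self.contours)
        return list(seen)


# ---------------------------------------------------------------------------
# Basic polygon helpers


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area; positive for counterclockwise traversal."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    return float(np.sum(np.hypot(*(np.roll(v, -1, axis=0) - v).T)))


def ensure_ccw(c: Contour) -> Contour:
    """Reverse vertex order if traversal is clockwise (negative area)."""
    if signed_area(c.vertices) < 0:
        return c.with_vertices(c.vertices[::-1])
    return c


def _dedupe_consecutive(vertices: np.ndarray) -> np.ndarray:
    d = np.hypot(*(np.roll(vertices, -1, axis=0) - vertices).T)
    keep = d > 1e-12
    if not np.all(keep):
        vertices = vertices[keep]
    return vertices


# ---------------------------------------------------------------------------
# I/O


def read_contours(path, format: str = "xy", metadata: pd.DataFrame | None = None) -> OutlineSet:
    """Read closed outlines from a delimited xy file or a TPS outline file.

    The xy dialect is comma-separated with header
    ``artifact_id,view,x,y``; vertices appear in file order and each
    (artifact_id, view) block must be contiguous and unique.
    """
    if format == "xy":
        contours = _read_xy(path)
    elif format == "tps":
        contours = _read_tps(path)
    else:
        raise ParameterError(f"unknown outline format {format!r}")
    return OutlineSet(contours=contours, metadata=metadata if metadata is not None else pd.DataFrame())


def _read_xy(path) -> list:
    contours = []
    seen = set()
    cur_key, cur_pts = None, []

    def flush():
        if cur_key is not None:
            if cur_key in seen:
                raise DuplicateRecordError(f"duplicate (artifact_id, view) record: {cur_key}")
            seen.add(cur_key)
            contours.append(Contour(cur_key[0], cur_key[1], np.array(cur_pts)))

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != XY_HEADER:
            raise ParseError(f"{path}: expected header {','.join(XY_HEADER)!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            aid, view = row[0].strip(), row[1].strip()
            try:
                x, y = float(row[2]), float(row[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate: {exc}") from None
            key = (aid, view)
            if key != cur_key:
                flush()
                cur_key, cur_pts = key, []
            cur_pts.append((x, y))
        flush()
    return contours


def _read_tps(path) -> list:
    """Minimal TPS outline reader: OUTLINES=/POINTS= records closed by ID=."""
    contours = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i, pending = 0, []
    while i < len(lines):
        ln = lines[i]
        up = ln.upper()
        if up.startswith("OUTLINES="):
            i += 1
        elif up.startswith("POINTS="):
            try:
                npts = int(ln.split("=", 1)[1])
            except ValueError:
                raise ParseError(f"{path}: bad POINTS record {ln!r}") from None
            pts = []
            for j in range(npts):
                i += 1
                if i >= len(lines):
                    raise ParseError(f"{path}: truncated POINTS block")
                try:
                    x, y = map(float, lines[i].split())
                except ValueError:
                    raise ParseError(f"{path}: bad coordinate line {lines[i]!r}") from None
                pts.append((x, y))
            pending.append(np.array(pts))
            i += 1
        elif up.startswith("ID="):
            ident = ln.split("=", 1)[1].strip()
            aid, view = ident, "top"
            for v in VIEWS:
                if ident.endswith("_" + v):
                    aid, view = ident[: -(len(v) + 1)], v
            for k, pts in enumerate(pending):
                cid = aid if len(pending) == 1 else f"{aid}.{k + 1}"
                contours.append(Contour(cid, view, pts))
            pending = []
            i += 1
        elif up.startswith(("LM=", "IMAGE=", "SCALE=")):
            i += 1
        else:
            raise ParseError(f"{path}: unrecognised TPS record {ln!r}")
    if pending:
        raise ParseError(f"{path}: OUTLINES block without closing ID= record")
    return contours


def write_contours(oset: OutlineSet, path, format: str = "xy") -> None:
    """Write an OutlineSet so that ``read_contours`` round-trips exactly."""
    if format == "xy":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(XY_HEADER)
            for c in oset:
                for x, y in c.vertices:
                    w.writerow([c.artifact_id, c.view, repr(float(x)), repr(float(y))])
    elif format == "tps":
        with open(path, "w") as fh:
            for c in oset:
                fh.write("OUTLINES=1\n")
                fh.write(f"POINTS={c.n}\n")
                for x, y in c.vertices:
                    fh.write(f"{float(x)!r} {float(y)!r}\n")
                fh.write(f"ID={c.artifact_id}_{c.view}\n")
    else:
        raise ParameterError(f"unknown outline format {format!r}")


# ---------------------------------------------------------------------------
# Raster extraction


def extract_contour(
    mask: RasterMask,
    threshold_policy: str | float = "otsu",
    artifact_id: str = "unknown",
    view: str = "top",
) -> Contour:
    """Trace the boundary of the largest foreground component of a mask.

    The image is thresholded (Otsu by default, or at a fixed value), holes
    are filled, the largest connected component is kept, and its boundary is
    returned as a closed counterclockwise polygon in y-up mm coordinates
    (image rows flipped, scaled by ``mask.scale``, offset by ``mask.origin``).
    """
    img = np.asarray(mask.pixels)
    if img.dtype == bool:
        fg = img
    elif threshold_policy == "otsu":
        if img.min() == img.max():
            raise ExtractionError("constant image: cannot threshold")
        fg = img > threshold_otsu(img)
    elif isinstance(threshold_policy, (int, float)):
        fg = img > float(threshold_policy)
    else:
        raise ParameterError(f"unknown threshold policy {threshold_policy!r}")

    if not fg.any():
        raise ExtractionError("no foreground pixels after thresholding")
    border = np.concatenate([fg[0], fg[-1], fg[:, 0], fg[:, -1]])
    if border.any():
        warnings.warn("foreground touches the image border; contour may be clipped")

    fg = ndimage.binary_fill_holes(fg)
    labels, nlab = ndimage.label(fg)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
        fg = labels == (1 + int(np.argmax(sizes)))

    # Sub-pixel boundary at level 0.5 on the padded mask (padding guards
    # against components touching the border).
    padded = np.pad(fg, 1)
    rings = measure.find_contours(padded.astype(float), 0.5)
    ring = max(rings, key=len)
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    rows, cols = ring[:, 0] - 1.0, ring[:, 1] - 1.0
    h = fg.shape[0]
    x = cols * mask.scale + mask.origin[0]
    y = (h - 1 - rows) * mask.scale + mask.origin[1]
    verts = _dedupe_consecutive(np.column_stack([x, y]))
    return ensure_ccw(Contour(artifact_id, view, verts))


# ---------------------------------------------------------------------------
# Resampling and orientation


def resample_contour(c: Contour, n: int) -> Contour:
    """Resample a closed contour to ``n`` vertices equally spaced by arc length.

    The first output vertex coincides with the input's first vertex, so a
    tip-anchored correspondence survives resampling.
    """
    if n % 2 != 0:
        raise ParameterError("n must be even (the mirror-pairing scheme requires it)")
    if n < 8:
        raise ParameterError("n must be at least 8")
    v = _dedupe_consecutive(np.asarray(c.vertices, dtype=float))
    if len(v) < 3:
        raise DegenerateContourError("contour has fewer than 3 distinct vertices")
    closed = np.vstack([v, v[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        raise DegenerateContourError("zero-perimeter contour")
    stations = np.arange(n) * total / n
    x = np.interp(stations, t, closed[:, 0])
    y = np.interp(stations, t, closed[:, 1])
    return c.with_vertices(np.column_stack([x, y]))


def vertex_sharpness(vertices: np.ndarray, window: int = 2) -> np.ndarray:
    """Discrete curvature proxy: exterior turning angle at each vertex,
    averaged over a ±``window`` vertex neighbourhood.

    Positive values are convex for counterclockwise traversal; the sharpest
    vertex is the maximum.
    """
    v = np.asarray(vertices, dtype=float)
    fwd = np.roll(v, -1, axis=0) - v
    bwd = v - np.roll(v, 1, axis=0)
    ang = np.arctan2(
        bwd[:, 0] * fwd[:, 1] - bwd[:, 1] * fwd[:, 0],
        bwd[:, 0] * fwd[:, 0] + bwd[:, 1] * fwd[:, 1],
    )
    kernel = np.zeros(len(v))
    kernel[: window + 1] = 1.0
    kernel[-window:] = 1.0
    # circular moving average via FFT-free convolution on the ring
    smoothed = np.real(np.fft.ifft(np.fft.fft(ang) * np.fft.fft(kernel))) / (2 * window + 1)
    return smoothed


def orient_contour(c: Contour) -> Contour:
    """Rotate a contour to canonical pose and renumber its vertices.

    After orientation the major principal axis of the vertices is
    horizontal, the sharper end sits at +x, traversal is counterclockwise,
    and the sharpest vertex is vertex 1 (``tip_index == 1``). A perfectly
    isotropic contour (circle) triggers a deterministic tie-break on the
    lowest original vertex index, with a warning.
    """
    c = ensure_ccw(c)
    v = np.asarray(c.vertices, dtype=float)
    centroid = v.mean(axis=0)
    x = v - centroid

    cov = x.T @ x / len(x)
    evals, evecs = np.linalg.eigh(cov)
    if evals.max() - evals.min() > 1e-12 * evals.max():
        major = evecs[:, int(np.argmax(evals))]
        theta = np.arctan2(major[1], major[0])
        if theta <= -np.pi / 2:
            theta += np.pi
        elif theta > np.pi / 2:
            theta -= np.pi
        rot = np.array([[np.cos(-theta), -np.sin(-theta)], [np.sin(-theta), np.cos(-theta)]])
        x = x @ rot.T
    # isotropic vertex clouds (circles) have no principal axis: left unrotated

    sharp = vertex_sharpness(x)
    if sharp.max() - sharp.min() < 1e-9:
        warnings.warn("isotropic contour: curvature tie broken on lowest vertex index")
        tip = 0
    else:
        tip = int(np.argmax(sharp))
        if x[tip, 0] < 0:  # sharper end to +x
            x = -x
        # recompute in case the flip moved the argmax among near-ties
        tip = int(np.argmax(vertex_sharpness(x)))

    x = np.roll(x, -tip, axis=0)
    out = c.with_vertices(x)  # canonical pose is centered on the centroid
    out.tip_index = 1
    return ensure_ccw(out)


# ---------------------------------------------------------------------------
# Metrics


def contour_metrics(c: Contour) -> dict:
    """Centroid, centroid size, area and perimeter of a closed contour.

    The centroid is the mean vertex — the same reference point the symmetry
    measure normalizes by — and the centroid size is the root summed squared
    deviation of the vertices from it, the standard morphometric size.
    """
    v = np.asarray(c.vertices, dtype=float)
    centroid = v.mean(axis=0)
    dev = v - centroid
    size = float(np.sqrt(np.sum(dev**2)))
    if size <= 0:
        raise DegenerateContourError("all vertices coincide: zero centroid size")
    return {
        "centroid": centroid,
        "centroid_size": size,
        "area": abs(signed_area(v)),
        "perimeter": perimeter(v),
    }


def centroid_size(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    dev = v - v.mean(axis=0)
    return float(np.sqrt(np.sum(dev**2)))
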