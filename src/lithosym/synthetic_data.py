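"""Synthetic handaxe-outline assemblages with known ground truth.

The generator emulates the design of a multi-assemblage outline study:
three orthogonal views per artifact, assemblage-level differences in mean
asymmetry, an elongation-refinement covariance, tip-reduction series, and
retouch-invasiveness scores that rise with reduction stage. Shapes come
from a two-parameter "egg curve"

    x(t) = (L/2) cos t,   y(t) = (W/2) sin t (1 + p cos t)

which is mirror-symmetric about the x axis for any pointedness p in
[0, 0.9) and has its sharpest point (the tip) at t = 0. Asymmetry of known
magnitude is injected on top (shear, differential edge scaling, or tip
rotation), so every pipeline estimate — minimal S, best axis, axis class,
elongation PCs, size-reduction slopes — has a recorded true value.

No claim is made that the egg family matches real handaxe shape
distributions; it provides controlled, recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LinearRing
from skimage.draw import polygon as draw_polygon

from .exceptions import ParameterError, SelfIntersectionError
from .outlines import Contour, OutlineSet, RasterMask, resample_contour

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "base_outline",
    "inject_asymmetry",
    "reduction_series",
    "generate_assemblage",
    "rasterize_outline",
]

_DENSE = 720  # parameter samples before arc-length resampling


@dataclass
class GroupSpec:
    """Parameters of one synthetic assemblage.

    Lengths are mm. ``asymmetry`` is the dimensionless magnitude passed to
    :func:`inject_asymmetry`; ``latitudinal_fraction`` is the probability
    that an artifact is built with its mirror axis across, rather than
    along, the long axis. ``elongation_refinement_rho`` couples log
    elongation to log refinement (more elongated pieces are flatter).
    """

    name: str
    n: int
    length_mean: float = 120.0
    length_cv: float = 0.15
    elongation_mean: float = 1.7
    elongation_cv: float = 0.12
    thickness_ratio: float = 0.45  # frontal thickness / width
    pointedness: float = 0.4
    asymmetry: float = 0.1
    asymmetry_mode: str = "shear"
    latitudinal_fraction: float = 0.15
    noise_sd: float = 0.5  # mm, isotropic per-vertex
    elongation_refinement_rho: float = 0.4
    stage_dist: str = "uniform"  # reduction stage in [0, 1]


@dataclass
class SyntheticSpec:
    """Full dataset specification: groups, views, vertex count, seed."""

    groups: list
    seed: int
    n_points: int = 60
    views: tuple = ("top", "lateral", "frontal")

    def __post_init__(self):
        if self.seed is None:
            raise ParameterError("a seed is mandatory for reproducible generation")
        if self.n_points % 2 != 0 or self.n_points < 8:
            raise ParameterError("n_points must be even and >= 8")


def base_outline(L: float, W: float, p: float, n: int = 60,
                 artifact_id: str = "synthetic", view: str = "top") -> Contour:
    """Egg-curve outline: length L, width W, pointedness p, n vertices.

    Sampled at n equal arc-length stations with the first vertex at the
    tip (t = 0); mirror-symmetric about the x axis by construction.
    """
    if L <= 0 or W <= 0:
        raise ParameterError("L and W must be positive")
    if not 0 <= p < 0.9:
        raise ParameterError("pointedness must be in [0, 0.9)")
    if n % 2 != 0 or n < 8:
        raise ParameterError("n must be even and >= 8")
    t = 2 * np.pi * np.arange(_DENSE) / _DENSE
    x = (L / 2) * np.cos(t)
    y = (W / 2) * np.sin(t) * (1 + p * np.cos(t))
    dense = Contour(artifact_id, view, np.column_stack([x, y]))
    return resample_contour(dense, n)


def _transverse_outline(L: float, W: float, p: float, q: float, n: int,
                        artifact_id: str, view: str) -> Contour:
    """Egg-like outline symmetric across, not along, its long axis.

    The cross-axis modulation q bulges the upper edge while preserving the
    left-right mirror exactly; a small pointedness p keeps the tip
    identifiable at +x. Used for latitudinal-axis ground truth.
    """
    t = 2 * np.pi * np.arange(_DENSE) / _DENSE
    x = (L / 2) * np.cos(t)
    y = (W / 2) * np.sin(t) * (1 + p * np.cos(t)) * (1 + q * np.sin(t))
    dense = Contour(artifact_id, view, np.column_stack([x, y]))
    return resample_contour(dense, n)


def _check_simple(vertices: np.ndarray, context: str):
    if not LinearRing(vertices).is_simple:
        raise SelfIntersectionError(f"{context} produced a self-intersecting outline")


def inject_asymmetry(c: Contour, mode: str, alpha: float) -> Contour:
    """Deform a contour by a controlled asymmetry of magnitude alpha.

    ``shear``: x' = x + alpha * y (about the centroid).
    ``differential_edge``: the upper edge (y above the centroid) is scaled
    by 1 + alpha, emulating one working edge retouched harder.
    ``tip_offset``: the tip half (x above the centroid) is rotated by
    alpha radians about the centroid.
    alpha = 0 returns the input unchanged. Deformations that make the
    outline self-intersect are rejected.
    """
    if alpha < 0:
        raise ParameterError("alpha must be nonnegative")
    if alpha == 0:
        return c.copy()
    v = np.asarray(c.vertices, dtype=float).copy()
    ctr = v.mean(axis=0)
    v -= ctr
    if mode == "shear":
        v[:, 0] = v[:, 0] + alpha * v[:, 1]
    elif mode == "differential_edge":
        upper = v[:, 1] > 0
        v[upper, 1] *= 1 + alpha
    elif mode == "tip_offset":
        tip_half = v[:, 0] > 0
        ca, sa = np.cos(alpha), np.sin(alpha)
        rot = np.array([[ca, -sa], [sa, ca]])
        v[tip_half] = v[tip_half] @ rot.T
    else:
        raise ParameterError(f"unknown asymmetry mode {mode!r}")
    v += ctr
    _check_simple(v, f"inject_asymmetry({mode}, {alpha})")
    return c.with_vertices(v)


def _truncate_tip(c: Contour, stage: float) -> Contour:
    """Remove the tip beyond x = (1 - 0.4 stage) x_max and cap with an arc.

    The circular-arc cap bulges outward with sagitta equal to half the
    truncation depth, so total length — and with it centroid size and
    elongation — decreases strictly with stage.
    """
    v = np.asarray(c.vertices, dtype=float)
    ctr = v.mean(axis=0)
    x = v - ctr
    xmax = x[:, 0].max()
    xcut = (1 - 0.4 * stage) * xmax
    inside = x[:, 0] <= xcut
    if not inside.any():
        raise ParameterError("over-truncation: no outline left")
    n = len(x)
    # walk the ring, keeping inside vertices and interpolated crossings;
    # record whether each crossing leaves (exit) or re-enters (entry)
    pieces, crossings = [], []
    for i in range(n):
        j = (i + 1) % n
        if inside[i]:
            pieces.append(x[i])
        if inside[i] != inside[j]:
            f = (xcut - x[i, 0]) / (x[j, 0] - x[i, 0])
            pt = x[i] + f * (x[j] - x[i])
            crossings.append((len(pieces), "exit" if inside[i] else "entry", pt.copy()))
            pieces.append(pt)
    if len(crossings) != 2:
        raise ParameterError("truncation expects a single tip crossing")
    arr = np.array(pieces)
    (ia, ka, pa), (ib, kb, pb) = crossings
    if ka == kb:
        raise ParameterError("inconsistent truncation crossings")
    exit_idx, exit_pt = (ia, pa) if ka == "exit" else (ib, pb)
    entry_pt = pb if ka == "exit" else pa
    cap = _arc_cap(exit_pt, entry_pt, sagitta=0.5 * (xmax - xcut))
    # the removed stretch sits between the exit crossing and the entry
    # crossing in ring order; insert the cap right after the exit point
    # (wrapping past index 0 when the tip contains vertex 0)
    order = np.vstack([arr[: exit_idx + 1], cap, arr[exit_idx + 1:]])
    # anchor the ring at its base vertex (minimal x, on the mirror axis for
    # symmetric inputs) so equal-arc resampling preserves vertex-level
    # mirror correspondence of noise-free symmetric shapes
    order = np.roll(order, -int(np.argmin(order[:, 0])), axis=0)
    out = c.with_vertices(order + ctr)
    return resample_contour(out, len(v))


def _arc_cap(exit_pt: np.ndarray, entry_pt: np.ndarray, sagitta: float,
             points: int = 24) -> np.ndarray:
    """Interior points of a circular arc from exit_pt to entry_pt whose apex
    sits ``sagitta`` beyond the chord midpoint, bulging towards +x."""
    chord = entry_pt - exit_pt
    half = np.hypot(*chord) / 2
    if half <= 0 or sagitta <= 0:
        return np.empty((0, 2))
    normal = np.array([chord[1], -chord[0]]) / (2 * half)
    if normal[0] < 0:
        normal = -normal
    mid = (exit_pt + entry_pt) / 2
    apex = mid + sagitta * normal
    r = (half**2 + sagitta**2) / (2 * sagitta)
    center = apex - r * normal
    a_exit = np.arctan2(*(exit_pt - center)[::-1])
    a_entry = np.arctan2(*(entry_pt - center)[::-1])
    a_apex = np.arctan2(*(apex - center)[::-1])
    ccw_sweep = (a_entry - a_exit) % (2 * np.pi)
    if (a_apex - a_exit) % (2 * np.pi) <= ccw_sweep:
        angs = a_exit + np.linspace(0.0, ccw_sweep, points)[1:-1]
    else:
        cw_sweep = (a_exit - a_entry) % (2 * np.pi)
        angs = a_exit - np.linspace(0.0, cw_sweep, points)[1:-1]
    return center + r * np.column_stack([np.cos(angs), np.sin(angs)])


def reduction_series(c: Contour, stages: int) -> list:
    """Progressive tip-removal series: [(contour, stage)] for stages steps.

    Stage 0 is the original contour; later stages truncate the outline at
    x = (1 - 0.4 stage) of the tip extent and re-close it with a circular
    arc, shrinking centroid size and elongation monotonically.
    """
    if stages < 2:
        raise ParameterError("need at least 2 stages")
    out = []
    for s in np.linspace(0.0, 1.0, stages):
        out.append((c.copy() if s == 0 else _truncate_tip(c, float(s)), float(s)))
    return out


def _zone_scores(stage: float, rng: np.random.Generator) -> np.ndarray:
    """16 zone scores increasing stochastically with reduction stage."""
    u = np.clip(stage + rng.normal(0.0, 0.2, size=(2, 8)), 0, 1)
    scores = np.where(u < 1 / 3, 0.0, np.where(u < 2 / 3, 0.5, 1.0))
    return scores


def _make_views(L, W, T, p, n, aid, views):
    dims = {
        "top": (L, W, p),
        "lateral": (L, T, p),
        "frontal": (W, T, 0.0),
    }
    return {v: base_outline(*dims[v], n=n, artifact_id=aid, view=v) for v in views}


def generate_assemblage(spec: SyntheticSpec):
    """Generate an OutlineSet and its ground-truth table from a spec.

    Per artifact: latent size and elongation/refinement factors are drawn
    (correlated by rho), the three views are built from the shared latent
    geometry, a reduction stage truncates the tip (longitudinal artifacts
    only; latitudinal ones are modelled as ovates maintained whole), the
    group's asymmetry is injected, isotropic vertex noise is added, and
    zone scores are assigned as a noisy increasing function of stage.
    Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    contours, meta_rows, truth_rows = [], [], []
    for g in spec.groups:
        for i in range(g.n):
            aid = f"{g.name}-{i + 1:04d}"
            z_size = rng.normal()
            # clip the low tail: near-circular blanks make the axis class
            # unidentifiable (any mirror line fits a round blob), so the
            # generator keeps elongation bounded away from 1
            z_e = max(rng.normal(), -1.2)
            rho = g.elongation_refinement_rho
            z_r = rho * z_e + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal()
            L = g.length_mean * np.exp(g.length_cv * z_size)
            elong = g.elongation_mean * np.exp(g.elongation_cv * z_e)
            W = L / elong
            # more elongated -> relatively flatter (refined): T/W shrinks
            T = W * g.thickness_ratio * np.exp(-0.1 * z_r)
            stage = float(rng.uniform()) if g.stage_dist == "uniform" else float(np.clip(rng.beta(2, 2), 0, 1))
            latitudinal = bool(rng.uniform() < g.latitudinal_fraction)

            if latitudinal:
                alpha_eff = max(g.asymmetry, 0.15)
                views = {}
                for vname in spec.views:
                    dims = {"top": (L, W), "lateral": (L, T), "frontal": (W, T)}[vname]
                    views[vname] = _transverse_outline(dims[0], dims[1], 0.05, alpha_eff,
                                                       spec.n_points, aid, vname)
                alpha_used = alpha_eff
                true_angle = np.pi / 2
            else:
                views = _make_views(L, W, T, g.pointedness, spec.n_points, aid, spec.views)
                if stage > 0:
                    for vname in ("top", "lateral"):
                        if vname in views:
                            views[vname] = _truncate_tip(views[vname], stage)
                if g.asymmetry > 0:
                    views = {v: inject_asymmetry(cc, g.asymmetry_mode, g.asymmetry)
                             for v, cc in views.items()}
                alpha_used = g.asymmetry
                true_angle = 0.0

            for vname, cc in views.items():
                noisy = cc.vertices + rng.normal(0.0, g.noise_sd, size=cc.vertices.shape)
                contours.append(cc.with_vertices(noisy))

            zones = _zone_scores(stage, rng)
            invasiveness = float(zones.sum() / 16)
            mass = 2.6e-3 * 0.55 * L * W * T  # density x fill factor, grams
            raw_material = "flint" if rng.uniform() < 0.5 else "millstone"
            blank = "slab" if rng.uniform() < 0.7 else "flake"
            for vname in views:
                meta_rows.append({
                    "artifact_id": aid, "view": vname, "assemblage": g.name,
                    "raw_material": raw_material, "blank_type": blank,
                    "mass": mass, "invasiveness": invasiveness,
                })
            truth_rows.append({
                "artifact_id": aid, "group": g.name, "true_alpha": alpha_used,
                "true_axis_class": "latitudinal" if latitudinal else "longitudinal",
                "true_axis_angle": true_angle, "stage": stage,
                "elongation": elong, "L": L, "W": W, "T": T,
                "invasiveness": invasiveness,
                "zone_scores": zones.ravel().tolist(),
            })
    oset = OutlineSet(contours=contours, metadata=pd.DataFrame(meta_rows))
    return oset, pd.DataFrame(truth_rows)


def rasterize_outline(c: Contour, scale: float = 0.1, margin: int = 8) -> RasterMask:
    """Filled-polygon binary mask of a contour at ``scale`` mm per pixel.

    The mask records its origin so extraction returns coordinates in the
    contour's own frame; a margin of at least 5 px separates the foreground
    from every border.
    """
    if scale <= 0:
        raise ParameterError("scale must be positive")
    if margin < 5:
        raise ParameterError("margin must be at least 5 px")
    v = np.asarray(c.vertices, dtype=float)
    x0 = v[:, 0].min() - margin * scale
    y0 = v[:, 1].min() - margin * scale
    cols = (v[:, 0] - x0) / scale
    h = int(np.ceil((v[:, 1].max() - y0) / scale)) + margin + 1
    w = int(np.ceil((v[:, 0].max() - x0) / scale)) + margin + 1
    rows = (h - 1) - (v[:, 1] - y0) / scale
    img = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=img.shape)
    img[rr, cc] = True
    return RasterMask(pixels=img, scale=scale, origin=(x0, y0))
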