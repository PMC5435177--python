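"""Reflection Continuous Symmetry Measure (CSM) for closed outlines.

The CSM of a shape with respect to mirror symmetry is

    S = 100 * sum_k |Q_k - P_k|^2 / sum_k |Q_k - Q_0|^2

where {Q_k} are the outline vertices, Q_0 their centroid, and {P_k} the
nearest mirror-symmetric configuration. S is 0 for a perfectly symmetric
shape and approaches 100 as the nearest symmetric shape collapses to a
point; it is invariant to translation, rotation and uniform scaling.

On a closed outline of N (even) vertices a candidate mirror line induces an
involutive vertex correspondence ("pairing"): N/2 lines pass through two
opposing vertices and N/2 pass between two adjacent vertices on each side,
giving N candidates in total. For each pairing the optimal mirror-line
angle through the centroid has a closed form; the reported S is the minimum
over all pairings.

Given a pairing sigma and centered vertices X, the nearest symmetric shape
is the fold-average P_k = (X_k + R_theta X_sigma(k)) / 2 with R_theta the
reflection across the line at angle theta through the origin. Writing
A = sum(x_k x_s - y_k y_s) and B = sum(x_k y_s + y_k x_s) over paired
coordinates, the squared residual is (D - (A cos 2θ + B sin 2θ)) / 2 with
D = sum |X_k|^2, so the optimum is 2θ* = atan2(B, A) and

    S = 100 * (D - sqrt(A² + B²)) / (2 D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateContourError, ParameterError
from .outlines import Contour

__all__ = [
    "Pairing",
    "SymmetryResult",
    "enumerate_pairings",
    "pairing_from_anchor",
    "optimal_reflection_angle",
    "reflection_matrix",
    "nearest_symmetric",
    "csm_reflection",
    "classify_axis",
]


@dataclass(frozen=True)
class Pairing:
    """An order-2 vertex correspondence induced by one candidate mirror line.

    ``kind`` is ``"vertex"`` when the line passes through two opposing
    vertices (anchor and anchor + n/2; two fixed points) and ``"edge"``
    when it passes between adjacent vertices on both sides (no fixed
    point). ``sigma`` is the 0-based involution on vertex indices;
    ``anchor`` is the 1-based vertex the line is anchored at (for edge
    pairings, the first vertex of the anchoring edge).
    """

    index: int
    kind: str
    anchor: int
    sigma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=int))

    @property
    def n(self) -> int:
        return len(self.sigma)

    @property
    def fixed_points(self) -> np.ndarray:
        return np.nonzero(self.sigma == np.arange(self.n))[0]


@dataclass
class SymmetryResult:
    """Outcome of the reflection-CSM minimization for one contour."""

    s_value: float
    per_pairing_s: np.ndarray
    best_pairing: int
    axis_angle: float  # radians, mod pi, in the input frame
    axis_point: np.ndarray  # the contour centroid Q_0
    nearest_symmetric: Contour
    axis_class: str | None = None  # "latitudinal" | "longitudinal"
    pairings: list | None = None


def _sigma_about(n: int, twice_center: int) -> np.ndarray:
    """Involution j -> (twice_center - j) mod n, reversing cyclic order."""
    return (twice_center - np.arange(n)) % n


def pairing_from_anchor(n: int, anchor: int, kind: str) -> Pairing:
    """Build the pairing anchored at 1-based vertex ``anchor``.

    Anchors separated by n/2 describe the same mirror line and therefore
    the same involution — e.g. for n = 60 the vertex line through (1, 31)
    can be anchored at vertex 1 or vertex 31.
    """
    if n % 2 != 0 or n < 4:
        raise ParameterError("n must be even and at least 4")
    if not 1 <= anchor <= n:
        raise ParameterError(f"anchor must be in 1..{n}")
    a0 = anchor - 1
    if kind == "vertex":
        sigma = _sigma_about(n, 2 * a0)
        index = a0 % (n // 2) + 1
    elif kind == "edge":
        sigma = _sigma_about(n, 2 * a0 + 1)
        index = n // 2 + a0 % (n // 2) + 1
    else:
        raise ParameterError(f"unknown pairing kind {kind!r}")
    return Pairing(index=index, kind=kind, anchor=a0 % (n // 2) + 1, sigma=sigma)


def enumerate_pairings(n: int) -> list:
    """Enumerate all n candidate mirror-line pairings of an n-vertex outline.

    Returns n/2 vertex-kind pairings (indices 1..n/2, anchored at vertices
    1..n/2) followed by n/2 edge-kind pairings (indices n/2+1..n, anchored
    at edges (1,2)..(n/2, n/2+1)). All involutions are distinct.
    """
    if n % 2 != 0 or n < 4:
        raise ParameterError("n must be even and at least 4")
    out = [pairing_from_anchor(n, a, "vertex") for a in range(1, n // 2 + 1)]
    out += [pairing_from_anchor(n, a, "edge") for a in range(1, n // 2 + 1)]
    return out


def reflection_matrix(theta: float) -> np.ndarray:
    """Matrix reflecting across the line at angle ``theta`` through the origin."""
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    return np.array([[c, s], [s, -c]])


def _cross_sums(x: np.ndarray, sigma: np.ndarray):
    xs = x[sigma]
    a = float(np.sum(x[:, 0] * xs[:, 0] - x[:, 1] * xs[:, 1]))
    b = float(np.sum(x[:, 0] * xs[:, 1] + x[:, 1] * xs[:, 0]))
    return a, b


def optimal_reflection_angle(points: np.ndarray, p: Pairing) -> float:
    """Closed-form optimal mirror-line angle for centered points and a pairing.

    Minimizes sum_k |Q_k - (Q_k + R_theta Q_sigma(k))/2|^2 over theta; the
    optimum is 2 theta = atan2(B, A) with A, B the paired coordinate sums
    (see module docstring). Returned mod pi. An isotropic configuration
    (A = B = 0) leaves every angle optimal; 0 is returned with a warning.
    """
    x = np.asarray(points, dtype=float)
    a, b = _cross_sums(x, p.sigma)
    scale = float(np.sum(x**2))
    if np.hypot(a, b) < 1e-12 * max(scale, 1e-30):
        warnings.warn("isotropic pairing: any reflection angle is optimal; returning 0")
        return 0.0
    return float(np.arctan2(b, a) / 2 % np.pi)


def _chord_angle(points: np.ndarray, p: Pairing) -> float:
    """Angle of the candidate mirror chord the pairing was drawn through."""
    n = p.n
    a0 = p.anchor - 1
    if p.kind == "vertex":
        u = points[a0] - points[(a0 + n // 2) % n]
    else:
        e1 = (points[a0] + points[(a0 + 1) % n]) / 2
        e2 = (points[(a0 + n // 2) % n] + points[(a0 + n // 2 + 1) % n]) / 2
        u = e1 - e2
    return float(np.arctan2(u[1], u[0]) % np.pi)


def nearest_symmetric(c: Contour, p: Pairing, mode: str = "free"):
    """Nearest mirror-symmetric shape and its CSM value for one pairing.

    Centers the contour on its centroid Q_0, chooses the mirror-line angle
    (optimal closed form in ``free`` mode; the anchoring chord direction in
    ``chord`` mode), folds each vertex with its partner's reflection, and
    averages. Returns ``(symmetric_contour, s, theta)`` with the symmetric
    shape translated back to the original frame.
    """
    v = np.asarray(c.vertices, dtype=float)
    if len(v) != p.n:
        raise ParameterError(f"pairing is for n={p.n}, contour has {len(v)} vertices")
    q0 = v.mean(axis=0)
    x = v - q0
    denom = float(np.sum(x**2))
    if denom <= 0:
        raise DegenerateContourError("degenerate contour: zero size normalization")
    if mode == "free":
        theta = optimal_reflection_angle(x, p)
    elif mode == "chord":
        theta = _chord_angle(x, p)
    else:
        raise ParameterError(f"unknown csm mode {mode!r}")
    pk = (x + x[p.sigma] @ reflection_matrix(theta).T) / 2
    s = 100.0 * float(np.sum((x - pk) ** 2)) / denom
    return c.with_vertices(pk + q0), s, theta


def _per_pairing_s(x: np.ndarray, pairings: list, mode: str):
    """Vectorized S and theta for every pairing of centered vertices x."""
    denom = float(np.sum(x**2))
    sig = np.stack([p.sigma for p in pairings])  # (P, N)
    xs = x[sig]  # (P, N, 2)
    a = np.sum(x[:, 0] * xs[:, :, 0] - x[:, 1] * xs[:, :, 1], axis=1)
    b = np.sum(x[:, 0] * xs[:, :, 1] + x[:, 1] * xs[:, :, 0], axis=1)
    if mode == "free":
        theta = np.arctan2(b, a) / 2 % np.pi
        cross = np.hypot(a, b)
    else:
        theta = np.array([_chord_angle(x, p) for p in pairings])
        cross = a * np.cos(2 * theta) + b * np.sin(2 * theta)
    s = 100.0 * (denom - cross) / (2 * denom)
    # guard tiny negative values from floating cancellation on exact symmetry
    s[(s < 0) & (s > -1e-9)] = 0.0
    return s, theta


def csm_reflection(c: Contour, mode: str = "free", classify: bool = True) -> SymmetryResult:
    """Minimize the reflection CSM over all candidate pairings of a contour.

    Evaluates every enumerated pairing, reports the minimum S (ties broken
    on the lowest pairing index), the winning mirror angle and pairing, the
    nearest symmetric shape, and — when ``classify`` is set and the contour
    is tip-anchored — the axis class (longitudinal vs latitudinal).

    ``mode="chord"`` locks each candidate axis to its anchoring chord
    instead of optimizing the angle; S can only increase in that mode.
    """
    v = np.asarray(c.vertices, dtype=float)
    n = len(v)
    pairings = enumerate_pairings(n)
    q0 = v.mean(axis=0)
    x = v - q0
    denom = float(np.sum(x**2))
    if denom <= 0:
        raise DegenerateContourError("degenerate contour: zero size normalization")
    s, theta = _per_pairing_s(x, pairings, mode)
    best = int(np.argmin(s))  # argmin returns the lowest index on ties
    best_pairing = pairings[best]
    sym = nearest_symmetric(c, best_pairing, mode=mode)[0]
    result = SymmetryResult(
        s_value=float(s[best]),
        per_pairing_s=s,
        best_pairing=best_pairing.index,
        axis_angle=float(theta[best]),
        axis_point=q0,
        nearest_symmetric=sym,
        pairings=pairings,
    )
    if classify:
        result.axis_class = classify_axis(result, n)
    return result


def classify_axis(r: SymmetryResult, n: int) -> str:
    """Classify the winning mirror axis as longitudinal or latitudinal.

    The axis is longitudinal when it lies within pi/4 of the tip-to-base
    chord (vertex 1 to vertex 1 + n/2 of the tip-anchored outline), and
    latitudinal otherwise — i.e. latitudinal axes run perpendicular to the
    long axis of the artifact. Pairings anchored at vertex v and at
    v + n/2 describe the same line and classify identically.
    """
    v = np.asarray(r.nearest_symmetric.vertices, dtype=float)
    chord = v[0] - v[n // 2]
    chord_angle = np.arctan2(chord[1], chord[0]) % np.pi
    diff = abs(r.axis_angle - chord_angle) % np.pi
    diff = min(diff, np.pi - diff)
    return "longitudinal" if diff <= np.pi / 4 else "latitudinal"
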