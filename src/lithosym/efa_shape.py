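"""Shape space for outline sets: Procrustes alignment, elliptical Fourier
descriptors, and principal components.

Outlines enter as matched pseudolandmark configurations (equal vertex
counts, vertex 1 at the tip). A full generalized Procrustes alignment
removes location, scale and rotation; each aligned outline is then encoded
as elliptical Fourier coefficients — the harmonic ellipses of its x(t) and
y(t) coordinate functions on the closed traversal — and the raw
coefficients (constant terms dropped) feed a covariance PCA.

Coefficients are obtained by fitting the truncated Fourier series to the
vertices at their cumulative arc-length stations. For outlines resampled
to equal arc-length spacing (the pipeline's canonical form) this reduces
to the discrete Fourier transform of the coordinate sequences and is exact
at the sample points when all available harmonics are retained; for
irregular spacing a least-squares fit at the arc-length stations is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import DegenerateContourError, ParameterError
from .outlines import Contour

__all__ = [
    "EFACoefficients",
    "AlignedSet",
    "ShapeSpace",
    "gpa_align",
    "efa_coefficients",
    "efa_reconstruct",
    "coefficient_matrix",
    "shape_pca",
    "pc_extremes",
]

DEFAULT_HARMONICS = 8


@dataclass
class EFACoefficients:
    """Elliptical Fourier descriptor of one closed outline.

    ``coeffs`` has one row (a_h, b_h, c_h, d_h) per harmonic:
    x(t) = A0 + sum_h a_h cos(2 pi h t) + b_h sin(2 pi h t), likewise y(t)
    with (C0, c_h, d_h), for t in [0, 1) proportional to arc length.
    """

    a0: float
    c0: float
    coeffs: np.ndarray  # (H, 4)

    def __post_init__(self):
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        if self.coeffs.shape[1] != 4:
            raise ParameterError("coeffs must be (H, 4)")

    @property
    def harmonics(self) -> int:
        return len(self.coeffs)

    def flat(self, drop_constants: bool = True) -> np.ndarray:
        vec = self.coeffs.ravel()
        if drop_constants:
            return vec
        return np.concatenate([[self.a0, self.c0], vec])


@dataclass
class AlignedSet:
    """Generalized-Procrustes-aligned outlines and their mean shape."""

    aligned: np.ndarray  # (m, N, 2), unit centroid size, centered
    mean_shape: np.ndarray  # (N, 2)
    rotations: np.ndarray  # (m,) radians applied to each outline
    iterations: int
    converged: bool


@dataclass
class ShapeSpace:
    """PCA of raw elliptical Fourier coefficients.

    Scores are outline-by-component; loadings are component-by-coefficient
    rows of unit norm with the sign convention that each component's
    largest-magnitude loading is positive. ``variance_fractions`` sum to 1
    unless the input was degenerate (all shapes identical), in which case
    ``degenerate`` is set and the fractions are zero.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    variances: np.ndarray
    mean_vector: np.ndarray
    harmonics: int
    degenerate: bool = False
    labels: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Generalized Procrustes alignment


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> float:
    """Angle rotating configuration x onto target in the least-squares sense
    (rotation only, no reflection)."""
    num = float(np.sum(x[:, 0] * target[:, 1] - x[:, 1] * target[:, 0]))
    den = float(np.sum(x[:, 0] * target[:, 0] + x[:, 1] * target[:, 1]))
    return float(np.arctan2(num, den))


def _rotate(x: np.ndarray, ang: float) -> np.ndarray:
    c, s = np.cos(ang), np.sin(ang)
    return x @ np.array([[c, s], [-s, c]])


def gpa_align(outlines, tol: float = 1e-8, max_iter: int = 100) -> AlignedSet:
    """Full generalized Procrustes alignment of matched outlines.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated to the current mean shape (itself renormalized each
    round) until the mean moves less than ``tol`` or ``max_iter`` rounds
    elapse. Vertex counts must match; vertex 1 is treated as homologous
    across outlines (tip-anchored pseudolandmarks).
    """
    arrs = [np.asarray(o.vertices if isinstance(o, Contour) else o, dtype=float) for o in outlines]
    if len(arrs) < 2:
        raise ParameterError("alignment needs at least 2 outlines")
    npts = {len(a) for a in arrs}
    if len(npts) != 1:
        raise ParameterError(f"unequal vertex counts: {sorted(npts)}")

    x = np.stack(arrs)
    x = x - x.mean(axis=1, keepdims=True)
    sizes = np.sqrt((x**2).sum(axis=(1, 2), keepdims=True))
    if np.any(sizes <= 0):
        raise DegenerateContourError("zero-size configuration in alignment set")
    x = x / sizes

    total_rot = np.zeros(len(x))
    mean = x[0].copy()
    mean /= np.sqrt((mean**2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(x)):
            ang = _optimal_rotation(x[i], mean)
            x[i] = _rotate(x[i], ang)
            total_rot[i] += ang
        new_mean = x.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        delta = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"Procrustes alignment did not converge in {max_iter} iterations")
    return AlignedSet(aligned=x, mean_shape=mean, rotations=total_rot % (2 * np.pi),
                      iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# Elliptical Fourier descriptors


def efa_coefficients(c, harmonics: int = DEFAULT_HARMONICS) -> EFACoefficients:
    """Elliptical Fourier coefficients of a closed contour.

    ``harmonics`` may be at most N/2 - 1 for an N-vertex outline. The
    traversal parameter is the normalized vertex index t_k = k/N — for
    outlines resampled to equal arc-length spacing (the pipeline's
    canonical form) this is the arc-length parameterization — and the
    coefficients are the discrete Fourier transform of the coordinate
    sequences, so reconstruction with all N/2 - 1 harmonics reproduces a
    smooth outline at its sample points to numerical precision.
    """
    v = np.asarray(c.vertices if isinstance(c, Contour) else c, dtype=float)
    n = len(v)
    if harmonics < 1 or harmonics > n // 2 - 1:
        raise ParameterError(f"harmonics must be in 1..{n // 2 - 1} for {n} vertices")
    f = np.fft.rfft(v, axis=0) / n
    a0, c0 = float(f[0, 0].real), float(f[0, 1].real)
    h = np.arange(1, harmonics + 1)
    coeffs = np.column_stack([
        2 * f[h, 0].real, -2 * f[h, 0].imag,
        2 * f[h, 1].real, -2 * f[h, 1].imag,
    ])
    return EFACoefficients(a0=a0, c0=c0, coeffs=coeffs)


def efa_reconstruct(e: EFACoefficients, n: int = 60) -> Contour:
    """Evaluate the truncated Fourier series at n equally spaced stations."""
    if n < 8:
        raise ParameterError("n must be at least 8")
    t = np.arange(n) / n
    h = np.arange(1, e.harmonics + 1)
    cos = np.cos(2 * np.pi * np.outer(t, h))
    sin = np.sin(2 * np.pi * np.outer(t, h))
    x = e.a0 + cos @ e.coeffs[:, 0] + sin @ e.coeffs[:, 1]
    y = e.c0 + cos @ e.coeffs[:, 2] + sin @ e.coeffs[:, 3]
    return Contour("reconstruction", "top", np.column_stack([x, y]))


def coefficient_matrix(coeff_list) -> np.ndarray:
    """Stack per-outline coefficients into an (outlines, 4H) matrix,
    constant terms excluded, column order a1 b1 c1 d1 a2 b2 ..."""
    mats = [e.flat(drop_constants=True) for e in coeff_list]
    widths = {len(m) for m in mats}
    if len(widths) != 1:
        raise ParameterError("mixed harmonic counts in coefficient list")
    return np.stack(mats)


# ---------------------------------------------------------------------------
# Principal components


def shape_pca(coeff_matrix: np.ndarray, labels=None, harmonics: int | None = None) -> ShapeSpace:
    """Covariance PCA of raw elliptical Fourier coefficients.

    The matrix is column-centered but not scaled (the coefficients share
    units after alignment). Components are sign-fixed so the
    largest-magnitude loading of each is positive, making score directions
    reproducible across runs and platforms.
    """
    x = np.asarray(coeff_matrix, dtype=float)
    if x.ndim != 2 or len(x) < 3:
        raise ParameterError("shape PCA needs at least 3 outlines")
    if harmonics is None:
        if x.shape[1] % 4 != 0:
            raise ParameterError("coefficient matrix width must be a multiple of 4")
        harmonics = x.shape[1] // 4
    mean_vector = x.mean(axis=0)
    total_var = float(np.sum((x - mean_vector) ** 2)) / (len(x) - 1)
    if total_var < 1e-24:
        k = min(len(x) - 1, x.shape[1])
        return ShapeSpace(
            scores=np.zeros((len(x), k)), loadings=np.zeros((k, x.shape[1])),
            variance_fractions=np.zeros(k), variances=np.zeros(k),
            mean_vector=mean_vector, harmonics=harmonics, degenerate=True,
            labels=list(labels) if labels is not None else [],
        )
    pca = PCA(n_components=min(len(x) - 1, x.shape[1]), svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(len(loadings)), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    frac = pca.explained_variance_ratio_
    return ShapeSpace(
        scores=scores, loadings=loadings,
        variance_fractions=frac, variances=pca.explained_variance_,
        mean_vector=mean_vector, harmonics=harmonics,
        labels=list(labels) if labels is not None else [],
    )


def pc_extremes(space: ShapeSpace, pc: int = 1, k: float = 2.0, n: int = 60):
    """Reconstruct the mean shape displaced ±k standard deviations along a PC.

    Used to read the meaning of a component (elongation, refinement,
    plano-convexity) directly off the reconstructed outlines.
    """
    if not 1 <= pc <= len(space.loadings):
        raise ParameterError(f"pc must be in 1..{len(space.loadings)}")
    sd = float(np.sqrt(space.variances[pc - 1]))
    axis = space.loadings[pc - 1]
    out = []
    for sign in (+1.0, -1.0):
        vec = space.mean_vector + sign * k * sd * axis
        e = EFACoefficients(a0=0.0, c0=0.0, coeffs=vec.reshape(space.harmonics, 4))
        out.append(efa_reconstruct(e, n=n))
    return tuple(out)


def elongation(vertices) -> float:
    """Length/width ratio of an outline's principal-axis bounding extents."""
    v = np.asarray(vertices if not isinstance(vertices, Contour) else vertices.vertices, dtype=float)
    x = v - v.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    proj = x @ vt.T
    ext = proj.max(axis=0) - proj.min(axis=0)
    if ext[1] <= 0:
        raise DegenerateContourError("degenerate outline: zero width")
    return float(ext[0] / ext[1])
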