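"""Independent brute-force oracles used by the test suite.

These deliberately avoid the closed forms used by the package: the
reflection-CSM oracle scans a dense angle grid and constructs the folded
shape explicitly for every pairing, and the PCA oracle is a plain
eigendecomposition of the covariance matrix.
"""

import numpy as np


def random_smooth_contour(n, seed, irregularity=0.25, harmonics=4):
    """Star-shaped polygon with a smooth random radius function."""
    rng = np.random.default_rng(seed)
    th = 2 * np.pi * np.arange(n) / n
    r = np.ones(n)
    for h in range(1, harmonics + 1):
        r += irregularity / h * (rng.normal() * np.cos(h * th) + rng.normal() * np.sin(h * th))
    r = np.clip(r, 0.2, None)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def fold_s(x, sigma, theta):
    """CSM value of centered vertices x under pairing sigma at mirror angle
    theta, via explicit construction of the folded symmetric shape."""
    c2, s2 = np.cos(2 * theta), np.sin(2 * theta)
    refl = np.array([[c2, s2], [s2, -c2]])
    p = (x + x[sigma] @ refl.T) / 2
    return 100.0 * np.sum((x - p) ** 2) / np.sum(x**2)


def _refl_stack(thetas):
    c2, s2 = np.cos(2 * thetas), np.sin(2 * thetas)
    refl = np.zeros((len(thetas), 2, 2))
    refl[:, 0, 0] = c2
    refl[:, 0, 1] = s2
    refl[:, 1, 0] = s2
    refl[:, 1, 1] = -c2
    return refl


def _scan(x, sigma, thetas, denom):
    p = (x[None] + np.einsum("tij,kj->tki", _refl_stack(thetas), x[sigma])) / 2
    resid = np.sum((x[None] - p) ** 2, axis=(1, 2))
    i = int(np.argmin(resid))
    return 100.0 * resid[i] / denom, thetas[i]


def grid_min_s(vertices, sigmas, n_angles=10_000):
    """Exhaustive minimum of the reflection CSM over all pairings and a
    dense angle grid, with the folded shape built explicitly per angle.

    The coarse grid is refined locally around each near-optimal pairing's
    arg-min (grid quantization is quadratic in the step, ~5e-6 at 10,000
    angles) so the oracle value is accurate well below 1e-6.
    """
    v = np.asarray(vertices, dtype=float)
    x = v - v.mean(axis=0)
    denom = np.sum(x**2)
    coarse = np.pi * np.arange(n_angles) / n_angles
    step = np.pi / n_angles
    results = [_scan(x, sigma, coarse, denom) for sigma in sigmas]
    best_coarse = min(s for s, _ in results)
    best = np.inf
    for (s, theta), sigma in zip(results, sigmas):
        if s > best_coarse + 1e-4:
            continue
        fine = theta + np.linspace(-step, step, 2001)
        s_fine, _ = _scan(x, sigma, fine, denom)
        best = min(best, s_fine)
    return float(best)


def grid_best_angle(points, sigma, n_angles=10_000):
    """Arg-min angle of the per-pairing CSM on a dense grid."""
    x = np.asarray(points, dtype=float)
    thetas = np.pi * np.arange(n_angles) / n_angles
    vals = [fold_s(x, sigma, t) for t in thetas]
    return float(thetas[int(np.argmin(vals))])


def pca_eig(matrix):
    """Covariance PCA via eigendecomposition: (eigvalues desc, components)."""
    x = np.asarray(matrix, dtype=float)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (len(x) - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order].T
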