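# Methods

This note documents the models, numerical choices and known limitations
behind `lithosym`, in the order the pipeline applies them.

## Outline preparation

**Canonical form.** Every analysis runs on a closed polygon of N vertices
(default N = 60, even), equally spaced by cumulative arc length,
counterclockwise in y-up mm coordinates, with vertex 1 at the tip.

**Resampling** interpolates linearly along the closed source polyline at
stations k·P/N (P the perimeter), keeping the first input vertex as the
first output vertex so a tip-anchored correspondence survives. Two
numerical facts worth knowing: (1) resampling is not exactly idempotent on
curved outlines — the output vertices are equally spaced along the *input*
polyline, not along their own chord polygon, so a second pass moves them
by the chord/arc discrepancy, second order in vertex spacing (~1e-4 of a
spacing for a 60-gon of a smooth outline); (2) on a source polygon whose
vertex count is not a multiple of N, output chords vary at ~1e-6 relative
even though arc gaps are exactly equal. Both are standard behaviour for
outline-morphometrics resamplers.

**Orientation** rotates the major principal axis of the vertex cloud to
horizontal, flips so the sharper end points +x, and rolls the vertex
numbering so the sharpest vertex is vertex 1. Sharpness is the exterior
turning angle averaged over a ±2-vertex window — a windowed estimator was
chosen because single-vertex turning angles are dominated by pixel/vertex
noise at realistic digitization scales. Perfectly isotropic outlines
(circles) have no principal axis and no curvature maximum; they are left
unrotated and vertex 1 stays at the lowest original index, with a warning.

**Raster extraction** thresholds (Otsu or fixed), fills holes, keeps the
largest connected component, and traces the sub-pixel 0.5-level boundary.
Measured round-trip error (rasterize at 0.1 mm/px → extract) is ~0.5 px;
the test bound is 2 px. Boundary-touching foreground is traced but warned
about.

## Reflection CSM

For vertices {Q_k} with centroid Q_0, the symmetry measure is
S = 100 · Σ|Q_k − P_k|² / Σ|Q_k − Q_0|², where {P_k} is the nearest
configuration invariant under one mirror reflection composed with a vertex
permutation. S is dimensionless, 0 for exact symmetry, at most 100, and
invariant to similarity transforms (the denominator is the squared
centroid size).

**Candidate pairings.** A mirror line on a closed N-gon (N even) must map
the vertex cycle to itself reversing orientation; there are exactly N such
involutions — N/2 anchored at a vertex (two fixed points: the anchor and
its antipode) and N/2 anchored between adjacent vertices (no fixed point).
Anchors v and v + N/2 describe the same line; the canonical enumeration
indexes vertex-kind pairings 1..N/2 and edge-kind N/2+1..N, and the
antipodal identity is verified to 1e-12 in the tests.

**Per-pairing minimization.** With centered vertices X and pairing σ, the
nearest symmetric shape is the fold average P_k = (X_k + R_θ X_σ(k))/2.
Writing A = Σ(x_k x_σ(k) − y_k y_σ(k)) and B = Σ(x_k y_σ(k) + y_k x_σ(k)),
the residual is (D − (A cos 2θ + B sin 2θ))/2 with D = Σ|X_k|², so
2θ* = atan2(B, A) and S = 100 (D − √(A²+B²)) / (2D), evaluated for all N
pairings in one vectorized pass. Ties take the lowest pairing index.
A = B = 0 (isotropic pairing) leaves every angle optimal; θ = 0 is
returned with a warning.

**Axis position.** Only the angle is optimized; the axis always passes
through Q_0. With fold-averaging, translating the axis away from the
centroid cannot reduce the residual (the optimal translation aligns the
average of a configuration and its reflection, which is the centroid), so
the one-parameter optimization is exact. A `chord` mode that locks each
candidate axis to its anchoring vertex chord is available; it can only
raise S and is provided for comparison with drawing-based protocols.

**Axis classification.** The winning axis is longitudinal if it lies
within π/4 of the tip-to-base chord (vertex 1 to vertex 1 + N/2),
latitudinal otherwise. The angle rule — rather than a fixed index-range
rule — is used because it is orientation-meaningful and automatically
satisfies the antipodal equivalence of anchors.

**Discretization.** The measure operates on the digitized polygon, so S
carries a small vertex-correspondence quantization: correspondences snap
to half-vertex offsets, adding up to ~(half spacing / 2)² / mean-square
radius to S of a continuously symmetric shape, and perturbing fine
response curves by ~0.005 at N = 60. The monotone shear-response check is
therefore run at N = 120, where the continuous response is resolved;
strict monotonicity at N = 60 over a 0.05-step shear grid holds everywhere
except one ~0.004 inversion attributable to this quantization.

## Shape space

**Procrustes alignment** treats the N resampled vertices as matched
pseudolandmarks with tip-anchored correspondence (the generator and
orientation stage guarantee vertex 1 homology). Each configuration is
centered and scaled to unit centroid size; outlines are iteratively
rotated to the running mean (rotation only, no reflection) and the mean
renormalized until it moves < 1e-8 (at most 100 rounds).

**Elliptical Fourier coefficients** encode x(t), y(t) on the closed
traversal as harmonic ellipses (a_h, b_h, c_h, d_h), with constants
(A0, C0) carrying location. The traversal parameter is the normalized
vertex index — identical to arc length for resampled outlines — and the
coefficients are the discrete Fourier transform of the coordinate
sequences. This pseudo-spectral formulation was chosen over chain-integral
estimators because it is exact on band-limited outlines: the first
harmonic of a parameter-sampled ellipse is recovered to machine precision,
and reconstruction with all N/2 − 1 harmonics reproduces smooth outlines
at their sample points (chain integrals attenuate harmonic h by a
sinc²(πh/N) factor and miss both properties by 2–4 orders of magnitude).
Since alignment already removed size and orientation, no first-harmonic
normalization is applied — doing both would double-normalize.

**PCA** is computed on the raw coefficient matrix (constants dropped —
location is meaningless after centering), column-centered, unscaled
(covariance PCA: coefficients share units). Component signs are fixed by
making each component's largest-magnitude loading positive, so scores are
reproducible across runs and platforms. Identical-shape inputs are flagged
degenerate rather than dividing by zero variance. PC extremes reconstruct
the mean coefficient vector ± k·SD along a component.

## Reduction and allometry

The index of invasiveness is the mean of 16 zone scores (2 faces × 8
segments, each 0 / 0.5 / 1: no scars / marginal / invasive); it ranges 0–1
and is taken as recorded input, never computed from imagery. The thinning
index is plan-view area (mm²) over mass (g). Whole-artifact size defaults
to the geometric mean of the three per-view centroid sizes; a geometric
mean of view *areas* is available (`mode="area"`) since either convention
appears in practice, and neither is asserted as canonical.

Associations use two-sided tests throughout: Pearson r with
t = r√((n−2)/(1−r²)) on n−2 df, Spearman, pooled-variance Student t
(default two-group test; Welch by flag), two-sample Wilcoxon rank-sum
(reported as the Mann-Whitney W of the first sample), and OLS with slope,
intercept, standard error and R². No multiple-testing correction is
applied by default; raw p-values are reported (a Holm option exists at the
pipeline level).

## Synthetic data

The generator emulates a multi-assemblage outline study: three orthogonal
views per artifact, assemblage-level asymmetry differences, an
elongation–refinement covariance, tip-reduction series, and invasiveness
rising with reduction stage. It makes no claim of matching real handaxe
shape distributions; its purpose is *recoverable ground truth*.

**Base shape.** x(t) = (L/2)cos t, y(t) = (W/2)sin t (1 + p cos t):
mirror-symmetric about the x axis for pointedness p ∈ [0, 0.9), sharpest
at t = 0, sampled at equal arc length with vertex 1 at the tip (so
noise-free symmetric shapes score S < 1e-9 under the candidate-aligned
pairing). Defaults: L = 120 mm, W = L/elongation, elongation lognormal
around 1.7 (cv 0.12), p = 0.4, thickness ratio 0.45 — plausible magnitudes
for Lower Paleolithic bifaces.

**Identifiability constraints** (both documented design choices, not
physical claims): the elongation draw is clipped at z ≥ −1.2 because
near-circular blanks make the axis class undecidable (any mirror line fits
a round blob, and shear gives it spurious diagonal symmetry — measured ~2%
ground-truth misclassification without the clip, 0/264 with it); and
latitudinal artifacts are built from a transverse egg family (cross-axis
modulation with a small p = 0.05 tip) rather than by truncating
longitudinal ones, since tip truncation would destroy the cross-axis
mirror that defines them.

**Asymmetry injection** offers three modes: `shear` (x += αy, the default
group-level signal — strong, monotone response), `differential_edge`
(upper edge scaled 1 + α) and `tip_offset` (tip half rotated α about the
centroid). A measurement worth recording: differential edge scaling is
largely *absorbed* by the CSM's translation freedom — the constant α·f/2
offset is removed with the centroid, leaving a residual an order of
magnitude below the shear response and non-monotone in α. It is therefore
a realistic model of retouch-induced edge drift but a poor dial for
controlled asymmetry, and the generator default is shear. Deformations
that self-intersect are rejected (shapely simplicity check). Vertex noise
is isotropic Gaussian (default SD 0.5 mm, a plausible manual-digitization
jitter), added after asymmetry injection at the stored vertices.

**Reduction series** truncate the outline at x = (1 − 0.4·stage)·x_max and
re-close it with a circular-arc cap whose sagitta is half the truncation
depth — always less than the removed depth, so centroid size and
elongation decrease strictly with stage. The capped ring is re-anchored at
its base vertex (on the mirror axis) so noise-free truncated shapes remain
exactly candidate-aligned. Zone scores are drawn per segment as an
increasing noisy function of stage (correlation with stage ~0.8); mass is
a density × fill-factor product of L·W·T.

**Views.** Top = (L, W), lateral = (L, T), frontal = (W, T) from one
latent factor, with log elongation and log refinement correlated (ρ = 0.4
by default; more elongated pieces are relatively flatter). This yields the
moderate cross-view correlations expected of real artifacts without
modeling true 3-D geometry — a stated limitation: the "views" are
projections of a 2-parameter latent, not of a consistent solid, so tests
passing here validate the estimators, not any claim about real 3-D form.

## Pipeline and problem sizes

The pipeline is deterministic given the input ordering and configuration:
resample → orient → CSM per contour; GPA → Fourier → PCA per view;
indices and associations per artifact; tables with a versioned schema.
Group summaries report n, mean, median, SD and quartiles of S, and
latitudinal proportions with Wilson binomial CIs. Missing metadata skips
the affected analyses rather than imputing.

Validation problem sizes were chosen to resolve each property while
keeping the full suite in minutes on one core: 50 random contours
(N ∈ {8, 12, 60}) against a 10,000-angle brute-force grid (locally refined
around its arg-min, since bare-grid quantization is ~5e-6); 100 replicates
of the two-group (α = 0.05 vs 0.15, n = 100 each) ordering recovery; a
500-artifact 30%-latitudinal design for the proportion CI; 10,000 null
replicates at n = 49 for Pearson type-I calibration; 500 replicates for
OLS slope-CI coverage.

## Known limitations

- S is a polygon statistic: values at different N are comparable only
  approximately (quantization ~half-vertex correspondence snapping).
- GPA assumes vertex-1 homology; badly misdetected tips propagate to the
  shape space (the windowed curvature estimator mitigates but cannot
  eliminate this on near-round pieces).
- The egg family cannot represent concavities, shoulders or cortical
  backs; real assemblage shape spaces are richer than the generator's.
- Raster extraction assumes one artifact per image and a clean silhouette;
  no perspective or illumination correction is attempted.
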