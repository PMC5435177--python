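# lithosym

Outline symmetry and shape analysis for lithic artifacts (handaxes/bifaces)
— and for any closed 2-D outline where bilateral symmetry, outline shape
and allometry need quantifying together.

Archaeologists reading assemblages of shaped stone tools face three linked
questions: *how symmetric* is each piece, *about which axis*, and *how much
of the shape signal is reduction* (resharpening and thinning over the
tool's use-life) rather than design. `lithosym` answers all three from
digitized outlines:

- **Reflection Continuous Symmetry Measure (CSM).** For an outline with
  vertices {Q_k} and centroid Q_0, the measure is

  ```
  S = 100 · Σ_k |Q_k − P_k|² / Σ_k |Q_k − Q_0|²
  ```

  where {P_k} is the nearest mirror-symmetric configuration. S = 0 for a
  perfectly symmetric outline, approaches 100 as the nearest symmetric
  shape collapses to a point, and is invariant to translation, rotation
  and scale. On an N-vertex closed outline a candidate mirror line induces
  an involutive vertex pairing; there are exactly N candidates (N/2 lines
  through opposing vertex pairs, N/2 between adjacent vertices on each
  side). For each pairing the optimal mirror angle through the centroid
  has a closed form (2θ\* = atan2(B, A) with A, B the paired coordinate
  cross-sums), and the reported S is the minimum over all pairings. The
  winning axis is classified **longitudinal** (along the tip–base axis) or
  **latitudinal** (across it).

- **Shape space.** Outlines are resampled to N equally arc-length-spaced
  vertices (N = 60 by default), oriented tip-right, aligned by full
  generalized Procrustes analysis, encoded as elliptical Fourier
  coefficients (8 harmonics by default) and summarized by covariance PCA.
  PC extremes are reconstructed as outlines so each component can be read
  as elongation, refinement, plano-convexity, and so on.

- **Reduction and allometry.** Index of invasiveness (mean of 2 faces × 8
  segments of 0 / 0.5 / 1 retouch-zone scores), Johnson's thinning index
  (plan area / mass), centroid sizes per view and their geometric mean,
  plus the standard association statistics (Pearson/Spearman, pooled and
  Welch t, Wilcoxon rank-sum, OLS).

- **Synthetic assemblages with ground truth.** A two-parameter egg-curve
  generator produces multi-view, multi-group outline datasets with known
  asymmetry magnitude and axis, elongation–refinement covariance,
  tip-reduction series and invasiveness scores, so every estimate the
  pipeline produces can be validated against a recorded true value.

## Worked example

```python
import lithosym as ls

spec = ls.SyntheticSpec(
    groups=[
        ls.GroupSpec("lower", n=20, asymmetry=0.15),
        ls.GroupSpec("upper", n=20, asymmetry=0.08),
    ],
    seed=7,
)
outlines, truth = ls.generate_assemblage(spec)
report = ls.run_pipeline(outlines, ls.PipelineConfig(n_points=60, harmonics=8))

print(report.assemblage_summary[["assemblage", "view", "n", "mean_s", "median_s"]]
      .round(4).to_string(index=False))
```

```
assemblage    view  n  mean_s  median_s
     lower frontal 20  0.0295    0.0321
     lower lateral 20  0.0276    0.0248
     lower     top 20  0.1081    0.1042
     upper frontal 20  0.0283    0.0270
     upper lateral 20  0.0199    0.0181
     upper     top 20  0.0451    0.0427
```

The "lower" group was generated with twice the shear asymmetry of the
"upper" group, and its mean S in the top view (0.108 vs 0.045) recovers
that ordering; both are far from 0, and far from 100, as expected for
mildly asymmetric outlines. Axis-class proportions come with binomial
confidence intervals:

```python
print(report.axis_proportions.query("view == 'top'")
      [["assemblage", "proportion_latitudinal", "ci_low", "ci_high"]]
      .round(3).to_string(index=False))
```

```
assemblage  proportion_latitudinal  ci_low  ci_high
     lower                    0.05   0.009    0.236
     upper                    0.10   0.028    0.301
```

Both groups were generated with a 15% latitudinal-axis design, and both
estimates sit inside their intervals. The per-view shape spaces report
variance fractions (`report.shape_variance`; PC1 carries 55–82% here,
dominated by elongation/refinement), and `report.associations` holds the
size–invasiveness regressions and group comparisons.

The same stages are scriptable from a shell:

```sh
lithosym simulate --spec spec.yaml --out data/
lithosym symmetry --in data/outlines.csv --out symmetry.csv
lithosym shape    --in data/outlines.csv --view top --out scores.csv
lithosym report   --config run.yaml
```

## Layout

- `src/lithosym/outlines.py` — contour I/O (xy/TPS), raster extraction,
  arc-length resampling, canonical orientation, size metrics
- `src/lithosym/csm_symmetry.py` — pairing enumeration, closed-form mirror
  angle, fold-average nearest symmetric shape, CSM minimization, axis
  classification
- `src/lithosym/efa_shape.py` — Procrustes alignment, elliptical Fourier
  coefficients and reconstruction, shape PCA, PC-extreme outlines
- `src/lithosym/reduction_allometry.py` — invasiveness, thinning index,
  sizes, association statistics
- `src/lithosym/pipeline_stats.py` — end-to-end report
- `src/lithosym/synthetic_data.py` — ground-truthed outline generator
- `docs/methods.md` — model, parameter and design notes
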