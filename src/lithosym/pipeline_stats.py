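"""End-to-end assemblage analysis: per-contour symmetry, axis-class
proportions, per-view shape spaces, and reduction associations.

The pipeline mirrors the structure of an outline-morphometric study
report: every contour is resampled, oriented and scored for reflection
symmetry; axis classes are tallied per assemblage and view with binomial
confidence intervals; elliptical Fourier shape spaces are built per view;
and reduction indices are regressed against size and symmetry. Output is
a structured :class:`Report` of plain pandas tables — deterministic for a
fixed input ordering and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import csm_symmetry, efa_shape, reduction_allometry
from .exceptions import ParameterError
from .outlines import OutlineSet, contour_metrics, orient_contour, resample_contour

__all__ = ["PipelineConfig", "Report", "run_pipeline", "proportion_latitudinal", "compare_symmetry"]

log = logging.getLogger("lithosym.pipeline")

REPORT_SCHEMA_VERSION = "1"


@dataclass
class PipelineConfig:
    n_points: int = 60
    harmonics: int = 8
    csm_mode: str = "free"  # free | chord
    group_col: str = "assemblage"
    seed: int = 0
    holm: bool = False
    size_mode: str = "size"  # size | area geometric mean

    def __post_init__(self):
        if self.n_points % 2 != 0:
            raise ParameterError("n_points must be even")
        if self.harmonics > self.n_points // 2 - 1:
            raise ParameterError("harmonics must be at most n_points/2 - 1")


@dataclass
class Report:
    """Structured pipeline output; every table is a pandas DataFrame."""

    schema_version: str
    config: dict
    symmetry: pd.DataFrame
    assemblage_summary: pd.DataFrame
    axis_proportions: pd.DataFrame
    shape_variance: pd.DataFrame
    shape_scores: dict  # view -> DataFrame
    reduction: pd.DataFrame
    associations: pd.DataFrame
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "schema_version": self.schema_version,
            "config": self.config,
            "symmetry": self.symmetry.to_dict(orient="records"),
            "assemblage_summary": self.assemblage_summary.to_dict(orient="records"),
            "axis_proportions": self.axis_proportions.to_dict(orient="records"),
            "shape_variance": self.shape_variance.to_dict(orient="records"),
            "reduction": self.reduction.to_dict(orient="records"),
            "associations": self.associations.to_dict(orient="records"),
            "warnings": self.warnings,
        }
        return json.dumps(payload, sort_keys=True, default=float)

    def save(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.symmetry.to_csv(d / "symmetry.csv", index=False)
        self.assemblage_summary.to_csv(d / "assemblage_summary.csv", index=False)
        self.axis_proportions.to_csv(d / "axis_proportions.csv", index=False)
        self.shape_variance.to_csv(d / "shape_variance.csv", index=False)
        for view, df in self.shape_scores.items():
            df.to_csv(d / f"shape_scores_{view}.csv", index=False)
        self.reduction.to_csv(d / "reduction.csv", index=False)
        self.associations.to_csv(d / "associations.csv", index=False)
        (d / "report.json").write_text(self.to_json())


def _symmetry_pass(oset: OutlineSet, cfg: PipelineConfig):
    rows = []
    for c in oset:
        cc = orient_contour(resample_contour(c, cfg.n_points))
        res = csm_symmetry.csm_reflection(cc, mode=cfg.csm_mode)
        m = contour_metrics(cc)
        rows.append({
            "artifact_id": c.artifact_id, "view": c.view,
            "s_value": res.s_value, "best_pairing": res.best_pairing,
            "axis_angle_deg": float(np.degrees(res.axis_angle)),
            "axis_class": res.axis_class,
            "centroid_size": m["centroid_size"], "area": m["area"],
            "perimeter": m["perimeter"],
        })
    return pd.DataFrame(rows)


def _summaries(sym: pd.DataFrame, group_col: str):
    grouped = sym.groupby([group_col, "view"], sort=True)
    rows = []
    for (grp, view), sub in grouped:
        s = sub["s_value"]
        rows.append({
            group_col: grp, "view": view, "n": len(sub),
            "mean_s": s.mean(), "median_s": s.median(), "sd_s": s.std(ddof=1),
            "q1_s": s.quantile(0.25), "q3_s": s.quantile(0.75),
        })
    return pd.DataFrame(rows)


def proportion_latitudinal(sym: pd.DataFrame, group_col: str = "assemblage") -> pd.DataFrame:
    """Fraction of latitudinal best axes per group and view, with binomial
    95% Wilson confidence intervals."""
    if sym.empty:
        raise ParameterError("no symmetry results to summarize")
    rows = []
    for (grp, view), sub in sym.groupby([group_col, "view"], sort=True):
        if len(sub) == 0:
            log.warning("empty group (%s, %s) omitted", grp, view)
            continue
        k = int((sub["axis_class"] == "latitudinal").sum())
        n = len(sub)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append({group_col: grp, "view": view, "n": n, "n_latitudinal": k,
                     "proportion_latitudinal": k / n,
                     "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)


def compare_symmetry(groups: dict, method: str = "student_t"):
    """Compare symmetry distributions between groups.

    ``groups`` maps labels to s-value vectors. Two groups delegate to a
    single two-sample test; more produce all pairwise tests (a DataFrame),
    optionally Holm-adjusted by the caller.
    """
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups to compare")
    labels = list(groups)
    if len(labels) == 2:
        return reduction_allometry.association(groups[labels[0]], groups[labels[1]], method=method)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            res = reduction_allometry.association(groups[labels[i]], groups[labels[j]], method=method)
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "statistic": res.statistic, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def _shape_pass(oset: OutlineSet, cfg: PipelineConfig, group_col: str):
    var_rows, scores = [], {}
    meta = oset.metadata.set_index(["artifact_id", "view"]) if not oset.metadata.empty else None
    by_view = {}
    for c in oset:
        by_view.setdefault(c.view, []).append(c)
    for view, cs in sorted(by_view.items()):
        if len(cs) < 3:
            log.warning("view %s has %d outlines; shape space skipped", view, len(cs))
            continue
        prepared = [orient_contour(resample_contour(c, cfg.n_points)) for c in cs]
        aligned = efa_shape.gpa_align(prepared)
        coeffs = [efa_shape.efa_coefficients(a, cfg.harmonics) for a in aligned.aligned]
        space = efa_shape.shape_pca(efa_shape.coefficient_matrix(coeffs),
                                    labels=[c.artifact_id for c in cs])
        for k, frac in enumerate(space.variance_fractions, start=1):
            var_rows.append({"view": view, "pc": k, "variance_fraction": float(frac)})
        df = pd.DataFrame(space.scores[:, : min(5, space.scores.shape[1])],
                          columns=[f"PC{k + 1}" for k in range(min(5, space.scores.shape[1]))])
        df.insert(0, "artifact_id", [c.artifact_id for c in cs])
        df.insert(1, "view", view)
        if meta is not None:
            grp = [meta[group_col].get((c.artifact_id, c.view), None) if group_col in meta else None
                   for c in cs]
            df[group_col] = grp
        scores[view] = df
    return pd.DataFrame(var_rows), scores


def _reduction_pass(oset: OutlineSet, sym: pd.DataFrame, cfg: PipelineConfig, group_col: str):
    meta = oset.metadata
    rows = []
    size_by = sym.set_index(["artifact_id", "view"])["centroid_size"]
    for aid in oset.artifact_ids:
        views = oset.views_of(aid)
        sizes = {v: float(size_by.get((aid, v), np.nan)) for v in views}
        geo = None
        if all(v in sizes and np.isfinite(sizes[v]) for v in ("top", "lateral", "frontal")):
            geo = float(np.exp(np.mean(np.log([sizes["top"], sizes["lateral"], sizes["frontal"]]))))
        rec = {"artifact_id": aid, "geometric_mean_size": geo}
        for v in ("top", "lateral", "frontal"):
            rec[f"centroid_size_{v}"] = sizes.get(v)
        if not meta.empty:
            sub = meta[meta["artifact_id"] == aid]
            for col in ("invasiveness", "mass", group_col, "raw_material", "blank_type"):
                if col in sub.columns and len(sub):
                    rec[col] = sub.iloc[0][col]
        if "top" in views and rec.get("mass") and rec["mass"] > 0:
            area = contour_metrics(views["top"])["area"]
            rec["plan_area"] = float(area)
            rec["jti"] = reduction_allometry.thinning_index(area, float(rec["mass"]))
        rows.append(rec)
    red = pd.DataFrame(rows)

    assoc_rows = []

    def add(label, res, **ids):
        assoc_rows.append({"comparison": label, **ids, "kind": res.kind,
                           "statistic": res.statistic, "p": res.p, "n": res.n,
                           "df": res.df})

    if "invasiveness" in red.columns and red["invasiveness"].notna().any():
        grp_col_present = group_col in red.columns
        groups = red[group_col].dropna().unique() if grp_col_present else []
        for grp in sorted(groups):
            sub = red[(red[group_col] == grp)].dropna(subset=["invasiveness", "geometric_mean_size"])
            if len(sub) >= 3 and sub["invasiveness"].nunique() > 1:
                res = reduction_allometry.association(sub["invasiveness"].to_numpy(),
                                                      sub["geometric_mean_size"].to_numpy(), "ols")
                add("size_vs_invasiveness", res, group=grp)
        # symmetry vs invasiveness per view, pooled
        s_top = sym.merge(red[["artifact_id", "invasiveness"]], on="artifact_id")
        for view, sub in s_top.groupby("view"):
            sub = sub.dropna(subset=["invasiveness"])
            if len(sub) >= 3 and sub["invasiveness"].nunique() > 1 and sub["s_value"].nunique() > 1:
                res = reduction_allometry.association(sub["invasiveness"].to_numpy(),
                                                      sub["s_value"].to_numpy(), "pearson")
                add("symmetry_vs_invasiveness", res, view=view)
    if "raw_material" in red.columns and group_col in red.columns:
        s_mat = sym.merge(red[["artifact_id", "raw_material"]], on="artifact_id")
        for view, sub in s_mat.groupby("view"):
            mats = sorted(sub["raw_material"].dropna().unique())
            if len(mats) == 2:
                a = sub[sub["raw_material"] == mats[0]]["s_value"].to_numpy()
                b = sub[sub["raw_material"] == mats[1]]["s_value"].to_numpy()
                if min(len(a), len(b)) >= 3:
                    add("symmetry_by_raw_material", reduction_allometry.association(a, b, "student_t"),
                        view=view)
    return red, pd.DataFrame(assoc_rows)


def run_pipeline(data: OutlineSet, cfg: PipelineConfig | None = None) -> Report:
    """Run the full outline-symmetry analysis on an OutlineSet.

    Per contour: resample to ``cfg.n_points``, orient, minimize the
    reflection CSM over all pairings, classify the winning axis. Per view:
    Procrustes-align, compute elliptical Fourier coefficients, PCA. Per
    artifact: sizes, invasiveness, thinning index and the standard
    associations. Missing metadata degrades gracefully (affected analyses
    are skipped, never imputed).
    """
    cfg = cfg or PipelineConfig()
    group_col = cfg.group_col
    sym = _symmetry_pass(data, cfg)
    if not data.metadata.empty and group_col in data.metadata.columns:
        key = data.metadata.set_index(["artifact_id", "view"])[group_col]
        sym[group_col] = [key.get((r.artifact_id, r.view), "all") for r in sym.itertuples()]
    else:
        sym[group_col] = "all"
    summary = _summaries(sym, group_col)
    proportions = proportion_latitudinal(sym, group_col)
    shape_var, shape_scores = _shape_pass(data, cfg, group_col)
    red, assoc = _reduction_pass(data, sym, cfg, group_col)
    return Report(
        schema_version=REPORT_SCHEMA_VERSION,
        config={"n_points": cfg.n_points, "harmonics": cfg.harmonics,
                "csm_mode": cfg.csm_mode, "group_col": group_col, "seed": cfg.seed,
                "size_mode": cfg.size_mode},
        symmetry=sym, assemblage_summary=summary, axis_proportions=proportions,
        shape_variance=shape_var, shape_scores=shape_scores,
        reduction=red, associations=assoc,
    )
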