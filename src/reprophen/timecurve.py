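"""Reprogramming-progression model: rotated PCA embedding, quadratic time
curve, and shortest-distance projection.

The procedure mirrors the transcriptome progression analysis: PCA on the
log-normalized top-variable genes, axes swapped so x = PC2 (the component
that tracks time), a rigid rotation of all samples (default 15 degrees),
an ordinary least-squares degree-2 polynomial fitted to the time-course
samples (default days 2-7), and orthogonal projection of every sample onto
that curve. The projected x coordinate serves as a pseudotime proxy; the
Euclidean distance to the curve measures expression change unrelated to
progression. Day estimates come from monotone interpolation of the
time-course days' own projections.

Projection onto the quadratic is the global minimum of the quartic
``D(x) = (x - px)^2 + (f(x) - py)^2`` over the fit domain, found exactly by
solving the cubic stationarity condition and comparing the real roots with
the domain endpoints; ties break toward smaller x (earlier pseudotime).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .txome import normalize_counts, top_variable_genes

__all__ = ["Embedding2D", "TimeCurveModel", "ProjectionResult",
           "embed", "rotate", "fit_time_curve", "project_onto_curve",
           "project_points", "progression_report", "run_time_projection"]


@dataclass
class Embedding2D:
    coords: pd.DataFrame           # sample -> x, y
    provenance: dict = field(default_factory=dict)


@dataclass
class TimeCurveModel:
    coeffs: tuple[float, float, float]   # y = c0 + c1 x + c2 x^2
    domain: tuple[float, float]          # x range of the fitted time course
    calibration: pd.DataFrame            # day -> projected x (monotone)

    def curve(self, x):
        c0, c1, c2 = self.coeffs
        return c0 + c1 * np.asarray(x) + c2 * np.asarray(x) ** 2


@dataclass
class ProjectionResult:
    x: float          # projected x (pseudotime proxy)
    distance: float   # orthogonal distance to the curve
    day: float        # interpolated day estimate


def embed(lognorm: pd.DataFrame, samples: pd.DataFrame,
          n_top: int = 200) -> Embedding2D:
    """2-D PCA embedding with axes swapped (x = PC2, y = PC1).

    PCA is computed on gene-centered log-normalized values of the top
    variable genes, over all samples (time course and knockdowns together).
    Sign conventions are fixed deterministically using the time-course day
    labels: x is oriented so day increases with x, and y so that the
    time-course arc opens downward (corr(y, centered-day squared) <= 0).
    """
    if lognorm.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    genes = top_variable_genes(lognorm, min(n_top, len(lognorm)))
    X = lognorm.loc[genes].T.values            # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    pca = PCA(n_components=2, svd_solver="full")
    pcs = pca.fit_transform(X)
    if np.count_nonzero(pca.explained_variance_ > 1e-12) < 2:
        raise ValueError("fewer than 2 non-degenerate principal components")
    coords = pd.DataFrame({"x": pcs[:, 1], "y": pcs[:, 0]},
                          index=lognorm.columns)

    day = samples.set_index("sample")["day"].reindex(coords.index)
    tc = day.dropna()
    if len(tc) >= 2:
        d = tc.values.astype(float)
        cx = np.corrcoef(d, coords.loc[tc.index, "x"])[0, 1]
        if np.isfinite(cx) and cx < 0:
            coords["x"] = -coords["x"]
        d2 = (d - d.mean()) ** 2
        if d2.std() > 0:
            cy = np.corrcoef(d2, coords.loc[tc.index, "y"])[0, 1]
            if np.isfinite(cy) and cy > 0:
                coords["y"] = -coords["y"]
    return Embedding2D(coords, {"x": "PC2", "y": "PC1",
                                "rotation_deg": 0.0,
                                "n_top_genes": len(genes)})


def rotate(embedding: Embedding2D, angle_degrees: float = 15.0) -> Embedding2D:
    """Rigid rotation about the origin (counter-clockwise positive)."""
    theta = np.deg2rad(angle_degrees)
    c, s = np.cos(theta), np.sin(theta)
    xy = embedding.coords[["x", "y"]].values
    rot = xy @ np.array([[c, s], [-s, c]])
    coords = pd.DataFrame(rot, columns=["x", "y"],
                          index=embedding.coords.index)
    prov = dict(embedding.provenance)
    prov["rotation_deg"] = prov.get("rotation_deg", 0.0) + angle_degrees
    return Embedding2D(coords, prov)


def fit_time_curve(points: pd.DataFrame, degree: int = 2) -> TimeCurveModel:
    """OLS degree-2 fit of y on x for the (rotated) time-course points.

    ``points`` must have columns x, y and day (one row per time-course
    sample or per-day average). The day-calibration table is built from each
    day's own projection onto the fitted curve, made monotone for
    interpolation.
    """
    if degree != 2:
        raise ValueError("the time curve is quadratic (degree 2) by design")
    x = points["x"].values.astype(float)
    y = points["y"].values.astype(float)
    if len(np.unique(np.round(x, 12))) < 3:
        raise ValueError("need >= 3 distinct x values to fit a quadratic")
    c2, c1, c0 = np.polyfit(x, y, 2)
    model = TimeCurveModel((float(c0), float(c1), float(c2)),
                           (float(x.min()), float(x.max())),
                           pd.DataFrame(columns=["day", "x"]))
    day_means = points.groupby("day")[["x", "y"]].mean().sort_index()
    cal_x = [project_onto_curve((r.x, r.y), model).x
             for r in day_means.itertuples()]
    model.calibration = pd.DataFrame({"day": day_means.index.values,
                                      "x": cal_x})
    return model


def _stationary_points(px: float, py: float,
                       coeffs: tuple[float, float, float]) -> np.ndarray:
    """Real roots of D'(x)/2 = (x-px) + (c1 + 2 c2 x)(f(x) - py) = 0."""
    c0, c1, c2 = coeffs
    poly = np.array([
        2.0 * c2 ** 2,
        3.0 * c1 * c2,
        1.0 + c1 ** 2 + 2.0 * c2 * (c0 - py),
        c1 * (c0 - py) - px,
    ])
    lead = np.nonzero(np.abs(poly) > 0)[0]
    if len(lead) == 0 or lead[0] == len(poly) - 1:
        return np.array([])
    roots = np.roots(poly[lead[0]:])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return real


def project_onto_curve(point: tuple[float, float],
                       model: TimeCurveModel) -> ProjectionResult:
    """Closest point on the fitted curve within its domain.

    The quartic squared-distance is minimized exactly over candidate
    stationary points (clamped to the domain) plus the domain endpoints.
    Equidistant candidates resolve toward smaller x. The day estimate
    interpolates the calibration table, clamped at its ends.
    """
    px, py = float(point[0]), float(point[1])
    lo, hi = model.domain
    cand = np.clip(_stationary_points(px, py, model.coeffs), lo, hi)
    cand = np.unique(np.concatenate([cand, [lo, hi]]))
    d2 = (cand - px) ** 2 + (model.curve(cand) - py) ** 2
    best = np.min(d2)
    xstar = float(np.min(cand[d2 <= best + 1e-12 * (1.0 + best)]))
    dist = float(np.sqrt(max((xstar - px) ** 2
                             + (model.curve(xstar) - py) ** 2, 0.0)))
    day = _interpolate_day(xstar, model)
    return ProjectionResult(xstar, dist, day)


def _interpolate_day(xstar: float, model: TimeCurveModel) -> float:
    cal = model.calibration.sort_values("day")
    if cal.empty:
        return float("nan")
    xs = np.maximum.accumulate(cal["x"].values)   # enforce monotone x(day)
    return float(np.interp(xstar, xs, cal["day"].values))


def project_points(coords: pd.DataFrame, model: TimeCurveModel) -> pd.DataFrame:
    """Project every row of an (x, y) table; returns x, distance, day."""
    rows = [project_onto_curve((r.x, r.y), model) for r in coords.itertuples()]
    return pd.DataFrame({"x": [r.x for r in rows],
                         "distance": [r.distance for r in rows],
                         "day_estimate": [r.day for r in rows]},
                        index=coords.index)


def progression_report(coords: pd.DataFrame, samples: pd.DataFrame,
                       model: TimeCurveModel, reference: str = "nt",
                       delay_threshold: float = 1.0) -> pd.DataFrame:
    """Replicate-averaged pseudotime, day estimate and residual per condition.

    Knockdown conditions whose day estimate trails the reference nt control
    by more than ``delay_threshold`` days are flagged delayed.
    """
    cond = samples.set_index("sample")["condition"].reindex(coords.index)
    avg = coords.groupby(cond).mean()
    proj = project_points(avg, model)
    proj.insert(0, "condition", proj.index)
    day = samples.groupby("condition")["day"].first()
    proj["is_timecourse"] = proj.index.map(lambda c: pd.notna(day.get(c)))
    if reference in proj.index:
        ref_day = proj.loc[reference, "day_estimate"]
        proj["delayed"] = (~proj["is_timecourse"]) & \
            (proj["day_estimate"] < ref_day - delay_threshold)
    else:
        warnings.warn(f"reference condition {reference!r} missing; "
                      "delay flags not set", RuntimeWarning, stacklevel=2)
        proj["delayed"] = False
    return proj.sort_values("x").reset_index(drop=True)


def run_time_projection(counts: pd.DataFrame, samples: pd.DataFrame,
                        n_top: int = 200, angle: float = 15.0,
                        fit_days: tuple[float, float] = (2.0, 7.0),
                        reference: str = "nt",
                        delay_threshold: float = 1.0) -> dict:
    """Full pipeline: normalize, embed, rotate, fit, project, report."""
    lognorm = normalize_counts(counts)
    embedding = embed(lognorm, samples, n_top=n_top)
    rotated = rotate(embedding, angle)
    day = samples.set_index("sample")["day"].reindex(rotated.coords.index)
    in_fit = day.between(*fit_days)
    if in_fit.sum() < 3:
        raise ValueError(
            f"need >= 3 time-course samples with day in {fit_days}")
    tc_pts = rotated.coords.loc[in_fit].copy()
    tc_pts["day"] = day.loc[in_fit]
    tc_avg = tc_pts.groupby("day")[["x", "y"]].mean().reset_index()
    model = fit_time_curve(tc_avg)
    sample_proj = project_points(rotated.coords, model)
    report = progression_report(rotated.coords, samples, model,
                                reference=reference,
                                delay_threshold=delay_threshold)
    return {"lognorm": lognorm, "embedding": embedding, "rotated": rotated,
            "model": model, "sample_projections": sample_proj,
            "report": report}
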