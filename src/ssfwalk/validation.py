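"""Emergent-pattern validation: home ranges, resource selection functions,
and scenario contrasts.

The simulator is judged not on its likelihood but on the higher-level
patterns it reproduces: do simulated animals select landcover classes the
way real ones do (per-individual RSF coefficient vectors compared by Pearson
and Spearman correlation), and are their 95% minimum-convex-polygon home
ranges the right size (a symmetric area-ratio index that is 0 for equality)?
Scenario experiments compare pooled per-run RSF coefficients and MCP areas
between two landscapes with rank tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint, Point, Polygon, box

from .landscape import LandscapeGrid


# ---------------------------------------------------------------------------
# 95% minimum convex polygon


@dataclass
class HomeRange:
    polygon: Polygon
    area_km2: float
    degenerate: bool = False


def mcp95(points, trim: float = 0.05) -> HomeRange:
    """95% MCP: drop the floor(trim * n) points farthest from the centroid,
    take the convex hull of the rest.

    Collinear or duplicate point sets give a zero-area range flagged
    degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 (x, y) points")
    centroid = pts.mean(axis=0)
    d = np.hypot(*(pts - centroid).T)
    n_drop = int(math.floor(trim * len(pts)))
    if n_drop > 0:
        keep = np.argsort(d, kind="stable")[: len(pts) - n_drop]
        pts = pts[keep]
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        return HomeRange(Polygon(), 0.0, degenerate=True)
    return HomeRange(hull, hull.area / 1e6)


def homerange_index(area_sim: float, area_real: float) -> float:
    """Symmetric home-range size index: 0 for equal areas, +1 when the
    simulated range is twice the real one, -1 for the reverse."""
    if area_sim <= 0 or area_real <= 0:
        raise ValueError("areas must be positive")
    if area_sim >= area_real:
        return area_sim / area_real - 1.0
    return -(area_real / area_sim - 1.0)


# ---------------------------------------------------------------------------
# Resource selection functions


@dataclass
class RSFModel:
    """Logistic used-vs-available model on landcover presence dummies."""

    beta: pd.Series                 # index: class code (reference absent)
    se: pd.Series
    ci_lo: pd.Series
    ci_hi: pd.Series
    reference_class: int
    flagged: set = field(default_factory=set)   # classes with non-finite fits

    def finite(self) -> pd.Series:
        keep = [c for c in self.beta.index if c not in self.flagged
                and np.isfinite(self.beta[c])]
        return self.beta[keep]

    def significant(self) -> pd.Series:
        fin = self.finite()
        keep = [c for c in fin.index if self.ci_lo[c] > 0 or self.ci_hi[c] < 0]
        return fin[keep]


def _sample_in_polygon(polygon: Polygon, n: int, rng: np.random.Generator,
                       cap_factor: int = 200) -> np.ndarray:
    minx, miny, maxx, maxy = polygon.bounds
    out = []
    tries = 0
    while len(out) < n and tries < cap_factor * n:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        tries += 1
        if polygon.contains(Point(x, y)):
            out.append((x, y))
    if len(out) < n:
        raise RuntimeError("could not sample availability points in polygon")
    return np.array(out)


def _classes_at(points: np.ndarray, grid: LandscapeGrid) -> np.ndarray:
    cls = np.empty(len(points), dtype=int)
    for i, (x, y) in enumerate(points):
        r, c = grid.point_to_cell(x, y)
        cls[i] = grid.cover_type[r, c]
    return cls


def rsf_fit(used_points, availability_polygon: Polygon, grid: LandscapeGrid,
            n_random: int | None = None, rng: np.random.Generator | None = None,
            reference_class: int = 9, random_per_used: int = 10) -> RSFModel:
    """Used/available logistic regression on landcover class dummies.

    Availability points are uniform in the polygon (default 10 per used
    point).  The reference class carries no coefficient; classes absent from
    the pooled sample are dropped, and separated classes (entirely used or
    entirely available) are flagged non-finite.  A reference class that is
    itself unusable — never used, or absent from the sample — would separate
    every contrast at once, so in that case the most-used class stands in as
    reference (recorded on the returned model).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    used = np.asarray(used_points, dtype=float)
    if len(used) == 0:
        raise ValueError("need at least one used point")
    n_random = n_random if n_random is not None else random_per_used * len(used)
    avail = _sample_in_polygon(availability_polygon, n_random, rng)
    pts = np.vstack([used, avail])
    y = np.r_[np.ones(len(used)), np.zeros(len(avail))]
    cls = _classes_at(pts, grid)
    present = sorted(set(cls.tolist()))
    used_cls = cls[: len(used)]
    if not np.any(used_cls == reference_class):
        counts = np.bincount(used_cls)
        reference_class = int(np.argmax(counts))
    dummy_classes = [c for c in present if c != reference_class]
    if dummy_classes:
        dummies = np.column_stack([(cls == c).astype(float) for c in dummy_classes])
    else:
        dummies = np.empty((len(pts), 0))
    X = np.column_stack([np.ones(len(pts)), dummies])
    import statsmodels.api as sm
    flagged = set()
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
    except Exception:
        params = np.full(len(dummy_classes) + 1, np.nan)
        bse = np.full_like(params, np.nan)
        flagged.update(dummy_classes)
    beta = pd.Series(params[1:], index=dummy_classes, dtype=float)
    se = pd.Series(bse[1:], index=dummy_classes, dtype=float)
    # separation: absurd magnitude or exploded SE
    for c in dummy_classes:
        if not np.isfinite(beta[c]) or not np.isfinite(se[c]) \
                or abs(beta[c]) > 15 or se[c] > 50:
            flagged.add(c)
    z = stats.norm.ppf(0.975)
    return RSFModel(beta=beta, se=se, ci_lo=beta - z * se, ci_hi=beta + z * se,
                    reference_class=reference_class, flagged=flagged)


def compare_beta_vectors(real_rsf: RSFModel, sim_rsfs, mode: str = "all"
                         ) -> pd.DataFrame:
    """Pearson R and Spearman r_s between a real individual's RSF coefficient
    vector and each simulated run's, over shared finite coefficients.

    ``mode='significant'`` restricts to coefficients whose 95% CI excludes 0
    in the real model.  Runs sharing fewer than 3 coefficients are flagged
    with NaN correlations.
    """
    if mode not in ("all", "significant"):
        raise ValueError("mode must be 'all' or 'significant'")
    base = real_rsf.finite() if mode == "all" else real_rsf.significant()
    rows = []
    for i, sim in enumerate(sim_rsfs):
        shared = [c for c in base.index if c in sim.finite().index]
        if len(shared) < 3:
            rows.append({"run": i, "R": np.nan, "r_s": np.nan,
                         "n_shared": len(shared)})
            continue
        a = base[shared].to_numpy()
        b = sim.beta[shared].to_numpy()
        R = float(stats.pearsonr(a, b)[0])
        r_s = float(stats.spearmanr(a, b)[0])
        rows.append({"run": i, "R": R, "r_s": r_s, "n_shared": len(shared)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario contrasts


def extent_polygon(grid: LandscapeGrid) -> Polygon:
    x0, y0 = grid.origin
    return box(x0, y0, x0 + grid.ncols * grid.cell_size,
               y0 + grid.nrows * grid.cell_size)


def scenario_contrast(runs_a, runs_b, grid_a: LandscapeGrid, grid_b: LandscapeGrid,
                      rng: np.random.Generator | None = None,
                      reference_class: int = 9, random_per_used: int = 5) -> dict:
    """Compare two scenarios' emergent selection and home-range patterns.

    ``runs_a``/``runs_b`` are lists of step logs (one per simulation run,
    with columns individual, x1, y1).  Per run, one pooled RSF is fitted over
    all individuals with availability drawn over the whole extent; per-class
    coefficient distributions across runs are compared by Wilcoxon-Mann-
    Whitney tests, as are per-individual MCP areas.

    Returns a dict with 'beta_a'/'beta_b' (runs x classes), 'beta_tests'
    (per-class U and p; classes absent in a scenario excluded with a flag),
    'mcp_a'/'mcp_b' (areas), and 'mcp_test'.
    """
    if len(runs_a) < 2 or len(runs_b) < 2:
        raise ValueError("need >= 2 runs per scenario")
    rng = rng if rng is not None else np.random.default_rng(0)

    def _run_betas(runs, grid):
        poly = extent_polygon(grid)
        rows = []
        for log_df in runs:
            used = log_df[["x1", "y1"]].to_numpy(float)
            m = rsf_fit(used, poly, grid, rng=rng, reference_class=reference_class,
                        random_per_used=random_per_used)
            rows.append(m.finite())
        return pd.DataFrame(rows).reset_index(drop=True)

    def _run_mcps(runs):
        areas = []
        for log_df in runs:
            for _, sub in log_df.groupby("individual"):
                pts = sub[["x1", "y1"]].to_numpy(float)
                if len(pts) >= 3:
                    hr = mcp95(pts)
                    if not hr.degenerate:
                        areas.append(hr.area_km2)
        return np.array(areas)

    beta_a = _run_betas(runs_a, grid_a)
    beta_b = _run_betas(runs_b, grid_b)
    tests = []
    for cls in sorted(set(beta_a.columns) | set(beta_b.columns)):
        a = beta_a[cls].dropna().to_numpy() if cls in beta_a else np.array([])
        b = beta_b[cls].dropna().to_numpy() if cls in beta_b else np.array([])
        if len(a) < 2 or len(b) < 2:
            tests.append({"class": cls, "U": np.nan, "p": np.nan,
                          "excluded": True})
            continue
        if np.ptp(np.r_[a, b]) == 0:
            tests.append({"class": cls, "U": len(a) * len(b) / 2.0, "p": 1.0,
                          "excluded": False})
            continue
        U, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        tests.append({"class": cls, "U": float(U), "p": float(p),
                      "excluded": False})
    mcp_a = _run_mcps(runs_a)
    mcp_b = _run_mcps(runs_b)
    if len(mcp_a) >= 2 and len(mcp_b) >= 2 and np.ptp(np.r_[mcp_a, mcp_b]) > 0:
        U, p = stats.mannwhitneyu(mcp_a, mcp_b, alternative="two-sided")
        mcp_test = {"U": float(U), "p": float(p)}
    else:
        mcp_test = {"U": np.nan, "p": np.nan}
    return {"beta_a": beta_a, "beta_b": beta_b,
            "beta_tests": pd.DataFrame(tests),
            "mcp_a": mcp_a, "mcp_b": mcp_b, "mcp_test": mcp_test}
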