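import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st_h
from scipy import stats
from shapely.geometry import box

from ssfwalk.validation import (
    RSFModel,
    compare_beta_vectors,
    extent_polygon,
    homerange_index,
    mcp95,
    rsf_fit,
    scenario_contrast,
)

from conftest import uniform_grid


# ---------------------------------------------------------------------------
# 95% minimum convex polygon


def test_mcp_trims_constructed_outliers():
    rng = np.random.default_rng(0)
    inside = rng.uniform(0, 1, (95, 2))
    outliers = np.array([[1e3, 1e3], [-1e3, 1e3], [1e3, -1e3],
                         [-1e3, -1e3], [0, 1.5e3]])
    hr = mcp95(np.vstack([inside, outliers]))
    hull_inside = mcp95(inside, trim=0.0)
    assert hr.area_km2 == pytest.approx(hull_inside.area_km2, rel=1e-9)
    assert hr.area_km2 < 1e-5  # ~unit square in km^2


def test_mcp_degenerate_points_flagged():
    pts = np.tile([[5.0, 5.0]], (10, 1))
    hr = mcp95(pts)
    assert hr.degenerate and hr.area_km2 == 0.0
    collinear = np.column_stack([np.arange(10.0), np.arange(10.0)])
    hr2 = mcp95(collinear)
    assert hr2.degenerate and hr2.area_km2 == 0.0


def gift_wrap_area(pts):
    """Independent convex-hull + shoelace oracle."""
    pts = [tuple(p) for p in pts]
    start = min(pts)
    hull = [start]
    cur = start
    prev_dir = None
    while True:
        nxt = None
        for cand in pts:
            if cand == cur:
                continue
            if nxt is None:
                nxt = cand
                continue
            cross = ((nxt[0] - cur[0]) * (cand[1] - cur[1])
                     - (nxt[1] - cur[1]) * (cand[0] - cur[0]))
            if cross < 0 or (cross == 0 and
                             math.dist(cur, cand) > math.dist(cur, nxt)):
                nxt = cand
        if nxt == start:
            break
        hull.append(nxt)
        cur = nxt
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def test_mcp_area_matches_independent_hull_oracle():
    rng = np.random.default_rng(3)
    for _ in range(5):
        pts = rng.uniform(0, 5000, (20, 2))
        hr = mcp95(pts, trim=0.0)
        assert hr.area_km2 * 1e6 == pytest.approx(gift_wrap_area(pts), rel=1e-9)


def test_mcp_rigid_motion_invariance():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 1000, (50, 2))
    base = mcp95(pts).area_km2
    th = 0.7
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    moved = pts @ R.T + np.array([12345.0, -6789.0])
    assert mcp95(moved).area_km2 == pytest.approx(base, rel=1e-9)


# ---------------------------------------------------------------------------
# home-range index


def test_homerange_index_reference_points():
    assert homerange_index(10.0, 10.0) == 0.0
    assert homerange_index(20.0, 10.0) == pytest.approx(1.0)
    assert homerange_index(10.0, 20.0) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        homerange_index(0.0, 5.0)


@given(st_h.floats(min_value=0.1, max_value=1e4),
       st_h.floats(min_value=0.1, max_value=1e4))
def test_homerange_index_antisymmetric(a, b):
    assert homerange_index(a, b) == pytest.approx(-homerange_index(b, a),
                                                  abs=1e-9)


# ---------------------------------------------------------------------------
# RSF estimation


def two_class_grid(side=100):
    grid = uniform_grid(side, side, cls=9)   # reference class
    grid.cover_type[:, side // 2:] = 11      # east half: lichen conifer
    return grid


def test_rsf_recovers_known_odds_ratio():
    grid = two_class_grid()
    poly = extent_polygon(grid)
    rng = np.random.default_rng(1)
    n = 10_000
    # used points select class 11 at odds 2:1 relative to availability (50/50)
    east = rng.uniform([1250.0, 0.0], [2500.0, 2500.0], (n, 2))
    west = rng.uniform([0.0, 0.0], [1250.0, 2500.0], (n, 2))
    pick_east = rng.random(n) < 2 / 3
    used = np.where(pick_east[:, None], east, west)
    m = rsf_fit(used, poly, grid, n_random=20_000, rng=rng)
    assert 11 in m.beta.index
    assert abs(m.beta[11] - math.log(2)) < 3 * m.se[11]


def test_rsf_null_calibration():
    grid = two_class_grid()
    poly = extent_polygon(grid)
    ok = 0
    n_runs = 25
    for i in range(n_runs):
        rng = np.random.default_rng(50 + i)
        used = rng.uniform(0, 2500, (300, 2))  # identical to availability
        m = rsf_fit(used, poly, grid, rng=rng)
        fin = m.finite()
        if all(abs(fin[c]) < 2 * m.se[c] for c in fin.index):
            ok += 1
    assert ok >= 0.8 * n_runs


def test_rsf_unused_class_strongly_negative_or_flagged():
    grid = two_class_grid()
    poly = extent_polygon(grid)
    rng = np.random.default_rng(2)
    used = rng.uniform([0.0, 0.0], [1250.0, 2500.0], (500, 2))  # never east
    m = rsf_fit(used, poly, grid, rng=rng)
    assert (11 in m.flagged) or (m.beta[11] < -2)


def test_rsf_requires_used_points():
    grid = two_class_grid()
    with pytest.raises(ValueError):
        rsf_fit(np.empty((0, 2)), extent_polygon(grid), grid)


# ---------------------------------------------------------------------------
# beta-vector comparison


def _rsf_from(betas, se=0.1, reference_class=9):
    s = pd.Series(betas, dtype=float)
    se = pd.Series(se, index=s.index, dtype=float)
    z = stats.norm.ppf(0.975)
    return RSFModel(beta=s, se=se, ci_lo=s - z * se, ci_hi=s + z * se,
                    reference_class=reference_class)


def test_identical_and_negated_vectors():
    real = _rsf_from({1: 0.5, 2: -1.0, 3: 2.0, 4: 0.8})
    same = _rsf_from({1: 0.5, 2: -1.0, 3: 2.0, 4: 0.8})
    neg = _rsf_from({1: -0.5, 2: 1.0, 3: -2.0, 4: -0.8})
    out = compare_beta_vectors(real, [same, neg])
    assert out.loc[0, "R"] == pytest.approx(1.0)
    assert out.loc[0, "r_s"] == pytest.approx(1.0)
    assert out.loc[1, "R"] == pytest.approx(-1.0)
    assert out.loc[1, "r_s"] == pytest.approx(-1.0)


def test_correlations_match_textbook_oracle():
    a = {1: 0.2, 2: -0.7, 3: 1.4, 4: 0.1, 5: -1.1}
    b = {1: 0.5, 2: -0.2, 3: 0.9, 4: 0.4, 5: -0.8}
    out = compare_beta_vectors(_rsf_from(a), [_rsf_from(b)])
    va, vb = np.array(list(a.values())), np.array(list(b.values()))
    R = np.corrcoef(va, vb)[0, 1]
    ra = stats.rankdata(va)
    rb = stats.rankdata(vb)
    rs = np.corrcoef(ra, rb)[0, 1]
    assert out.loc[0, "R"] == pytest.approx(R)
    assert out.loc[0, "r_s"] == pytest.approx(rs)


def test_significant_mode_and_insufficient_overlap():
    real = _rsf_from({1: 0.05, 2: -1.0, 3: 2.0, 4: 0.8}, se=0.1)
    sim = _rsf_from({2: -0.9, 3: 1.8, 4: 0.9})
    out = compare_beta_vectors(real, [sim], mode="significant")
    assert out.loc[0, "n_shared"] == 3  # class 1 CI includes 0
    small = _rsf_from({2: -0.9, 3: 1.8})
    out2 = compare_beta_vectors(real, [small])
    assert np.isnan(out2.loc[0, "R"])  # < 3 shared -> flagged


def test_common_permutation_invariance():
    rng = np.random.default_rng(6)
    keys = [1, 2, 4, 5, 6, 7]
    a = dict(zip(keys, rng.normal(size=6)))
    b = dict(zip(keys, rng.normal(size=6)))
    base = compare_beta_vectors(_rsf_from(a), [_rsf_from(b)])
    perm = list(reversed(keys))
    ap = {k: a[k] for k in perm}
    bp = {k: b[k] for k in perm}
    out = compare_beta_vectors(_rsf_from(ap), [_rsf_from(bp)])
    assert out.loc[0, "R"] == pytest.approx(base.loc[0, "R"])
    assert out.loc[0, "r_s"] == pytest.approx(base.loc[0, "r_s"])


# ---------------------------------------------------------------------------
# scenario contrasts


def _fake_run(rng, grid, n=300, bias_class=None, bias_p=0.0):
    """Synthetic step log: locations uniform, optionally biased to one class."""
    side = grid.ncols * grid.cell_size
    pts = rng.uniform(0, side, (n, 2))
    if bias_class is not None:
        cells = np.argwhere(grid.cover_type == bias_class)
        take = rng.random(n) < bias_p
        for i in np.where(take)[0]:
            r, c = cells[rng.integers(len(cells))]
            pts[i] = grid.cell_center(int(r), int(c))
    return pd.DataFrame({"individual": np.repeat(np.arange(3), n // 3),
                         "x1": pts[:, 0], "y1": pts[:, 1]})


def test_identical_scenarios_not_rejected():
    grid = two_class_grid(60)
    rng = np.random.default_rng(7)
    runs = [_fake_run(np.random.default_rng(100 + i), grid) for i in range(4)]
    out = scenario_contrast(runs, runs, grid, grid, rng=rng)
    tests = out["beta_tests"].dropna(subset=["p"])
    assert (tests["p"] == 1.0).all()  # identical samples: never significant
    assert out["mcp_test"]["p"] == 1.0


def test_forced_selection_shift_detected():
    grid = uniform_grid(60, 60, cls=9)
    grid.cover_type[20:40, 20:40] = 12
    hits = 0
    reps = 10
    for rep in range(reps):
        rng = np.random.default_rng(200 + rep)
        runs_a = [_fake_run(rng, grid) for _ in range(4)]
        runs_b = [_fake_run(rng, grid, bias_class=12, bias_p=0.5)
                  for _ in range(4)]
        out = scenario_contrast(runs_a, runs_b, grid, grid, rng=rng)
        t = out["beta_tests"]
        row = t[t["class"] == 12]
        if len(row) and row["p"].iloc[0] < 0.05:
            hits += 1
    assert hits >= 0.8 * reps


def test_rank_test_matches_permutation_oracle():
    a = np.array([1.2, 3.4, 2.2])
    b = np.array([4.1, 5.0, 3.9])
    U, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    # exhaustive enumeration of the 20 labelings of 3-vs-3
    pooled = np.r_[a, b]
    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = pooled[[i for i in range(6) if i not in idx_a]]
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)
    observed = u_stat(range(3))
    us = [u_stat(c) for c in itertools.combinations(range(6), 3)]
    n = len(us)
    extreme = sum(min(u, 9 - u) <= min(observed, 9 - observed) for u in us)
    assert p == pytest.approx(extreme / n)


def test_scenario_requires_two_runs():
    grid = two_class_grid(30)
    with pytest.raises(ValueError):
        scenario_contrast([_fake_run(np.random.default_rng(0), grid)],
                          [], grid, grid)
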