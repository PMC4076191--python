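import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssfwalk.ssf import (
    FitError,
    build_independence_partition,
    conditional_loglik,
    fit_clogit,
    kfold_cv,
    model_select,
    qic,
    rank_bin_spearman,
    sandwich_covariance,
    simulate_clogit_strata,
    vif,
)


# ---------------------------------------------------------------------------
# conditional-likelihood fitting


def test_constant_covariates_unidentifiable():
    rows = []
    for s in range(5):
        for j in range(4):
            rows.append({"stratum": s, "case": int(j == 0), "x0": 1.0,
                         "individual": "a", "t_end": s})
    with pytest.raises(FitError, match="unidentifiable"):
        fit_clogit(pd.DataFrame(rows), terms=["x0"])


def test_one_parameter_fit_matches_grid_search_oracle():
    table = simulate_clogit_strata([0.8], n_strata=60, n_controls=5,
                                   rng=np.random.default_rng(3))
    m = fit_clogit(table, terms=["x0"])
    # independent oracle: dense grid scan refined around the best point
    grid = np.linspace(-3, 3, 1201)
    lls = [conditional_loglik(table, ["x0"], [b]) for b in grid]
    best = grid[int(np.argmax(lls))]
    fine = np.linspace(best - 0.01, best + 0.01, 2001)
    lls = [conditional_loglik(table, ["x0"], [b]) for b in fine]
    best = fine[int(np.argmax(lls))]
    assert m.beta[0] == pytest.approx(best, abs=1e-4)


def test_two_parameter_recovery_within_3_se():
    truth = np.array([1.0, -0.5])
    table = simulate_clogit_strata(truth, n_strata=500, n_controls=20,
                                   rng=np.random.default_rng(7))
    m = fit_clogit(table, terms=["x0", "x1"])
    z = (m.beta - truth) / m.se_naive
    assert np.all(np.abs(z) < 3.0)


def test_likelihood_invariant_to_stratum_constant_shift():
    table = simulate_clogit_strata([0.5, -0.3], n_strata=40,
                                   rng=np.random.default_rng(1))
    beta = [0.4, -0.2]
    base = conditional_loglik(table, ["x0", "x1"], beta)
    shifted = table.copy()
    offsets = {s: rng for s, rng in
               zip(shifted["stratum"].unique(),
                   np.random.default_rng(2).normal(0, 5, shifted["stratum"].nunique()))}
    shifted["x0"] = shifted["x0"] + shifted["stratum"].map(offsets)
    assert conditional_loglik(shifted, ["x0", "x1"], beta) == pytest.approx(base, abs=1e-8)


def test_separation_is_reported_not_returned():
    # observed step always has the strictly largest covariate: monotone likelihood
    rows = []
    rng = np.random.default_rng(0)
    for s in range(30):
        vals = np.sort(rng.normal(size=6))
        for j, v in enumerate(vals):
            rows.append({"stratum": s, "case": int(j == 5), "x0": v,
                         "individual": "a", "t_end": s})
    with pytest.raises(FitError):
        fit_clogit(pd.DataFrame(rows), terms=["x0"])


def test_fit_matches_r_survival_clogit():
    """Cross-check the Newton fitter against R's survival::clogit."""
    table = simulate_clogit_strata([0.7, -0.4, 0.2], n_strata=80, n_controls=10,
                                   rng=np.random.default_rng(11))
    m = fit_clogit(table, terms=["x0", "x1", "x2"])
    import tempfile, os
    with tempfile.TemporaryDirectory() as td:
        csv = os.path.join(td, "tab.csv")
        table.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(survival))
            d <- read.csv("{csv}")
            f <- clogit(case ~ x0 + x1 + x2 + strata(stratum), data = d)
            cat(sprintf("%.10f %.10f %.10f\\n", coef(f)[1], coef(f)[2], coef(f)[3]))
            cat(sprintf("%.10f %.10f %.10f\\n", sqrt(diag(vcov(f)))[1],
                        sqrt(diag(vcov(f)))[2], sqrt(diag(vcov(f)))[3]))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    lines = out.stdout.strip().splitlines()
    r_beta = np.array([float(v) for v in lines[0].split()])
    r_se = np.array([float(v) for v in lines[1].split()])
    assert np.allclose(m.beta, r_beta, atol=1e-4)
    assert np.allclose(m.se_naive, r_se, rtol=1e-3)


# ---------------------------------------------------------------------------
# independence partition


def _toy_table(n_strata, individual="a", t0=0, x=0.0):
    rows = []
    for s in range(n_strata):
        sid = f"{individual}-{s}"
        for j in range(3):
            rows.append({"stratum": sid, "individual": individual,
                         "t_end": t0 + s, "case": int(j == 0),
                         "x0": x, "y0": 0.0})
    return pd.DataFrame(rows)


def test_partition_blocks_and_gap_arithmetic():
    table = _toy_table(26)
    part = build_independence_partition(table, block_len=24, gap=2)
    assert len(part.retained) == 24
    assert len(part.dropped) == 2
    assert part.n_clusters() == 1


def test_partition_merges_simultaneous_close_individuals():
    a = _toy_table(5, "a", x=0.0)
    b = _toy_table(5, "b", x=50.0)  # 50 m apart at every shared timestamp
    part = build_independence_partition(pd.concat([a, b]), block_len=24)
    clusters = {part.cluster_of[s] for s in part.retained}
    assert len(clusters) == 1


def test_partition_keeps_distant_individuals_separate():
    a = _toy_table(5, "a", x=0.0)
    b = _toy_table(5, "b", x=500.0)
    part = build_independence_partition(pd.concat([a, b]), block_len=24)
    ca = {part.cluster_of[s] for s in part.retained if s.startswith("a")}
    cb = {part.cluster_of[s] for s in part.retained if s.startswith("b")}
    assert ca.isdisjoint(cb)


# ---------------------------------------------------------------------------
# sandwich covariance and QIC


def test_sandwich_close_to_naive_under_independence():
    table = simulate_clogit_strata([0.6], n_strata=600,
                                   rng=np.random.default_rng(5))
    m = fit_clogit(table, terms=["x0"])
    V = sandwich_covariance(m)  # every stratum its own cluster
    ratio = np.sqrt(V[0, 0]) / m.se_naive[0]
    assert 0.8 < ratio < 1.2


def test_duplicating_strata_keeps_beta_and_halves_sandwich():
    table = simulate_clogit_strata([0.8], n_strata=100,
                                   rng=np.random.default_rng(9))
    dup = table.copy()
    dup["stratum"] = dup["stratum"] + 1000
    both = pd.concat([table, dup], ignore_index=True)
    m1 = fit_clogit(table, terms=["x0"])
    m2 = fit_clogit(both, terms=["x0"])
    assert m2.beta[0] == pytest.approx(m1.beta[0], abs=1e-6)
    V1 = sandwich_covariance(m1)
    V2 = sandwich_covariance(m2)
    assert V2[0, 0] == pytest.approx(V1[0, 0] / 2, rel=1e-4)


def test_single_cluster_sandwich_degenerate():
    table = simulate_clogit_strata([0.5], n_strata=50,
                                   rng=np.random.default_rng(2))
    m = fit_clogit(table, terms=["x0"])
    part = build_independence_partition(table.assign(individual="a"),
                                        block_len=10**6)
    with pytest.raises(FitError, match="single cluster"):
        sandwich_covariance(m, part)


def test_qic_close_to_aic_under_independence():
    table = simulate_clogit_strata([0.7, -0.3], n_strata=600,
                                   rng=np.random.default_rng(4))
    m = fit_clogit(table, terms=["x0", "x1"])
    q = qic(m)
    aic = -2 * m.loglik + 2 * m.k
    assert abs(q - aic) / abs(aic) < 0.05


def test_noise_covariate_raises_qic_most_of_the_time():
    hits = 0
    n_sets = 100
    for i in range(n_sets):
        rng = np.random.default_rng(100 + i)
        table = simulate_clogit_strata([0.8], n_strata=100, n_controls=10, rng=rng)
        table["x_noise"] = rng.standard_normal(len(table))
        m1 = fit_clogit(table, terms=["x0"])
        m2 = fit_clogit(table, terms=["x0", "x_noise"])
        if qic(m2) > qic(m1):
            hits += 1
    assert hits >= 80


def test_model_select_prefers_generating_model(cov_table):
    part = build_independence_partition(cov_table)
    sel = model_select(cov_table, part)
    assert sel.index[0] == "environment"
    assert sel.loc["environment", "dQIC"] == 0.0
    assert sel["weight"].sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# VIF


def test_vif_orthogonal_covariates_near_one():
    rng = np.random.default_rng(8)
    n = 4000
    table = pd.DataFrame({
        "stratum": np.repeat(np.arange(n // 4), 4),
        "case": np.tile([1, 0, 0, 0], n // 4),
        "a": rng.standard_normal(n), "b": rng.standard_normal(n),
    })
    v = vif(table, terms=["a", "b"])
    assert np.all(v < 1.1)


def test_vif_duplicated_covariate_flags_infinity():
    rng = np.random.default_rng(8)
    table = pd.DataFrame({
        "stratum": np.repeat(np.arange(50), 4),
        "case": np.tile([1, 0, 0, 0], 50),
        "a": rng.standard_normal(200),
    })
    table["b"] = table["a"]
    v = vif(table, terms=["a", "b"])
    assert np.isinf(v["a"]) and np.isinf(v["b"])


def test_vif_matches_construction_r2_075():
    rng = np.random.default_rng(12)
    n = 20_000
    x1 = rng.standard_normal(n)
    e = rng.standard_normal(n)
    e = e - e @ x1 / (x1 @ x1) * x1          # exactly orthogonal noise
    e = e / e.std() * x1.std() / np.sqrt(3)  # var(e) = var(x1)/3 -> R^2 = 0.75
    table = pd.DataFrame({
        "stratum": np.repeat(np.arange(n // 4), 4),
        "case": np.tile([1, 0, 0, 0], n // 4),
        "x1": x1, "x2": x1 + e,
    })
    v = vif(table, terms=["x1", "x2"])
    assert v["x2"] == pytest.approx(4.0, abs=0.15)


# ---------------------------------------------------------------------------
# k-fold rank-bin cross-validation


def spearman_oracle(x, y):
    """From-scratch Spearman with midranks (independent of scipy)."""
    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def test_oracle_scorer_reaches_tie_handled_maximum(cov_table):
    res = kfold_cv(cov_table, reps=20, rng=np.random.default_rng(3),
                   score_fn=lambda df: df["case"].to_numpy(float))
    n_bins = len(res.bin_counts)
    expected = spearman_oracle(np.arange(1, n_bins + 1),
                               [0.0] * (n_bins - 1) + [1.0])
    assert np.allclose(res.rs_samples, expected, atol=1e-12)
    assert res.bin_counts[:-1].sum() == 0  # all mass in the top bin


def test_anti_oracle_scorer_gives_negative_rs(cov_table):
    res = kfold_cv(cov_table, reps=10, rng=np.random.default_rng(4),
                   score_fn=lambda df: -df["case"].to_numpy(float))
    assert res.mean_rs < 0


def test_random_scorer_null_centred_on_zero(cov_table):
    rng = np.random.default_rng(5)
    res = kfold_cv(cov_table, reps=100, rng=rng,
                   score_fn=lambda df: rng.standard_normal(len(df)))
    assert abs(res.mean_rs) < 0.1
    assert abs(res.null_mean) < 0.1


def test_fitted_model_cv_beats_null(cov_table):
    res = kfold_cv(cov_table, "environment", reps=10,
                   rng=np.random.default_rng(6))
    assert res.mean_rs > res.null_mean
    assert res.mean_rs > 0.5


def test_rank_bin_spearman_agrees_with_scipy_and_oracle():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 20, 21).astype(float)
    ours = rank_bin_spearman(counts)
    assert ours == pytest.approx(spearman_oracle(np.arange(1, 22), counts), abs=1e-12)
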