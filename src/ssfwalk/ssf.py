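"""Step-selection-function estimation and validation statistics.

The SSF is a conditional logistic regression: within each stratum (one
observed step and its matched random steps sharing a start point) the
observed step's probability is softmax(beta.x) over the stratum.  The log
conditional likelihood

    l(beta) = sum_s [ beta.x_obs - log sum_{j in s} exp(beta.x_j) ]

is maximized by Newton-Raphson with step-halving.  Because consecutive steps
of one animal are autocorrelated, inference uses a cluster-robust sandwich
covariance A^-1 B A^-1 over independence clusters, and model selection uses
the quasi-likelihood under independence criterion
QIC = -2 l + 2 trace(A V_robust), which reduces to AIC when clusters are
uninformative.

Three nested candidate models are predefined: memory (the patch-direction
cosine alone), energetic (adds the gain/loss ratio and its energy-balance
interaction), and environment (all ten terms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .replay import COVARIATE_COLUMNS

FORMULAS: dict[str, list[str]] = {
    "memory": ["cos_mem"],
    "energetic": ["cos_mem", "g_over_l", "gl_de"],
    "environment": list(COVARIATE_COLUMNS),
}


class FitError(RuntimeError):
    pass


@dataclass
class SSFModel:
    formula_id: str
    terms: list[str]
    beta: np.ndarray
    cov_naive: np.ndarray
    loglik: float
    n_strata: int
    information: np.ndarray                  # observed information A at beta-hat
    stratum_scores: pd.DataFrame             # per-stratum score vectors
    cov_robust: np.ndarray | None = None
    qic: float | None = None
    converged: bool = True

    @classmethod
    def from_beta(cls, formula_id: str, beta, terms: list[str] | None = None
                  ) -> "SSFModel":
        """A coefficient-only model (for simulating from a known truth)."""
        terms = list(terms) if terms is not None else FORMULAS[formula_id]
        beta = np.asarray(beta, dtype=float)
        k = len(beta)
        return cls(formula_id=formula_id, terms=terms, beta=beta,
                   cov_naive=np.full((k, k), np.nan), loglik=np.nan,
                   n_strata=0, information=np.full((k, k), np.nan),
                   stratum_scores=pd.DataFrame(columns=terms))

    @property
    def k(self) -> int:
        return len(self.beta)

    @property
    def se_naive(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_naive))

    @property
    def se_robust(self) -> np.ndarray | None:
        return None if self.cov_robust is None else np.sqrt(np.diag(self.cov_robust))

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return df[self.terms].to_numpy(float) @ self.beta

    def summary(self) -> pd.DataFrame:
        se = self.se_robust if self.cov_robust is not None else self.se_naive
        z = stats.norm.ppf(0.975)
        return pd.DataFrame({
            "beta": self.beta, "se": se,
            "ci_lo": self.beta - z * se, "ci_hi": self.beta + z * se,
        }, index=self.terms)


def _grouped(table: pd.DataFrame, terms: list[str]):
    """Sort rows by stratum; return X, case mask, group start offsets, ids."""
    df = table.sort_values(["stratum", "case"], ascending=[True, False])
    X = df[terms].to_numpy(float)
    case = df["case"].to_numpy(int)
    sid = df["stratum"].to_numpy()
    starts = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])
    ids = sid[starts]
    n_case = np.add.reduceat(case, starts)
    if not np.all(n_case == 1):
        raise ValueError("each stratum must contain exactly one observed (case=1) row")
    return X, case.astype(bool), starts, ids


def _loglik_parts(beta, X, case, starts):
    eta = X @ beta
    seg = np.searchsorted(starts, np.arange(len(eta)), side="right") - 1
    m = np.maximum.reduceat(eta, starts)
    z = np.exp(eta - m[seg])
    lse = m + np.log(np.add.reduceat(z, starts))
    ll = float(eta[case].sum() - lse.sum())
    p = np.exp(eta - lse[seg])
    return ll, p, seg


def fit_clogit(table: pd.DataFrame, formula_id: str = "environment",
               terms: list[str] | None = None, max_iter: int = 100,
               tol: float = 1e-8) -> SSFModel:
    """Maximum conditional likelihood fit of an SSF.

    ``formula_id`` selects a predefined candidate model; pass ``terms`` for a
    custom covariate list.  Raises :class:`FitError` on non-convergence or
    when the likelihood carries no information (covariates constant within
    every stratum, or monotone likelihood / complete separation).
    """
    terms = list(terms) if terms is not None else FORMULAS[formula_id]
    X, case, starts, ids = _grouped(table, terms)
    ends = np.r_[starts[1:], len(X)]
    # identifiability: some within-stratum variation must exist
    any_var = False
    for s, e in zip(starts, ends):
        if np.ptp(X[s:e], axis=0).max() > 0:
            any_var = True
            break
    if not any_var:
        raise FitError("covariates constant within every stratum; beta unidentifiable")

    k = len(terms)
    beta = np.zeros(k)
    ll, p, seg = _loglik_parts(beta, X, case, starts)
    for it in range(max_iter):
        # score and information
        mean_x = np.empty((len(starts), k))
        for j in range(k):
            mean_x[:, j] = np.add.reduceat(p * X[:, j], starts)
        score_s = X[case] - mean_x
        score = score_s.sum(axis=0)
        pX = X * p[:, None]
        A = np.zeros((k, k))
        EXXT = pX.T @ X
        A = EXXT - mean_x.T @ mean_x  # sum_s E[xx^T] - E[x]E[x]^T
        try:
            delta = np.linalg.solve(A, score)
        except np.linalg.LinAlgError as err:
            raise FitError(f"singular information matrix: {err}") from err
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, p_new, _ = _loglik_parts(cand, X, case, starts)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            raise FitError("step-halving failed to improve the likelihood")
        improved = ll_new - ll
        beta, ll, p = cand, ll_new, p_new
        if np.linalg.norm(beta) > 1e3:
            raise FitError("coefficients diverging: monotone likelihood "
                           "(complete separation) suspected")
        if abs(improved) < tol:
            break
    else:
        raise FitError(f"no convergence in {max_iter} iterations")

    # final information / scores at beta-hat
    mean_x = np.empty((len(starts), k))
    for j in range(k):
        mean_x[:, j] = np.add.reduceat(p * X[:, j], starts)
    A = (X * p[:, None]).T @ X - mean_x.T @ mean_x
    score_s = X[case] - mean_x
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise FitError(f"singular information at optimum: {err}") from err
    scores = pd.DataFrame(score_s, index=pd.Index(ids, name="stratum"), columns=terms)
    return SSFModel(formula_id=formula_id, terms=terms, beta=beta, cov_naive=cov,
                    loglik=ll, n_strata=len(starts), information=A,
                    stratum_scores=scores)


def conditional_loglik(table: pd.DataFrame, terms: list[str], beta) -> float:
    """Log conditional likelihood of a coefficient vector on a table.

    Exposed so the likelihood surface can be probed directly (grid scans,
    invariance checks) without going through the Newton fitter.
    """
    X, case, starts, _ = _grouped(table, list(terms))
    ll, _, _ = _loglik_parts(np.asarray(beta, dtype=float), X, case, starts)
    return ll


def simulate_clogit_strata(beta, n_strata: int, n_controls: int = 20,
                           rng: np.random.Generator | None = None,
                           terms: list[str] | None = None,
                           covariate_sampler=None) -> pd.DataFrame:
    """Strata drawn from the conditional-logit generative model.

    Each stratum holds ``n_controls + 1`` rows with covariates from
    ``covariate_sampler(rng, size)`` (standard normal by default); the case
    row is sampled with probability proportional to exp(beta.x) within the
    stratum.  Used for parameter-recovery and coverage checks.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    beta = np.asarray(beta, dtype=float)
    k = len(beta)
    terms = terms if terms is not None else [f"x{i}" for i in range(k)]
    m = n_controls + 1
    rows = []
    for s in range(n_strata):
        if covariate_sampler is None:
            X = rng.standard_normal((m, k))
        else:
            X = covariate_sampler(rng, (m, k))
        eta = X @ beta
        p = np.exp(eta - logsumexp(eta))
        case_idx = rng.choice(m, p=p)
        for j in range(m):
            row = {t: X[j, i] for i, t in enumerate(terms)}
            row.update(stratum=s + 1, case=int(j == case_idx),
                       individual="sim", t_end=s)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Independence partition and robust covariance


@dataclass
class IndependencePartition:
    """Stratum -> independence-cluster assignment with dropped gap strata."""

    cluster_of: dict = field(default_factory=dict)
    dropped: set = field(default_factory=set)

    @property
    def retained(self) -> set:
        return set(self.cluster_of)

    def n_clusters(self) -> int:
        return len(set(self.cluster_of.values()))


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, a):
        self.parent.setdefault(a, a)
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_independence_partition(table: pd.DataFrame, block_len: int = 24,
                                 gap: int = 2, proximity: float = 100.0
                                 ) -> IndependencePartition:
    """Blocks of consecutive strata per individual, separated by dropped gaps.

    Within an individual, strata are grouped into contiguous blocks of
    ``block_len``; the ``gap`` strata after each block are dropped from
    fitting so consecutive blocks are at least 8 h apart.  Simultaneous
    strata of different individuals whose start points are closer than
    ``proximity`` metres merge their blocks into one cluster (union-find).
    """
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    obs = table[table["case"] == 1]
    uf = _UnionFind()
    cluster_of: dict = {}
    dropped: set = set()
    block_of: dict = {}
    for ind, sub in obs.groupby("individual", sort=True):
        sub = sub.sort_values("t_end")
        for i, s in enumerate(sub["stratum"].tolist()):
            pos = i % (block_len + gap)
            if pos < block_len:
                block = (ind, i // (block_len + gap))
                block_of[s] = block
            else:
                dropped.add(s)
    # seed union-find with block keys
    for s, b in block_of.items():
        uf.find(b)
    # cross-individual merges at shared timestamps
    for _, sub in obs.groupby("t_end"):
        if len(sub) < 2:
            continue
        recs = sub[["stratum", "x0", "y0", "individual"]].to_records(index=False)
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                si, sj = recs[i][0], recs[j][0]
                if recs[i][3] == recs[j][3]:
                    continue
                if si in dropped or sj in dropped:
                    continue
                d = math.hypot(recs[i][1] - recs[j][1], recs[i][2] - recs[j][2])
                if d < proximity:
                    uf.union(block_of[si], block_of[sj])
    roots = {}
    for s, b in block_of.items():
        root = uf.find(b)
        roots.setdefault(root, len(roots))
        cluster_of[s] = roots[root]
    return IndependencePartition(cluster_of=cluster_of, dropped=dropped)


def sandwich_covariance(model: SSFModel, partition: IndependencePartition | None = None
                        ) -> np.ndarray:
    """Cluster-robust covariance A^-1 B A^-1; B sums clustered score outer
    products.  With ``partition=None`` every stratum is its own cluster.

    A single all-encompassing cluster is degenerate (the total score vanishes
    at the MLE) and raises.
    """
    scores = model.stratum_scores
    if partition is None:
        grouped = scores
    else:
        keep = [s for s in scores.index if s in partition.cluster_of]
        sub = scores.loc[keep]
        labels = [partition.cluster_of[s] for s in keep]
        grouped = sub.groupby(labels).sum()
    if len(grouped) < 2:
        raise FitError("robust covariance degenerate: a single cluster's score "
                       "sum is zero at the MLE")
    S = grouped.to_numpy(float)
    B = S.T @ S
    Ainv = np.linalg.inv(model.information)
    V = Ainv @ B @ Ainv
    model.cov_robust = V
    return V


def qic(model: SSFModel, partition: IndependencePartition | None = None) -> float:
    """Pan's quasi-likelihood under independence criterion.

    QIC = -2 l(beta-hat) + 2 trace(A V_robust); equals AIC exactly when the
    robust covariance is A^-1 (independent, well-specified data).
    """
    if model.cov_robust is None:
        sandwich_covariance(model, partition)
    penalty = float(np.trace(model.information @ model.cov_robust))
    value = -2.0 * model.loglik + 2.0 * penalty
    model.qic = value
    return value


def model_select(table: pd.DataFrame, partition: IndependencePartition | None = None,
                 formulas=("memory", "energetic", "environment")) -> pd.DataFrame:
    """Fit candidate SSFs, rank by QIC with Akaike-style weights.

    Returns a table (index formula_id) with K, QIC, dQIC and weight; failed
    fits appear with NaN and weight 0.  Fitted models are attached in
    ``result.attrs['models']``.
    """
    rows, models = {}, {}
    for fid in formulas:
        try:
            m = fit_clogit(table, fid)
            q = qic(m, partition)
            rows[fid] = {"K": m.k, "QIC": q, "loglik": m.loglik}
            models[fid] = m
        except (FitError, ValueError) as err:
            rows[fid] = {"K": len(FORMULAS.get(fid, [])), "QIC": np.nan,
                         "loglik": np.nan, "error": str(err)}
    out = pd.DataFrame(rows).T
    qvals = out["QIC"].astype(float)
    dq = qvals - qvals.min()
    w = np.exp(-dq / 2.0)
    w = w / np.nansum(w)
    out["dQIC"] = dq
    out["weight"] = w.fillna(0.0)
    out.attrs["models"] = models
    return out.sort_values("QIC")


def vif(table: pd.DataFrame, formula_id: str = "environment",
        terms: list[str] | None = None) -> pd.Series:
    """Variance inflation factors over control rows.

    VIF_i = 1 / (1 - R^2_i) from regressing covariate i on the others (with
    intercept); perfect collinearity reports +inf.
    """
    terms = list(terms) if terms is not None else FORMULAS[formula_id]
    ctrl = table[table["case"] == 0]
    X = ctrl[terms].to_numpy(float)
    out = {}
    for i, name in enumerate(terms):
        y = X[:, i]
        others = np.c_[np.ones(len(X)), np.delete(X, i, axis=1)]
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# k-fold case-control cross-validation


@dataclass
class CVResult:
    mean_rs: float
    ci: tuple[float, float]
    null_mean: float
    null_ci: tuple[float, float]
    rs_samples: np.ndarray
    null_samples: np.ndarray
    bin_counts: np.ndarray  # pooled over reps


def rank_bin_spearman(bin_counts: np.ndarray) -> float:
    """Spearman correlation between bin rank (1..n_bins) and bin frequency,
    with midranks for ties."""
    n = len(bin_counts)
    r, _ = stats.spearmanr(np.arange(1, n + 1), bin_counts)
    return float(r)


def kfold_cv(table: pd.DataFrame, formula_id: str = "environment",
             folds: int = 5, reps: int = 100,
             rng: np.random.Generator | None = None,
             score_fn=None) -> CVResult:
    """Case-control cross-validation by rank bins.

    Per repetition: fit on a random (1 - 1/folds) share of strata, score the
    withheld strata, rank each observed step among its stratum's rows
    (midranks on ties, rounded to a bin), tally ranks into bins, and take the
    Spearman correlation between bin index and frequency.  A matched null
    draws ranks uniformly.  Returns means and percentile 95% CIs over reps.

    ``score_fn(df) -> scores`` replaces the fitted model's linear predictor
    (used for oracle checks).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    strata = table["stratum"].unique()
    if len(strata) < folds:
        raise ValueError("fewer strata than folds")
    n_bins = int(table.groupby("stratum").size().max())
    train_frac = 1.0 - 1.0 / folds
    rs_list, null_list = [], []
    pooled = np.zeros(n_bins)
    for _ in range(reps):
        perm = rng.permutation(strata)
        n_train = int(round(train_frac * len(strata)))
        test_ids = set(perm[n_train:])
        test = table[table["stratum"].isin(test_ids)]
        if score_fn is None:
            train = table[~table["stratum"].isin(test_ids)]
            model = fit_clogit(train, formula_id)
            scores = model.linear_predictor(test)
        else:
            scores = np.asarray(score_fn(test), dtype=float)
        test = test.assign(_score=scores)
        counts = np.zeros(n_bins)
        n_test = 0
        for _, sub in test.groupby("stratum"):
            ranks = stats.rankdata(sub["_score"].to_numpy(), method="average")
            obs_rank = float(ranks[sub["case"].to_numpy() == 1][0])
            b = int(round(obs_rank)) - 1
            counts[min(max(b, 0), n_bins - 1)] += 1
            n_test += 1
        rs_list.append(rank_bin_spearman(counts))
        pooled += counts
        null_counts = np.bincount(rng.integers(0, n_bins, n_test), minlength=n_bins)
        null_list.append(rank_bin_spearman(null_counts.astype(float)))
    rs = np.array(rs_list)
    nl = np.array(null_list)
    return CVResult(
        mean_rs=float(rs.mean()), ci=tuple(np.percentile(rs, [2.5, 97.5])),
        null_mean=float(nl.mean()), null_ci=tuple(np.percentile(nl, [2.5, 97.5])),
        rs_samples=rs, null_samples=nl, bin_counts=pooled,
    )
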