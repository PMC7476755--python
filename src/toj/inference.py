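"""Group-level inference: permutation tests, effect sizes, and binomial GLMMs.

Permutation conventions
-----------------------
All permutation engines compute a classical statistic (t or F) and build its
null distribution by the scheme appropriate to the design: sign flips of the
centred values for one-sample tests, label permutation for two-sample tests
and one-way ANOVA, and shuffling of one variable for correlations. When the
full permutation group is small enough it is enumerated exhaustively and
p = #{T* as extreme as T} / #permutations (the observed arrangement is a
member of the enumeration). Otherwise n_perm Monte-Carlo draws are taken and
the add-one convention p = (#{T* as extreme} + 1) / (n_perm + 1) guarantees
p > 0 and validity.

Effect size
-----------
``r_equivalent`` converts a (one-tailed) p-value and degrees of freedom into
the correlation a t statistic of equivalent evidence would imply:
t_equiv = one-tailed t quantile at df, r = t_equiv / sqrt(t_equiv^2 + df).

Mixed model
-----------
``fit_binomial_glmm`` maximises the marginal likelihood of a binomial GLMM
with one random intercept per participant, integrating the random effect by
adaptive Gauss-Hermite quadrature (default 15 nodes). Links: logit (default)
and log.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats
from scipy.special import logsumexp

__all__ = [
    "TestResult",
    "GLMMFit",
    "perm_t_one_sample",
    "perm_t_two_sample",
    "perm_anova_oneway",
    "perm_pearson",
    "r_equivalent",
    "fit_binomial_glmm",
    "lrt",
    "wald_contrast",
    "bias_accuracy_correlation",
]

EXHAUSTIVE_LIMIT = 2**15
_REL_TOL = 1e-12


@dataclass
class TestResult:
    """A statistic with its permutation p-value and effect size."""

    test: str
    statistic: float
    df: float | tuple
    p_perm: float
    tails: str  # 'one' or 'two'
    n_perm: int
    exhaustive: bool
    r_equiv: float = np.nan
    r_equiv_clipped: bool = False
    seed: int | None = None
    note: str = ""

    def as_row(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": str(self.df),
            "p_perm": self.p_perm,
            "tails": self.tails,
            "n_perm": self.n_perm,
            "exhaustive": self.exhaustive,
            "r_equiv": self.r_equiv,
            "seed": self.seed,
            "note": self.note,
        }


def r_equivalent(p_one_tailed: float, df: float) -> float:
    """Effect size r from a one-tailed p-value and its degrees of freedom.

    p >= 0.5 (evidence opposite to the tested direction) maps to r = 0.
    """
    if not 0 < p_one_tailed < 1:
        raise ValueError("p must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    t_equiv = stats.t.isf(p_one_tailed, df)
    if t_equiv <= 0:
        return 0.0
    return float(t_equiv / np.sqrt(t_equiv**2 + df))


def _attach_r_equiv(res: TestResult, df_for_r: float) -> TestResult:
    """Attach r_equivalent using the one-tailed version of the permutation p."""
    p = res.p_perm / 2 if res.tails == "two" else res.p_perm
    p = min(max(p, 1e-12), 1 - 1e-12)
    r = r_equivalent(p, df_for_r)
    res.r_equiv = r
    res.r_equiv_clipped = r == 0.0
    return res


def _count_p(null: np.ndarray, observed: float, exhaustive: bool) -> float:
    thresh = abs(observed) * (1 - _REL_TOL) - _REL_TOL
    count = int(np.sum(null >= thresh))
    if exhaustive:
        return count / len(null)
    return (count + 1) / (len(null) + 1)


def _resolve_tails(tails: str, observed: float) -> tuple[str, int]:
    """Map a tails spec onto ('one'|'two', direction).

    ``'one'`` tests in the direction of the observed statistic (the planned,
    directional comparisons of the analysis all predicted the observed
    direction); ``'greater'``/``'less'`` fix the direction explicitly.
    """
    if tails == "two":
        return "two", 0
    if tails == "one":
        return "one", 1 if observed >= 0 else -1
    if tails == "greater":
        return "one", 1
    if tails == "less":
        return "one", -1
    raise ValueError(f"unknown tails {tails!r}")


def _one_sample_t(x: np.ndarray) -> float:
    n = len(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.nan
    return float(x.mean() / (sd / np.sqrt(n)))


def perm_t_one_sample(
    values,
    mu0: float = 0.0,
    tails: str = "two",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """One-sample t-test against mu0 with a sign-flip permutation null.

    Exhaustive over all 2^n sign patterns when 2^n <= 32768, Monte-Carlo
    otherwise. df = n - 1.
    """
    x = np.asarray(values, dtype=float) - mu0
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 finite values")
    t_obs = _one_sample_t(x)
    df = n - 1
    if not np.isfinite(t_obs):
        return TestResult(
            "one_sample_t", np.nan, df, 1.0, tails, 0, False,
            seed=seed, note="zero variance; statistic undefined",
        )

    mode, direction = _resolve_tails(tails, t_obs)
    exhaustive = 2**n <= EXHAUSTIVE_LIMIT
    if exhaustive:
        codes = np.arange(2**n, dtype=np.int64)
        signs = ((codes[:, None] >> np.arange(n)) & 1) * 2 - 1
        n_used = 2**n
    else:
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
        n_used = n_perm

    flipped = signs * x
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = means / (sds / np.sqrt(n))
    t_null = np.where(np.isfinite(t_null), t_null, 0.0)

    if mode == "two":
        p = _count_p(np.abs(t_null), t_obs, exhaustive)
    else:
        p = _count_p(direction * t_null, direction * t_obs, exhaustive)

    res = TestResult("one_sample_t", t_obs, df, p, mode, n_used, exhaustive, seed=seed)
    return _attach_r_equiv(res, df)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def perm_t_two_sample(
    a,
    b,
    tails: str = "two",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Unpaired Student t (pooled variance) with a label-permutation null.

    Exhaustive over all C(na+nb, na) group assignments when that count is
    <= 32768. df = na + nb - 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 values per group")
    df = na + nb - 2
    t_obs = _pooled_t(a, b)
    if not np.isfinite(t_obs):
        return TestResult(
            "two_sample_t", np.nan, df, 1.0, tails, 0, False,
            seed=seed, note="degenerate: all values identical",
        )

    mode, direction = _resolve_tails(tails, t_obs)
    pooled = np.concatenate([a, b])
    n_assign = comb(na + nb, na)
    exhaustive = n_assign <= EXHAUSTIVE_LIMIT
    if exhaustive:
        t_null = np.empty(n_assign)
        all_idx = frozenset(range(na + nb))
        for i, pick in enumerate(itertools.combinations(range(na + nb), na)):
            rest = list(all_idx - frozenset(pick))
            t_null[i] = _pooled_t(pooled[list(pick)], pooled[rest])
        n_used = n_assign
    else:
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_perm, na + nb)), axis=1)
        shuffled = pooled[order]
        ga, gb = shuffled[:, :na], shuffled[:, na:]
        sp2 = ((na - 1) * ga.var(axis=1, ddof=1) + (nb - 1) * gb.var(axis=1, ddof=1)) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = (ga.mean(axis=1) - gb.mean(axis=1)) / np.sqrt(
                sp2 * (1 / na + 1 / nb)
            )
        n_used = n_perm
    t_null = np.where(np.isfinite(t_null), t_null, 0.0)

    if mode == "two":
        p = _count_p(np.abs(t_null), t_obs, exhaustive)
    else:
        p = _count_p(direction * t_null, direction * t_obs, exhaustive)

    res = TestResult("two_sample_t", t_obs, df, p, mode, n_used, exhaustive, seed=seed)
    return _attach_r_equiv(res, df)


def _oneway_f(values: np.ndarray, sizes: list[int]) -> float:
    """F for contiguous groups laid out along the last axis of ``values``."""
    total_mean = values.mean(axis=-1, keepdims=True)
    ss_total = ((values - total_mean) ** 2).sum(axis=-1)
    ss_between = np.zeros(values.shape[:-1])
    start = 0
    for n in sizes:
        g = values[..., start : start + n]
        ss_between = ss_between + n * (g.mean(axis=-1) - total_mean[..., 0]) ** 2
        start += n
    k = len(sizes)
    n_total = sum(sizes)
    ss_within = ss_total - ss_between
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (n_total - k))
    return f


def perm_anova_oneway(
    groups,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """One-way ANOVA F with a group-label permutation null."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    k, n_total = len(sizes), len(pooled)
    df = (k - 1, n_total - k)

    f_obs = float(_oneway_f(pooled[None, :], sizes)[0])
    if not np.isfinite(f_obs):
        return TestResult(
            "oneway_anova_F", np.nan, df, 1.0, "one", 0, False,
            seed=seed, note="degenerate: zero within-group variance",
        )
    if f_obs == 0.0:
        # all group means identical: every permutation is at least as extreme
        return TestResult("oneway_anova_F", 0.0, df, 1.0, "one", 0, False, seed=seed)

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n_total)), axis=1)
    f_null = _oneway_f(pooled[order], sizes)
    f_null = np.where(np.isfinite(f_null), f_null, 0.0)
    p = _count_p(f_null, f_obs, exhaustive=False)

    res = TestResult("oneway_anova_F", f_obs, df, p, "one", n_perm, False, seed=seed)
    # F-based r_equiv only meaningful for 2 groups; report using error df.
    return _attach_r_equiv(res, df[1])


def perm_pearson(
    x,
    y,
    tails: str = "two",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Pearson correlation with a permutation null (shuffle one variable)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 paired values")
    df = n - 2
    if x.std() == 0 or y.std() == 0:
        return TestResult(
            "pearson_r", np.nan, df, 1.0, tails, 0, False,
            seed=seed, note="zero variance in one measure",
        )
    r_obs = float(np.corrcoef(x, y)[0, 1])
    mode, direction = _resolve_tails(tails, r_obs)

    rng = np.random.default_rng(seed)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    r_null = (ys[order] * xs).mean(axis=1)

    if mode == "two":
        p = _count_p(np.abs(r_null), r_obs, exhaustive=False)
    else:
        p = _count_p(direction * r_null, direction * r_obs, exhaustive=False)

    res = TestResult("pearson_r", r_obs, df, p, mode, n_perm, False, seed=seed)
    return _attach_r_equiv(res, df)


# ---------------------------------------------------------------------------
# Binomial random-intercept GLMM via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------


class GLMMError(RuntimeError):
    pass


def _link_loglik_derivs(eta: np.ndarray, k: np.ndarray, m: np.ndarray, link: str):
    """Binomial log-likelihood and its first two derivatives in eta.

    Returns (ll, d1, d2) elementwise over observations.
    """
    if link == "logit":
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = k * np.log(mu) + (m - k) * np.log1p(-mu)
        d1 = k - m * mu
        d2 = -m * mu * (1 - mu)
    elif link == "log":
        # mu = exp(eta), capped below 1 to keep the binomial likelihood proper
        mu = np.clip(np.exp(eta), 1e-12, 1 - 1e-9)
        ll = k * np.log(mu) + (m - k) * np.log1p(-mu)
        frac = mu / (1 - mu)
        d1 = k - (m - k) * frac
        d2 = -(m - k) * frac / (1 - mu)
    else:
        raise ValueError(f"unknown link {link!r}")
    return ll, d1, d2


def _cluster_modes(
    eta0: np.ndarray,
    k: np.ndarray,
    m: np.ndarray,
    cluster: np.ndarray,
    n_clusters: int,
    tau2: float,
    link: str,
    n_iter: int = 25,
):
    """Per-cluster mode and curvature of the integrand, by vectorised Newton."""
    b = np.zeros(n_clusters)
    for _ in range(n_iter):
        eta = eta0 + b[cluster]
        _, d1, d2 = _link_loglik_derivs(eta, k, m, link)
        g = np.bincount(cluster, weights=d1, minlength=n_clusters) - b / tau2
        h = np.bincount(cluster, weights=d2, minlength=n_clusters) - 1.0 / tau2
        step = g / h
        # dampen large steps for stability
        step = np.clip(step, -5.0, 5.0)
        b = b - step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + b[cluster]
    _, _, d2 = _link_loglik_derivs(eta, k, m, link)
    h = np.bincount(cluster, weights=d2, minlength=n_clusters) - 1.0 / tau2
    return b, -h  # mode, positive curvature


def _marginal_loglik(
    beta: np.ndarray,
    tau2: float,
    X: np.ndarray,
    k: np.ndarray,
    m: np.ndarray,
    cluster: np.ndarray,
    n_clusters: int,
    nodes: np.ndarray,
    weights: np.ndarray,
    link: str,
) -> float:
    eta0 = X @ beta
    if tau2 < 1e-10:
        ll, _, _ = _link_loglik_derivs(eta0, k, m, link)
        return float(ll.sum())
    bhat, curv = _cluster_modes(eta0, k, m, cluster, n_clusters, tau2, link)
    curv = np.maximum(curv, 1e-8)
    shat = 1.0 / np.sqrt(curv)
    # adaptive Gauss-Hermite (probabilists'): b = bhat + shat * z_q
    bq = bhat[:, None] + shat[:, None] * nodes[None, :]  # (C, Q)
    eta = eta0[:, None] + bq[cluster]  # (N, Q)
    ll, _, _ = _link_loglik_derivs(eta, k[:, None], m[:, None], link)
    ll_cluster = np.zeros((n_clusters, len(nodes)))
    np.add.at(ll_cluster, cluster, ll)
    # integrand: f(y|b) phi(b; 0, tau2); GH weights absorb exp(-z^2/2)
    log_prior = -0.5 * bq**2 / tau2 - 0.5 * np.log(2 * np.pi * tau2)
    log_terms = (
        np.log(weights)[None, :]
        + 0.5 * nodes[None, :] ** 2
        + np.log(shat)[:, None]
        + ll_cluster
        + log_prior
    )
    return float(logsumexp(log_terms, axis=1).sum())


@dataclass
class GLMMFit:
    """A fitted binomial random-intercept mixed model."""

    fixed_effects: pd.Series
    se: pd.Series
    random_intercept_variance: float
    log_marginal_likelihood: float
    link: str
    converged: bool
    n_quadrature_nodes: int
    n_params: int
    n_obs: int
    n_groups: int
    cov: np.ndarray = field(repr=False, default=None)
    separation: bool = False


def _aggregate(data: pd.DataFrame, response: str, fixed: list[str], group: str):
    """Collapse Bernoulli rows to binomial counts per group x covariate cell."""
    df = data[[group, response] + fixed].dropna().copy()
    agg = (
        df.groupby([group] + fixed, observed=True)[response]
        .agg(["sum", "count"])
        .reset_index()
    )
    return agg


def _design_matrix(agg: pd.DataFrame, fixed: list[str]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with intercept, including interactions
    when more than one fixed factor is given."""
    X = pd.DataFrame({"Intercept": np.ones(len(agg))})
    names = ["Intercept"]
    mains = []
    for f in fixed:
        col = agg[f]
        if col.dtype.kind in "ifu" and col.nunique() > 8:
            X[f] = col.astype(float)
            names.append(f)
            mains.append([f])
        else:
            levels = sorted(col.astype(str).unique())
            dummies = []
            for lev in levels[1:]:
                name = f"{f}[{lev}]"
                X[name] = (col.astype(str) == lev).astype(float)
                names.append(name)
                dummies.append(name)
            mains.append(dummies)
    if len(fixed) == 2:
        for a in mains[0]:
            for b in mains[1]:
                name = f"{a}:{b}"
                X[name] = X[a] * X[b]
                names.append(name)
    return X[names].to_numpy(dtype=float), names


def fit_binomial_glmm(
    data: pd.DataFrame,
    response: str,
    fixed: list[str] | None = None,
    group: str = "participant_id",
    link: str = "logit",
    n_quad: int = 15,
) -> GLMMFit:
    """Fit a binomial GLMM with a participant random intercept.

    ``fixed`` lists covariate column names (categorical columns are
    treatment-coded; with two factors their interaction is included).
    The marginal likelihood is integrated by adaptive Gauss-Hermite
    quadrature and maximised over (beta, log tau).
    """
    fixed = list(fixed or [])
    if data[response].dropna().nunique() > 2:
        raise ValueError(f"{response} must be binary")
    agg = _aggregate(data, response, fixed, group)
    n_groups = agg[group].nunique()
    if n_groups < 2:
        raise GLMMError("need >= 2 participants")

    X, names = _design_matrix(agg, fixed)
    k = agg["sum"].to_numpy(dtype=float)
    m = agg["count"].to_numpy(dtype=float)
    cluster = pd.factorize(agg[group])[0]

    # complete separation heuristic: a covariate cell with all 0s or all 1s
    # in every cluster it appears in can push coefficients to infinity
    separation = bool(np.all(k == 0) or np.all(k == m))

    nodes, weights = hermegauss(n_quad)

    # start from the fixed-effects-only ML fit
    def glm_negll(beta):
        ll, _, _ = _link_loglik_derivs(X @ beta, k, m, link)
        return -ll.sum()

    beta0 = np.zeros(X.shape[1])
    if link == "log":
        beta0[0] = np.log(max(k.sum() / m.sum(), 1e-3))
    glm_res = optimize.minimize(glm_negll, beta0, method="BFGS")
    start = np.append(glm_res.x, np.log(0.5))

    def negll(theta):
        beta, log_tau = theta[:-1], theta[-1]
        tau2 = np.exp(2 * log_tau)
        return -_marginal_loglik(
            beta, tau2, X, k, m, cluster, n_groups, nodes, weights, link
        )

    bounds = [(None, None)] * X.shape[1] + [(np.log(1e-4), np.log(50.0))]
    res = optimize.minimize(negll, start, method="L-BFGS-B", bounds=bounds)
    # polish with a second pass from the optimum (helps flat tau profiles)
    res2 = optimize.minimize(negll, res.x, method="L-BFGS-B", bounds=bounds)
    if res2.fun <= res.fun:
        res = res2

    beta_hat = res.x[:-1]
    tau_hat = float(np.exp(res.x[-1]))
    loglik = -float(res.fun)

    from statsmodels.tools.numdiff import approx_hess1

    try:
        H = approx_hess1(res.x, negll)
        cov_all = np.linalg.inv(H)
        se_beta = np.sqrt(np.maximum(np.diag(cov_all)[: len(beta_hat)], 0))
        cov_beta = cov_all[: len(beta_hat), : len(beta_hat)]
    except np.linalg.LinAlgError:
        se_beta = np.full(len(beta_hat), np.nan)
        cov_beta = np.full((len(beta_hat),) * 2, np.nan)

    return GLMMFit(
        fixed_effects=pd.Series(beta_hat, index=names),
        se=pd.Series(se_beta, index=names),
        random_intercept_variance=tau_hat**2,
        log_marginal_likelihood=loglik,
        link=link,
        converged=bool(res.success) and np.isfinite(loglik),
        n_quadrature_nodes=n_quad,
        n_params=X.shape[1] + 1,
        n_obs=int(m.sum()),
        n_groups=n_groups,
        cov=cov_beta,
        separation=separation,
    )


def lrt(full: GLMMFit, reduced: GLMMFit, r_equiv_df: float | None = None) -> TestResult:
    """Likelihood-ratio test of nested binomial GLMMs.

    chi2 = 2 (ll_full - ll_reduced), df = difference in parameter count.
    ``r_equiv_df`` is the participants-based df used for the effect size
    (e.g. n-1 for a single-group contrast, N-2 for a two-group effect).
    """
    if full.n_params <= reduced.n_params:
        raise ValueError("full model must have more parameters than reduced")
    delta = 2.0 * (full.log_marginal_likelihood - reduced.log_marginal_likelihood)
    if delta < -1e-6:
        raise GLMMError(
            "full-model likelihood below reduced model: optimisation failure"
        )
    delta = max(delta, 0.0)
    df = full.n_params - reduced.n_params
    p = float(stats.chi2.sf(delta, df))
    res = TestResult(
        "glmm_lrt_chi2", float(delta), df, p, "two", 0, False,
        note=f"link={full.link}",
    )
    if r_equiv_df is not None:
        # chi-square p-values are inherently one-sided in the deviance;
        # convert via the one-tailed t quantile at the participants-based df
        p_r = min(max(p, 1e-12), 1 - 1e-12)
        res.r_equiv = r_equivalent(p_r, r_equiv_df) if p_r < 0.5 else 0.0
        res.r_equiv_clipped = res.r_equiv == 0.0
    return res


def wald_contrast(
    fit: GLMMFit,
    contrast: dict | np.ndarray,
    value: float = 0.0,
    r_equiv_df: float | None = None,
) -> TestResult:
    """Wald z-test of a linear contrast of fixed effects on the link scale."""
    names = list(fit.fixed_effects.index)
    if isinstance(contrast, dict):
        c = np.zeros(len(names))
        for key, w in contrast.items():
            c[names.index(key)] = w
    else:
        c = np.asarray(contrast, dtype=float)
    est = float(c @ fit.fixed_effects.to_numpy())
    var = float(c @ fit.cov @ c)
    if not var > 0:
        return TestResult(
            "glmm_wald_z", np.nan, np.inf, 1.0, "two", 0, False,
            note="non-positive contrast variance",
        )
    z = (est - value) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    res = TestResult("glmm_wald_z", float(z), np.inf, p, "two", 0, False)
    if r_equiv_df is not None:
        return _attach_r_equiv(res, r_equiv_df)
    return res


def bias_accuracy_correlation(
    summaries: pd.DataFrame,
    bias_col: str = "bias",
    accuracy_col: str = "accuracy",
    group_col: str = "group",
    exclude_sd: float = 2.5,
    tails: str = "two",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[TestResult, pd.DataFrame]:
    """Pearson correlation between bias and accuracy across participants.

    Before pooling, a participant is excluded if either measure lies more
    than ``exclude_sd`` standard deviations from their group's mean of that
    measure. Returns the test and the pooled table with an ``excluded``
    column.
    """
    df = summaries.dropna(subset=[group_col, bias_col, accuracy_col]).copy()
    excl = np.zeros(len(df), dtype=bool)
    for col in (bias_col, accuracy_col):
        for _, idx in df.groupby(group_col).groups.items():
            v = df.loc[idx, col].to_numpy(dtype=float)
            if len(v) < 2 or v.std(ddof=1) == 0:
                continue
            z = np.abs(v - v.mean()) / v.std(ddof=1)
            excl[df.index.get_indexer(idx)] |= z > exclude_sd
    df["excluded"] = excl
    kept = df[~df["excluded"]]
    if len(kept) < 4:
        raise ValueError("fewer than 4 participants after exclusion")
    res = perm_pearson(
        kept[accuracy_col], kept[bias_col], tails=tails, n_perm=n_perm, seed=seed
    )
    res.test = "bias_accuracy_pearson"
    return res, df
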