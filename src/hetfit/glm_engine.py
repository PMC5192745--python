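"""Binomial model machinery for the recruitment analyses.

Fixed-effects logistic regression is fitted by Newton/IRLS. The mating-pair
random intercept model (binomial, logit link, one Gaussian random intercept
per pair) is fitted by maximum likelihood with one-dimensional *adaptive*
Gauss-Hermite quadrature: the integrand of each cluster's likelihood is
centred at its conditional mode and scaled by its curvature before applying
the quadrature rule, which keeps the rule accurate with a modest node count.

Model selection fits all subsets of the candidate terms, ranks them by AICc,
and averages the equivalent models (delta AICc <= 2) with Akaike weights,
reporting unconditional standard errors that carry the between-model variance
component.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger("hetfit")

CI_Z = 1.96  # normal-approximation multiplier for 95% intervals


class SeparationError(RuntimeError):
    """The likelihood has no finite maximizer (complete separation)."""


@dataclass
class FittedModel:
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    loglik: float
    k_params: int               # fixed effects + 1 if a random intercept is present
    n_obs: int
    deviance: float
    random_intercept_sd: float | None = None
    converged: bool = True

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.terms.index(term)])


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop columns that are linearly dependent on earlier ones (QR pivot test)."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropped aliased/zero-variance design columns: {dropped}")
    return X[:, keep], [names[j] for j in keep], dropped


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log p(y|eta) with the numerically safe log(1 + e^eta)
    return float((y * eta - np.logaddexp(0.0, eta)).sum())


def fit_logistic(y, X, names: list[str] | None = None, groups=None,
                 max_iter: int = 100, tol: float = 1e-10,
                 gh_nodes: int = 25) -> FittedModel:
    """Maximum-likelihood logistic fit, optionally with a random intercept.

    ``X`` must contain the intercept column if one is wanted. With ``groups``
    (cluster labels, e.g. mating-pair ids) a Gaussian random intercept is
    integrated out by adaptive Gauss-Hermite quadrature with ``gh_nodes``
    nodes. Standard errors come from the observed information matrix.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    X, names, _ = _drop_aliased(X, list(names))
    n, p = X.shape
    if n < p:
        raise ValueError("more parameters than observations")

    if groups is None:
        return _fit_irls(y, X, names, max_iter, tol)
    return _fit_aghq(y, X, names, np.asarray(groups), max_iter, gh_nodes)


def _fit_irls(y, X, names, max_iter, tol) -> FittedModel:
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = _bernoulli_loglik(y, X @ beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        if np.max(np.abs(eta)) > 30 and np.min(w) < 1e-12:
            sep_term = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"complete or quasi-complete separation (term {sep_term!r})")
        XtWX = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, score, rcond=None)[0]
        # step-halving to guarantee ascent
        for halving in range(20):
            cand = beta + step
            ll_new = _bernoulli_loglik(y, X @ cand)
            if ll_new >= ll_old - 1e-14:
                break
            step = step / 2.0
        beta = cand
        if abs(ll_new - ll_old) < tol:
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new
    # a perfectly predicted 0/1 outcome means the MLE is at infinity
    if ll_old > -1e-6 and np.max(np.abs(beta)) > 10:
        sep_term = names[int(np.argmax(np.abs(beta)))]
        raise SeparationError(
            f"complete or quasi-complete separation (term {sep_term!r})")
    mu = special.expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    if not converged:
        logger.warning("IRLS did not converge in %d iterations (|dll| tol %.1e)",
                       max_iter, tol)
    return FittedModel(terms=names, coefficients=beta,
                       standard_errors=np.sqrt(np.diag(cov)),
                       loglik=ll_old, k_params=len(names), n_obs=len(y),
                       deviance=-2.0 * ll_old, converged=converged)


# ---------------------------------------------------------------------------
# Random-intercept model via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _aghq_loglik(theta: np.ndarray, y, X, cluster_idx, n_clusters,
                 z_nodes, log_w, b_start=None) -> tuple[float, np.ndarray, np.ndarray]:
    """Marginal log-likelihood, its score, and the cluster modes.

    ``theta = (beta, log sigma_b)``. Each cluster's integrand is centred at
    its conditional mode (Newton, warm-started from ``b_start``) and scaled by
    its curvature. The score is the quadrature posterior expectation of the
    complete-data score, which is exact for the marginal likelihood the
    quadrature approximates.
    """
    beta, log_sd = theta[:-1], theta[-1]
    var = np.exp(2.0 * log_sd)
    xb = X @ beta

    # conditional mode of each cluster's integrand by Newton in b
    b = np.zeros(n_clusters) if b_start is None else b_start.copy()
    for _ in range(50):
        eta = xb + b[cluster_idx]
        mu = special.expit(eta)
        grad = np.bincount(cluster_idx, weights=y - mu, minlength=n_clusters) - b / var
        hess = -np.bincount(cluster_idx, weights=mu * (1 - mu), minlength=n_clusters) - 1.0 / var
        step = grad / hess
        b = b - step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = xb + b[cluster_idx]
    mu = special.expit(eta)
    tau = np.bincount(cluster_idx, weights=mu * (1 - mu), minlength=n_clusters) + 1.0 / var
    scale = np.sqrt(2.0 / tau)                    # (m,)

    # evaluate log integrand at shifted/scaled nodes: b_iq = b_i + scale_i * z_q
    bq = b[:, None] + scale[:, None] * z_nodes[None, :]          # (m, Q)
    eta_q = xb[:, None] + bq[cluster_idx, :]                     # (N, Q)
    ll_obs = y[:, None] * eta_q - np.logaddexp(0.0, eta_q)
    ll_cluster = np.zeros((n_clusters, ll_obs.shape[1]))
    np.add.at(ll_cluster, cluster_idx, ll_obs)
    log_prior = -0.5 * bq ** 2 / var - 0.5 * np.log(2 * np.pi * var)
    log_f = ll_cluster + log_prior + z_nodes[None, :] ** 2 + log_w[None, :]
    log_int = special.logsumexp(log_f, axis=1) + np.log(scale)
    loglik = float(log_int.sum())

    # posterior node weights per cluster (the log(scale) constant cancels)
    w_post = np.exp(log_f - special.logsumexp(log_f, axis=1)[:, None])  # (m, Q)
    mu_q = special.expit(eta_q)
    resid = ((y[:, None] - mu_q) * w_post[cluster_idx, :]).sum(axis=1)  # (N,)
    g_beta = X.T @ resid
    g_logsd = float((w_post * (bq ** 2 / var - 1.0)).sum())
    return loglik, np.concatenate([g_beta, [g_logsd]]), b


def _fit_aghq(y, X, names, groups, max_iter, gh_nodes) -> FittedModel:
    groups = np.asarray(groups)
    _, cluster_idx = np.unique(groups, return_inverse=True)
    m = int(cluster_idx.max()) + 1
    z_nodes, w_nodes = np.polynomial.hermite.hermgauss(gh_nodes)
    log_w = np.log(w_nodes)

    start_fixed = _fit_irls(y, X, names, max_iter=100, tol=1e-10)
    theta0 = np.concatenate([start_fixed.coefficients, [np.log(0.5)]])
    warm = {"b": None}

    def nll_and_grad(theta):
        ll, grad, b = _aghq_loglik(theta, y, X, cluster_idx, m, z_nodes, log_w,
                                   b_start=warm["b"])
        warm["b"] = b
        return -ll, -grad

    bounds = [(None, None)] * X.shape[1] + [(-10.0, 3.0)]
    res = optimize.minimize(nll_and_grad, theta0, method="L-BFGS-B", jac=True,
                            bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-6})
    theta = res.x
    loglik = -res.fun

    # observed information: central differences of the analytic score
    p = len(theta)
    hess = np.zeros((p, p))
    h = np.maximum(1e-5, 1e-5 * np.abs(theta))
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        _, gp = nll_and_grad(theta + ei)
        _, gm = nll_and_grad(theta - ei)
        hess[:, i] = (gp - gm) / (2 * h[i])
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))[:-1]
    except np.linalg.LinAlgError:
        se = np.full(p - 1, np.nan)

    sd_hat = float(np.exp(theta[-1]))
    return FittedModel(terms=list(names), coefficients=theta[:-1],
                       standard_errors=se, loglik=loglik,
                       k_params=X.shape[1] + 1, n_obs=len(y),
                       deviance=-2.0 * loglik, random_intercept_sd=sd_hat,
                       converged=bool(res.success))


# ---------------------------------------------------------------------------
# Information-theoretic machinery
# ---------------------------------------------------------------------------

def aicc(model: FittedModel) -> float:
    """Small-sample AIC: -2*loglik + 2k + 2k(k+1)/(n-k-1)."""
    k, n = model.k_params, model.n_obs
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * model.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(delta AICc, weights) over a set of candidate models."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    raw = np.exp(-delta / 2.0)
    return delta, raw / raw.sum()


@dataclass
class ModelSet:
    models: list[FittedModel]
    term_sets: list[tuple[str, ...]]   # candidate terms present in each model
    delta_aicc: np.ndarray
    weights: np.ndarray
    top_set: list[int] = field(default_factory=list)  # indices with delta <= 2

    @property
    def best(self) -> FittedModel:
        return self.models[int(np.argmin(self.delta_aicc))]


def build_design(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; categorical columns dummy-coded (drop first)."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for t in terms:
        col = data[t]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            dummies = pd.get_dummies(col, prefix=t, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(t)
    return np.column_stack(cols), names


def model_selection(data: pd.DataFrame, response: str, candidate_terms: list[str],
                    always_terms: list[str] | None = None, groups: str | None = None,
                    max_models: int = 4096, gh_nodes: int = 25) -> ModelSet:
    """Fit all subsets of ``candidate_terms`` and rank them by AICc.

    Every model includes the intercept and ``always_terms`` (and the random
    intercept when ``groups`` names a cluster column). Non-converged members
    are excluded with a warning.
    """
    always_terms = list(always_terms or [])
    n_models = 2 ** len(candidate_terms)
    if n_models > max_models:
        raise ValueError(f"all-subsets enumeration of {n_models} models exceeds cap {max_models}")
    y = data[response].to_numpy(dtype=float)
    g = data[groups].to_numpy() if groups is not None else None

    models, term_sets = [], []
    for r in range(len(candidate_terms) + 1):
        for combo in itertools.combinations(candidate_terms, r):
            X, names = build_design(data, always_terms + list(combo))
            try:
                fm = fit_logistic(y, X, names=names, groups=g, gh_nodes=gh_nodes)
            except (SeparationError, np.linalg.LinAlgError) as e:
                warnings.warn(f"model {combo} failed: {e}")
                continue
            if not fm.converged:
                warnings.warn(f"model {combo} did not converge; excluded")
                continue
            models.append(fm)
            term_sets.append(combo)
    if not models:
        raise RuntimeError("no candidate model converged")
    delta, w = akaike_weights([aicc(mdl) for mdl in models])
    top = [i for i in range(len(models)) if delta[i] <= 2.0]
    return ModelSet(models=models, term_sets=term_sets, delta_aicc=delta,
                    weights=w, top_set=top)


def model_average(ms: ModelSet, include_always: bool = True) -> pd.DataFrame:
    """Natural model averaging over the equivalent (delta AICc <= 2) models.

    Weights are renormalized within the top set. Each design term present in
    at least one top model gets: weighted estimate, unconditional SE
    (USE = sum w_i * sqrt(SE_i^2 + (est_i - avg)^2)), the summed weight of the
    models containing it, and a normal 95% CI. Rows are sorted by summed
    weight, descending.
    """
    if not ms.top_set:
        raise ValueError("empty top set")
    w_top = ms.weights[ms.top_set]
    w_top = w_top / w_top.sum()
    rows = {}
    for w_i, idx in zip(w_top, ms.top_set):
        mdl = ms.models[idx]
        for term in mdl.terms:
            if term == "(Intercept)" and not include_always:
                continue
            rows.setdefault(term, []).append((w_i, mdl.coef(term), mdl.se(term)))
    table = []
    for term, entries in rows.items():
        if term == "(Intercept)":
            continue
        ws = np.array([e[0] for e in entries])
        ths = np.array([e[1] for e in entries])
        ses = np.array([e[2] for e in entries])
        wn = ws / ws.sum()                       # condition on models containing the term
        est = float((wn * ths).sum())
        use = float((wn * np.sqrt(ses ** 2 + (ths - est) ** 2)).sum())
        sum_w = float(ws.sum())
        lo, hi = est - CI_Z * use, est + CI_Z * use
        table.append({"term": term, "estimate": est, "use": use,
                      "sum_weights": sum_w, "ci_low": lo, "ci_high": hi,
                      "significant": bool(lo > 0 or hi < 0)})
    out = pd.DataFrame(table).sort_values("sum_weights", ascending=False,
                                          kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# MLH vs SLH variance decomposition (F-ratio test)
# ---------------------------------------------------------------------------

def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def mlh_vs_slh_ftest(y, base_X, mlh, slh_normalized) -> tuple[float, int, int, float]:
    """Does replacing multilocus heterozygosity by all single-locus terms help?

    Linear models of the 0/1 outcome: (base covariates + MLH) vs (base
    covariates + all L normalized SLH columns). Returns (F, df1, df2, p) with
    F = [(RSS_MLH - RSS_SLH)/(L-1)] / [RSS_SLH/(n - p_base - L - 1)], where
    p_base counts the base covariates (the intercept is added here).
    """
    y = np.asarray(y, dtype=float).ravel()
    base_X = np.atleast_2d(np.asarray(base_X, dtype=float))
    if base_X.shape[0] != len(y):
        base_X = base_X.T
    mlh = np.asarray(mlh, dtype=float).ravel()
    S = np.atleast_2d(np.asarray(slh_normalized, dtype=float))
    n = len(y)
    L = S.shape[1]
    if L < 2:
        raise ValueError("need >= 2 single-locus columns (df1 would be 0)")
    p_base = base_X.shape[1]
    if n <= p_base + L + 1:
        raise ValueError("too few observations for the SLH model")
    ones = np.ones((n, 1))
    rss_mlh = _ols_rss(y, np.hstack([ones, base_X, mlh[:, None]]))
    rss_slh = _ols_rss(y, np.hstack([ones, base_X, S]))
    if rss_slh <= 1e-12:
        raise ValueError("saturated SLH fit: residual sum of squares is zero")
    df1 = L - 1
    df2 = n - p_base - L - 1
    F = ((rss_mlh - rss_slh) / df1) / (rss_slh / df2)
    p = float(stats.f.sf(max(F, 0.0), df1, df2))
    return float(F), df1, df2, p
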