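"""Multilevel inference for clustered momentary-affect data.

Observations (momentary states) are nested in participants; participants in
groups.  This module provides the two-level machinery the analysis needs:

* method-of-moments (one-way ANOVA) variance components and the intraclass
  correlation tau^2 / (tau^2 + sigma^2);
* the inverse-variance pooled mean, weighting each participant's mean by
  1 / (tau^2 + sigma^2 / n_j) so that even single-observation participants
  contribute;
* a random-intercept logistic model with a group fixed effect, maximum
  likelihood via adaptive Gauss-Hermite quadrature, Wald intervals computed
  on the logit scale and back-transformed (hence asymmetric probability
  CIs);
* deviance (likelihood-ratio) comparison of nested fits against the
  chi-squared reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats
from scipy.special import expit, logsumexp

DEFAULT_QUAD_NODES = 15
_LOG_SIGMA_BOUNDS = (-8.0, 4.0)


class SeparationError(RuntimeError):
    """The likelihood is unbounded: a covariate separates the outcome."""


class ConvergenceError(RuntimeError):
    """The optimizer failed; the message carries the solver trace."""


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_within: float
    tau2_between: float

    @property
    def icc(self) -> float:
        total = self.tau2_between + self.sigma2_within
        if total == 0:
            return 0.0  # degenerate constant data: ICC undefined -> 0 by convention
        return self.tau2_between / total


@dataclass(frozen=True)
class MlmFit:
    """A fitted random-intercept logistic model."""

    coef: dict[str, float]
    se: dict[str, float]
    tau2: float
    deviance: float
    n_params: int
    n_obs: int
    n_clusters: int
    vcov: np.ndarray
    coef_names: tuple[str, ...]

    @property
    def loglik(self) -> float:
        return -0.5 * self.deviance


def variance_components(values, clusters) -> VarianceComponents:
    """One-way ANOVA estimates of within/between variance, truncated at 0."""
    values = np.asarray(values, dtype=float)
    clusters = np.asarray(clusters)
    ids, idx = np.unique(clusters, return_inverse=True)
    J = len(ids)
    if J < 2:
        raise ValueError("between-cluster variance needs at least 2 clusters")
    N = len(values)
    n_j = np.bincount(idx)
    sums = np.bincount(idx, weights=values)
    means = sums / n_j
    grand = values.mean()

    ssw = float(np.sum((values - means[idx]) ** 2))
    ssb = float(np.sum(n_j * (means - grand) ** 2))
    msw = ssw / (N - J) if N > J else 0.0
    msb = ssb / (J - 1)
    n0 = (N - np.sum(n_j**2) / N) / (J - 1)
    tau2 = max(0.0, (msb - msw) / n0)
    return VarianceComponents(sigma2_within=msw, tau2_between=tau2)


def pooled_mean(
    cluster_means, cluster_sizes, components: VarianceComponents
) -> tuple[float, float]:
    """Inverse-variance weighted mean of cluster means, with its SE.

    weight_j = 1 / (tau^2 + sigma^2 / n_j): large clusters dominate when the
    between-cluster variance is small, and every cluster counts — including
    those with a single observation.
    """
    means = np.asarray(cluster_means, dtype=float)
    sizes = np.asarray(cluster_sizes, dtype=float)
    var_j = components.tau2_between + components.sigma2_within / sizes
    if np.any(var_j <= 0):
        # constant data: all cluster means identical
        return float(means.mean()), 0.0
    w = 1.0 / var_j
    est = float(np.sum(w * means) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return est, se


# ---------------------------------------------------------------------------
# Random-intercept logistic regression (adaptive Gauss-Hermite ML)


def _cluster_loglik(eta, y, cluster_idx, n_clusters, sigma, nodes, weights):
    """Per-cluster marginal log-likelihoods by adaptive GH quadrature."""
    # mode of h_j(b) = sum_i [y eta_b - log(1+e^{eta_b})] - b^2/(2 sigma^2)
    b = np.zeros(n_clusters)
    inv_s2 = 1.0 / (sigma * sigma)
    for _ in range(30):
        p = expit(eta + b[cluster_idx])
        grad = np.bincount(cluster_idx, weights=y - p, minlength=n_clusters) - b * inv_s2
        curv = np.bincount(cluster_idx, weights=p * (1 - p), minlength=n_clusters) + inv_s2
        step = grad / curv
        b += np.clip(step, -5.0, 5.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(eta + b[cluster_idx])
    curv = np.bincount(cluster_idx, weights=p * (1 - p), minlength=n_clusters) + inv_s2
    scale = np.sqrt(2.0 / curv)  # per-cluster node spread

    log_terms = np.empty((len(nodes), n_clusters))
    log_norm = -0.5 * np.log(2 * np.pi) - np.log(sigma)
    for q, (z, w) in enumerate(zip(nodes, weights)):
        bq = b + scale * z
        eta_b = eta + bq[cluster_idx]
        ll_obs = y * eta_b - np.logaddexp(0.0, eta_b)
        h = (
            np.bincount(cluster_idx, weights=ll_obs, minlength=n_clusters)
            - 0.5 * bq * bq * inv_s2
            + log_norm
        )
        log_terms[q] = np.log(w) + z * z + h
    return np.log(scale) + logsumexp(log_terms, axis=0)


def _nll(params, X, y, cluster_idx, n_clusters, nodes, weights):
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    return -float(
        np.sum(_cluster_loglik(eta, y, cluster_idx, n_clusters, sigma, nodes, weights))
    )


def _numerical_hessian(fun, x0, eps=1e-4):
    k = len(x0)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            H[i, j] = H[j, i] = (
                fun(x0 + ei + ej) - fun(x0 + ei - ej) - fun(x0 - ei + ej) + fun(x0 - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_logistic_mixed_design(
    y,
    X,
    clusters,
    coef_names=None,
    n_quad: int = DEFAULT_QUAD_NODES,
    tol: float = 1e-8,
) -> MlmFit:
    """ML fit of a random-intercept logistic model with design matrix X."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    ids, cluster_idx = np.unique(np.asarray(clusters), return_inverse=True)
    n_clusters = len(ids)
    k = X.shape[1]
    coef_names = tuple(coef_names or (f"b{i}" for i in range(k)))

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    # start from the pooled logistic solution (tau^2 = 0 corner)
    beta0 = np.zeros(k)
    rate = y.mean()
    if 0 < rate < 1 and np.allclose(X[:, 0], 1.0):
        beta0[0] = np.log(rate / (1 - rate))
    x0 = np.concatenate([beta0, [np.log(0.3)]])

    args = (X, y, cluster_idx, n_clusters, nodes, weights)
    res = scipy.optimize.minimize(
        _nll, x0, args=args, method="L-BFGS-B",
        bounds=[(None, None)] * k + [_LOG_SIGMA_BOUNDS],
        options={"maxiter": 500, "ftol": tol, "gtol": 1e-7},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise ConvergenceError(f"mixed-model fit failed: {res.message}")
    if np.any(np.abs(res.x[:-1]) > 15):
        raise SeparationError(
            "a fixed-effect estimate diverged; the outcome is likely separated"
        )

    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    deviance = 2.0 * float(res.fun)

    H = _numerical_hessian(lambda p: _nll(p, *args), res.x)
    try:
        vcov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_full = np.linalg.pinv(H)
    vcov = vcov_full[:k, :k]
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))

    return MlmFit(
        coef=dict(zip(coef_names, beta.tolist())),
        se=dict(zip(coef_names, se.tolist())),
        tau2=sigma * sigma,
        deviance=deviance,
        n_params=k + 1,
        n_obs=len(y),
        n_clusters=n_clusters,
        vcov=vcov,
        coef_names=coef_names,
    )


def fit_logistic_mixed(
    outcome,
    group,
    cluster,
    n_quad: int = DEFAULT_QUAD_NODES,
) -> MlmFit:
    """Random-intercept logistic model of a binary outcome on a group factor.

    Treatment coding with the alphabetically first group as reference; pass
    ``group=None`` for the intercept-only (null) model.
    """
    y = np.asarray(outcome, dtype=float)
    if group is None:
        X = np.ones((len(y), 1))
        names = ("intercept",)
    else:
        group = np.asarray(group)
        levels = np.unique(group)
        if len(levels) < 2:
            raise ValueError("need at least 2 groups (or pass group=None)")
        X = np.column_stack(
            [np.ones(len(y))] + [(group == g).astype(float) for g in levels[1:]]
        )
        names = ("intercept",) + tuple(f"group[{g}]" for g in levels[1:])
    return fit_logistic_mixed_design(y, X, cluster, names, n_quad=n_quad)


def group_probabilities(fit: MlmFit, alpha: float = 0.05) -> dict[str, tuple[float, float, float]]:
    """Per-group probabilities with Wald CIs on the logit scale.

    Returns {group: (estimate, lower, upper)}; back-transforming the logit
    interval yields the asymmetric probability intervals reported for group
    rates.  Probabilities are at the cluster median (random intercept = 0).
    """
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    names = fit.coef_names
    out = {}
    intercept_idx = 0
    for i, name in enumerate(names):
        if name == "intercept":
            contrast = np.zeros(len(names))
            contrast[intercept_idx] = 1.0
            label = "reference"
        else:
            contrast = np.zeros(len(names))
            contrast[intercept_idx] = 1.0
            contrast[i] = 1.0
            label = name[len("group["):-1] if name.startswith("group[") else name
        eta = float(contrast @ np.array([fit.coef[n] for n in names]))
        var = float(contrast @ fit.vcov @ contrast)
        half = z * np.sqrt(max(var, 0.0))
        out[label] = (float(expit(eta)), float(expit(eta - half)), float(expit(eta + half)))
    return out


def deviance_compare(fit0: MlmFit, fit1: MlmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, df, p-value).

    The deviance drop from the simpler to the richer model is referred to a
    chi-squared distribution with the parameter-count difference as degrees
    of freedom.
    """
    df = fit1.n_params - fit0.n_params
    if df < 1:
        raise ValueError("fit1 must have more parameters than fit0")
    stat = fit0.deviance - fit1.deviance
    if stat < 0:
        warnings.warn(
            "negative deviance difference: the richer model fit worse "
            "(non-convergence suspected)", RuntimeWarning,
        )
        stat = 0.0
    p = float(scipy.stats.chi2.sf(stat, df))
    return float(stat), df, p
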