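"""Random-effects meta-analysis and meta-regression primitives.

Everything downstream (the two-step meta-epidemiological pipeline) is
built on four operations:

* :func:`estimate_tau2` — between-study variance by DerSimonian–Laird
  moments or restricted maximum likelihood;
* :func:`pool_random_effects` — inverse-variance pooling under the
  random-effects model, with Cochran's Q and I²;
* :func:`meta_regress_binary` — weighted least squares of effect sizes
  on a binary moderator with residual heterogeneity, whose slope is the
  difference in SMD between the two groups;
* :func:`robust_se` — cluster-robust (sandwich) standard error of that
  slope with the CR2 small-sample correction and Satterthwaite degrees
  of freedom, for arms nested in studies.

All functions take plain sequences/arrays; no DataFrame enters this
module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    InsufficientClustersError,
    InsufficientDataError,
    NoContrastError,
    ValidationError,
)

__all__ = [
    "PooledEstimate",
    "RegressionEstimate",
    "RobustVariance",
    "estimate_tau2",
    "pool_random_effects",
    "meta_regress_binary",
    "robust_se",
]


@dataclass(frozen=True)
class PooledEstimate:
    """Random-effects pooled estimate with heterogeneity statistics.

    ``q_stat`` and ``i2`` use fixed-effect (1/v) weights; ``i2`` is on
    the percent scale, ``max(0, (Q - df)/Q) * 100``.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q_stat: float
    df: int
    i2: float
    k: int
    method: str = "REML"
    ci_method: str = "wald"


@dataclass(frozen=True)
class RegressionEstimate:
    """Result of a random-effects meta-regression on one binary moderator.

    ``slope`` is the mean difference in effect size between the group
    coded 1 and the group coded 0 (in meta-epidemiological use: high or
    unclear risk of bias minus low risk, i.e. the DMSD).
    """

    intercept: float
    slope: float
    se_slope: float
    tau2_residual: float
    robust: bool = False
    df: float = float("nan")


@dataclass(frozen=True)
class RobustVariance:
    """Cluster-robust standard error of the moderator slope."""

    se: float
    df: float
    n_clusters: int
    cr_type: str = "CR2"


def _check_inputs(y: np.ndarray, v: np.ndarray) -> None:
    if len(y) != len(v):
        raise ValidationError("effects and variances differ in length")
    if len(y) < 2:
        raise InsufficientDataError(
            f"need at least 2 effects, got {len(y)}"
        )
    if np.any(v < 0):
        raise ValidationError("negative variance supplied")
    if np.all(v == 0):
        raise ValidationError("all sampling variances are zero")
    if np.any(v == 0):
        raise ValidationError("zero sampling variance supplied")


def _dl_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Method-of-moments (DerSimonian–Laird) tau², generalised to a
    design matrix X (Raudenbush's estimator; with X = 1 it reduces to
    the classic DL formula)."""
    w = 1.0 / v
    W = np.diag(w)
    xtwx = X.T @ W @ X
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ (X.T @ (w * y))
    resid = y - X @ beta
    q_e = float(np.sum(w * resid**2))
    n, p = X.shape
    # trace(P) with P = W - W X (X'WX)^-1 X'W
    trace_p = float(np.sum(w) - np.trace(xtwx_inv @ (X.T @ np.diag(w**2) @ X)))
    if trace_p <= 0:
        return 0.0
    return max(0.0, (q_e - (n - p)) / trace_p)


def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    xtwx = X.T @ (X * w[:, None])
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta
    sign, logdet = np.linalg.slogdet(xtwx)
    return float(
        np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid**2)
    )


def _reml_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """REML tau²: bounded scalar minimisation of the restricted negative
    log-likelihood on [0, 10 * var(y)], deterministic."""
    var_y = float(np.var(y))
    if var_y == 0.0:
        return 0.0
    upper = 10.0 * var_y
    res = optimize.minimize_scalar(
        _reml_nll,
        bounds=(0.0, upper),
        args=(y, v, X),
        method="bounded",
        options={"xatol": 1e-8},
    )
    tau2 = float(res.x)
    # the bounded optimiser never lands exactly on 0; snap when the
    # boundary is at least as good
    if _reml_nll(0.0, y, v, X) <= res.fun:
        tau2 = 0.0
    return max(0.0, tau2)


def _tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray, method: str) -> float:
    method = method.upper()
    if method == "DL":
        return _dl_tau2(y, v, X)
    if method == "REML":
        return _reml_tau2(y, v, X)
    raise ValidationError(f"unknown tau2 method {method!r}")


def estimate_tau2(effects, variances, method: str = "REML") -> float:
    """Between-study variance tau² of a set of effects.

    DL is the closed-form moments estimator
    ``max(0, (Q - df) / C)`` with ``C = sum(w) - sum(w^2)/sum(w)``;
    REML maximises the restricted likelihood, truncated at zero.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    _check_inputs(y, v)
    X = np.ones((len(y), 1))
    return _tau2(y, v, X, method)


def pool_random_effects(
    effects,
    variances,
    method: str = "REML",
    ci_method: str = "wald",
    level: float = 0.95,
    tau2: float | None = None,
) -> PooledEstimate:
    """Random-effects pooled estimate of a set of effects.

    Weights are ``1 / (v_i + tau2)``. Q and I² are computed with
    fixed-effect weights regardless of ``tau2``. ``ci_method`` is
    ``"wald"`` (normal quantile) or ``"knapp_hartung"`` (t quantile with
    the Hartung–Knapp variance rescaling). ``tau2`` may be supplied to
    bypass estimation (used by tests and sensitivity analyses).
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    _check_inputs(y, v)
    k = len(y)

    w_fe = 1.0 / v
    mu_fe = float(np.sum(w_fe * y) / np.sum(w_fe))
    q = float(np.sum(w_fe * (y - mu_fe) ** 2))
    df = k - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0

    if tau2 is None:
        tau2 = _tau2(y, v, np.ones((k, 1)), method)
    w = 1.0 / (v + tau2)
    est = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))

    if ci_method == "wald":
        crit = stats.norm.ppf(0.5 + level / 2.0)
        ci_se = se
    elif ci_method == "knapp_hartung":
        s2 = float(np.sum(w * (y - est) ** 2) / (df * np.sum(w)))
        ci_se = float(np.sqrt(s2))
        crit = stats.t.ppf(0.5 + level / 2.0, df)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    return PooledEstimate(
        estimate=est,
        se=se,
        ci_low=est - crit * ci_se,
        ci_high=est + crit * ci_se,
        tau2=float(tau2),
        q_stat=q,
        df=df,
        i2=i2,
        k=k,
        method=method,
        ci_method=ci_method,
    )


def _binary_design(labels) -> np.ndarray:
    lab = np.asarray(labels, dtype=float)
    if not set(np.unique(lab)) <= {0.0, 1.0}:
        raise ValidationError("labels must be coded 0/1")
    if len(np.unique(lab)) < 2:
        raise NoContrastError("moderator takes a single value")
    return np.column_stack([np.ones(len(lab)), lab])


def _wls(y, v, X, tau2):
    w = 1.0 / (v + tau2)
    xtwx = X.T @ (X * w[:, None])
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    cov = np.linalg.inv(xtwx)
    return beta, cov, w


def meta_regress_binary(
    effects,
    variances,
    labels,
    method: str = "REML",
    tau2: float | None = None,
) -> RegressionEstimate:
    """Random-effects meta-regression of effects on a binary moderator.

    Fits ``y_i = b0 + b1 * label_i + u_i + e_i`` by weighted least
    squares with weights ``1/(v_i + tau2_residual)``; the residual
    heterogeneity ``tau2_residual`` is estimated by ``method`` unless
    supplied. The slope ``b1`` is the mean difference in effect size
    between group 1 and group 0 (the DMSD when labels encode
    high/unclear vs low risk of bias).
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    _check_inputs(y, v)
    if len(y) < 3:
        raise InsufficientDataError(
            f"meta-regression needs >= 3 observations, got {len(y)}"
        )
    X = _binary_design(labels)
    if len(labels) != len(y):
        raise ValidationError("labels and effects differ in length")
    if tau2 is None:
        tau2 = _tau2(y, v, X, method)
    beta, cov, _ = _wls(y, v, X, tau2)
    return RegressionEstimate(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_slope=float(np.sqrt(cov[1, 1])),
        tau2_residual=float(tau2),
        robust=False,
        df=float(len(y) - 2),
    )


def _inv_sqrt_sym(a: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition, with
    eigenvalues floored at a small positive value for stability."""
    vals, vecs = np.linalg.eigh(a)
    vals = np.maximum(vals, 1e-12)
    return (vecs / np.sqrt(vals)) @ vecs.T


def robust_se(
    effects,
    variances,
    labels,
    cluster_ids,
    method: str = "REML",
    tau2: float | None = None,
    cr_type: str = "CR2",
) -> RobustVariance:
    """Cluster-robust standard error of the binary-moderator slope.

    The sandwich estimator is computed on the weight-transformed scale
    (the working model treats ``1/(v_i + tau2)`` as inverse variances,
    so pre-multiplying by ``sqrt(w)`` reduces the problem to OLS).
    ``CR2`` applies the bias-reduced adjustment
    ``A_j = (I - H_jj)^{-1/2}`` per cluster and reports Satterthwaite
    degrees of freedom; ``CR0`` is the unadjusted sandwich and ``CR1``
    the ``J/(J-1)`` rescaling, both with ``J - 1`` df.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    _check_inputs(y, v)
    X = _binary_design(labels)
    clusters = np.asarray(cluster_ids)
    if len(clusters) != len(y):
        raise ValidationError("cluster_ids and effects differ in length")
    unique = np.unique(clusters)
    n_clusters = len(unique)
    if n_clusters < 2:
        raise InsufficientClustersError(
            f"need >= 2 clusters, got {n_clusters}"
        )

    if tau2 is None:
        tau2 = _tau2(y, v, X, method)
    w = 1.0 / (v + tau2)
    sw = np.sqrt(w)
    U = X * sw[:, None]          # transformed design
    z = y * sw                   # transformed response
    M = np.linalg.inv(U.T @ U)
    beta = M @ (U.T @ z)
    e_t = z - U @ beta           # transformed residuals
    c = np.array([0.0, 1.0])     # slope contrast

    cr_type = cr_type.upper()
    if cr_type not in {"CR0", "CR1", "CR2"}:
        raise ValidationError(f"unknown robust type {cr_type!r}")

    n = len(y)
    idx_by_cluster = [np.flatnonzero(clusters == g) for g in unique]

    meat = 0.0
    ell_list = []
    for idx in idx_by_cluster:
        Uj = U[idx]
        if cr_type == "CR2":
            Hjj = Uj @ M @ Uj.T
            Aj = _inv_sqrt_sym(np.eye(len(idx)) - Hjj)
        else:
            Aj = np.eye(len(idx))
        ell = Aj @ (Uj @ (M @ c))        # n_j vector
        ell_list.append((idx, ell))
        meat += float(ell @ e_t[idx]) ** 2

    if cr_type == "CR1":
        meat *= n_clusters / (n_clusters - 1)

    se = float(np.sqrt(meat))

    if cr_type == "CR2":
        # Satterthwaite df under the working model Var(z) = sigma^2 I:
        # each cluster contributes b_j = (I - H)'[, j-rows] ell_j
        H = U @ M @ U.T
        I_H = np.eye(n) - H
        B = np.empty((n, n_clusters))
        for j, (idx, ell) in enumerate(ell_list):
            B[:, j] = I_H[idx, :].T @ ell
        S = B.T @ B
        df = float(np.trace(S) ** 2 / np.sum(S**2))
    else:
        df = float(n_clusters - 1)

    return RobustVariance(se=se, df=df, n_clusters=n_clusters, cr_type=cr_type)
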