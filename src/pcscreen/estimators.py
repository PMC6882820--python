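"""Base sparse-GGM estimators for a fixed regularization value.

Four first-stage estimators of a partial correlation network:

* :func:`fit_glasso` — l1-penalized maximum likelihood for the precision
  matrix (graphical lasso),
* :func:`fit_nodewise_lasso` — p separate lasso regressions whose supports
  define neighborhoods, reconciled with an AND or OR rule,
* :func:`fit_space` — joint sparse regression with a single shared
  partial-correlation parameter per pair (SPACE), and
* :func:`fit_ridge_nodewise` — p separate ridge regressions (closed form,
  no exact zeros: the resulting network is complete).

Each returns a small fit object; :func:`estimate_network` wraps them into
a common (Gamma, EdgeSet) interface used by tuning and screening.

Objective scalings
------------------
The nodewise lasso and ridge losses are taken per observation
(``1/(2n) ||X_i - X beta||^2``, the glmnet convention), which makes the
regularization grids and the finite-sample penalty level directly
comparable across sample sizes.  SPACE uses the unscaled joint loss
``1/2 sum_i ||X_i - ...||^2``; its sqrt(n)-scaled lambda grid is defined
against that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .core import (
    EDGE_TOL,
    EdgeSet,
    edge_set,
    precision_to_partial,
    regression_to_partial,
    validate_covariance,
)

__all__ = [
    "GlassoFit",
    "NodewiseFit",
    "SpaceFit",
    "RidgeFit",
    "FirstStageFit",
    "fit_glasso",
    "fit_nodewise_lasso",
    "fit_space",
    "fit_ridge_nodewise",
    "estimate_network",
    "space_objective",
    "METHODS",
]

METHODS = ("glasso", "space", "nr-and", "nr-or", "ridge")


@dataclass
class GlassoFit:
    omega: np.ndarray
    lambda1: float
    loglik: float  # -(tr(S Omega) - log det Omega), up to the Gaussian constant

    def partial_correlations(self) -> np.ndarray:
        return precision_to_partial(self.omega)


@dataclass
class NodewiseFit:
    beta: np.ndarray  # beta[i, j]: weight of X_j in the regression of X_i
    resid_var: np.ndarray
    lambda2: np.ndarray  # per-node penalty actually used

    def partial_correlations(self) -> np.ndarray:
        return regression_to_partial(self.beta, self.resid_var)


@dataclass
class SpaceFit:
    gamma: np.ndarray  # symmetric, unit diagonal
    omega_diag: np.ndarray  # precision diagonal = inverse residual variances
    lambda3: float
    objective: float
    n_iter: int
    converged: bool


@dataclass
class RidgeFit:
    delta: np.ndarray
    resid_var: np.ndarray
    lambda4: np.ndarray

    def partial_correlations(self) -> np.ndarray:
        """Symmetrized one-sided estimates rho_ij = delta_ij * sqrt(v_j / v_i).

        Each regression gives its own estimate of rho_ij through the
        prediction-error relation; the two are averaged.  Unlike the signed
        geometric mean this never produces spurious exact zeros on
        discordant-sign pairs, so the ridge network is complete with
        probability one — exact zeros are not in the nature of an l2
        penalty.
        """
        v = self.resid_var
        if np.any(v <= 0):
            raise ValueError("non-positive residual variance")
        ratio = np.sqrt(np.outer(1.0 / v, v))  # ratio[i, j] = sqrt(v_j / v_i)
        gamma = 0.5 * (self.delta * ratio + (self.delta * ratio).T)
        off = ~np.eye(len(v), dtype=bool)
        gamma[off] = np.clip(gamma[off], -1.0, 1.0)
        np.fill_diagonal(gamma, 1.0)
        return gamma


@dataclass
class FirstStageFit:
    """Common wrapper: any base estimator reduced to (Gamma, edges)."""

    method: str
    lam: object  # scalar (glasso/space) or per-node array (nr/ridge)
    gamma: np.ndarray
    edges: EdgeSet
    fit: object = field(repr=False)


# ---------------------------------------------------------------------------
# graphical lasso


def fit_glasso(
    S: np.ndarray,
    lambda1: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> GlassoFit:
    """Penalized ML precision estimate: min tr(S Omega) - log det Omega + lambda1 * sum_{i!=j} |omega_ij|.

    Only off-diagonal entries are penalized, so full shrinkage
    (lambda1 >= max off-diagonal |S_ij|) returns a diagonal Omega.
    """
    S = validate_covariance(S)
    if lambda1 <= 0:
        raise ValueError("lambda1 must be positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            _, omega = graphical_lasso(S, alpha=float(lambda1), tol=tol, max_iter=max_iter)
        except FloatingPointError as err:  # numerical failure deep in the solver
            raise RuntimeError(f"graphical lasso failed at lambda1={lambda1:g}: {err}") from err
    omega = 0.5 * (omega + omega.T)
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise RuntimeError(f"graphical lasso returned a non-PD precision at lambda1={lambda1:g}")
    loglik = logdet - float(np.sum(S * omega))
    return GlassoFit(omega=omega, lambda1=float(lambda1), loglik=loglik)


def gaussian_loglik(S: np.ndarray, omega: np.ndarray, n: int) -> float:
    """Full Gaussian log-likelihood of n centered observations at Omega."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - float(np.sum(S * omega)) - p * np.log(2 * np.pi))


# ---------------------------------------------------------------------------
# nodewise lasso


def _lasso_path_node(X: np.ndarray, i: int, lambdas: np.ndarray) -> np.ndarray:
    """Lasso weights of node i on the rest for each penalty (per-sample scale).

    Returns an array of shape (len(lambdas), p) with a zero at column i.
    Warm-started from large to small penalties.
    """
    n, p = X.shape
    others = [j for j in range(p) if j != i]
    Xo, y = X[:, others], X[:, i]
    order = np.argsort(lambdas)[::-1]
    out = np.zeros((len(lambdas), p))
    model = Lasso(alpha=1.0, fit_intercept=False, warm_start=True, max_iter=5000, tol=1e-6)
    for idx in order:
        model.set_params(alpha=float(lambdas[idx]))
        model.fit(Xo, y)
        out[idx, others] = model.coef_
    return out


def fit_nodewise_lasso(
    X: np.ndarray,
    lambda2: np.ndarray | float,
    rule: str = "and",
    edge_tol: float = EDGE_TOL,
) -> tuple[NodewiseFit, EdgeSet]:
    """p separate lasso regressions; edges from the AND or OR support rule.

    ``lambda2`` is the per-observation l1 penalty (scalar or one value per
    node).  Edge (i, j) is kept iff both beta_ij and beta_ji are non-zero
    (AND) or at least one is (OR).  Partial correlations are the signed
    geometric means of concordant weight pairs, so OR-only edges carry a
    zero partial correlation.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    n, p = X.shape
    lam = np.broadcast_to(np.asarray(lambda2, dtype=float), (p,))
    if np.any(lam <= 0):
        raise ValueError("lambda2 must be positive")
    beta = np.zeros((p, p))
    model = Lasso(alpha=1.0, fit_intercept=False, max_iter=5000, tol=1e-6)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        model.set_params(alpha=float(lam[i]))
        model.fit(X[:, others], X[:, i])
        beta[i, others] = model.coef_
    resid = X - X @ beta.T
    resid_var = (resid**2).mean(axis=0)
    fit = NodewiseFit(beta=beta, resid_var=resid_var, lambda2=np.array(lam))
    edges = _support_rule_edges(beta, rule, edge_tol)
    return fit, edges


def _support_rule_edges(beta: np.ndarray, rule: str, tol: float) -> EdgeSet:
    nz = np.abs(beta) > tol
    joint = (nz & nz.T) if rule == "and" else (nz | nz.T)
    iu, ju = np.triu_indices(beta.shape[0], k=1)
    mask = joint[iu, ju]
    return EdgeSet(frozenset(zip(iu[mask].tolist(), ju[mask].tolist())), beta.shape[0])


# ---------------------------------------------------------------------------
# SPACE


def space_objective(X: np.ndarray, gamma: np.ndarray, omega_diag: np.ndarray, lambda3: float) -> float:
    """Joint loss 1/2 sum_i ||X_i - sum_j rho_ij sqrt(w_j/w_i) X_j||^2 + lambda3 sum_{i<j} |rho_ij|."""
    n, p = X.shape
    C = _space_weights(gamma, omega_diag)
    R = X - X @ C.T
    iu, ju = np.triu_indices(p, k=1)
    return 0.5 * float((R**2).sum()) + lambda3 * float(np.abs(gamma[iu, ju]).sum())


def _space_weights(gamma: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Prediction weights C[i, j] = rho_ij sqrt(w_j / w_i), zero diagonal."""
    s = np.sqrt(w)
    C = gamma * np.outer(1.0 / s, s)
    np.fill_diagonal(C, 0.0)
    return C


def fit_space(
    X: np.ndarray,
    lambda3: float,
    max_outer: int = 50,
    max_inner: int = 100,
    tol: float = 1e-6,
    gamma_init: np.ndarray | None = None,
    omega_init: np.ndarray | None = None,
) -> SpaceFit:
    """SPACE: joint sparse regression with shared rho_ij parameters.

    Alternates (a) active-set coordinate descent on the rho_ij (each update
    a soft-threshold of residual inner products aggregated over both
    regressions i->j and j->i) with (b) re-estimation of the precision
    diagonal omega_ii as inverse residual variances.  All inner products
    are carried on the Gram matrix, so one sweep costs O(p^3) independent
    of n.  Initialization: rho = 0, omega_ii = 1/var(X_i).
    """
    if lambda3 < 0:
        raise ValueError("lambda3 must be non-negative")
    n, p = X.shape
    G = X.T @ X
    gram_d = np.diag(G).copy()
    w = omega_init.copy() if omega_init is not None else n / gram_d
    rho = gamma_init.copy() if gamma_init is not None else np.zeros((p, p))
    np.fill_diagonal(rho, 0.0)

    iu, ju = np.triu_indices(p, k=1)
    obj_prev = np.inf
    n_outer = 0
    converged = False
    for n_outer in range(1, max_outer + 1):
        rho = _space_cd(G, rho, w, lambda3, max_inner, tol)
        C = _space_weights(rho, w)
        rss = gram_d - 2 * np.einsum("ij,ji->i", C, G) + np.einsum("ij,ij->i", C, C @ G)
        rss = np.maximum(rss, 1e-12)
        w = n / rss
        obj = 0.5 * float(rss.sum()) + lambda3 * float(np.abs(rho[iu, ju]).sum())
        if abs(obj_prev - obj) <= tol * max(1.0, abs(obj)):
            converged = True
            obj_prev = obj
            break
        obj_prev = obj
    if not converged:
        warnings.warn(
            f"SPACE did not converge in {max_outer} outer iterations "
            f"(last objective {obj_prev:.6g})",
            RuntimeWarning,
        )
    gamma = rho.copy()
    np.fill_diagonal(gamma, 1.0)
    gamma = 0.5 * (gamma + gamma.T)
    return SpaceFit(
        gamma=gamma,
        omega_diag=w,
        lambda3=float(lambda3),
        objective=float(obj_prev),
        n_iter=n_outer,
        converged=converged,
    )


def _space_cd(
    G: np.ndarray,
    rho: np.ndarray,
    w: np.ndarray,
    lam: float,
    max_inner: int,
    tol: float,
) -> np.ndarray:
    """Coordinate descent on the shared rho parameters with omega fixed.

    Maintains M = C @ G (C the prediction-weight matrix) so each coordinate
    update is O(p).  Active-set strategy: after a full sweep, iterate on
    the current support until stable, then re-check all coordinates.
    """
    p = G.shape[0]
    s = np.sqrt(w)
    C = _space_weights(rho, w)
    M = C @ G  # M[i, k] = sum_j C_ij G_jk
    gd = np.diag(G)

    def update_pair(i: int, j: int) -> float:
        # coefficient of rho_ij: a_ij = sqrt(w_j/w_i) X_j in regression i,
        #                        a_ji = sqrt(w_i/w_j) X_i in regression j
        f_ij = s[j] / s[i]
        f_ji = s[i] / s[j]
        r_old = rho[i, j]
        # partial residual inner products (exclude the rho_ij terms)
        u = f_ij * (G[i, j] - (M[i, j] - r_old * f_ij * gd[j]))
        u += f_ji * (G[i, j] - (M[j, i] - r_old * f_ji * gd[i]))
        denom = f_ij**2 * gd[j] + f_ji**2 * gd[i]
        r_new = _soft(u, lam) / denom
        if r_new != r_old:
            d = r_new - r_old
            M[i, :] += d * f_ij * G[j, :]
            M[j, :] += d * f_ji * G[i, :]
            rho[i, j] = rho[j, i] = r_new
        return abs(r_new - r_old)

    pairs = list(zip(*np.triu_indices(p, k=1)))
    scale = max(1.0, np.abs(rho).max())
    for sweep in range(max_inner):
        max_delta = 0.0
        full = sweep == 0 or sweep % 5 == 4
        active = pairs if full else [(i, j) for (i, j) in pairs if rho[i, j] != 0.0]
        for i, j in active:
            max_delta = max(max_delta, update_pair(int(i), int(j)))
        if full and max_delta <= tol * scale:
            break
    return rho


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


# ---------------------------------------------------------------------------
# ridge


def fit_ridge_nodewise(X: np.ndarray, lambda4: np.ndarray | float) -> RidgeFit:
    """p separate ridge regressions, solved in closed form.

    Minimizes ``1/2 ||X_i - sum_j delta_ij X_j||^2 + lambda4_i sum_j delta_ij^2``
    per node, i.e. ``delta_i = (X'X + 2 lambda4_i I)^{-1} X' X_i`` over the
    remaining columns.  No exact zeros: the implied network is complete.
    """
    n, p = X.shape
    lam = np.broadcast_to(np.asarray(lambda4, dtype=float), (p,))
    if np.any(lam < 0):
        raise ValueError("lambda4 must be non-negative")
    G = X.T @ X
    delta = np.zeros((p, p))
    for i in range(p):
        others = [j for j in range(p) if j != i]
        A = G[np.ix_(others, others)] + 2.0 * lam[i] * np.eye(p - 1)
        b = G[others, i]
        try:
            delta[i, others] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular ridge system at node {i} (lambda4={lam[i]:g}, n={n}, p={p})"
            ) from err
    resid = X - X @ delta.T
    resid_var = (resid**2).mean(axis=0)
    return RidgeFit(delta=delta, resid_var=resid_var, lambda4=np.array(lam))


# ---------------------------------------------------------------------------
# common wrapper


def estimate_network(
    X: np.ndarray,
    method: str,
    lam: np.ndarray | float,
    edge_tol: float = EDGE_TOL,
    **kwargs,
) -> FirstStageFit:
    """Fit one base estimator at a fixed penalty and reduce it to (Gamma, edges).

    ``method`` is one of ``glasso``, ``space``, ``nr-and``, ``nr-or``,
    ``ridge``.  For the regression methods ``lam`` may be per-node.
    """
    n = X.shape[0]
    if method == "glasso":
        S = np.cov(X, rowvar=False, bias=True)
        fit = fit_glasso(S, float(lam), **kwargs)
        gamma = fit.partial_correlations()
        edges = edge_set(gamma, edge_tol)
    elif method == "space":
        fit = fit_space(X, float(lam), **kwargs)
        gamma = fit.gamma
        edges = edge_set(gamma, edge_tol)
    elif method in ("nr-and", "nr-or"):
        rule = method.split("-")[1]
        fit, edges = fit_nodewise_lasso(X, lam, rule=rule, edge_tol=edge_tol)
        # geometric-mean entries vanish off the AND support; OR-only edges
        # therefore carry a zero partial correlation
        gamma = fit.partial_correlations()
    elif method == "ridge":
        fit = fit_ridge_nodewise(X, lam)
        gamma = fit.partial_correlations()
        edges = edge_set(gamma, edge_tol)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return FirstStageFit(method=method, lam=lam, gamma=gamma, edges=edges, fit=fit)
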